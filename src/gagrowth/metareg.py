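"""Hierarchical Gamma meta-regression of forecast error (CRPS).

Per-forecast CRPS is modelled as Gamma with a log link: the linear predictor
has a fixed intercept per growth model, model-specific slopes for the
standardized forecast horizon and the standardized number of prior visits,
and random intercepts for patient and eye (non-centered).  Marginal effects
are reported as percent change in expected CRPS per 1 SD of the predictor
(exp(beta) - 1), and the probability of being best is the posterior
probability that a model has the lowest expected CRPS for a new forecast
(population intercepts, covariates at 0 SD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from ._sampler import SamplerConfig, run_hmc
from .errors import GagrowthError
from .scoring import ScoreRecord

__all__ = [
    "MetaRegressionSpec",
    "MetaPosterior",
    "fit_crps_regression",
    "marginal_effect",
    "probability_best",
]

META_SAMPLER = SamplerConfig(warmup=600, draws=400, max_store_draws=1500)


@dataclass(frozen=True)
class MetaRegressionSpec:
    """Response handling and standardization for the CRPS regression."""

    crps_floor: float = 1e-6  # Gamma support excludes 0
    horizon_sd: float | None = None  # None -> sample SD of the analysis data
    visits_sd: float | None = None


@dataclass
class MetaPosterior:
    """Coefficient and variance draws from the Gamma meta-regression."""

    models: tuple[str, ...]
    draws: dict[str, np.ndarray]  # beta0/beta_h/beta_v (S, M), tau_*, alpha (S,)
    horizon_sd: float
    visits_sd: float
    chain: np.ndarray
    meta: dict
    warnings: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.draws["alpha"].shape[0]


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        required = {"patient_id", "eye_id", "model", "horizon", "n_prior_visits", "crps"}
        missing = required - set(df.columns)
        if missing:
            raise GagrowthError(f"score table missing columns {sorted(missing)}")
        return df
    rows = [
        {
            "patient_id": r.eye_key[0],
            "eye_id": r.eye_key[1],
            "model": r.model,
            "horizon": r.horizon,
            "n_prior_visits": r.n_prior_visits,
            "crps": r.crps,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


class _GammaTarget:
    """Vectorized log-posterior of the Gamma GLMM over walker batches."""

    def __init__(self, y, m_idx, xh, xv, pat_idx, eye_idx, M, nP, nE, beta0_loc):
        self.y = y
        self.logy = np.log(y)
        self.m_idx = m_idx
        self.xh = xh
        self.xv = xv
        self.pat_idx = pat_idx
        self.eye_idx = eye_idx
        self.M, self.nP, self.nE = M, nP, nE
        self.beta0_loc = beta0_loc
        self.ndim = 3 * M + 3 + nP + nE
        n = y.size
        self.Imod = np.zeros((n, M))
        self.Imod[np.arange(n), m_idx] = 1.0
        self.Ipat = np.zeros((n, nP))
        self.Ipat[np.arange(n), pat_idx] = 1.0
        self.Ieye = np.zeros((n, nE))
        self.Ieye[np.arange(n), eye_idx] = 1.0

    def unpack(self, X):
        M, nP, nE = self.M, self.nP, self.nE
        b0 = X[:, :M]
        bh = X[:, M : 2 * M]
        bv = X[:, 2 * M : 3 * M]
        ltp = X[:, 3 * M]
        lte = X[:, 3 * M + 1]
        la = X[:, 3 * M + 2]
        zp = X[:, 3 * M + 3 : 3 * M + 3 + nP]
        ze = X[:, 3 * M + 3 + nP :]
        return b0, bh, bv, ltp, lte, la, zp, ze

    def logp_grad(self, X):
        """Log posterior and analytic gradient, vectorized over chains."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        C = X.shape[0]
        M, nP, nE = self.M, self.nP, self.nE
        b0, bh, bv, ltp, lte, la, zp, ze = self.unpack(X)
        grad = np.zeros_like(X)
        n = self.y.size
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp = np.zeros(C)
            lp += np.sum(-0.5 * ((b0 - self.beta0_loc) / 2.0) ** 2, axis=1)
            grad[:, :M] += -(b0 - self.beta0_loc) / 4.0
            lp += np.sum(-0.5 * bh**2, axis=1) + np.sum(-0.5 * bv**2, axis=1)
            grad[:, M : 2 * M] += -bh
            grad[:, 2 * M : 3 * M] += -bv
            tau_p = np.exp(ltp)
            tau_e = np.exp(lte)
            for i, (lt, tau) in enumerate(((ltp, tau_p), (lte, tau_e))):
                lp += -0.5 * (tau / 0.5) ** 2 + lt  # half-normal(0.5) + Jacobian
                grad[:, 3 * M + i] += -((tau / 0.5) ** 2) + 1.0
            lp += -0.5 * ((la - 0.5) / 1.5) ** 2  # lognormal shape prior
            grad[:, 3 * M + 2] += -(la - 0.5) / 1.5**2
            lp += -0.5 * np.sum(zp**2, axis=1) - 0.5 * np.sum(ze**2, axis=1)
            grad[:, 3 * M + 3 : 3 * M + 3 + nP] += -zp
            grad[:, 3 * M + 3 + nP :] += -ze

            eta = (
                b0[:, self.m_idx]
                + bh[:, self.m_idx] * self.xh[None, :]
                + bv[:, self.m_idx] * self.xv[None, :]
                + tau_p[:, None] * zp[:, self.pat_idx]
                + tau_e[:, None] * ze[:, self.eye_idx]
            )
            alpha = np.exp(la)[:, None]
            y_exp = self.y[None, :] * np.exp(-eta)
            ll = (
                alpha * (la[:, None] - eta)
                - gammaln(alpha)
                + (alpha - 1.0) * self.logy[None, :]
                - alpha * y_exp
            )
            lp += ll.sum(axis=1)

            gi = alpha * (y_exp - 1.0)  # dll/deta, (C, n)
            grad[:, :M] += gi @ self.Imod
            grad[:, M : 2 * M] += (gi * self.xh[None, :]) @ self.Imod
            grad[:, 2 * M : 3 * M] += (gi * self.xv[None, :]) @ self.Imod
            Gp = gi @ self.Ipat
            Ge = gi @ self.Ieye
            grad[:, 3 * M + 3 : 3 * M + 3 + nP] += tau_p[:, None] * Gp
            grad[:, 3 * M + 3 + nP :] += tau_e[:, None] * Ge
            grad[:, 3 * M] += tau_p * np.sum(Gp * zp, axis=1)
            grad[:, 3 * M + 1] += tau_e * np.sum(Ge * ze, axis=1)
            # shape: d ll / d log(alpha)
            dll_dalpha = (
                la[:, None] + 1.0 - eta - digamma(alpha) + self.logy[None, :] - y_exp
            )
            grad[:, 3 * M + 2] += (alpha * dll_dalpha).sum(axis=1)

            bad = ~np.isfinite(lp)
            lp = np.where(bad, -np.inf, lp)
            grad[bad] = 0.0
            grad[~np.isfinite(grad)] = 0.0
            return lp, grad

    def __call__(self, X):
        return self.logp_grad(X)[0]


def fit_crps_regression(
    records,
    spec: MetaRegressionSpec | None = None,
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
) -> MetaPosterior:
    """Fit the hierarchical Gamma CRPS regression; deterministic given seed."""
    spec = spec or MetaRegressionSpec()
    cfg = sampler_config or META_SAMPLER
    df = _records_frame(records)
    if (df["crps"] < 0).any():
        bad = df.index[df["crps"] < 0].tolist()
        raise GagrowthError(f"negative CRPS at rows {bad}")
    y = np.maximum(df["crps"].to_numpy(dtype=float), spec.crps_floor)

    models = tuple(sorted(df["model"].unique()))
    if len(models) < 2:
        raise GagrowthError("meta-regression needs >= 2 models to be identifiable")
    m_idx = df["model"].map({m: i for i, m in enumerate(models)}).to_numpy()

    h_sd = spec.horizon_sd or float(df["horizon"].std(ddof=1))
    v_sd = spec.visits_sd or float(df["n_prior_visits"].std(ddof=1))
    if not (h_sd > 0 and v_sd > 0):
        raise GagrowthError("horizon / visit-count SDs must be positive")
    xh = (df["horizon"] - df["horizon"].mean()).to_numpy() / h_sd
    xv = (df["n_prior_visits"] - df["n_prior_visits"].mean()).to_numpy() / v_sd

    patients = sorted(df["patient_id"].unique())
    eyes = sorted(set(zip(df["patient_id"], df["eye_id"])))
    pat_idx = df["patient_id"].map({p: i for i, p in enumerate(patients)}).to_numpy()
    eye_map = {k: i for i, k in enumerate(eyes)}
    eye_idx = np.array(
        [eye_map[(p, e)] for p, e in zip(df["patient_id"], df["eye_id"])]
    )

    beta0_loc = math.log(float(y.mean()))
    target = _GammaTarget(
        y, m_idx, xh, xv, pat_idx, eye_idx, len(models), len(patients), len(eyes),
        beta0_loc,
    )
    M = len(models)
    x0 = np.zeros(target.ndim)
    for i, m in enumerate(models):
        x0[i] = math.log(float(y[m_idx == i].mean()))
    x0[3 * M] = x0[3 * M + 1] = -1.5
    x0[3 * M + 2] = math.log(1.5)
    scale = np.full(target.ndim, 0.9)
    scale[: 3 * M] = 0.15
    scale[3 * M : 3 * M + 2] = 0.3
    scale[3 * M + 2] = 0.15
    bounds = (
        [(-12.0, 8.0)] * M
        + [(-5.0, 5.0)] * (2 * M)
        + [(-5.0, 1.5)] * 2
        + [(-3.0, 5.0)]
        + [(-6.0, 6.0)] * (target.nP + target.nE)
    )
    chain, stats = run_hmc(target, x0, scale, bounds, cfg, seed)

    steps, chains, ndim = chain.shape
    flat = chain.reshape(steps * chains, ndim)
    S = min(cfg.max_store_draws, flat.shape[0])
    sel = np.linspace(0, flat.shape[0] - 1, S).astype(int)
    b0, bh, bv, ltp, lte, la, zp, ze = target.unpack(flat[sel])
    draws = {
        "beta0": b0,
        "beta_h": bh,
        "beta_v": bv,
        "tau_patient": np.exp(ltp),
        "tau_eye": np.exp(lte),
        "alpha": np.exp(la),
        "z_patient": zp,
        "z_eye": ze,
    }
    warnings_list = []
    if stats["divergence_rate"] > 0.02:
        warnings_list.append(
            f"divergent transitions above tolerance "
            f"({100 * stats['divergence_rate']:.1f}%)"
        )
    return MetaPosterior(
        models=models,
        draws=draws,
        horizon_sd=h_sd,
        visits_sd=v_sd,
        chain=chain,
        meta={
            "seed": seed,
            "chains": cfg.chains,
            "warmup": cfg.warmup,
            "iterations": cfg.draws,
            **stats,
        },
        warnings=warnings_list,
    )


def marginal_effect(
    post: MetaPosterior, predictor: str, delta_in_sd: float = 1.0
) -> pd.DataFrame:
    """Percent change in expected CRPS per ``delta_in_sd`` SDs of a predictor."""
    key = {"horizon": "beta_h", "visits": "beta_v"}.get(predictor)
    if key is None:
        raise GagrowthError(f"unknown predictor {predictor!r}; use 'horizon' or 'visits'")
    beta = post.draws[key]  # (S, M)
    pct = (np.exp(beta * delta_in_sd) - 1.0) * 100.0
    lo, med, hi = np.percentile(pct, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "model": post.models,
            "predictor": predictor,
            "delta_in_sd": delta_in_sd,
            "pct_change_mean": pct.mean(axis=0),
            "pct_change_median": med,
            "pct_change_lo": lo,
            "pct_change_hi": hi,
        }
    )


def probability_best(post: MetaPosterior) -> dict[str, float]:
    """Posterior probability each model has the lowest expected CRPS (new forecast)."""
    mu = np.exp(post.draws["beta0"])  # (S, M): covariates at 0 SD, effects at 0
    best = mu == mu.min(axis=1, keepdims=True)
    probs = (best / best.sum(axis=1, keepdims=True)).mean(axis=0)
    return {m: float(p) for m, p in zip(post.models, probs)}
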