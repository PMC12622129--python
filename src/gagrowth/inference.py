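"""Hierarchical Bayesian estimation of growth models over a cohort.

The observation model is Gaussian on the model's fit scale (lesion area in
mm^2, or sqrt-area for the effective-radius law) with a single shared noise
sd.  Each transformed growth parameter receives patient-level and
eye-within-patient random effects:

    theta_eye = mu + tau_patient * z_patient[pat(eye)] + tau_eye * z_eye[eye]

sampled non-centered by default (sparse per-eye series make the centered
geometry pathological).  Sampling uses the shared ensemble-MCMC engine; the
walker ensemble is partitioned into groups reported as chains for
split-R-hat / ESS diagnostics.

Pointwise log-likelihoods are evaluated on the *area* scale for every model
(the sqrt-area fit gets the change-of-variables Jacobian) so that PSIS-LOO
and pseudo-BMA+ compare densities of the same observable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._sampler import SamplerConfig, run_hmc
from .cohort import CohortTable, cohort_summary
from .errors import FitError, GagrowthError
from .models import GrowthModelSpec, ParamPrior, PriorSpec, default_priors

__all__ = [
    "HierarchySpec",
    "PosteriorDraws",
    "ConvergenceReport",
    "SamplerConfig",
    "fit_hierarchical",
    "posterior_predictive",
    "convergence_check",
]

_LOG_2PI = math.log(2.0 * math.pi)
_AREA_FLOOR = 1e-6  # for the sqrt-scale Jacobian


@dataclass(frozen=True)
class HierarchySpec:
    """Which transformed parameters get random effects, and the centering."""

    re_params: tuple[str, ...] | None = None  # None -> all model parameters
    noncentered: bool = True

    def resolve(self, spec: GrowthModelSpec) -> tuple[str, ...]:
        if self.re_params is None:
            return spec.transformed_params
        unknown = set(self.re_params) - set(spec.transformed_params)
        if unknown:
            raise GagrowthError(
                f"random-effect parameters {sorted(unknown)} not in model "
                f"{spec.name!r} parameters {spec.transformed_params}"
            )
        return tuple(p for p in spec.transformed_params if p in self.re_params)


@dataclass
class ConvergenceReport:
    """Split R-hat and rank-normalized ESS for every sampled parameter."""

    table: pd.DataFrame  # columns: parameter, rhat, ess_bulk, ess_tail, ok
    rhat_max: float
    ess_min: float
    passed: bool


@dataclass
class PosteriorDraws:
    """Posterior sample for one hierarchical growth-model fit."""

    model: str
    param_names: tuple[str, ...]
    re_params: tuple[str, ...]
    patients: list[str]
    eye_keys: list[tuple[str, str]]
    pat_of_eye: np.ndarray
    chain: np.ndarray  # kept chain (draws, chains, ndim)
    draws: dict[str, np.ndarray]  # thinned: mu, tau_patient, tau_eye, z_*, sigma, ...
    loglik: np.ndarray  # (S, n_obs), area scale
    train_t: np.ndarray
    train_area: np.ndarray
    train_eye_idx: np.ndarray
    priors: PriorSpec
    meta: dict
    warnings: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.draws["sigma"].shape[0]

    def eye_index(self, key: tuple[str, str]) -> int:
        try:
            return self.eye_keys.index((str(key[0]), str(key[1])))
        except ValueError:
            raise KeyError(f"eye {key!r} not in training set") from None


# ---------------------------------------------------------------------------
# log-posterior construction
# ---------------------------------------------------------------------------


class _HierarchicalTarget:
    """Vectorized log-posterior over walker batches for one model + cohort."""

    def __init__(
        self,
        spec: GrowthModelSpec,
        priors: PriorSpec,
        hierarchy: HierarchySpec,
        t: np.ndarray,
        y_fit: np.ndarray,
        eye_idx: np.ndarray,
        pat_of_eye: np.ndarray,
        n_patients: int,
    ):
        self.spec = spec
        self.priors = priors
        self.noncentered = hierarchy.noncentered
        self.t = t
        self.y = y_fit
        self.eye_idx = eye_idx
        self.pat_of_eye = pat_of_eye
        self.pnames = spec.transformed_params
        self.re = hierarchy.resolve(spec)
        self.re_mask = np.array([p in self.re for p in self.pnames])
        self.J = len(self.pnames)
        self.nP = n_patients
        self.nE = int(eye_idx.max()) + 1
        self.ndim = 3 * self.J + (self.nP + self.nE) * self.J + 1
        self.mu_priors = [priors.params[p] for p in self.pnames]
        # dense scatter matrices for gradient accumulation (obs -> group)
        n_obs = t.size
        self.pat_of_obs = pat_of_eye[eye_idx]
        self.Ipat = np.zeros((n_obs, self.nP))
        self.Ipat[np.arange(n_obs), self.pat_of_obs] = 1.0
        self.Ieye = np.zeros((n_obs, self.nE))
        self.Ieye[np.arange(n_obs), eye_idx] = 1.0

    # slices
    def unpack(self, X: np.ndarray):
        J, nP, nE = self.J, self.nP, self.nE
        mu = X[:, :J]
        ltp = X[:, J : 2 * J]
        lte = X[:, 2 * J : 3 * J]
        o = 3 * J
        zp = X[:, o : o + nP * J].reshape(-1, nP, J)
        ze = X[:, o + nP * J : o + (nP + nE) * J].reshape(-1, nE, J)
        lsig = X[:, -1]
        return mu, ltp, lte, zp, ze, lsig

    def eye_transformed(self, mu, ltp, lte, zp, ze):
        tau_p = np.exp(ltp) * self.re_mask
        tau_e = np.exp(lte) * self.re_mask
        if self.noncentered:
            return (
                mu[:, None, :]
                + tau_p[:, None, :] * zp[:, self.pat_of_eye, :]
                + tau_e[:, None, :] * ze
            )
        return mu[:, None, :] + zp[:, self.pat_of_eye, :] + ze

    def natural_obs(self, eye_t: np.ndarray) -> dict[str, np.ndarray]:
        """Natural-scale parameter arrays aligned with observations: (W, n_obs)."""
        obs_t = eye_t[:, self.eye_idx, :]
        out = {}
        for j, (nat, fn) in enumerate(zip(self.spec.natural_params, self.spec.transforms)):
            out[nat] = fn(obs_t[:, :, j])
        return out

    def logp_grad(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Log posterior and its analytic gradient, vectorized over chains."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        C = X.shape[0]
        J, nP, nE = self.J, self.nP, self.nE
        mu, ltp, lte, zp, ze, lsig = self.unpack(X)
        grad = np.zeros_like(X)
        g_mu = grad[:, :J]
        g_ltp = grad[:, J : 2 * J]
        g_lte = grad[:, 2 * J : 3 * J]
        o = 3 * J
        g_zp = grad[:, o : o + nP * J].reshape(C, nP, J)
        g_ze = grad[:, o + nP * J : o + (nP + nE) * J].reshape(C, nE, J)

        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp = np.zeros(C)
            out_of_bounds = np.zeros(C, dtype=bool)
            for j, pr in enumerate(self.mu_priors):
                x = mu[:, j]
                lp += -0.5 * ((x - pr.loc) / pr.scale) ** 2
                g_mu[:, j] += -(x - pr.loc) / pr.scale**2
                out_of_bounds |= (x < pr.lower) | (x > pr.upper)
            s_re = self.priors.re_sd.scale
            tau_p_raw = np.exp(ltp)
            tau_e_raw = np.exp(lte)
            for lt, tau, g in ((ltp, tau_p_raw, g_ltp), (lte, tau_e_raw, g_lte)):
                lp += np.sum(-0.5 * (tau / s_re) ** 2 + lt, axis=1)
                g += -((tau / s_re) ** 2) + 1.0
            if self.noncentered:
                lp += -0.5 * (zp**2).sum(axis=(1, 2)) - 0.5 * (ze**2).sum(axis=(1, 2))
                g_zp += -zp
                g_ze += -ze
            else:
                tp = tau_p_raw[:, None, :]
                te = tau_e_raw[:, None, :]
                lp += np.sum(-0.5 * (zp / tp) ** 2 - np.log(tp), axis=(1, 2))
                lp += np.sum(-0.5 * (ze / te) ** 2 - np.log(te), axis=(1, 2))
                g_zp += -zp / tp**2
                g_ze += -ze / te**2
                g_ltp += np.sum((zp / tp) ** 2 - 1.0, axis=1)
                g_lte += np.sum((ze / te) ** 2 - 1.0, axis=1)
            sig = np.exp(lsig)
            s_n = self.priors.noise_sd.scale
            lp += -0.5 * (sig / s_n) ** 2 + lsig
            grad[:, -1] += -((sig / s_n) ** 2) + 1.0

            # likelihood on the fit scale
            eye_t = self.eye_transformed(mu, ltp, lte, zp, ze)
            params = self.natural_obs(eye_t)
            mean, dmean = self.spec.fit_mean_and_grad(self.t, params)
            mean = np.broadcast_to(mean, (C, self.t.size))
            resid = self.y - mean
            inv_s2 = np.exp(-2.0 * lsig)
            lp += -0.5 * np.sum(resid**2, axis=1) * inv_s2 - self.y.size * lsig
            grad[:, -1] += np.sum(resid**2, axis=1) * inv_s2 - self.y.size

            gi_base = resid * inv_s2[:, None]  # (C, n_obs)
            tau_p = tau_p_raw * self.re_mask
            tau_e = tau_e_raw * self.re_mask
            for j in range(J):
                gi = gi_base * np.broadcast_to(dmean[j], (C, self.t.size))
                g_mu[:, j] += gi.sum(axis=1)
                Gp = gi @ self.Ipat  # (C, nP)
                Ge = gi @ self.Ieye  # (C, nE)
                if self.noncentered:
                    g_zp[:, :, j] += tau_p[:, j : j + 1] * Gp
                    g_ze[:, :, j] += tau_e[:, j : j + 1] * Ge
                    g_ltp[:, j] += tau_p[:, j] * np.sum(Gp * zp[:, :, j], axis=1)
                    g_lte[:, j] += tau_e[:, j] * np.sum(Ge * ze[:, :, j], axis=1)
                else:
                    g_zp[:, :, j] += Gp
                    g_ze[:, :, j] += Ge

            lp = np.where(out_of_bounds, -np.inf, lp)
            bad = ~np.isfinite(lp)
            lp = np.where(bad, -np.inf, lp)
            grad[bad] = 0.0
            grad[~np.isfinite(grad)] = 0.0
            return lp, grad

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.logp_grad(X)[0]


def _init_center(
    target: _HierarchicalTarget, summary: Mapping[str, float]
) -> np.ndarray:
    spec = target.spec
    max_area = max(float(summary.get("max_area", 5.0)), 0.5)
    t_span = max(float(summary.get("t_span", 5.0)), 1.0)
    base = float(summary.get("median_baseline_area", 0.5))
    mu0 = {
        "gompertz": {"logK": math.log(1.3 * max_area + 0.5), "logb": math.log(2.5), "logc": math.log(0.5)},
        "logistic": {"logK": math.log(1.3 * max_area + 0.5), "logr": math.log(0.6), "t0": 0.5 * t_span},
        "linear": {"a": base, "s": max(0.1, 0.5 * max_area / t_span)},
        "effective_radius": {"a": math.sqrt(base + 0.05), "s": max(0.05, 0.5 * math.sqrt(max_area) / t_span)},
        "von_bertalanffy": {"logK": math.log(1.3 * max_area + 0.5), "logk": math.log(0.5), "t0": 0.0},
        "mitscherlich": {"logK": math.log(1.3 * max_area + 0.5), "logk": math.log(0.4), "t0": 0.0},
    }[spec.name]
    # respect prior truncation
    for p, pr in zip(target.pnames, target.mu_priors):
        mu0[p] = float(np.clip(mu0[p], pr.lower + 1e-3, pr.upper - 1e-3))
    x = np.zeros(target.ndim)
    x[: target.J] = [mu0[p] for p in target.pnames]
    x[target.J : 3 * target.J] = math.log(0.25)
    x[-1] = math.log(0.3)
    return x


def _bounds_and_scale(target: _HierarchicalTarget) -> tuple[list, np.ndarray]:
    """MAP box constraints plus posterior-scale guesses seeding the mass matrix."""
    J, nP, nE = target.J, target.nP, target.nE
    bounds: list[tuple[float, float]] = []
    scale = np.empty(target.ndim)
    for j, pr in enumerate(target.mu_priors):
        lo = max(pr.lower, pr.loc - 6 * pr.scale)
        hi = min(pr.upper, pr.loc + 6 * pr.scale)
        bounds.append((lo, hi))
        scale[j] = 0.15
    for j in range(2 * J):
        bounds.append((-4.0, 1.5))
        scale[J + j] = 0.3
    z_hw = 6.0 if target.noncentered else 10.0
    for j in range((nP + nE) * J):
        bounds.append((-z_hw, z_hw))
        scale[3 * J + j] = 0.9 if target.noncentered else 0.3
    bounds.append((-5.0, 2.0))
    scale[-1] = 0.1
    return bounds, scale


def _area_loglik(
    spec: GrowthModelSpec,
    eye_t: np.ndarray,
    sigma: np.ndarray,
    t: np.ndarray,
    area: np.ndarray,
    eye_idx: np.ndarray,
) -> np.ndarray:
    """Pointwise log density of observed areas, (S, n_obs), with sqrt Jacobian."""
    obs_t = eye_t[:, eye_idx, :]
    params = {
        nat: fn(obs_t[:, :, j])
        for j, (nat, fn) in enumerate(zip(spec.natural_params, spec.transforms))
    }
    mean = spec.fit_mean(t, params)
    if spec.fit_scale == "radius":
        y = np.sqrt(area)
        jac = -np.log(2.0 * np.sqrt(np.maximum(area, _AREA_FLOOR)))
    else:
        y = area
        jac = 0.0
    s = sigma[:, None]
    return -0.5 * ((y - mean) / s) ** 2 - np.log(s) - 0.5 * _LOG_2PI + jac


def fit_hierarchical(
    cohort: CohortTable,
    spec: GrowthModelSpec,
    hierarchy: HierarchySpec | None = None,
    priors: PriorSpec | None = None,
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit one growth law hierarchically over a cohort; deterministic given seed."""
    hierarchy = hierarchy or HierarchySpec()
    cfg = sampler_config or SamplerConfig()
    summary = cohort_summary(cohort)
    if summary["n_eyes"] == 0:
        raise FitError("empty cohort")
    priors = priors or default_priors(spec, summary)

    eye_keys = cohort.eye_keys()
    patients = sorted({p for p, _ in eye_keys})
    pat_index = {p: i for i, p in enumerate(patients)}
    eye_index = {k: i for i, k in enumerate(eye_keys)}
    pat_of_eye = np.array([pat_index[p] for p, _ in eye_keys])

    df = cohort.df.sort_values(["patient_id", "eye_id", "t_years"], kind="mergesort")
    t = df["t_years"].to_numpy(dtype=float)
    area = df["area_mm2"].to_numpy(dtype=float)
    eye_idx = np.array(
        [eye_index[(p, e)] for p, e in zip(df["patient_id"], df["eye_id"])]
    )
    y_fit = np.sqrt(area) if spec.fit_scale == "radius" else area

    target = _HierarchicalTarget(
        spec, priors, hierarchy, t, y_fit, eye_idx, pat_of_eye, len(patients)
    )
    x0 = _init_center(target, summary)
    bounds, scale_guess = _bounds_and_scale(target)
    chain, stats = run_hmc(target, x0, scale_guess, bounds, cfg, seed)

    # thin the flattened kept chain for storage / prediction / LOO
    steps, chains, ndim = chain.shape
    flat = chain.reshape(steps * chains, ndim)
    S = min(cfg.max_store_draws, flat.shape[0])
    sel = np.linspace(0, flat.shape[0] - 1, S).astype(int)
    sub = flat[sel]
    mu, ltp, lte, zp, ze, lsig = target.unpack(sub)
    eye_t = target.eye_transformed(mu, ltp, lte, zp, ze)
    sigma = np.exp(lsig)
    loglik = _area_loglik(spec, eye_t, sigma, t, area, eye_idx)

    warnings_list: list[str] = []
    if stats["divergence_rate"] > 0.02:
        warnings_list.append(
            f"divergent transitions above tolerance "
            f"({100 * stats['divergence_rate']:.1f}%); inspect convergence"
        )
    if stats["accept_rate"] < 0.5:
        warnings_list.append(f"low HMC acceptance ({stats['accept_rate']:.2f})")

    draws = {
        "mu": mu,
        "tau_patient": np.exp(ltp),
        "tau_eye": np.exp(lte),
        "z_patient": zp,
        "z_eye": ze,
        "sigma": sigma,
        "eye_transformed": eye_t,
    }
    meta = {
        "seed": seed,
        "chains": cfg.chains,
        "warmup": cfg.warmup,
        "iterations": cfg.draws,
        "ndim": ndim,
        **stats,
    }
    return PosteriorDraws(
        model=spec.name,
        param_names=spec.transformed_params,
        re_params=hierarchy.resolve(spec),
        patients=patients,
        eye_keys=eye_keys,
        pat_of_eye=pat_of_eye,
        chain=chain,
        draws=draws,
        loglik=loglik,
        train_t=t,
        train_area=area,
        train_eye_idx=eye_idx,
        priors=priors,
        meta=meta,
        warnings=warnings_list,
    )


def posterior_predictive(
    post: PosteriorDraws,
    spec: GrowthModelSpec,
    eye_key: tuple[str, str] | None,
    times,
    seed: int = 0,
    new_eye: bool = False,
    include_noise: bool = True,
) -> np.ndarray:
    """Predictive draw matrix (draw x time) in mm^2, truncated at zero.

    Known eyes use their posterior random effects; with ``new_eye`` the
    effects are drawn fresh from the population.  Sqrt-scale fits are squared
    back to area after truncating the radius at zero.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    rng = np.random.default_rng(seed)
    if new_eye:
        mu = post.draws["mu"]
        tau_p = post.draws["tau_patient"]
        tau_e = post.draws["tau_eye"]
        re_mask = np.array([p in post.re_params for p in post.param_names])
        S, J = mu.shape
        et = (
            mu
            + tau_p * re_mask * rng.standard_normal((S, J))
            + tau_e * re_mask * rng.standard_normal((S, J))
        )
    else:
        if eye_key is None:
            raise KeyError("eye_key required unless new_eye=True")
        e = post.eye_index(eye_key)
        et = post.draws["eye_transformed"][:, e, :]

    params = {
        nat: fn(et[:, j])[:, None]
        for j, (nat, fn) in enumerate(zip(spec.natural_params, spec.transforms))
    }
    mean = spec.fit_mean(times[None, :], params)
    if include_noise:
        sig = post.draws["sigma"][:, None]
        mean = mean + sig * rng.standard_normal(mean.shape)
    pred = np.maximum(0.0, mean)
    if spec.fit_scale == "radius":
        pred = pred**2
    return pred


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------


def _parameter_names(post: PosteriorDraws) -> list[str]:
    names = [f"mu[{p}]" for p in post.param_names]
    names += [f"tau_patient[{p}]" for p in post.param_names]
    names += [f"tau_eye[{p}]" for p in post.param_names]
    for pid in post.patients:
        names += [f"z_patient[{pid},{p}]" for p in post.param_names]
    for pid, eid in post.eye_keys:
        names += [f"z_eye[{pid}|{eid},{p}]" for p in post.param_names]
    names.append("log_sigma")
    return names


def convergence_check(
    post: PosteriorDraws, rhat_max: float = 1.01, ess_min: float = 400.0
) -> ConvergenceReport:
    """Split R-hat and rank-normalized bulk/tail ESS over walker groups."""
    import arviz as az

    G = post.chain.shape[1]
    if G < 2:
        raise GagrowthError("R-hat undefined with a single chain")
    grouped = post.chain.transpose(1, 0, 2)  # (chain, draw, ndim)
    ds = az.convert_to_dataset(grouped)
    var = list(ds.data_vars)[0]
    rhat = np.asarray(az.rhat(ds)[var])
    ess_bulk = np.asarray(az.ess(ds, method="bulk")[var])
    ess_tail = np.asarray(az.ess(ds, method="tail")[var])
    table = pd.DataFrame(
        {
            "parameter": _parameter_names(post),
            "rhat": rhat,
            "ess_bulk": ess_bulk,
            "ess_tail": ess_tail,
        }
    )
    table["ok"] = (
        (table["rhat"] <= rhat_max)
        & (table["ess_bulk"] >= ess_min)
        & (table["ess_tail"] >= ess_min)
    )
    return ConvergenceReport(
        table=table,
        rhat_max=rhat_max,
        ess_min=ess_min,
        passed=bool(table["ok"].all()),
    )
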