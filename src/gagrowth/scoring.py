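"""Probabilistic forecast scoring and model weighting.

Implements the sample (``fair``) CRPS estimator, MAE from predictive medians,
equal-tailed interval score/coverage, PSIS-LOO expected log predictive
densities, and pseudo-BMA+ model weights with the Bayesian-bootstrap
regularization.  All quantities are in the units of the observable (mm^2 for
lesion areas); cohort-level CRPS/MAE are unweighted means over forecast
tasks.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import GagrowthError

__all__ = [
    "ScoreRecord",
    "ModelWeights",
    "crps_sample",
    "mae_from_median",
    "interval_score",
    "psis_loo",
    "pseudo_bma_plus",
]


@dataclass(frozen=True)
class ScoreRecord:
    """Scores for one (task, model) forecast."""

    eye_key: tuple[str, str]
    model: str
    origin_t: float
    target_t: float
    horizon: float
    n_prior_visits: int
    observed: float
    crps: float
    abs_err_median: float
    signed_err_median: float
    interval_low: float
    interval_high: float
    covered: bool
    width: float
    level: float


@dataclass(frozen=True)
class ModelWeights:
    """pseudo-BMA+ weights with PSIS-LOO elpd summaries and diagnostics."""

    models: tuple[str, ...]
    weights: np.ndarray
    elpd: np.ndarray  # total elpd per model
    elpd_se: np.ndarray
    n_high_pareto_k: np.ndarray  # observations with k > 0.7, per model

    def as_dict(self) -> dict[str, float]:
        return {m: float(w) for m, w in zip(self.models, self.weights)}


def crps_sample(draws, y: float) -> float:
    """Sample CRPS with the unbiased S(S-1) pairwise term.

    CRPS = mean_i |X_i - y| - (1 / (2 S (S-1))) * sum_{i != j} |X_i - X_j|,
    evaluated in O(S log S) via the sorted-sum identity
    sum_{i<j} (X_(j) - X_(i)) = sum_k (2k - S - 1) X_(k).
    """
    x = np.asarray(draws, dtype=float).ravel()
    S = x.size
    if S < 2:
        raise GagrowthError("crps_sample needs at least 2 draws")
    if not np.all(np.isfinite(x)) or not np.isfinite(y):
        raise GagrowthError("crps_sample requires finite draws and observation")
    term1 = np.mean(np.abs(x - y))
    xs = np.sort(x)
    k = np.arange(1, S + 1)
    pair_sum = np.sum((2 * k - S - 1) * xs)  # = sum_{i<j} |X_i - X_j|
    return float(term1 - pair_sum / (S * (S - 1)))


def mae_from_median(draws, y: float) -> float:
    """|median(draws) - y| (type-7 interpolated median)."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise GagrowthError("mae_from_median needs at least 1 draw")
    return float(abs(np.quantile(x, 0.5) - y))


def interval_score(
    draws, y: float, level: float = 0.90
) -> tuple[float, float, float, bool]:
    """Equal-tailed predictive interval (type-7 quantiles): (low, high, width, covered)."""
    if not 0.0 < level < 1.0:
        raise GagrowthError(f"interval level must be in (0, 1), got {level}")
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 20:
        raise GagrowthError("interval_score needs at least 20 draws")
    alpha = 1.0 - level
    low, high = np.quantile(x, [alpha / 2.0, 1.0 - alpha / 2.0])
    covered = bool(low <= y <= high)
    return float(low), float(high), float(high - low), covered


def psis_loo(pointwise_loglik: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PSIS-LOO elpd per observation plus Pareto-k diagnostics.

    ``pointwise_loglik`` has shape (draws, observations).  Importance weights
    for leaving observation i out are proportional to 1/p(y_i | theta_s);
    their tail is smoothed by a fitted generalized Pareto (via arviz) and the
    smoothed, truncated, self-normalized weights give
    elpd_i = log sum_s w_s p(y_i | theta_s).  Degenerate columns (identical
    log-likelihood across draws) reduce to uniform weights exactly.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise GagrowthError("pointwise_loglik must be (draws, observations)")
    if not np.all(np.isfinite(ll)):
        raise GagrowthError("pointwise_loglik contains non-finite values")
    S, n = ll.shape
    elpd = np.empty(n)
    pareto_k = np.zeros(n)
    spread = ll.max(axis=0) - ll.min(axis=0)
    degenerate = spread < 1e-12
    todo = np.nonzero(~degenerate)[0]
    if todo.size:
        import arviz as az

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            lw, k = az.psislw(-ll[:, todo].T)  # (n_todo, S) normalized log weights
        lw = np.asarray(lw)
        pareto_k[todo] = np.asarray(k)
        elpd[todo] = logsumexp(lw + ll[:, todo].T, axis=1)
    if degenerate.any():
        elpd[degenerate] = ll[0, degenerate]
    return elpd, pareto_k


def pseudo_bma_plus(
    elpd_matrix: np.ndarray,
    model_names=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> ModelWeights:
    """pseudo-BMA+ weights from per-observation elpd values.

    ``elpd_matrix`` is (models, observations).  Bayesian-bootstrap replicates
    draw Dirichlet(1) weights over observations, each replicate's total elpd
    per model is soft-maxed, and weights are the replicate average — the
    regularization that penalizes models whose advantage is unstable across
    observations.
    """
    E = np.asarray(elpd_matrix, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2:
        raise GagrowthError("elpd_matrix must be (>=2 models, observations)")
    if not np.all(np.isfinite(E)):
        raise GagrowthError("elpd_matrix contains non-finite values")
    M, N = E.shape
    names = tuple(model_names) if model_names is not None else tuple(
        f"model_{i}" for i in range(M)
    )
    if len(names) != M:
        raise GagrowthError("model_names length mismatch")
    rng = np.random.default_rng(seed)
    w_obs = rng.dirichlet(np.ones(N), size=n_boot)  # (n_boot, N)
    z = N * w_obs @ E.T  # (n_boot, M) replicate total elpd
    z = z - z.max(axis=1, keepdims=True)
    soft = np.exp(z)
    soft /= soft.sum(axis=1, keepdims=True)
    weights = soft.mean(axis=0)
    weights = weights / weights.sum()
    elpd_tot = E.sum(axis=1)
    elpd_se = np.sqrt(N * E.var(axis=1, ddof=1)) if N > 1 else np.zeros(M)
    return ModelWeights(
        models=names,
        weights=weights,
        elpd=elpd_tot,
        elpd_se=elpd_se,
        n_high_pareto_k=np.zeros(M, dtype=int),
    )
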