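"""Growth laws for geographic-atrophy lesion area.

Six mean functions A(t) (mm^2 versus years since first visit) are supported:

* ``gompertz``          A(t) = K * exp(-b * exp(-c t))         (asymmetric sigmoid)
* ``logistic``          A(t) = K / (1 + exp(-r (t - t0)))      (symmetric sigmoid)
* ``linear``            A(t) = max(0, a + s t)
* ``effective_radius``  A(t) = max(0, a + s t)^2               (linear sqrt-area)
* ``von_bertalanffy``   A(t) = K * (1 - exp(-k (t - t0)))^3, clipped at 0
* ``mitscherlich``      A(t) = K * (1 - exp(-k (t - t0))),   clipped at 0

The sigmoids encode biological deceleration toward an anatomical asymptote K;
the linear and effective-radius (square-root transformation) laws are the
field's traditional unbounded alternatives.  Each model declares the scale its
likelihood applies to: ``area`` for all models except ``effective_radius``,
which is fit on sqrt-area (radius) and squared back for area-scale scoring.

Sampling happens on transformed scales (log for positivity-constrained
parameters); :class:`GrowthModelSpec` owns the transform, the analytic rate
dA/dt, and landmark solvers (time of peak growth rate and the rate curve's
inflection times) used for growth-phase classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigError, DomainError

__all__ = [
    "GrowthModelSpec",
    "Landmarks",
    "ParamPrior",
    "PriorSpec",
    "MODELS",
    "get_model",
    "mean_area",
    "growth_rate",
    "landmarks",
    "default_priors",
]

_LANDMARK_WINDOW = (-5.0, 50.0)  # years searched for rate-curve features


@dataclass(frozen=True)
class Landmarks:
    """Times (years) of the rate curve's features for a fitted trajectory.

    ``t_peak_rate`` maximizes dA/dt; ``t_accel`` and ``t_decel`` are the rate
    curve's inflections bracketing the peak (A''' = 0).  Any of the three may
    be ``None`` when the model has no such feature inside the search window.
    ``asymptote`` is ``inf`` for unbounded models.
    """

    t_peak_rate: float | None
    t_accel: float | None
    t_decel: float | None
    asymptote: float

    def all_present(self) -> bool:
        return (
            self.t_peak_rate is not None
            and self.t_accel is not None
            and self.t_decel is not None
        )


@dataclass(frozen=True)
class ParamPrior:
    """One parameter's prior on its sampling (transformed) scale."""

    family: str  # "normal" | "halfnormal"
    loc: float = 0.0
    scale: float = 1.0
    lower: float = -math.inf
    upper: float = math.inf

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "loc": self.loc,
            "scale": self.scale,
            "lower": self.lower,
            "upper": self.upper,
        }


@dataclass(frozen=True)
class PriorSpec:
    """Priors for a model's population parameters, random-effect scales and noise."""

    params: Mapping[str, ParamPrior]
    re_sd: ParamPrior = field(default_factory=lambda: ParamPrior("halfnormal", 0.0, 0.5))
    noise_sd: ParamPrior = field(default_factory=lambda: ParamPrior("halfnormal", 0.0, 1.0))

    def to_dict(self) -> dict:
        return {
            "params": {k: v.to_dict() for k, v in self.params.items()},
            "re_sd": self.re_sd.to_dict(),
            "noise_sd": self.noise_sd.to_dict(),
        }


def _exp(x):
    return np.exp(x)


def _ident(x):
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class GrowthModelSpec:
    """A named growth law with transforms, derivatives and landmark hooks."""

    name: str
    natural_params: tuple[str, ...]
    transformed_params: tuple[str, ...]
    transforms: tuple[Callable, ...]  # transformed -> natural, elementwise
    fit_scale: str  # "area" | "radius"
    _mean: Callable = field(repr=False, default=None)
    _rate: Callable = field(repr=False, default=None)
    _fit_grad: Callable = field(repr=False, default=None)
    _peak_rate_time: Callable | None = field(repr=False, default=None)
    _positive: tuple[str, ...] = ()
    bounded: bool = True

    # -- parameter plumbing -------------------------------------------------
    def to_natural(self, transformed: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        return {
            nat: tr_fn(np.asarray(transformed[tr]))
            for nat, tr, tr_fn in zip(
                self.natural_params, self.transformed_params, self.transforms
            )
        }

    def check_params(self, params: Mapping[str, float]) -> None:
        for p in self.natural_params:
            if p not in params:
                raise DomainError(f"{self.name}: missing parameter {p!r}")
            v = np.asarray(params[p], dtype=float)
            if not np.all(np.isfinite(v)):
                raise DomainError(f"{self.name}: non-finite value for {p!r}")
            if p in self._positive and np.any(v <= 0):
                raise DomainError(f"{self.name}: parameter {p!r} must be > 0")

    # -- mean / rate ---------------------------------------------------------
    def mean(self, t, params: Mapping[str, np.ndarray]):
        """Mean lesion area (mm^2) at time t (years)."""
        return self._mean(np.asarray(t, dtype=float), params)

    def rate(self, t, params: Mapping[str, np.ndarray]):
        """Analytic growth rate dA/dt (mm^2 / year)."""
        return self._rate(np.asarray(t, dtype=float), params)

    def fit_mean(self, t, params: Mapping[str, np.ndarray]):
        """Mean on the likelihood scale (sqrt-area linear predictor for radius fits)."""
        t = np.asarray(t, dtype=float)
        if self.fit_scale == "radius":
            return params["a"] + params["s"] * t
        return self._mean(t, params)

    def fit_mean_and_grad(self, t, params: Mapping[str, np.ndarray]):
        """Fit-scale mean and its derivatives w.r.t. the *transformed* parameters.

        Returns ``(mean, grads)`` with one gradient array per entry of
        ``transformed_params`` (chain rule through the log transforms is
        already applied).  Used by the HMC log-posterior.
        """
        return self._fit_grad(np.asarray(t, dtype=float), params)

    def asymptote(self, params: Mapping[str, np.ndarray]) -> float:
        if not self.bounded:
            return math.inf
        return float(np.asarray(params["K"]))


# ---------------------------------------------------------------------------
# mean functions and their analytic derivatives
# ---------------------------------------------------------------------------

def _gompertz_mean(t, p):
    return p["K"] * np.exp(-p["b"] * np.exp(-p["c"] * t))


def _gompertz_rate(t, p):
    u = p["b"] * np.exp(-p["c"] * t)
    return p["K"] * p["c"] * u * np.exp(-u)


def _logistic_mean(t, p):
    return p["K"] / (1.0 + np.exp(-p["r"] * (t - p["t0"])))


def _logistic_rate(t, p):
    e = np.exp(-p["r"] * (t - p["t0"]))
    return p["K"] * p["r"] * e / (1.0 + e) ** 2


def _linear_mean(t, p):
    return np.maximum(0.0, p["a"] + p["s"] * t)


def _linear_rate(t, p):
    pred = p["a"] + p["s"] * t
    return np.where(pred > 0, p["s"] * np.ones_like(pred), 0.0)


def _effrad_mean(t, p):
    r = np.maximum(0.0, p["a"] + p["s"] * t)
    return r**2


def _effrad_rate(t, p):
    r = p["a"] + p["s"] * t
    return np.where(r > 0, 2.0 * p["s"] * r, 0.0)


def _vb_mean(t, p):
    g = 1.0 - np.exp(-p["k"] * (t - p["t0"]))
    return p["K"] * np.maximum(0.0, g) ** 3


def _vb_rate(t, p):
    e = np.exp(-p["k"] * (t - p["t0"]))
    g = 1.0 - e
    return np.where(g > 0, 3.0 * p["K"] * p["k"] * g**2 * e, 0.0)


def _mit_mean(t, p):
    g = 1.0 - np.exp(-p["k"] * (t - p["t0"]))
    return p["K"] * np.maximum(0.0, g)


def _mit_rate(t, p):
    e = np.exp(-p["k"] * (t - p["t0"]))
    return np.where(e < 1.0, p["K"] * p["k"] * e, 0.0)


# fit-scale mean + gradients w.r.t. transformed parameters (for HMC)

def _gompertz_grad(t, p):
    u = p["b"] * np.exp(-p["c"] * t)
    m = p["K"] * np.exp(-u)
    return m, (m, -m * u, m * u * p["c"] * t)


def _logistic_grad(t, p):
    w = p["r"] * (t - p["t0"])
    s = 1.0 / (1.0 + np.exp(-w))
    m = p["K"] * s
    d = p["K"] * s * (1.0 - s)
    return m, (m, d * w, -d * p["r"])


def _linear_grad(t, p):
    pred = p["a"] + p["s"] * t
    ind = (pred > 0).astype(float)
    return np.maximum(0.0, pred), (ind, ind * t)


def _effrad_grad(t, p):
    m = p["a"] + p["s"] * t  # radius scale, unclipped
    one = np.ones(np.broadcast(m, t).shape)
    return m, (one, one * t)


def _vb_grad(t, p):
    tau = t - p["t0"]
    e = np.exp(-p["k"] * tau)
    g = np.maximum(0.0, 1.0 - e)
    m = p["K"] * g**3
    core = 3.0 * p["K"] * g**2 * e
    return m, (m, core * tau * p["k"], -core * p["k"])


def _mit_grad(t, p):
    tau = t - p["t0"]
    e = np.exp(-p["k"] * tau)
    ind = (e < 1.0).astype(float)
    g = np.maximum(0.0, 1.0 - e)
    m = p["K"] * g
    return m, (m, p["K"] * e * tau * p["k"] * ind, -p["K"] * p["k"] * e * ind)


MODELS: dict[str, GrowthModelSpec] = {
    "gompertz": GrowthModelSpec(
        name="gompertz",
        natural_params=("K", "b", "c"),
        transformed_params=("logK", "logb", "logc"),
        transforms=(_exp, _exp, _exp),
        fit_scale="area",
        _mean=_gompertz_mean,
        _fit_grad=_gompertz_grad,
        _rate=_gompertz_rate,
        _peak_rate_time=lambda p: math.log(float(p["b"])) / float(p["c"]),
        _positive=("K", "b", "c"),
        bounded=True,
    ),
    "logistic": GrowthModelSpec(
        name="logistic",
        natural_params=("K", "r", "t0"),
        transformed_params=("logK", "logr", "t0"),
        transforms=(_exp, _exp, _ident),
        fit_scale="area",
        _mean=_logistic_mean,
        _fit_grad=_logistic_grad,
        _rate=_logistic_rate,
        _peak_rate_time=lambda p: float(p["t0"]),
        _positive=("K", "r"),
        bounded=True,
    ),
    "linear": GrowthModelSpec(
        name="linear",
        natural_params=("a", "s"),
        transformed_params=("a", "s"),
        transforms=(_ident, _ident),
        fit_scale="area",
        _mean=_linear_mean,
        _fit_grad=_linear_grad,
        _rate=_linear_rate,
        _peak_rate_time=None,
        _positive=(),
        bounded=False,
    ),
    "effective_radius": GrowthModelSpec(
        name="effective_radius",
        natural_params=("a", "s"),
        transformed_params=("a", "s"),
        transforms=(_ident, _ident),
        fit_scale="radius",
        _mean=_effrad_mean,
        _fit_grad=_effrad_grad,
        _rate=_effrad_rate,
        _peak_rate_time=None,
        _positive=(),
        bounded=False,
    ),
    "von_bertalanffy": GrowthModelSpec(
        name="von_bertalanffy",
        natural_params=("K", "k", "t0"),
        transformed_params=("logK", "logk", "t0"),
        transforms=(_exp, _exp, _ident),
        fit_scale="area",
        _mean=_vb_mean,
        _fit_grad=_vb_grad,
        _rate=_vb_rate,
        _peak_rate_time=None,  # numeric; closed form t0 + ln(3)/k used as oracle in tests
        _positive=("K", "k"),
        bounded=True,
    ),
    "mitscherlich": GrowthModelSpec(
        name="mitscherlich",
        natural_params=("K", "k", "t0"),
        transformed_params=("logK", "logk", "t0"),
        transforms=(_exp, _exp, _ident),
        fit_scale="area",
        _mean=_mit_mean,
        _fit_grad=_mit_grad,
        _rate=_mit_rate,
        _peak_rate_time=None,
        _positive=("K", "k"),
        bounded=True,
    ),
}

SIGMOID_MODELS = ("gompertz", "logistic", "von_bertalanffy", "mitscherlich")


def get_model(name: str) -> GrowthModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise ConfigError(
            f"unknown growth model {name!r}; choose from {sorted(MODELS)}"
        ) from None


def mean_area(spec: GrowthModelSpec, params: Mapping[str, float], t) -> np.ndarray:
    """Mean lesion area (mm^2) with domain checking."""
    spec.check_params(params)
    return spec.mean(t, params)


def growth_rate(spec: GrowthModelSpec, params: Mapping[str, float], t) -> np.ndarray:
    """Analytic dA/dt (mm^2/year) with domain checking."""
    spec.check_params(params)
    return spec.rate(t, params)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def _rate_curvature(spec: GrowthModelSpec, params, t: float, h: float = 1e-4) -> float:
    """Second derivative of the rate curve (= A''') by central differences."""
    r = spec.rate(np.array([t - h, t, t + h]), params)
    return float((r[0] - 2.0 * r[1] + r[2]) / h**2)


def _bracketed_root(f, lo: float, hi: float, n_scan: int = 400) -> float | None:
    ts = np.linspace(lo, hi, n_scan)
    vals = np.array([f(t) for t in ts])
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    return float(brentq(f, ts[i], ts[i + 1], xtol=1e-10))


def landmarks(
    spec: GrowthModelSpec,
    params: Mapping[str, float],
    search_window: tuple[float, float] = _LANDMARK_WINDOW,
) -> Landmarks:
    """Locate the peak-rate time and the rate curve's inflections.

    Unbounded models (linear, effective radius) have no landmarks and return
    an all-absent record with an infinite asymptote.  The Mitscherlich rate is
    monotone decreasing, so its peak sits at the curve onset t0 and it has no
    inflections.  Missing roots inside ``search_window`` are reported absent.
    """
    spec.check_params(params)
    if not spec.bounded:
        return Landmarks(None, None, None, math.inf)
    lo, hi = search_window
    if "t0" in params and spec.name in ("von_bertalanffy", "mitscherlich"):
        # the clipped mean is flat before onset; the kink at t0 would fake a
        # sign change for the finite-difference root scans
        lo = max(lo, float(params["t0"]) + 1e-3)

    if spec._peak_rate_time is not None:
        t_peak = spec._peak_rate_time(params)
    elif spec.name == "mitscherlich":
        t_peak = float(params["t0"])
    else:
        # interior maximum of the rate: root of A'' via finite difference of rate
        def drate(t, h=1e-5):
            r = spec.rate(np.array([t - h, t + h]), params)
            return float((r[1] - r[0]) / (2 * h))

        t_peak = _bracketed_root(drate, lo, hi)
    if t_peak is not None and not (lo <= t_peak <= hi):
        t_peak = None

    t_accel = t_decel = None
    if t_peak is not None and spec.name != "mitscherlich":
        f = lambda t: _rate_curvature(spec, params, t)
        t_accel = _bracketed_root(f, lo, t_peak - 1e-6)
        t_decel = _bracketed_root(f, t_peak + 1e-6, hi)
    return Landmarks(t_peak, t_accel, t_decel, spec.asymptote(params))


# ---------------------------------------------------------------------------
# default priors
# ---------------------------------------------------------------------------

def default_priors(spec: GrowthModelSpec, cohort_summary: Mapping[str, float]) -> PriorSpec:
    """Weakly-informative priors scaled to the observed cohort.

    ``cohort_summary`` needs ``max_area`` (mm^2) and ``t_span`` (years of
    follow-up).  Asymptote priors are lognormal centred near 10 mm^2 and
    truncated above at 4x the largest observed lesion so prior-predictive
    areas stay in a plausible range; slopes and offsets get broad normals.
    """
    max_area = float(cohort_summary.get("max_area", 10.0))
    t_span = float(cohort_summary.get("t_span", 6.0))
    logK_cap = math.log(max(4.0 * max_area, 4.0))
    k_prior = ParamPrior("normal", math.log(10.0), 1.0, upper=logK_cap)

    if spec.name == "gompertz":
        params = {
            "logK": k_prior,
            "logb": ParamPrior("normal", math.log(2.5), 1.0),
            "logc": ParamPrior("normal", math.log(0.5), 0.8),
        }
    elif spec.name == "logistic":
        params = {
            "logK": k_prior,
            "logr": ParamPrior("normal", math.log(0.5), 0.8),
            "t0": ParamPrior("normal", 0.5 * t_span, max(t_span, 2.0)),
        }
    elif spec.name in ("linear", "effective_radius"):
        params = {
            "a": ParamPrior("normal", 0.0, 5.0),
            "s": ParamPrior("normal", 0.0, 5.0),
        }
    elif spec.name in ("von_bertalanffy", "mitscherlich"):
        params = {
            "logK": k_prior,
            "logk": ParamPrior("normal", math.log(0.5), 0.8),
            "t0": ParamPrior("normal", 0.0, max(t_span, 2.0)),
        }
    else:  # pragma: no cover
        raise ConfigError(f"no default priors for model {spec.name!r}")
    return PriorSpec(params=params)
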