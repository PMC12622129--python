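"""Synthetic cohorts with the statistical structure of a GA natural-history clinic.

The generator emulates the longitudinal design the analysis assumes: patients
contribute one or two eyes (bilateral involvement ~49.6%), each eye is imaged
on an irregular schedule built from a six-month scheduled grid with skipped
appointments, visit counts follow a shifted negative binomial floored at five
(median ~7, IQR ~4), and lesion areas follow hierarchical sigmoidal (default
Gompertz) trajectories — patient and eye-within-patient random effects on log
scales — observed with Gaussian noise truncated at zero.  Defaults target the
reference cohort summaries: baseline area median ~0.8 mm^2, follow-up median
~5.8 years.

Ground-truth parameters are retained per eye so recovery and phase tests can
compare against the generating process.  All randomness derives from one seed
through `numpy.random.SeedSequence` spawning, so per-patient streams are
independent of call order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import cohort as cio
from .errors import ConfigError, DomainError
from .models import GrowthModelSpec, get_model

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "simulate_cohort",
    "simulate_trajectory",
]

# Transformed-scale population locations and random-effect sds per truth model.
# Gompertz values are calibrated to the reference cohort: median K ~ 10 mm^2,
# baseline K*exp(-b) ~ 0.8 mm^2, peak growth around year 2 and deceleration
# from year ~4 so 5-6 year follow-up spans all growth phases.
_DEFAULT_POPULATION: dict[str, dict[str, float]] = {
    "gompertz": {"logK": math.log(10.0), "logb": math.log(2.5), "logc": math.log(0.45)},
    "logistic": {"logK": math.log(10.0), "logr": math.log(0.8), "t0": 2.5},
    "linear": {"a": 0.6, "s": 1.2},
    "effective_radius": {"a": 0.7, "s": 0.35},
    "von_bertalanffy": {"logK": math.log(10.0), "logk": math.log(0.4), "t0": -0.5},
    "mitscherlich": {"logK": math.log(10.0), "logk": math.log(0.3), "t0": -0.2},
}
_DEFAULT_PATIENT_SD: dict[str, dict[str, float]] = {
    "gompertz": {"logK": 0.50, "logb": 0.35, "logc": 0.25},
    "logistic": {"logK": 0.50, "logr": 0.25, "t0": 1.0},
    "linear": {"a": 0.4, "s": 0.4},
    "effective_radius": {"a": 0.3, "s": 0.12},
    "von_bertalanffy": {"logK": 0.5, "logk": 0.25, "t0": 0.8},
    "mitscherlich": {"logK": 0.5, "logk": 0.25, "t0": 0.8},
}
_DEFAULT_EYE_SD: dict[str, dict[str, float]] = {
    "gompertz": {"logK": 0.35, "logb": 0.25, "logc": 0.15},
    "logistic": {"logK": 0.35, "logr": 0.15, "t0": 0.6},
    "linear": {"a": 0.25, "s": 0.25},
    "effective_radius": {"a": 0.2, "s": 0.08},
    "von_bertalanffy": {"logK": 0.35, "logk": 0.15, "t0": 0.5},
    "mitscherlich": {"logK": 0.35, "logk": 0.15, "t0": 0.5},
}


class SimulationConfig(BaseModel):
    """Generator settings; defaults reproduce the reference-cohort summaries."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(121, ge=1)
    bilateral_prob: float = Field(0.496, ge=0.0, le=1.0)
    truth_model: str = "gompertz"
    population_params: dict[str, float] | None = None  # transformed-scale locations
    between_patient_sd: dict[str, float] | None = None
    between_eye_sd: dict[str, float] | None = None
    noise_sd: float = Field(0.3, ge=0.0)
    visit_interval_mean: float = Field(0.5, gt=0.0)  # scheduled slot spacing, years
    visit_interval_jitter_sd: float = Field(0.08, ge=0.0)
    attendance_prob: float = Field(0.60, gt=0.0, le=1.0)  # per scheduled slot
    min_interval: float = Field(0.1, gt=0.0)
    visits_nb_r: float = Field(1.6, gt=0.0)  # extra-visit count ~ NB, shifted by 5
    visits_nb_mean: float = Field(3.0, gt=0.0)
    min_visits: int = Field(5, ge=2)
    ensure_inclusion: bool = True
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.truth_model not in _DEFAULT_POPULATION:
            raise ConfigError(f"unknown truth model {self.truth_model!r}")
        for d in (self.population_params, self.between_patient_sd, self.between_eye_sd):
            if d is not None:
                expected = set(_DEFAULT_POPULATION[self.truth_model])
                if set(d) != expected:
                    raise ConfigError(
                        f"parameter dict keys {sorted(d)} != expected {sorted(expected)}"
                    )
        for d in (self.between_patient_sd, self.between_eye_sd):
            if d is not None and any(v < 0 for v in d.values()):
                raise ConfigError("random-effect sds must be >= 0")
        return self

    def resolved(self) -> tuple[dict, dict, dict]:
        m = self.truth_model
        return (
            dict(self.population_params or _DEFAULT_POPULATION[m]),
            dict(self.between_patient_sd or _DEFAULT_PATIENT_SD[m]),
            dict(self.between_eye_sd or _DEFAULT_EYE_SD[m]),
        )

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from YAML or JSON."""
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)  # JSON is a YAML subset
        return cls(**payload)


@dataclass
class TrueParameters:
    """Ground truth for a simulated cohort."""

    model: str
    eye_params: dict[tuple[str, str], dict[str, float]]  # natural scale per eye
    patient_effects: dict[str, dict[str, float]]  # transformed-scale offsets
    noise_sd: float

    def to_json(self, path) -> None:
        payload = {
            "model": self.model,
            "noise_sd": self.noise_sd,
            "eye_params": {
                f"{p}|{e}": v for (p, e), v in sorted(self.eye_params.items())
            },
            "patient_effects": self.patient_effects,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def simulate_trajectory(
    spec: GrowthModelSpec,
    params: Mapping[str, float],
    times,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Mean trajectory plus i.i.d. Gaussian noise, truncated at zero."""
    spec.check_params(params)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0):
        raise DomainError("times must be a 1-D ascending array")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    mean = spec.mean(times, dict(params))
    obs = mean + rng.normal(0.0, noise_sd, size=times.shape) if noise_sd > 0 else mean
    return np.maximum(0.0, obs)


def _draw_schedule(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Visit times: NB visit count floored at min_visits on a thinned 6-month grid."""
    p_nb = cfg.visits_nb_r / (cfg.visits_nb_r + cfg.visits_nb_mean)
    n = cfg.min_visits + int(rng.negative_binomial(cfg.visits_nb_r, p_nb))
    # gap between consecutive attended visits = geometric number of scheduled slots
    slots = 1 + rng.geometric(cfg.attendance_prob, size=n - 1) - 1
    slots = np.maximum(1, slots)
    gaps = slots * cfg.visit_interval_mean + rng.normal(
        0.0, cfg.visit_interval_jitter_sd, size=n - 1
    )
    gaps = np.maximum(cfg.min_interval, gaps)
    return np.concatenate([[0.0], np.cumsum(gaps)])


def _passes_inclusion(area: np.ndarray, cfg: SimulationConfig) -> bool:
    return len(area) >= cfg.min_visits and int((area > 2.0).sum()) >= 3


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[cio.CohortTable, TrueParameters]:
    """Draw a full synthetic cohort plus its ground truth.

    Deterministic given ``config.seed``.  Per patient: 1 or 2 eyes
    (Bernoulli(bilateral_prob) + 1), patient-level and eye-level random
    effects on transformed scales, a visit schedule, then observed areas =
    mean(t; eye params) + truncated Gaussian noise.  With
    ``ensure_inclusion`` (default) each eye is re-drawn, on its own derived
    stream, until it passes the default inclusion filters, so the emitted
    cohort survives filtering unchanged.
    """
    spec = get_model(config.truth_model)
    loc, sd_pat, sd_eye = config.resolved()
    pnames = list(loc)

    root = np.random.SeedSequence(config.seed)
    patient_seeds = root.spawn(config.n_patients)

    rows: list[pd.DataFrame] = []
    eye_params: dict[tuple[str, str], dict[str, float]] = {}
    patient_effects: dict[str, dict[str, float]] = {}

    for i, pss in enumerate(patient_seeds):
        pid = f"P{i + 1:04d}"
        rng = np.random.default_rng(pss)
        n_eyes = 1 + int(rng.random() < config.bilateral_prob)
        pat_eff = {k: rng.normal(0.0, sd_pat[k]) for k in pnames}
        for j in range(n_eyes):
            eid = "OD" if j == 0 else "OS"
            for attempt in range(100):
                eye_eff = {k: rng.normal(0.0, sd_eye[k]) for k in pnames}
                transformed = {
                    k: loc[k] + pat_eff[k] + eye_eff[k] for k in pnames
                }
                natural = {
                    nat: float(fn(np.asarray(transformed[tr])))
                    for nat, tr, fn in zip(
                        spec.natural_params, spec.transformed_params, spec.transforms
                    )
                }
                t = _draw_schedule(rng, config)
                area = simulate_trajectory(spec, natural, t, config.noise_sd, rng)
                if not config.ensure_inclusion or _passes_inclusion(area, config):
                    break
                if attempt == 40:  # stubborn patient-level draw; refresh it too
                    pat_eff = {k: rng.normal(0.0, sd_pat[k]) for k in pnames}
            eye_params[(pid, eid)] = natural
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "eye_id": eid,
                        "t_years": t,
                        "area_mm2": area,
                        "gradable": True,
                    }
                )
            )
        patient_effects[pid] = pat_eff

    df = pd.concat(rows, ignore_index=True)
    table = cio.from_dataframe(df, provenance=f"simulation:seed={config.seed}")
    truth = TrueParameters(
        model=config.truth_model,
        eye_params=eye_params,
        patient_effects=patient_effects,
        noise_sd=config.noise_sd,
    )
    return table, truth
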