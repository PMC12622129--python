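"""Rolling out-of-sample forecast harness mimicking clinic flow.

Starting from each eye's fifth visit, the focal eye's history is truncated at
the forecast origin, the hierarchical model is refit on that truncated series
plus every other eye's full history (so population-level parameters stay
informed), and the next visit's lesion area is predicted.  The default
scheme is one-step-ahead with growing history (``next``); ``all-from-5``
fixes the origin at visit 5 and predicts every later visit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._sampler import SamplerConfig
from .cohort import CohortTable, from_dataframe
from .errors import ConfigError, FitError
from .inference import HierarchySpec, fit_hierarchical, posterior_predictive
from .models import GrowthModelSpec
from .scoring import ScoreRecord, crps_sample, interval_score, mae_from_median

__all__ = [
    "ForecastTask",
    "ForecastResult",
    "build_forecast_tasks",
    "run_rolling_forecasts",
    "score_forecasts",
    "results_table",
]

logger = logging.getLogger(__name__)

# small default for per-task refits; forecasting quality needs predictive
# draws, not publication-grade tail ESS
FORECAST_SAMPLER = SamplerConfig(
    warmup=200, draws=150, path_factor_max=6.0, max_leapfrog=48, max_store_draws=500
)


@dataclass(frozen=True)
class ForecastTask:
    """One (eye, origin, target) prediction problem; visit ordinals are 1-based."""

    eye_key: tuple[str, str]
    origin_index: int
    target_index: int
    origin_t: float
    target_t: float
    observed: float

    @property
    def horizon(self) -> float:
        return self.target_t - self.origin_t

    @property
    def n_prior_visits(self) -> int:
        return self.origin_index


@dataclass
class ForecastResult:
    """Predictive draws and the realized observation for one (task, model)."""

    task: ForecastTask
    model: str
    draws: np.ndarray | None
    failed: bool = False
    failure_reason: str = ""


def build_forecast_tasks(
    cohort: CohortTable, min_history: int = 5, scheme: str = "next"
) -> list[ForecastTask]:
    """Enumerate forecast tasks; an eye with V visits yields max(0, V - min_history)."""
    if scheme not in ("next", "all-from-5"):
        raise ConfigError(f"unknown forecast scheme {scheme!r}")
    tasks: list[ForecastTask] = []
    for eye in cohort.eyes():
        V = eye.n_visits
        if V <= min_history:
            continue
        if scheme == "next":
            origins = range(min_history, V)  # 1-based origin = o, target = o+1
            pairs = [(o, o + 1) for o in origins]
        else:
            pairs = [(min_history, tgt) for tgt in range(min_history + 1, V + 1)]
        for o, tgt in pairs:
            tasks.append(
                ForecastTask(
                    eye_key=(eye.patient_id, eye.eye_id),
                    origin_index=o,
                    target_index=tgt,
                    origin_t=float(eye.t[o - 1]),
                    target_t=float(eye.t[tgt - 1]),
                    observed=float(eye.area[tgt - 1]),
                )
            )
    return tasks


def _truncated_cohort(cohort: CohortTable, task: ForecastTask) -> CohortTable:
    """Training table: focal eye cut at the origin, all other eyes complete."""
    df = cohort.df
    pid, eid = task.eye_key
    focal = (df["patient_id"] == pid) & (df["eye_id"] == eid)
    focal_df = df[focal].sort_values("t_years", kind="mergesort")
    keep_focal = focal_df.iloc[: task.origin_index]
    out = pd.concat([df[~focal], keep_focal], ignore_index=True)
    return from_dataframe(out, provenance=f"{cohort.provenance}|trunc")


def run_rolling_forecasts(
    cohort: CohortTable,
    models: list[GrowthModelSpec],
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
    min_history: int = 5,
    scheme: str = "next",
    hierarchy: HierarchySpec | None = None,
) -> list[ForecastResult]:
    """One ForecastResult per (task x model); refits independent across origins.

    Leakage guard: the focal eye's visits beyond the origin never enter the
    training set of their task.  A failed refit flags its result and the
    harness continues.
    """
    cfg = sampler_config or FORECAST_SAMPLER
    tasks = build_forecast_tasks(cohort, min_history=min_history, scheme=scheme)
    results: list[ForecastResult] = []
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(tasks) * len(models))
    for mi, spec in enumerate(models):
        for ti, task in enumerate(tasks):
            child = streams[mi * len(tasks) + ti]
            fit_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
            train = _truncated_cohort(cohort, task)
            assert not (
                (train.df["patient_id"] == task.eye_key[0])
                & (train.df["eye_id"] == task.eye_key[1])
                & (train.df["t_years"] > task.origin_t)
            ).any(), "leakage: focal eye's future visits in training set"
            try:
                post = fit_hierarchical(
                    train, spec, hierarchy=hierarchy, sampler_config=cfg, seed=fit_seed
                )
                draws = posterior_predictive(
                    post,
                    spec,
                    task.eye_key,
                    [task.target_t],
                    seed=fit_seed + 1,
                )[:, 0]
                results.append(ForecastResult(task=task, model=spec.name, draws=draws))
            except FitError as exc:
                logger.warning("fit failed for %s / %s: %s", task, spec.name, exc)
                results.append(
                    ForecastResult(
                        task=task,
                        model=spec.name,
                        draws=None,
                        failed=True,
                        failure_reason=str(exc),
                    )
                )
    return results


def score_forecasts(
    results: list[ForecastResult], level: float = 0.90
) -> list[ScoreRecord]:
    """CRPS / MAE / interval records for every successful forecast."""
    records: list[ScoreRecord] = []
    for res in results:
        if res.failed or res.draws is None:
            continue
        t = res.task
        low, high, width, covered = interval_score(res.draws, t.observed, level)
        med = float(np.quantile(res.draws, 0.5))
        records.append(
            ScoreRecord(
                eye_key=t.eye_key,
                model=res.model,
                origin_t=t.origin_t,
                target_t=t.target_t,
                horizon=t.horizon,
                n_prior_visits=t.n_prior_visits,
                observed=t.observed,
                crps=crps_sample(res.draws, t.observed),
                abs_err_median=mae_from_median(res.draws, t.observed),
                signed_err_median=med - t.observed,
                interval_low=low,
                interval_high=high,
                covered=covered,
                width=width,
                level=level,
            )
        )
    return records


def results_table(records: list[ScoreRecord]) -> pd.DataFrame:
    """Score records as a tidy frame (one row per task x model)."""
    return pd.DataFrame(
        {
            "patient_id": [r.eye_key[0] for r in records],
            "eye_id": [r.eye_key[1] for r in records],
            "model": [r.model for r in records],
            "origin_t": [r.origin_t for r in records],
            "target_t": [r.target_t for r in records],
            "horizon": [r.horizon for r in records],
            "n_prior_visits": [r.n_prior_visits for r in records],
            "observed": [r.observed for r in records],
            "crps": [r.crps for r in records],
            "abs_err_median": [r.abs_err_median for r in records],
            "signed_err_median": [r.signed_err_median for r in records],
            "interval_low": [r.interval_low for r in records],
            "interval_high": [r.interval_high for r in records],
            "covered": [r.covered for r in records],
            "width": [r.width for r in records],
        }
    )
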