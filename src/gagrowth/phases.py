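"""Growth-phase classification of forecast windows and phase-stratified scores.

A sigmoid trajectory passes through acceleration (before the rate curve's
first inflection), a near-linear stretch around the peak growth rate, and
deceleration (after the second inflection).  Forecast windows are labelled
by where they fall relative to a fitted (or simulation-truth) Gompertz
curve's landmarks; windows straddling a boundary are ``mixed``.  Phase
boundaries partition time as acceleration = (-inf, t_accel), linear =
[t_accel, t_decel] (closed), deceleration = (t_decel, inf).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GagrowthError
from .models import Landmarks
from .scoring import ScoreRecord

__all__ = ["PhaseLabel", "classify_window", "stratified_scores"]

PHASES = ("acceleration", "linear", "deceleration", "mixed")


@dataclass(frozen=True)
class PhaseLabel:
    """A window's phase plus the boundaries and landmark source used."""

    label: str
    t_accel: float
    t_decel: float
    source: str = "fitted"


def classify_window(
    landmarks: Landmarks, window: tuple[float, float], source: str = "fitted"
) -> PhaseLabel:
    """Assign acceleration / linear / deceleration / mixed to a forecast window."""
    if not landmarks.all_present():
        raise GagrowthError(
            "phase classification needs sigmoid landmarks; fit a bounded "
            "(e.g. Gompertz) model for this eye"
        )
    lo, hi = float(window[0]), float(window[1])
    if hi < lo:
        raise GagrowthError(f"invalid window {window}")
    ta, td = landmarks.t_accel, landmarks.t_decel
    if hi < ta:
        label = "acceleration"
    elif lo >= ta and hi <= td:
        label = "linear"
    elif lo > td:
        label = "deceleration"
    else:
        label = "mixed"
    return PhaseLabel(label=label, t_accel=ta, t_decel=td, source=source)


def stratified_scores(
    records: list[ScoreRecord],
    labels: list[PhaseLabel],
    n_boot: int = 2000,
    seed: int = 0,
    interval_level: float = 0.95,
) -> pd.DataFrame:
    """Per-(phase, model) mean CRPS with bootstrap interval and prob-best.

    The probability of being best in a stratum is the fraction of bootstrap
    replicates (resampling tasks within the stratum) in which the model has
    the lowest mean CRPS; exact ties share the credit.  Empty strata are
    omitted.
    """
    if len(records) != len(labels):
        raise GagrowthError("records and labels must align one-to-one")
    df = pd.DataFrame(
        {
            "phase": [l.label for l in labels],
            "model": [r.model for r in records],
            "crps": [r.crps for r in records],
            "task": [
                (r.eye_key[0], r.eye_key[1], r.origin_t, r.target_t) for r in records
            ],
        }
    )
    rng = np.random.default_rng(seed)
    rows = []
    alpha = 1.0 - interval_level
    for phase in PHASES:
        sub = df[df["phase"] == phase]
        if sub.empty:
            continue
        models = sorted(sub["model"].unique())
        tasks = sorted(sub["task"].unique())
        # crps matrix (task, model); tasks missing a model's score are dropped
        wide = sub.pivot_table(index="task", columns="model", values="crps")
        wide = wide.dropna()
        if wide.empty:
            continue
        mat = wide.to_numpy()  # (n_tasks, n_models)
        models = list(wide.columns)
        nT = mat.shape[0]
        idx = rng.integers(0, nT, size=(n_boot, nT))
        boot_means = mat[idx].mean(axis=1)  # (n_boot, n_models)
        best = boot_means == boot_means.min(axis=1, keepdims=True)
        prob_best = (best / best.sum(axis=1, keepdims=True)).mean(axis=0)
        lo_q, hi_q = np.quantile(boot_means, [alpha / 2, 1 - alpha / 2], axis=0)
        for m_i, m in enumerate(models):
            rows.append(
                {
                    "phase": phase,
                    "model": m,
                    "n_tasks": nT,
                    "mean_crps": float(mat[:, m_i].mean()),
                    "crps_lo": float(lo_q[m_i]),
                    "crps_hi": float(hi_q[m_i]),
                    "prob_best": float(prob_best[m_i]),
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["phase", "mean_crps"]).reset_index(drop=True)
    return out
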