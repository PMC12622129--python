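"""Shared fixtures: small synthetic cohorts built from the generator's laws."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from gagrowth.cohort import CohortTable, from_dataframe
from gagrowth.models import get_model
from gagrowth.simulate import (
    _DEFAULT_EYE_SD,
    _DEFAULT_PATIENT_SD,
    _DEFAULT_POPULATION,
    simulate_trajectory,
)

GOMPERTZ_POP = _DEFAULT_POPULATION["gompertz"]


def make_gompertz_cohort(
    seed: int,
    n_eyes: int = 30,
    n_visits: int = 8,
    sigma: float = 0.3,
    spacing: float = 0.8,
) -> CohortTable:
    """Fixed-size Gompertz-truth cohort drawn from the generator's default laws.

    Unlike the full generator this pins the visit count and (jittered)
    spacing, which is what the parameter-recovery experiments call for.
    Every other patient contributes both eyes.
    """
    spec = get_model("gompertz")
    loc = _DEFAULT_POPULATION["gompertz"]
    sd_pat = _DEFAULT_PATIENT_SD["gompertz"]
    sd_eye = _DEFAULT_EYE_SD["gompertz"]
    rng = np.random.default_rng(seed)
    rows = []
    eyes: list[tuple[str, str]] = []
    pat_eff: dict[str, dict[str, float]] = {}
    p = 0
    while len(eyes) < n_eyes:
        pid = f"P{p:03d}"
        pat_eff[pid] = {k: rng.normal(0, sd_pat[k]) for k in loc}
        for eid in ["OD", "OS"] if p % 2 == 0 else ["OD"]:
            if len(eyes) < n_eyes:
                eyes.append((pid, eid))
        p += 1
    for pid, eid in eyes:
        eff = {k: loc[k] + pat_eff[pid][k] + rng.normal(0, sd_eye[k]) for k in loc}
        nat = {
            "K": math.exp(eff["logK"]),
            "b": math.exp(eff["logb"]),
            "c": math.exp(eff["logc"]),
        }
        t = np.cumsum(
            np.concatenate(
                [[0.0], np.maximum(0.2, spacing + rng.normal(0, 0.1, n_visits - 1))]
            )
        )
        area = simulate_trajectory(spec, nat, t, sigma, rng)
        rows.append(
            pd.DataFrame(
                dict(patient_id=pid, eye_id=eid, t_years=t, area_mm2=area, gradable=True)
            )
        )
    return from_dataframe(pd.concat(rows, ignore_index=True), provenance=f"fixture:{seed}")


def make_linear_cohort(
    seed: int, n_eyes: int = 3, n_visits: int = 7, sigma: float = 0.0
) -> CohortTable:
    """Tiny linear-truth cohort (noiseless by default) for exact-recovery tests."""
    spec = get_model("linear")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_eyes):
        a = 1.0 + 0.3 * i
        s = 2.0 + 0.2 * i
        t = np.arange(n_visits) * 0.6
        area = simulate_trajectory(spec, {"a": a, "s": s}, t, sigma, rng)
        rows.append(
            pd.DataFrame(
                dict(
                    patient_id=f"P{i:02d}",
                    eye_id="OD",
                    t_years=t,
                    area_mm2=area,
                    gradable=True,
                )
            )
        )
    return from_dataframe(pd.concat(rows, ignore_index=True), provenance="linear-fixture")


@pytest.fixture(scope="session")
def tiny_gompertz_cohort() -> CohortTable:
    return make_gompertz_cohort(seed=7, n_eyes=8, n_visits=7)


@pytest.fixture(scope="session")
def noiseless_linear_cohort() -> CohortTable:
    return make_linear_cohort(seed=0)
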