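"""Longitudinal lesion-area cohort tables: read, validate, align, filter.

The canonical on-disk form is a comma-separated, UTF-8, headered CSV with
columns ``patient_id, eye_id, t_years, area_mm2, gradable`` (``visit_date``
may replace ``t_years`` on input; dates are converted to years since each
eye's first visit using day-count / 365.25).  Within an eye, times are
re-anchored so the earliest visit sits at t = 0 and duplicate timestamps are
resolved by keeping the last record.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError, ValidationError

__all__ = [
    "VisitRecord",
    "EyeSeries",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "apply_inclusion_filters",
    "eligibility_flags",
    "cohort_summary",
]

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["patient_id", "eye_id", "t_years", "area_mm2", "gradable"]
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class VisitRecord:
    """A single graded lesion measurement for one eye."""

    patient_id: str
    eye_id: str
    t: float  # years since the eye's first visit
    area: float  # lesion area, mm^2
    gradable: bool = True


@dataclass(frozen=True)
class EyeSeries:
    """One eye's time-ordered measurements (strictly increasing t)."""

    patient_id: str
    eye_id: str
    t: np.ndarray
    area: np.ndarray
    gradable: np.ndarray

    @property
    def n_visits(self) -> int:
        return len(self.t)

    @property
    def records(self) -> list[VisitRecord]:
        return [
            VisitRecord(self.patient_id, self.eye_id, float(tt), float(aa), bool(gg))
            for tt, aa, gg in zip(self.t, self.area, self.gradable)
        ]


@dataclass
class CohortTable:
    """A validated cohort: one row per (eye, visit) in canonical columns.

    ``eye_id`` values are unique within a patient but not globally; the
    ``eye_key`` helper joins the two.  ``filter_report`` accumulates exclusion
    counts so that (eyes in) = (eyes out) + (eyes excluded).
    """

    df: pd.DataFrame
    provenance: str = ""
    filter_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    # -- views --------------------------------------------------------------
    @property
    def n_visits(self) -> int:
        return len(self.df)

    @property
    def n_eyes(self) -> int:
        return self.df.groupby(["patient_id", "eye_id"], sort=True).ngroups

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    def eye_keys(self) -> list[tuple[str, str]]:
        return sorted(
            self.df.groupby(["patient_id", "eye_id"], sort=True).groups.keys()
        )

    def eyes(self) -> Iterator[EyeSeries]:
        for (pid, eid), grp in self.df.groupby(["patient_id", "eye_id"], sort=True):
            yield EyeSeries(
                patient_id=pid,
                eye_id=eid,
                t=grp["t_years"].to_numpy(dtype=float),
                area=grp["area_mm2"].to_numpy(dtype=float),
                gradable=grp["gradable"].to_numpy(dtype=bool),
            )

    def eye(self, patient_id: str, eye_id: str) -> EyeSeries:
        sub = self.df[
            (self.df["patient_id"] == patient_id) & (self.df["eye_id"] == eye_id)
        ]
        if sub.empty:
            raise KeyError(f"no eye ({patient_id!r}, {eye_id!r}) in cohort")
        return EyeSeries(
            patient_id,
            eye_id,
            sub["t_years"].to_numpy(dtype=float),
            sub["area_mm2"].to_numpy(dtype=float),
            sub["gradable"].to_numpy(dtype=bool),
        )


def _normalize(df: pd.DataFrame, provenance: str) -> CohortTable:
    """Sort, re-anchor times per eye, drop duplicate timestamps (keep last)."""
    df = df.sort_values(["patient_id", "eye_id", "t_years"], kind="mergesort")
    dup = df.duplicated(subset=["patient_id", "eye_id", "t_years"], keep="last")
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate-timestamp rows dropped (kept last record)",
            stacklevel=3,
        )
        df = df[~dup]
    df["t_years"] = df["t_years"] - df.groupby(["patient_id", "eye_id"])[
        "t_years"
    ].transform("min")
    return CohortTable(df=df.reset_index(drop=True), provenance=provenance)


def read_cohort(path, *, provenance: str | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    Requires ``patient_id``, ``eye_id``, ``area_mm2`` and one of ``t_years``
    or ``visit_date``.  A missing ``gradable`` column defaults to all-true.
    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` naming offending rows for bad values.
    """
    raw = pd.read_csv(
        path, dtype={"patient_id": str, "eye_id": str}, float_precision="round_trip"
    )
    for col in ("patient_id", "eye_id", "area_mm2"):
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    if "t_years" in raw.columns:
        t = pd.to_numeric(raw["t_years"], errors="coerce")
    elif "visit_date" in raw.columns:
        dates = pd.to_datetime(raw["visit_date"], errors="coerce")
        if dates.isna().any():
            bad = raw.index[dates.isna()].tolist()
            raise ValidationError(f"unparseable visit_date at rows {bad}")
        first = dates.groupby([raw["patient_id"], raw["eye_id"]]).transform("min")
        t = (dates - first).dt.days / DAYS_PER_YEAR
    else:
        raise SchemaError(f"need a 't_years' or 'visit_date' column in {path}")

    area = pd.to_numeric(raw["area_mm2"], errors="coerce")
    bad_area = raw.index[~np.isfinite(area) | (area < 0)].tolist()
    if bad_area:
        raise ValidationError(f"non-finite or negative area_mm2 at rows {bad_area}")
    bad_t = raw.index[~np.isfinite(t) | (t < 0)].tolist()
    if "t_years" in raw.columns and bad_t:
        raise ValidationError(f"non-finite or negative t_years at rows {bad_t}")

    gradable = (
        raw["gradable"].astype(bool)
        if "gradable" in raw.columns
        else pd.Series(True, index=raw.index)
    )
    df = pd.DataFrame(
        {
            "patient_id": raw["patient_id"],
            "eye_id": raw["eye_id"],
            "t_years": t.astype(float),
            "area_mm2": area.astype(float),
            "gradable": gradable,
        }
    )
    return _normalize(df, provenance or str(path))


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the canonical CSV dialect (comma, UTF-8, header, '.' decimal)."""
    out = cohort.df[CANONICAL_COLUMNS].copy()
    # %.17g guarantees value-exact float round-trips (read . write is identity)
    out.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def from_dataframe(df: pd.DataFrame, provenance: str = "") -> CohortTable:
    """Build a validated CohortTable from an in-memory canonical frame."""
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}")
    if (df["area_mm2"] < 0).any() or not np.isfinite(df["area_mm2"]).all():
        bad = df.index[(df["area_mm2"] < 0) | ~np.isfinite(df["area_mm2"])].tolist()
        raise ValidationError(f"non-finite or negative area_mm2 at rows {bad}")
    return _normalize(df.copy(), provenance)


def apply_inclusion_filters(
    cohort: CohortTable,
    min_visits: int = 5,
    min_large_visits: int = 3,
    large_area_threshold: float = 2.0,
) -> CohortTable:
    """Natural-history inclusion rule: keep eyes with a measurable growth signal.

    Retains eyes with at least ``min_visits`` gradable visits of which at
    least ``min_large_visits`` show an area strictly greater than
    ``large_area_threshold`` mm^2.  Non-gradable visits are dropped before
    counting (and from the output).  Idempotent.
    """
    df = cohort.df
    dropped_ungradable = int((~df["gradable"]).sum())
    df = df[df["gradable"]].copy()

    grp = df.groupby(["patient_id", "eye_id"], sort=True)
    n_vis = grp["area_mm2"].transform("size")
    n_large = grp["area_mm2"].transform(lambda a: (a > large_area_threshold).sum())
    keep = (n_vis >= min_visits) & (n_large >= min_large_visits)

    eyes_in = cohort.n_eyes
    per_eye = df.assign(_keep=keep).groupby(["patient_id", "eye_id"], sort=True)
    excl_visits = 0
    excl_large = 0
    for _, g in per_eye:
        if bool(g["_keep"].iloc[0]):
            continue
        if len(g) < min_visits:
            excl_visits += 1
        else:
            excl_large += 1
    out_df = df[keep].drop(columns=[], errors="ignore").reset_index(drop=True)
    out = _normalize(out_df, cohort.provenance)
    eyes_out = out.n_eyes
    report = dict(cohort.filter_report)
    report.update(
        {
            "eyes_in": eyes_in,
            "eyes_out": eyes_out,
            "eyes_excluded_min_visits": excl_visits,
            "eyes_excluded_min_large_visits": excl_large,
            "visits_dropped_nongradable": dropped_ungradable,
            "rule": {
                "min_visits": min_visits,
                "min_large_visits": min_large_visits,
                "large_area_threshold": large_area_threshold,
            },
        }
    )
    out.filter_report = report
    return out


def eligibility_flags(
    cohort: CohortTable, window: tuple[float, float] = (2.5, 17.5)
) -> pd.Series:
    """Flag visits inside the standard trial-eligibility window (inclusive)."""
    lo, hi = window
    if lo >= hi:
        raise ConfigError(f"eligibility window lower bound {lo} >= upper bound {hi}")
    a = cohort.df["area_mm2"]
    return ((a >= lo) & (a <= hi)).rename("trial_eligible")


def cohort_summary(cohort: CohortTable) -> dict[str, float]:
    """Per-cohort descriptives used for prior scaling and reporting."""
    df = cohort.df
    if df.empty:
        return {"max_area": 1.0, "t_span": 1.0, "n_eyes": 0, "n_visits": 0}
    per_eye = df.groupby(["patient_id", "eye_id"], sort=True)
    followup = per_eye["t_years"].max()
    baseline = per_eye["area_mm2"].first()
    visits = per_eye.size()
    return {
        "n_patients": cohort.n_patients,
        "n_eyes": cohort.n_eyes,
        "n_visits": int(len(df)),
        "max_area": float(df["area_mm2"].max()),
        "t_span": float(followup.max()),
        "median_followup_years": float(followup.median()),
        "median_visits_per_eye": float(visits.median()),
        "median_baseline_area": float(baseline.median()),
        "iqr_visits_per_eye": float(visits.quantile(0.75) - visits.quantile(0.25)),
        "iqr_followup_years": float(followup.quantile(0.75) - followup.quantile(0.25)),
    }
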