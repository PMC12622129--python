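"""Cohort I/O: schema validation, time alignment, inclusion filters, eligibility."""

import numpy as np
import pandas as pd
import pytest

from gagrowth.cohort import (
    apply_inclusion_filters,
    cohort_summary,
    eligibility_flags,
    from_dataframe,
    read_cohort,
    write_cohort,
)
from gagrowth.errors import ConfigError, SchemaError, ValidationError


def _csv(text: str, tmp_path, name="cohort.csv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


def test_dates_convert_to_years_since_first_visit(tmp_path):
    path = _csv(
        "patient_id,eye_id,visit_date,area_mm2\n"
        "P1,OD,2020-01-01,1.0\n"
        "P1,OD,2020-07-01,1.5\n"
        "P1,OD,2021-01-01,2.0\n",
        tmp_path,
    )
    cohort = read_cohort(path)
    t = cohort.df["t_years"].to_numpy()
    assert t[0] == 0.0
    assert t[1] == pytest.approx(182 / 365.25, abs=1e-9)
    assert t[2] == pytest.approx(366 / 365.25, abs=1e-9)


def test_header_only_file_gives_empty_cohort(tmp_path):
    path = _csv("patient_id,eye_id,t_years,area_mm2\n", tmp_path)
    cohort = read_cohort(path)
    assert cohort.n_eyes == 0 and cohort.n_visits == 0


def test_negative_area_names_offending_row(tmp_path):
    path = _csv(
        "patient_id,eye_id,t_years,area_mm2\nP1,OD,0.0,1.0\nP1,OD,0.5,-1.0\n",
        tmp_path,
    )
    with pytest.raises(ValidationError, match="1"):
        read_cohort(path)


def test_missing_column_names_the_column(tmp_path):
    path = _csv("patient_id,t_years,area_mm2\nP1,0.0,1.0\n", tmp_path)
    with pytest.raises(SchemaError, match="eye_id"):
        read_cohort(path)
    path2 = _csv("patient_id,eye_id,area_mm2\nP1,OD,1.0\n", tmp_path, "c2.csv")
    with pytest.raises(SchemaError, match="t_years"):
        read_cohort(path2)


def test_duplicate_timestamps_keep_last_with_warning(tmp_path):
    path = _csv(
        "patient_id,eye_id,t_years,area_mm2\nP1,OD,0.0,1.0\nP1,OD,0.5,2.0\nP1,OD,0.5,3.0\n",
        tmp_path,
    )
    with pytest.warns(UserWarning, match="duplicate"):
        cohort = read_cohort(path)
    eye = cohort.eye("P1", "OD")
    assert eye.n_visits == 2
    assert eye.area[-1] == 3.0


def test_times_reanchored_per_eye(tmp_path):
    path = _csv(
        "patient_id,eye_id,t_years,area_mm2\nP1,OD,2.0,1.0\nP1,OD,3.0,2.0\n",
        tmp_path,
    )
    cohort = read_cohort(path)
    assert cohort.df["t_years"].tolist() == [0.0, 1.0]


def _eye_df(areas, gradable=None, pid="P1", eid="OD"):
    n = len(areas)
    return pd.DataFrame(
        {
            "patient_id": pid,
            "eye_id": eid,
            "t_years": np.arange(n) * 0.5,
            "area_mm2": areas,
            "gradable": gradable if gradable is not None else [True] * n,
        }
    )


@pytest.mark.parametrize(
    "areas,gradable,kept",
    [
        # three visits strictly > 2.0 (the 2.0 itself does not count) -> kept
        ([0.5, 1.0, 2.0, 2.1, 2.5, 3.0], None, True),
        # 5 visits, one non-gradable -> only 4 gradable < 5 -> excluded
        ([2.5, 2.6, 2.7, 2.8, 2.9], [True, True, True, True, False], False),
        # 7 gradable visits all <= 2.0 -> excluded
        ([0.5, 1.0, 1.5, 1.8, 1.9, 2.0, 2.0], None, False),
    ],
)
def test_inclusion_rule_examples(areas, gradable, kept):
    cohort = from_dataframe(_eye_df(areas, gradable))
    out = apply_inclusion_filters(cohort)
    assert (out.n_eyes == 1) is kept


def test_filter_is_idempotent_and_counts_balance():
    df = pd.concat(
        [
            _eye_df([0.5, 1.0, 2.0, 2.1, 2.5, 3.0], pid="P1"),
            _eye_df([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], pid="P2"),
            _eye_df([3.0, 3.5, 4.0], pid="P3"),
        ],
        ignore_index=True,
    )
    cohort = from_dataframe(df)
    once = apply_inclusion_filters(cohort)
    twice = apply_inclusion_filters(once)
    pd.testing.assert_frame_equal(once.df, twice.df)
    rep = once.filter_report
    assert rep["eyes_in"] == 3 and rep["eyes_out"] == 1
    assert (
        rep["eyes_in"]
        == rep["eyes_out"]
        + rep["eyes_excluded_min_visits"]
        + rep["eyes_excluded_min_large_visits"]
    )


def test_roundtrip_is_bit_exact(tmp_path, tiny_gompertz_cohort):
    p1 = tmp_path / "a.csv"
    p2 = tmp_path / "b.csv"
    write_cohort(tiny_gompertz_cohort, p1)
    again = read_cohort(p1)
    write_cohort(again, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_eligibility_window_inclusive_bounds():
    cohort = from_dataframe(_eye_df([1.0, 2.49, 2.5, 3.0, 17.5, 20.0]))
    flags = eligibility_flags(cohort)
    assert flags.tolist() == [False, False, True, True, True, False]


def test_eligibility_window_config_error():
    cohort = from_dataframe(_eye_df([1.0, 2.0, 3.0]))
    with pytest.raises(ConfigError):
        eligibility_flags(cohort, window=(5.0, 5.0))


def test_cohort_summary_reports_medians(tiny_gompertz_cohort):
    s = cohort_summary(tiny_gompertz_cohort)
    assert s["n_eyes"] == 8
    assert s["median_visits_per_eye"] == 7
    assert s["max_area"] > 0
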