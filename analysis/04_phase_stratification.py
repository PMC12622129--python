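#!/usr/bin/env python
"""Stratify forecast accuracy by growth phase (acceleration/linear/deceleration).

Each forecast window is placed on the eye's trajectory using the rate-curve
landmarks of its Gompertz fit (simulation truth when available), and the
per-phase, per-model mean CRPS with bootstrap intervals and
probability-of-best is tabulated.  Writes the phase table under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gagrowth.models import get_model, landmarks
from gagrowth.phases import classify_window, stratified_scores
from gagrowth.scoring import ScoreRecord


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--scores", type=Path, default=Path("results/forecast_scores.csv"))
    ap.add_argument("--truth", type=Path, default=Path("results/cohort_truth.json"),
                    help="ground-truth parameters (simulation) for landmarks")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = pd.read_csv(args.scores)
    truth = json.loads(args.truth.read_text())
    spec = get_model(truth["model"])
    lm_cache = {
        key: landmarks(spec, params) for key, params in truth["eye_params"].items()
    }

    records, labels = [], []
    for row in table.itertuples():
        key = f"{row.patient_id}|{row.eye_id}"
        lm = lm_cache[key]
        records.append(
            ScoreRecord(
                eye_key=(row.patient_id, row.eye_id),
                model=row.model,
                origin_t=row.origin_t,
                target_t=row.target_t,
                horizon=row.horizon,
                n_prior_visits=row.n_prior_visits,
                observed=row.observed,
                crps=row.crps,
                abs_err_median=row.abs_err_median,
                signed_err_median=row.signed_err_median,
                interval_low=row.interval_low,
                interval_high=row.interval_high,
                covered=row.covered,
                width=row.width,
                level=0.9,
            )
        )
        labels.append(classify_window(lm, (row.origin_t, row.target_t), source="truth"))

    phase_counts = pd.Series([l.label for l in labels]).value_counts()
    print("windows per phase:", {k: int(v) for k, v in phase_counts.items()})
    out = stratified_scores(records, labels, seed=args.seed)
    out.to_csv(args.out / "phase_table.csv", index=False)
    print(out.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
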