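#!/usr/bin/env python
"""Simulate a study cohort of 24-h waist-accelerometer recordings.

Generates 8 patients with planted motor-fluctuation (gait-off) hours and
5 healthy controls, each a full simulated day sampled at 100 Hz, together
with ground-truth hour labels and hourly symptom diaries. Traces are large
and transient, so they are regenerated from the seed by later stages; this
script records the plans and ground truth under results/.
"""

import json
from pathlib import Path

import pandas as pd

from gaitrhythm.simulate import generate_cohort

SEED = 20260926
N_PATIENTS, N_CONTROLS = 8, 5
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cohort = generate_cohort(N_PATIENTS, N_CONTROLS, seed=SEED,
                             awareness=0.6, walking_minutes=10.0)
    rows = []
    for rec in cohort:
        for h, lbl, c, a, d in zip(rec.truth.hours, rec.truth.labels,
                                   rec.truth.cadences, rec.truth.amplitudes,
                                   rec.truth.diary_states):
            rows.append({"subject": rec.subject_id, "kind": rec.kind,
                         "hour": h, "label": lbl, "cadence": c,
                         "amplitude": a, "diary_truth": d,
                         "diary_reported": rec.diary.states.get(h, "")})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "cohort_ground_truth.csv", index=False)

    n_off = int((df["label"].isin(["off_bradykinetic", "off_shortstep"])).sum())
    summary = {
        "seed": SEED,
        "n_patients": N_PATIENTS,
        "n_controls": N_CONTROLS,
        "n_planted_off_hours": n_off,
        "n_subject_hours": len(df),
    }
    (OUT / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"simulated {N_PATIENTS} patients + {N_CONTROLS} controls "
          f"({len(df)} subject-hours, {n_off} planted off hours)")
    print(f"wrote {OUT / 'cohort_ground_truth.csv'}")


if __name__ == "__main__":
    main()
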