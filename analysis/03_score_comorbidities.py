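#!/usr/bin/env python
"""Score the simulated cohort and tabulate comorbidity burden.

Reads the cohort written by 02_simulate_cohort.py, computes comorbidity
profiles under the three look-back windows, and writes:

* results/count_distribution_{charlson,elixhauser}.csv — the diagnosis-count
  distribution (bins 0..5, >6) split by cases vs controls, complete record;
* results/lookback_trend.csv — share of patients with zero Charlson /
  Elixhauser categories per window, showing the expected monotone fall as
  the ascertainment window lengthens.
"""

import sys
from pathlib import Path

import pandas as pd

import readmorbid as rm
from readmorbid.synth_codes import build_synthetic_codelist

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    cohort_dir = ROOT / "scratch" / "cohort"
    if not cohort_dir.exists():
        print("run 02_simulate_cohort.py first", file=sys.stderr)
        return 1
    patients, events, _ = rm.read_cohort(cohort_dir)
    codelists = {m: build_synthetic_codelist(m) for m in ("charlson", "elixhauser")}

    profiles = {w: rm.score_cohort(patients, events, codelists, w)
                for w in ("1y", "5y", "full")}

    for measure in ("charlson", "elixhauser"):
        table = rm.count_distribution(profiles["full"], patients, measure)
        (100 * table).round(1).to_csv(
            ROOT / "results" / f"count_distribution_{measure}.csv"
        )
        print(f"\nDiagnosis-count distribution, {measure} (% by role, full record):")
        print((100 * table).round(1).to_string())

    trend_rows = []
    case_ids = patients.loc[patients["role"] == "case", "patient_id"]
    for w, prof in profiles.items():
        sub = prof.loc[case_ids]
        trend_rows.append({
            "window": w,
            "pct_cci_zero": 100 * (sub["charlson_count"] == 0).mean(),
            "pct_em_zero": 100 * (sub["em_count"] == 0).mean(),
            "median_cci": sub["cci_original"].median(),
            "median_em": sub["em_count"].median(),
        })
    trend = pd.DataFrame(trend_rows)
    trend.to_csv(ROOT / "results" / "lookback_trend.csv", index=False)
    print("\nZero-count share by look-back window (cases):")
    print(trend.round(1).to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
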