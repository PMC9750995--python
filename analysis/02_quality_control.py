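#!/usr/bin/env python
"""Apply the actigraphy inclusion rules to the simulated cohort.

A participant stays in the analysis with at least 7 days of usable data and
at most one day carrying >= 6 h of EXCLUDED minutes. Reports who was
filtered and why; the surviving subset feeds every later stage.
"""

from pathlib import Path

import pandas as pd

from sleepreg.qc import QCRule, filter_cohort
from sleepreg.simulate import GeneratorConfig, generate_cohort

SEED = 42
N = 120
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    records, _ = generate_cohort(GeneratorConfig(seed=SEED, n_participants=N))
    included, reports = filter_cohort(records, QCRule())

    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in reports],
            "n_days_with_data": [r.n_days_with_data for r in reports],
            "n_days_with_ge6h_excluded": [r.n_days_with_ge6h_excluded for r in reports],
            "included": [int(r.included) for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
        }
    ).sort_values("participant_id")
    df.to_csv(RESULTS / "qc_report.csv", index=False)

    n_min = df["reasons"].str.contains("MIN_DAYS").sum()
    n_exc = df["reasons"].str.contains("EXCLUDED_DAYS").sum()
    print(f"quality control on {len(records)} participants:")
    print(f"  included: {len(included)}   filtered: {len(records) - len(included)}")
    print(f"    < 7 days of data:            {n_min}")
    print(f"    > 1 day with >= 6 h excluded: {n_exc}")
    print(f"report -> {RESULTS / 'qc_report.csv'}")


if __name__ == "__main__":
    main()
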