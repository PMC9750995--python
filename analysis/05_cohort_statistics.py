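#!/usr/bin/env python
"""Cohort statistics: screening, correlations, relapse models.

Runs the full statistics stage on the QC-passing cohort: bivariate tests of
every derived variable against relapse; Pearson correlations of total SRI
with subjective measures, light windows and sleep duration plus the four
weekly SRI-vs-nap correlations; the three-block logistic regression of
relapse (SRI; +age; +subjective sleep efficiency); and the weekly-SRI
repeated-measures model with AIC-selected residual covariance.
"""

from pathlib import Path

import pandas as pd

from sleepreg.pipeline import build_cohort_tables
from sleepreg.qc import filter_cohort
from sleepreg.simulate import GeneratorConfig, generate_cohort
from sleepreg.stats import (
    bivariate_tests,
    correlate_sri_metrics,
    lmm_weekly_sri,
    stepwise_logistic_relapse,
)

SEED = 42
N = 120
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    records, _ = generate_cohort(GeneratorConfig(seed=SEED, n_participants=N))
    included, _ = filter_cohort(records)
    wide, long = build_cohort_tables(included)

    biv = bivariate_tests(
        wide,
        variables=["age", "sex", "marital", "total_sri", "psqi",
                   "subjective_sleep_efficiency", "sleep_duration_mean"],
    )
    biv.to_csv(RESULTS / "bivariate_tests.csv", index=False, float_format="%.6g")

    pairs = [("total_sri", "psqi"), ("total_sri", "subjective_sleep_efficiency"),
             ("total_sri", "light_24h"), ("total_sri", "sleep_duration_mean")]
    pairs += [(f"sri_w{w}", f"nap_w{w}") for w in range(1, 5)]
    corr = correlate_sri_metrics(wide, [p for p in pairs if p[1] in wide.columns])
    corr.to_csv(RESULTS / "correlations.csv", index=False, float_format="%.6g")

    blocks = stepwise_logistic_relapse(wide)
    rows = []
    for rep in blocks:
        t = rep.terms.copy()
        t.insert(0, "block", rep.block)
        rows.append(t)
    logistic = pd.concat(rows)
    logistic.to_csv(RESULTS / "logistic_blocks.csv", index=False, float_format="%.6g")

    lmm = lmm_weekly_sri(long.dropna(subset=["sri", "relapse"]))
    lt = lmm.terms.copy()
    lt["structure"] = lmm.structure
    lt["aic"] = lmm.aic
    lt.to_csv(RESULTS / "lmm_weekly_sri.csv", index=False, float_format="%.6g")

    rel = wide[wide["relapse"] == True]["total_sri"]  # noqa: E712
    non = wide[wide["relapse"] == False]["total_sri"]  # noqa: E712
    print(f"cohort statistics on {len(wide)} included participants")
    print(f"  total SRI, relapse vs none: {rel.mean():.2f} vs {non.mean():.2f}")
    sri_row = biv.set_index("variable").loc["total_sri"]
    print(f"  t-test for total SRI by relapse: t={sri_row['statistic']:.2f}, p={sri_row['p']:.4f}")
    for w in range(1, 5):
        row = corr.set_index(["x", "y"]).loc[(f"sri_w{w}", f"nap_w{w}")]
        print(f"  week {w} SRI vs nap duration: r={row['r']:.2f}, p={row['p']:.4f}")
    print("  logistic regression (odds ratio per SRI point):")
    for rep in blocks:
        row = rep.terms.set_index("term").loc["total_sri"]
        print(f"    block {rep.block}: OR={row['odds_ratio']:.3f} "
              f"[{row['ci_low']:.3f}, {row['ci_high']:.3f}], p={row['p']:.4f}")
    nap_rel = lmm.terms.set_index("term").loc["relapse:nap_duration"]
    print(f"  mixed model: residual covariance '{lmm.structure}'; "
          f"nap x relapse F({nap_rel['df_num']:.0f},{nap_rel['df_den']:.0f})="
          f"{nap_rel['F']:.2f}, p={nap_rel['p']:.4f}")
    print(f"reports -> {RESULTS}")


if __name__ == "__main__":
    main()
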