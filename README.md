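# sleepreg

Sleep-regularity analysis for wrist-actigraphy cohorts, built around the
question of whether an irregular sleep/wake schedule after discharge from
inpatient alcohol-use-disorder (AUD) treatment predicts relapse to drinking.

People leaving a structured inpatient program lose fixed lights-out and meal
times at exactly the moment relapse risk is highest. The **Sleep Regularity
Index (SRI)** quantifies how consistent a person's minute-by-minute
sleep/wake pattern is from one day to the next. For a record of *N* days
with *M* one-minute epochs per day and state *s<sub>i,j</sub>* (sleep/wake)
on day *i* at epoch *j*,

```
SRI = -100 + 200 / (M (N-1)) * Σ_j Σ_i δ(s_{i,j}, s_{i+1,j})
```

where δ = 1 when the two states agree and 0 otherwise. Sleeping and waking
at the same clock times every day gives SRI = 100; flipping state at every
epoch between consecutive days gives -100. Epochs marked EXCLUDED (device
off or invalid) carry no information: the default policy drops those
columns pair-wise and renormalizes by the remaining valid epochs, which
reduces exactly to the formula above on complete data.

The package implements the full pipeline on that index:

| stage | module | what it does |
|---|---|---|
| data model & I/O | `sleepreg.io` | canonical epoch/diary/interval/covariate CSVs; day-by-epoch matrices anchored at 17:00 |
| SRI core | `sleepreg.sri` | per-day-pair, weekly (days 1-7 / 8-14 / 15-21 / 22-28) and total scores |
| quality control | `sleepreg.qc` | inclusion: ≥ 7 days of data, ≤ 1 day with ≥ 6 h excluded |
| daily metrics | `sleepreg.metrics` | sleep duration / WASO / SOL / efficiency, diary-gated naps, ≥ 250 lux light minutes by clock window, drinking outcomes |
| cohort statistics | `sleepreg.stats` | bivariate screening, Pearson correlations, three-block logistic regression of relapse, weekly-SRI repeated-measures model with AIC-selected residual covariance (CS / AR(1) / unstructured) |
| synthetic cohort | `sleepreg.simulate` | 28-day cohorts with known jitter, nap coupling, missingness, light profiles and a logistic relapse link on the realized SRI |
| orchestration | `sleepreg.pipeline`, `sleepreg.cli` | end-to-end runs with manifests; `sleepreg {simulate,qc,sri,metrics,stats,run}` |

The clinical study this models did not deposit its raw data, so the
synthetic-cohort generator is a first-class module: it reproduces the
cohort's published summary profile (total SRI ≈ 70, ~23% relapse, ~7.5 h
sleep, roughly a third of enrollees failing actigraphy QC) with every
ground-truth parameter known, which is what makes the statistics stage
testable end to end.

## Worked example

The `analysis/` scripts run the whole study design on a simulated
120-participant cohort (seed 42):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quality_control.py
python analysis/03_sleep_regularity.py
python analysis/04_daily_metrics.py
python analysis/05_cohort_statistics.py
```

The final script prints (abridged):

```
cohort statistics on 89 included participants
  total SRI, relapse vs none: 65.85 vs 71.57
  t-test for total SRI by relapse: t=2.88, p=0.0050
  week 1 SRI vs nap duration: r=-0.27, p=0.0097
  week 2 SRI vs nap duration: r=-0.43, p=0.0000
  week 3 SRI vs nap duration: r=-0.41, p=0.0001
  week 4 SRI vs nap duration: r=-0.50, p=0.0000
  logistic regression (odds ratio per SRI point):
    block 1: OR=0.927 [0.871, 0.985], p=0.0151
    block 2: OR=0.927 [0.872, 0.986], p=0.0156
    block 3: OR=0.926 [0.869, 0.986], p=0.0164
```

Read: of 120 simulated enrollees, 89 pass actigraphy QC; participants who
relapse have visibly lower sleep regularity; weekly nap minutes correlate
negatively with weekly SRI in all four weeks; and each additional SRI point
lowers the odds of relapse by ~7% (OR < 1), robust to adjusting for age and
subjective sleep efficiency. Every number above is recomputed by the
scripts from the seed — per-stage tables land in `results/`.

The same pipeline runs from the shell on any canonical epoch CSV:

```bash
sleepreg simulate --seed 42 --n 20 --out simdir/
sleepreg sri --epochs simdir/epochs.csv --day-start 17:00 --out sri.csv
sleepreg run --out outdir/ --seed 42
```

## Documentation

`docs/methods.md` describes the model and estimation choices: EXCLUDED-epoch
policy, week-window semantics, the REML engine behind the repeated-measures
model and its degrees-of-freedom convention, what the synthetic cohort does
and does not emulate, and known limitations.
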