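# herdtools

Dairy herd-management software records per-cow health and production
"events" (mastitis, milk fever, twins, sold/died, ...) alongside stored
"items" such as first-test butterfat, and exports them as wide CSVs with
repeated event/date/remark columns. Those exports are awkward to analyse:
events are free-text aliases, duplicate recordings pile up, and the unit of
analysis an epidemiologist wants — one row per cow-lactation — has to be
assembled by hand. `herdtools` automates that assembly and bundles the two
analyses herd consultants ask for first:

1. **Compilation** — raw export → cleaned cow-lactation table: alias
   renaming (SCOURS → DIARRHEA), remark/protocol merging, a 3-day rolling
   de-duplication filter, occurrence numbering and widening
   (`MAST_1_DATE`, `MAST_1_REMARK`, ...), removal (REMVD) derived from
   sold/died, row exclusions (pre-first-lactation, invalid dates, fresh
   date outside the analysis window), rule-driven derived indicators
   (`MLK_FVR<=7`, `REMVD<60`, lactation group `LCTGP = min(LACT, 3)`), and
   factor-level ordering (binary reference `'0'` first, multinomial levels
   by ascending frequency).
2. **Pivot / odds ratios** — a two-way frequency table with margins plus an
   odds ratio per non-reference level pair, estimated by a baseline-category
   multinomial logit. For a 2×2 table with cells *a, b, c, d* this equals the
   cross-product ratio OR = *ad/bc* with Wald interval
   exp(log OR ± z·√(1/a + 1/b + 1/c + 1/d)).
3. **Regression** — response type picks the model (numeric → linear,
   two-level factor → logistic, more → multinomial), with a coefficient
   table and a sequential (Type I) ANOVA / analysis-of-deviance table.

A synthetic herd generator (`herdtools.synth`) emits raw exports in the same
layout with a ground-truth manifest, so every stage is testable without farm
data. The analyses are also available as sklearn-style estimators
(`HerdCleaner`, `PivotOddsRatio`, `AutoRegression`).

## Worked example

Simulate a herd under the package's default study conditions (a ~1000-cow
dairy over a 2-year fresh-date window, with injected twin/lactation odds
ratios 1.7 and 4.6, a removal-before-60-DIM odds ratio of 3.4 for twins, and
a −0.28 direct twin effect on first-test butterfat), then compile and
analyse it:

```sh
herdtools simulate --out sim --seed 1
herdtools clean --input sim/synthetic_raw.csv --out run \
    --fresh-start 2020-10-12 --fresh-end 2023-10-12
herdtools pivot   --input run/cleaned.csv --row LCTGP --col TWINS \
    --row-ref 1 --col-ref 0 --out run/pivot
herdtools regress --input run/cleaned.csv --response FSTBF \
    --predictors TWINS --predictors LCTGP --out run/regress
```

`clean` reports the row bookkeeping (seed 1):

```
rows in:  2275
rows out: 2106
  excluded (lactation_not_started): 54
  excluded (invalid_or_missing_dates): 38
  excluded (fresh_date_outside_window): 77
event triples read: 1457
  dropped blank/missing event: 0
  dropped unparseable date:    0
  dropped by rolling filter:   116
```

2106 cow-lactation rows survive the filters; 116 duplicate event recordings
fell to the 3-day rolling filter. The pivot command then estimates
OR(twins; lactation group 2 vs 1) ≈ 2.5 (95% CI 1.3–4.7) and
OR(group 3+ vs 1) ≈ 5.3 (3.0–9.3) — the injected truths 1.7 and 4.6 lie
inside both intervals; older cows twin far more often. The regression
command fits FSTBF ~ TWINS + LCTGP and reports a twin coefficient of −0.25
(SE 0.055): twin-bearing cows lose about a quarter of a butterfat point at
first test, after controlling for lactation group. Estimates vary from seed
to seed within their reported standard errors.

Each output directory also contains the plots (`forest.png`,
`comparative_bar.png`, `pairs.png`, `coefficient_plot.png`), their
underlying CSV data, and a `run_manifest.json` recording inputs and
configuration.

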