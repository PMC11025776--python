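# Methods

## The compilation pipeline

Raw herd exports are header-first CSVs, one row per cow-lactation, holding
identification (`ID`), lactation number (`LACT`), birth/fresh/first-calving
dates (`BDAT`, `FDAT`, `FCDAT`), item columns (first-test butterfat `FSTBF`,
percent), and repeated event triples (`EVT1, DAT1, REM1, ...`). All naming
is configurable (`IngestConfig`); the defaults match the bundled generator.
Dates are short month/day/two-digit-year strings; two-digit years resolve
against a pivot of 1970 (`yy < 70 → 20yy`, else `19yy`), because herd
records span roughly the 1990s–2020s. Invalid date text never raises — it
maps to an explicit missing value that downstream filters handle. Files are
read as UTF-8 with BOM tolerance (they usually originate on Windows).

Compilation proceeds in a fixed order; every dropped row or event is
counted in the compile report:

1. **Melt and canonicalise.** Event triples become a long stream; names are
   upper-cased and passed through a configurable rename map (default:
   SCOURS → DIARRHEA, MF → MLK_FVR, KETOSIS → KET, RETPLA → RP,
   TWINS → TWIN). Unmapped names pass through unchanged with a log note, so
   an unexpected event is never silently lost. Blank event names and
   unparseable event dates are dropped and counted. Remark and protocol
   text are merged with `" | "`, blanks elided.
2. **Rolling de-duplication.** Within each (cow, lactation, event), sorted
   by date, the first observation is always kept and a later one is dropped
   iff its gap to the last *kept* observation is `< lag_days` (default 3).
   Milk fever recorded at 1, 2 and 4 DIM therefore keeps 1 and 4: the 2-DIM
   entry is 1 day after the kept 1-DIM entry (dropped), the 4-DIM entry is
   3 days after it (kept). Anchoring on the last kept observation — rather
   than the previous raw one — is what makes the 4-DIM entry survive, and
   strict `<` is the comparison consistent with it. The filter runs before
   occurrence numbering so that counts and first-occurrence DIMs reflect
   de-duplicated events.
3. **Number and widen.** Occurrences are numbered per (cow, lactation,
   event) in date order and widened to `{EVENT}_{n}_DATE` /
   `{EVENT}_{n}_REMARK` columns plus a `{EVENT}_N` count. Events required
   downstream (the default roster: TWIN, RP, KET, MLK_FVR, MAST, DIARRHEA,
   SOLD, DIED) get first-occurrence placeholder columns even when never
   observed.
4. **Removal.** `REMVD` is `'1'` with the sold-or-died date and remark if
   either event exists; when both exist the earlier one supplies the date
   and both are noted in the remark.
5. **Row filters.** Rows are excluded, with exclusive counted reasons
   checked in order, when lactation is missing or `< 1` (the cow has not
   started its first lactation), when any of the three core dates is
   invalid or missing, or when the fresh date falls outside the analysis
   window (a closed interval; both endpoints retained).
6. **Derived variables.** A rule engine computes occurrence flags,
   first-occurrence DIM, and cutoff indicators from the event columns, with
   DIM = event date − fresh date in whole days. Only occurrences with
   DIM ≥ 0 count as lactation-period occurrences; events recorded before
   the fresh date belong to the previous lactation and are ignored here.
   Cutoff indicators (e.g. `MLK_FVR<=7`, milk fever within 7 days in milk;
   `REMVD<60`, removal strictly before 60 DIM — "before" read as strict)
   are `'0'` whenever the event never occurred, so the indicator implies
   the occurrence flag. `LCTGP = min(LACT, 3)` groups lactations 1, 2, 3+,
   the standard transition-cow grouping.
7. **Factor ordering.** Binary factors carry level order `['0', '1']` with
   `'0'` as reference; multinomial factors are ordered by ascending
   observed frequency with an alphabetical tie-break (a deterministic
   choice where frequency alone is ambiguous).

The pipeline is deterministic: identical input and configuration yield a
byte-identical cleaned CSV. Cleaned CSVs serialise dates as ISO 8601 and
re-import losslessly; re-import re-derives factor order from the same data,
so round-tripping preserves every cell value.

## Pivot tables and odds ratios

`crosstab` builds the two-way table over pairwise-complete rows (the
excluded count is reported) with margins. Odds ratios come from a
baseline-category multinomial logit of the column variable on row-variable
dummies, fitted by Newton's method on the expanded counts (statsmodels
`MNLogit`); the declared reference levels are the baselines. Because the
model is saturated, the MLE for each non-reference (row, column) pair is
exactly the 2×2 cross-product ratio of the corresponding cells, and the
Wald interval on the log scale equals
exp(log OR ± z·√(1/a + 1/b + 1/c + 1/d)); the test suite holds the fit to
that closed form at 1e-4/1e-3 relative. Confidence level defaults to 0.95
and is configurable. Any contrast whose 2×2 cells include a zero is
reported as non-estimable with a warning instead of forcing a diverging
fit; the remaining contrasts are computed from their own all-positive
sub-tables. For an all-positive R×C table the joint fit and the per-contrast
2×2 collapse coincide, so the choice of a joint fit costs nothing and keeps
a single model behind the table.

## Regression

The response type selects the model: numeric → OLS; two-level factor →
logistic; more levels → baseline-category multinomial. Categorical
predictors enter treatment-coded against their declared reference (first
level, i.e. `'0'` for binary indicators; note that a multinomial factor's
first level is its *least frequent* one under the ordering rule, which
changes which dummy is dropped but not the other coefficients). Fits are
complete-case with the dropped count reported. The ANOVA table is
sequential (Type I) in user-entry order — term order changes per-term sums
of squares but never the residual — computed by `anova_lm` for OLS and by
nested-model likelihood-ratio deviances (chi-square p-values) for the
logistic/multinomial kinds. Wald CIs are reported at 95%; standard errors
are in the machine output so other levels are recomputable. Rank-deficient
designs raise an error naming the aliased terms (QR with pivoting).
Perfect separation makes Newton's method blow up; the fit falls back to
BFGS and any term with |coefficient| > 15, or a non-converged fit, is
flagged non-estimable with a warning. Interactions and random effects are
out of scope.

## The synthetic herd generator

The generator emulates the structure the pipeline assumes — not dairy
biology. Its defaults are the package's study conditions: 2106 valid
cow-lactation rows (plus 54 pre-first-lactation heifers, 38 rows with a
corrupted core date and 77 rows freshening before the window, all of which
the pipeline must drop), a 2020-10-12..2023-10-12 fresh window, a lactation
mix of 38/27/35% across groups 1/2/3+, and about 15% of rows paired as
consecutive lactations of the same cow to exercise the (ID, LACT) grouping.

Injected associations, all recoverable from the manifest:

* twin birth: 2.5% in first lactation, odds ratios 1.7 (group 2) and 4.6
  (group 3+) applied on the odds scale;
* removal before 60 DIM: 3.5% baseline, odds ratio 3.4 for twin-bearing
  cows; later removals (60–330 DIM) occur at 15/17/28% by lactation group;
* first-test butterfat: 4.2% baseline, lactation-group offsets 0/−0.04/−0.07,
  direct twin effect −0.28 and ketosis effect 0, Gaussian noise SD 0.55,
  rounded to one decimal as exports do. The offsets were sized analytically
  so that, with twins concentrated in older cows, the *unadjusted* twin
  effect is ≈ −0.30 while adjusting for LCTGP recovers −0.28 — a small,
  realistic confounding structure.

Disease events (milk fever near calving, ketosis at 3–25 DIM, retained
placenta at 0–2, mastitis at 4–250 with a 30% second case ≥ 10 days later,
scours — written under its raw alias SCOURS) are Bernoulli per lactation,
some with lactation-group-dependent rates. With probability 0.15 an event
is re-recorded 1–2 days later ("RECHECK"), which the rolling filter must
remove; genuine repeat cases are always ≥ 10 days apart, so manifest counts
equal post-filter counts by construction. Events dated after a cow's
removal are suppressed. Cows removed before 30 DIM have no first test and
hence missing FSTBF — missingness depends only on model covariates, so
regression estimates stay unbiased.

All draws flow through one seeded `numpy` generator; the same (config,
seed) pair yields byte-identical CSVs.

What passing tests on this generator do **not** show: robustness to real
exports' naming drift beyond the configured map, non-Gaussian butterfat
distributions, seasonality, within-cow correlation across lactations, or
recording error other than the modelled duplicates and date corruption.

## Problem sizes and numerical choices

The verification suite runs at the study sizes above: the worked-example
herd once (n = 2106); 500 random 2×2 tables against the closed-form OR
oracle; interval coverage for a true OR of 4.0 over 400 replicates of
n = 5000 (the ±3 pp acceptance band is wide relative to the ~1 pp Monte
Carlo error at that replicate count); and twin-effect recovery over 200
full generate→compile→fit replicates at n = 1000. Statistical recoveries
are asserted within two fitted standard errors of the injected truth;
structural quantities (row counts, margins, SS decompositions, round
trips) are exact. Quantiles in the summary report use linear interpolation
(type 7). MNLogit fits use Newton with a 200-iteration cap; saturated
pivot fits converge to the closed form well inside the 1e-4 tolerance.

## Known limitations

Calf events, cross-herd merging, imputation of invalid dates, random
effects, interaction terms, exact (Fisher) intervals and stratified
(Mantel–Haenszel) odds ratios are all out of scope. The rename map ships
with a small default alias set; real deployments should extend it in the
YAML config. The web-dashboard style of the original workflow is replaced
by CLI subcommands writing CSV/PNG outputs.
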