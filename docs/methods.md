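# Methods

This note documents the models, conventions and design choices behind
`pigpex`, in the order a user meets them: growth curve → excretion
equations → lifetime projection → model-development pipeline →
synthetic balance-trial generator.

## Growth curve

Body weight follows the Gompertz form BW(t) = A·exp(−b·exp(−k·t)) with
defaults A = 217.4 kg (mature weight), b = 4.6919 (dimensionless
shape), k = 0.0116 /d, for age t in days. The defaults describe a
modern commercial crossbred (barrow/gilt average) reaching 7 kg at 27 d
and 121.5 kg at 180 d. The curve is strictly increasing and bounded by
A; `age_at_bw` is the closed-form inverse, defined on (0, A).

Age is continuous in this module. No validity clamp is applied here —
whether an age or weight is sensible for a given purpose (e.g. the
equations' fitted range) is judged by the caller, and the projection
layer carries an explicit in-domain flag instead.

## Excretion equations

An `ExcretionModel` is intercept + Σ coefficient·term, where each term
is one of the nine deterministic functions of (BW, FI, dietP): the
three covariates, their squares, and their pairwise products. Units
are a hard contract: BW kg, FI kg/d, dietP percent as-fed (0.64 means
0.64 g P / 100 g feed). The module never rescales inputs; the CSV
reader converts g/d feed intake to kg/d only when told to
(`--fi-units g_d`), so a unit error surfaces as an obvious ×1000
discrepancy rather than a silent correction.

Predictions are returned unclamped. The shipped equations were fitted
on BW 7–121.5 kg and dietP 0.40–0.64 %; outside that box they can go
negative (the BW² term dominates), and `evaluate_with_flag` reports
whether inputs sit inside the fitted domain. Clamping at zero would
silently distort any budget computed near the domain edge, so it is
deliberately not done.

The six published equations ship as package data (JSON) at the printed
precision, which is treated as canonical; serialization round-trips
them bit-identically.

## Lifetime projection

Conventions, each of which matters for reproducing published budgets:

- daily grid = integer ages, **inclusive** at both ends (default
  27..180 → 154 days), every day weighted equally;
- BW evaluated at the integer age itself (not mid-day);
- dietP from the phase covering that age; the default schedule is
  age-indexed (27–39 / 40–66 / 67–94 / 95–117 / 118–138 / 139–180 d at
  0.64 / 0.58 / 0.51 / 0.46 / 0.43 / 0.40 % as-fed) with the BW ranges
  carried as metadata only, avoiding a circular BW lookup;
- the total stream is the per-day **sum of the fecal and urinary
  predictions** (Eq1 + Eq2), not the separately fitted total model;
  Eq3 can be projected explicitly for comparison;
- annualization = lifetime mean (g/d) × 365 / 1000 (kg/yr);
- rounding to 2 decimals (half-up) happens only in the presentation
  layer (`rounded_summary`, the CLI report); all stored values are
  full precision.

Under these conventions the default projection gives lifetime means of
3.393 (fecal), 0.240 (urinary) and 3.633 (total) g/d and annual totals
of 1.24 / 0.09 / 1.33 kg/yr. A handful of phase means differ by
exactly 0.01 g/d from previously reported values (e.g. phase-4 fecal
4.3751 → 4.38; phase-5 total 4.9546 → 4.95): these are
rounding-order artifacts — summing two independently rounded streams,
or rounding a value that sits at a .xx5 boundary — not model
differences, and the package always reports the full-precision
computation rounded once.

Only BW/dietP models can be projected: the projection defines no daily
feed-intake trajectory, so FI-based models are rejected with an
explicit error rather than silently fed a fabricated FI.

`herd_adjust(pig, m, f) = (1−f)·pig + f·m·pig` folds the sow population
into a per-head annual figure; defaults m = 2 (a sow excretes about
twice a market pig's P) and f = 0.10 (sows ≈ 10 % of the herd).

## Model-development pipeline

**Outlier screen.** Daily urinary P is screened per experiment with a
Tukey-type fence: flag values strictly beyond quartile ± k·IQR,
default k = 3. Quartiles use linear interpolation between order
statistics (the numpy default); quantile conventions differ across
software, but at k = 3 only gross errors are flagged under any common
definition, and both k and the screen column are configurable. The
screen runs per experiment because urinary-P scale differs severalfold
between growth stages. At least 4 values are required.

**Correlation screen.** Pearson r among BW, FI, dietP and the
excretion streams, with two-sided p-values from the exact t transform
(df = n−2). Zero-variance columns yield flagged NaN entries rather
than an exception.

**Stepwise selection.** Forward entry with post-entry removal, the
SAS-style SLENTRY/SLSTAY procedure at 0.05/0.05: at each step every
remaining candidate is fitted on top of the current model; the
candidate with the smallest coefficient p-value enters if below
`alpha_enter` (ties broken by larger partial R², then candidate list
order); after each entry any included term with p ≥ `alpha_stay` is
removed, largest first, refitting after each removal. Setting
`alpha_stay = 1` gives pure forward selection. The intercept is always
estimated and never removed (published equations of this family retain
non-significant intercepts). Rank-deficient candidates are skipped
with a logged warning; if nothing enters, the intercept-only model is
a valid result. Every decision is recorded in a trace.

Candidate sets: `ALL_CANDIDATE_TERMS` (all nine) and the guided
families `BW_DIETP_TERMS` / `FI_DIETP_TERMS`. Equations meant for
field use are developed within one family, because FI ∝ BW under
percentage-of-BW feeding makes the families nearly interchangeable in
fit while only one may be computable by the end user.

Numerical core: OLS via `numpy.linalg.lstsq` with intercept prepended,
t-test p-values from scipy; RMSE = √(SSE/(n−p)) with p counting the
intercept, R² = 1 − SSE/SST. A fit with SSE ≤ 1e−12·SST is treated as
numerically perfect: entry stops, and any term whose removal keeps the
fit perfect is pruned exactly — at that point t-statistics are
floating-point artifacts and must not drive decisions. This is what
makes noiseless identifiability exact: data generated from a shipped
equation with zero residual recovers precisely its term set and
coefficients. The statsmodels OLS implementation is used in the test
suite as an independent oracle for coefficients, standard errors and
p-values, never as the implementation.

No multiplicity correction is applied beyond the per-term entry
threshold; this mirrors standard practice for this family of
equations. The fitted records are pig×period observations treated as
independent experimental units (no mixed-model period/square effects).

## Synthetic balance-trial generator

The generator emulates four total-collection experiments at BW centers
≈15/30/50/80 kg: 12 pigs × 2 periods each (9 d periods: 5 d adaptation
+ 4 d collection), three diets per experiment in a balanced Latin-
square-like rotation (each diet 8 of 24 records), 96 records in all.

Per experiment: initial BW ~ Normal(mean, sd) with the study's
dispersions (15.2/29.9/50.2/78.2 kg, sd 0.7/1.8/2.2/3.7); per-pig
total gain ~ Normal(final − initial mean, √(final_sd² − initial_sd²)),
truncated at 10 % of the mean span, so that the final-BW dispersions
(sd 1.4/2.7/4.2/4.5) are also reproduced; record BW is the period
midpoint. Feed allowance is 6.0 % of experiment-initial BW (Exp 1;
over-allowance feeding of weanlings) or 4.5/4.0/3.0 % of
period-initial BW (Exps 2–4), with ±5 % multiplicative jitter for
realized intake. Diet P levels are the analyzed concentrations of the
twelve experimental diets. P intake = FI × dietP × 10 (g/d).

Responses: fecal = truth-model prediction (default Eq1) + Normal(0,
0.656) truncated below at 0.05 g/d; urinary likewise (default Eq2, sd
0.194, floor 0.01 g/d). With probability `outlier_rate` (default 0.01
≈ 1 gross error per 96 records, matching the screen's intended catch
rate) a record's urinary value is multiplied by `outlier_scale`
(default 10). Everything is driven by one master seed;
per-experiment sub-streams are spawned deterministically so any
stratum can be regenerated alone.

What the generator does *not* emulate — and therefore what passing
tests do not establish about real data:

- **Crossover correlation.** Records within a pig are independent
  given the design; the real Latin-square structure induces
  within-pig correlation that plain OLS ignores (as does the pipeline
  being validated).
- **Heteroscedastic residuals.** Residual SD is constant at the
  published RMSE. Real fecal residuals shrink with pig size: with a
  constant 0.656 g/d SD the 15-kg stratum's fecal CV is necessarily
  ≈45 %, above the ≈28 % observed in real data, while the heavier
  strata fall inside the observed 12–28 % envelope. Tests assert the
  envelope only where the homoscedastic design can meet it.
- **Urinary right-skew.** Real urinary-P CVs (47–120 %) suggest a
  skewed residual; the default is truncated Gaussian. A
  moment-matched lognormal option (`urinary_distribution="lognormal"`)
  exists, but no distributional claim is made.
- **Assay error** in diet-P concentrations (taken as exact).

### Recovery properties and their limits

With the default design, refitting the fecal response within the
BW/dietP family recovers the BW×dietP coefficient within ±3 SE of
truth in ≈90 % of replicates, and selects BW×dietP in ≥95 % of seeds.
The dominant failure mode is an alias: the four BW clusters make BW
and BW² nearly collinear (r > 0.97), so greedy selection occasionally
keeps BW instead of BW² — a nearly equivalent model whose coefficients
are not comparable to the generating ones. For the same reason the
pure-noise false-entry rate (~10 % on generator covariates, ~19 % on
iid covariates) is far below the 1 − 0.95⁹ ≈ 37 % that nine
*independent* candidates would give: the nine terms span only about
two to four effective dimensions.

## Problem sizes used in validation

Stochastic checks run at the scale of the emulated study: 96-record
datasets, 100–200 seeded replicates for recovery and calibration
rates, 1000 random vectors for the outlier-screen oracle, and
exhaustive best-subset enumeration at n = 40 with 5 candidates. These
sizes give Monte-Carlo standard errors of ~2 % on the reported rates;
rates quoted near a bound (e.g. 90 %) should be read with that error
in mind.
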