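# Methods

`capeneeg` implements a prognostic EEG analysis for patients with
unresponsive wakefulness syndrome (UWS): nonlinear cortical-network
features are extracted from 16-channel EEG recorded under closed-eyes and
pain-stimulation conditions, reduced to a single pain-evoked difference
statistic, and used to classify 12-month recovery (modified Glasgow Outcome
Scale, mGOS ≥ 3) at a fixed clinical cutoff. Because no patient-level EEG
is publicly available for this design, the package ships a seeded synthetic
cohort generator that realizes the coupling structure the analysis assumes,
so every stage can be exercised and validated end to end.

## Cross-approximate entropy

For two series `u` (template) and `v` (target), both standardized to zero
mean and unit SD, with embedding dimension `m`, delay `lag` and Chebyshev
tolerance `r` (a fraction of the now-unit SD):

    C_i^k = #{ j : max_{0<=s<k} |u*(i+s·lag) − v*(j+s·lag)| <= r } / T
    Φ^k   = mean_i ln C_i^k          over templates with C_i^k > 0
    C-ApEn = Φ^m − Φ^{m+1}

Low values mean patterns recurring in `u` also recur in `v` (synchrony);
high values mean asynchrony. `apen(u) = capen(u, u)` exactly, including the
self-match. Conventions, all deliberate:

- **Common template count** `T = N − m·lag` at both lengths. The textbook
  convention uses `N − m·lag + 1` templates at length `m` and one fewer at
  `m + 1`; sharing one count removes that small mismatch bias and makes the
  two Φ averages directly comparable.
- **Inclusive tolerance** (`d <= r`).
- **Zero-match templates** are dropped from the Φ average at the length
  where they match nothing (no pseudo-counts) and reported in
  `n_zero_match`; the estimate is declared undefined (an error carrying the
  diagnostic counts) only when every template drops.
- **Standardization first**, so the statistic is exactly invariant to
  channel gain and offset; unit mistakes upstream cannot change any result.
- The statistic is **directional**; the pipeline always uses the central
  electrode (Cu or Ca) as the template series.

Defaults `m = 2`, `r = 0.2·SD`, `lag = 1` are the standard choices for
cross-ApEn on biomedical series. The fast kernel counts matches in compiled
code with exact float64 arithmetic; `capen_reference` is an independent
double-loop enumeration kept solely as a testing oracle, and the suite
holds the two to 1e−12 agreement.

### Epoching

Long recordings are split into non-overlapping epochs of `epoch_len`
samples; per-epoch estimates are averaged (mean, matching the
one-value-per-cell layout of the downstream regression). The default epoch
is 1024 samples = 8 s at the generator's 128 Hz sampling rate. C-ApEn has a
strong template-count dependence, so epoch means are only comparable
between equal epoch lengths; the tests check stationary consistency at
fixed epoch size. Epochs with degenerate signals or undefined estimates are
skipped and counted; a cell is reported only with at least one valid epoch.

## Montage, relabeling, and the pair catalog

The montage is fixed at 16 channels in 8 homologous left/right pairs. The
design names only region codes (FP, F, AT, C, MT, P, PT, O); the package
assigns the conventional 10-20 electrodes Fp1/Fp2, F3/F4, F7/F8, C3/C4,
T3/T4, P3/P4, T5/T6, O1/O2. Because lesion side varies across patients,
left/right labels are replaced by affected (`a`) / unaffected (`u`) roles
per patient; relabeling touches labels only, never the signal. Features are
computed over a fixed catalog of ten within-hemisphere pairs anchored at
the central electrode: six local (C–F, C–MT, C–P per side) and four remote
(C–FP, C–O per side).

## The difference statistic and classifier

    D = C-ApEn(Cu–FPu | pain stimulation, unaffected side)
      − C-ApEn(Cu–FPu | closed eyes)

Only the unaffected-side pain condition enters D; affected-side pain
features are still computed for the regression stage. Recovery is predicted
iff `D >= 0.07`. The boundary is inclusive — the cutoff is read as the
least value that predicts recovery; the clinically adopted 0.07 (not the
ROC-derived 0.045) is the default and is configurable. ROC analysis sweeps
the observed D values with the same `D >= t` rule, trapezoidal AUC
(verified identical to Mann–Whitney pair counting and to scikit-learn), and
a Youden cutoff with ties broken toward the smallest threshold (favoring
sensitivity).

## Cohort statistics

- Continuous baselines: pooled-variance two-sample t (df `n1+n2−2`),
  computable from printed group summaries; this convention — not Welch —
  reproduces the published age/duration statistics.
- Dichotomous baselines: Pearson chi-square without continuity correction,
  df 1 — again the convention that reproduces the published values.
- Improvement rates: percentages to one decimal.
- Outcome model: OLS of the mGOS score (default; the binary improvement
  label is a supported alternative, since the source text is ambiguous and
  the published intercept of ~2.3 sits on the score scale) on eight C-ApEn
  cells (three affected-side cells under affected pain, five
  unaffected-side cells under unaffected pain) plus sex, age, duration and
  lesion type. Sex and lesion are coded 0/1 (male = 0, TBI = 0); the coding
  affects only signs and the intercept. Tolerance is `1 − R²` of each
  predictor's auxiliary regression on the others; VIF its reciprocal
  (cross-checked against statsmodels). Rank-deficient designs raise an
  error naming the dependent columns.

Note: pooled t on the published age summaries gives −1.9636 where the
source prints −1.963; the printed group summaries are rounded to two
decimals, which perturbs t by about ±0.002. The tests assert at that
input-precision tolerance.

## Synthetic cohort generator

Every channel is a convex mixture of a shared latent source and
channel-private noise, both standardized:

    x_c(t) = w_c·z(t) + (1 − w_c)·ε_c(t)

- `z`: AR(2) with spectral peak at 10 Hz and pole radius 0.9 at 128 Hz — a
  smooth, alpha-band-dominated rhythm.
- `ε_c`: independent AR(2) with the same peak but pole radius 0.3 —
  broadband, weakly autocorrelated.
- `w_c = coupling_base = 0.88` everywhere, except the Cu and FPu channels
  under unaffected-side pain stimulation, where a per-patient *knob*
  applies.

The latent/noise smoothness split matters: when both components share the
latent's smooth spectrum, coincidental template matches extend with high
probability regardless of coupling and C-ApEn barely responds to `w`
(span ≈ 0.02 across the whole weight range). With broadband private noise
the response is strong and strictly monotone — C-ApEn falls from ≈1.55 at
`w = 0.60` to ≈1.04 at `w = 0.97` under the default estimator settings —
which is what lets the generator realize prescribed D values at all.

The knob → C-ApEn map is **calibrated, not assumed**: `calibrate_knob`
simulates a 9-point grid over `w ∈ [0.60, 0.97]` (16 replicates × 3 epochs
per point), asserts strict monotonicity (failing loudly if replication is
insufficient), and returns an interpolated map with its inverse. Each
patient draws a target D from their phenotype's distribution — recoverers
N(0.12, 0.02), non-recoverers N(0.00, 0.02), straddling the 0.07 cutoff —
and the pain-condition knob is set through the calibrated inverse so the
pain-minus-rest difference realizes that target in expectation. Under
closed eyes the two phenotypes are generatively identical.

Cohort composition mirrors the study design: 50 control + 35 tDCS
patients; per-group recoverer counts are the rounded observed improvement
rates (11/50, 13/35), so cohort-level rates are exact by construction.
Demographics (age ≈ N(47, 14) truncated to 17–83, 72% male, 68% traumatic
brain injury, log-normal duration with median 121 days, CRS-R ≈ N(7.7,
1.3)) are plausibility scaffolding for the baseline tables, not an
analysis target. The metadata CSV carries an `affected_side` column
(assigned at random per patient) because relabeling needs it.

All randomness flows from one integer seed through documented
`default_rng` seed lists (`[seed, patient, condition]` for signals;
separate fixed offsets for demographics, calibration, and the regression
cohort), so any stage replays in isolation.

### Problem sizes

Recordings default to 64 s per condition at 128 Hz → eight 1024-sample
epochs per C-ApEn cell. At these sizes the per-patient D estimate has an
empirical SD of ≈0.016 against its generator target (correlation ≈ 0.96
across a cohort), an 85-patient cohort evaluates in well under a minute
for the D-only path, and the full ten-pair feature table takes a few
minutes. These are the package's chosen desk-scale study conditions; all
are config fields.

### What the generator does not model

No 1/f background, eye/muscle artifacts, nonstationarity, volume
conduction, electrode noise or drift; no tDCS mechanism — phenotype enters
only through the pain-evoked Cu–FPu coupling change. Passing tests
therefore show that the pipeline recovers the structure it assumes from
signals that carry it, not that real UWS EEG carries that structure.

## Regression-recovery cohort

`gen_regression_cohort` draws correlated C-ApEn-scale predictors (mean
1.2, SD 0.05, pairwise correlation 0.5 — which is what makes coefficients
of magnitude ~10 plausible) plus clinical covariates, and an outcome from
a fixed known coefficient vector with N(0, 0.3) noise. The CI-coverage
check aggregates over all (replicate × coefficient) cells: per-coefficient
coverage over 100 replicates is Binomial(100, 0.95) with SD ≈ 2.2, so a
per-coefficient bar at 93% would fail a correct implementation roughly one
time in eight per coefficient; the aggregate over 1300 cells has SD ≈ 0.6
percentage points and separates correct from miscalibrated intervals
cleanly. The headline Cu–FPu coefficient is additionally held to the
per-coefficient bar.

## Numerical and degenerate-input choices

- Zero-variance series raise `DegenerateSignalError`; dead channels make
  feature cells explicitly missing (never zero, never imputed).
- EDF output quantizes to 16-bit physical scaling (per-channel min/max);
  round-trip error is bounded by the channel range / 2^16.
- `pooled_t` with zero pooled variance returns t = 0 for equal means and
  raises for unequal (infinite t).
- ROC requires both outcome classes; 2×2 tables require positive margins.
- Calibration inverse queries outside the calibrated C-ApEn range raise a
  config error rather than extrapolate.

## Known limitations

- The C-ApEn parameterization of the original analysis is unpublished;
  `m = 2, r = 0.2·SD, lag = 1` are field conventions, and results at other
  settings require recalibration of the generator knob (done automatically,
  since calibration uses the analysis parameters).
- The published patient-level results (AUC 0.948, per-group sensitivities)
  arise from unpublished data and are not reproduction targets; the
  synthetic cohort is built around the published cutoffs and rates instead.
- The direction "higher C-ApEn = more inter-cortical communication" in the
  source literature inverts the usual asynchrony reading of the statistic;
  this package computes the standard statistic and leaves interpretation
  to the caller.
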