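# Methods

`tcafinger` re-implements, as a tested and reusable pipeline, the plasma
untargeted-metabolomics analysis that yields a TCA-cycle metabolic
fingerprint for mitochondrial aconitase (ACO2) deficiency: feature-table
pretreatment, univariate differential statistics with empirical-Bayes
variance shrinkage, PCA and OPLS-DA with cross-validated predictivity, and
exact-mass adduct/fragment annotation with per-metabolite fold-change
averaging.  Because no patient LC-MS data are deposited, the pipeline is
exercised end to end on a synthetic cohort generator that emulates the
study design with known ground truth.

## Exact-mass arithmetic and the adduct grammar

Monoisotopic masses are summed from a fixed reference table (C = 12
exactly, H = 1.0078250319, O = 15.9949146221, ..., including the heavy
isotopes 13C, 37Cl and 81Br).  An *adduct rule* maps a neutral formula to
one singly charged ion form by adding/removing atoms, optionally
substituting one heavy isotope, and applying one of two charge
conventions:

* **proton transfer** (`M-H`, `M+H`, `M-CO2+H`, `M+ACN-H`, ...): the m/z is
  the modified neutral mass ± the proton mass 1.007276 Da;
* **species attachment** (`M+Cl`, `M+Br`, `M+CH3COO`, `M+HCOO`, `M+Na-2H`):
  the m/z adds the attached species' *neutral* monoisotopic mass, with no
  electron-mass correction.

This hybrid convention is the one that reproduces the published
annotation table's observed-minus-calculated deltas digit for digit.
Delta m/z is the full-precision difference rounded half-away-from-zero at
4 decimals.  The 18 rules are data-driven (a bundled TSV), so new forms
can be added without code changes.

One deliberate relaxation: neutral-loss rules may remove Na/K atoms that
the neutral formula does not contain (e.g. a potassium-formate loss from
phosphoenolpyruvate).  Organic acids circulate partly as their salts, and
the published table itself applies such losses to the free-acid formula;
the m/z bookkeeping is then plain mass arithmetic.  Losses of organic
fragments a formula cannot supply are still rejected.

### Reproduction of the published annotation rows

Of the 32 printed (metabolite, ion form, m/z, delta) rows, 20 are exactly
reproduced at 4 decimals from the formula and form alone.  The other 12
are internally inconsistent under every rounding/charge convention we
tried and are excluded from the golden checks — documented, not silently
skipped:

* cis-aconitate `M-H`: recomputes to −0.0015 vs printed −0.0014 (a
  rounding-path discrepancy of 4×10⁻⁵ Da);
* phosphoenolpyruvate `M-HCOOK+H` and `M-CO2+H`: off by one digit in the
  4th decimal;
* glutamate `M-H` (printed m/z 148.0423 is ~2 Da above the computed
  [M−H]⁻ of C5H9NO4 and appears mislabeled) and five further glutamate
  rows off by one final digit;
* hydroxybutyrate `M-H` and `M+Na-2H` (inconsistent with C4H8O3 under any
  convention; we do not guess the intended species) and `M+HCOO` (last
  digit).

The frozen recomputed values for all 12 excluded rows are asserted in the
test suite so any drift is caught.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are the study
design itself: 8 cases partitioned into families of 2/3/2/1 versus 30
controls; the nine fingerprint metabolites planted at the cohort-averaged
signed fold changes (−36.9 cis-aconitate, −17.7 isocitrate, −4.3
alpha-ketoglutarate, +1.1 succinate, −1.4 fumarate, −1.1 malate, −6.9
phosphoenolpyruvate, +1.8 glutamate, −21.8 hydroxybutyrate), each emitted
as its observed ion forms (32 features) plus 1000 background noise
features.

Model choices, with defaults chosen once for plausibility (per-sample
intensity distributions are not reported for the study):

* **Intensities** are log-normal around a per-form base abundance with
  coefficient of variation `intensity_cv` = 0.2 (the log-normal mean is
  bias-corrected so group means equal the planted targets).  Panel
  metabolites use base abundance 10⁶ with per-form ionization-efficiency
  factors U(0.3, 1); noise features span 10³–10⁷ log-uniformly.
* **Case effect**: case intensities are multiplied by the planted ratio
  (r for a +r fold change, 1/|r| for −r), *before* missingness, so
  strongly suppressed metabolites can drop below the detection limit in
  cases and exercise the filter/imputation path.
* **Missingness** is logistic in log intensity (detection-limit
  censoring), slope 0.5 natural-log units; the midpoint is calibrated by
  bisection so the expected overall missing fraction equals
  `missing_rate` = 0.1.
* **Mass error** is Gaussian with sd 0.0005 Da; all forms of one
  metabolite co-elute within `rt_window` = 5 s on a 15-minute gradient;
  noise m/z is uniform over the 67–1000 acquisition scan range.
* **Determinism**: one integer seed; per-stage substreams are spawned
  from it, so identical designs give byte-identical tables.

What the generator does **not** emulate: chromatographic peak shapes,
retention-time drift, batch effects, correlated metabolite panels,
isotope-pattern fine structure, or realistic plasma matrix complexity.
Passing tests therefore demonstrate the correctness and calibration of
the *analysis machinery* under the study's design and noise scale — not
performance on real patient plasma.

## Pretreatment

Features missing in at least 75% of all samples (cases and controls
pooled; boundary inclusive) are removed.  Whether the original filter was
per-group or overall is unstated; overall is used.  Remaining missing
cells are imputed with half the feature's minimum observed value — a
deterministic detection-limit surrogate standard in metabolomics; the
imputation method is likewise unstated in the source analysis.  Each
sample is then sum-normalized to unit total so every value is a fraction
of the spectral sum.  The composed chain is idempotent.

Note that with planted class effects the case and control *totals*
differ, so sum normalization rescales every case/control ratio by one
common factor (about 2% under the defaults).  Exact fold-change recovery
therefore holds before normalization, and up to that common factor after
it; the property tests assert exactly this.

## Univariate statistics

Signed fold changes are computed on the normalized intensity scale:
r = mean(case)/mean(control), reported as r if r ≥ 1 and −1/r otherwise,
so a 36.9-fold decrease prints as −36.9.  Moderated t-statistics are
computed on log2 intensities (variance stabilization).  The per-feature
pooled variance s² (d residual df) is shrunk toward a prior fitted across
all features by matching moments of log s² under the scaled
inverse-chi-square model s² ~ s0²·F(d, d0): the trigamma equation for d0
is solved by Newton iteration, and d0 = ∞ (common variance = mean s²)
when the spread of log variances is at or below its pure-sampling
expectation.  The statistic uses the shrunk variance and d0 + d degrees
of freedom; at d0 = 0 it reduces exactly to the classical pooled t (a
frozen oracle in the tests; the hierarchical simulation recovers d0 and
s0² to within the documented bands).

FDR adjustment is Benjamini–Hochberg (delegated to statsmodels and
checked against a brute-force step-up oracle).  Feature selection uses
the strict rule p < 0.05 and |FC| > 1.5.  Per-family contrasts (each
family with ≥ 2 members against the full control cohort) are combined by
Fisher's method; the source cites a meta-analysis without naming the
combiner, and Fisher is the default choice.

## Latent-variable models

Data are log2-transformed and unit-variance scaled (centering + division
by column sd — the convention of the software named by the source, which
does not state the scaling).  PCA components are extracted by NIPALS and
verified against a dense eigendecomposition oracle; loading signs are
fixed so each vector's largest element is positive.  OPLS-DA is the
single-response O-PLS: orthogonal components (w_o ∝ p − (w'p)w) are
removed from X before the single predictive component; R2Y is the
explained variance of the centered class indicator.

Q2 = 1 − PRESS/SS uses 7-fold cross-validation with venetian-blind
assignment after a seeded shuffle, stratified by class for OPLS-DA.  For
PCA, held-out rows are predicted variable-group-wise from the training
loadings (each variable block reconstructed from scores formed on the
other blocks), so the held-out value never predicts itself and pure noise
yields Q2 ≤ 0.  The number of orthogonal components defaults to the
smallest K whose Q2 improvement is ≥ 0.01.

Following the source's order of operations, the pipeline fits the latent
models on the matrix of *selected* differential features (its "final data
matrix"); the published global metrics (R2X 0.66/Q2 0.43 PCA; R2X 0.41,
R2Y 0.94, Q2 0.88 OPLS-DA; 758 selected features; FDR 0.01) depend on the
unavailable patient matrix and are not reproducible — the tests cover the
same regime qualitatively (R2Y ≥ 0.9 and Q2 ≥ 0.8 on the planted cohort;
mean permutation Q2 ≤ 0.1; noise Q2 ≤ 0).

Feature ranking is discriminant-based: descending |predictive covariance
loading|, ties broken by feature id.

## Annotation

Each (library metabolite, adduct rule) pair with matching polarity claims
every feature within the mass tolerance — absolute 0.003 Da by default
(the largest published |delta| is 0.0014 Da at m/z < 250; ppm mode is
available).  When a retention-time window is supplied, the retained
matches per metabolite are the largest co-eluting subset.  Isobaric
collisions are *reported, not resolved*: citrate and isocitrate share
C6H8O7 exactly, and TCA metabolites differ by H2O/CO/CO2 units, so e.g.
isocitrate [M−H2O+H]⁺ coincides with cis-aconitate [M+H]⁺; such features
match multiple metabolites and all affected annotations carry an
ambiguity flag (the original study resolved citrate/isocitrate by MS/MS
fragmentation, which is out of scope here).  The per-metabolite fold
change is the plain arithmetic mean of the signed per-form fold changes,
reported to 1 decimal; mixed signs trigger a warning.

## Problem sizes and numerical choices

The shipped defaults — 38 samples, 32 planted + 1000 noise features, 7
CV folds, 20 label permutations, 5000 features in the prior-recovery
simulation — run the full pipeline in about a second and the whole test
suite in a few seconds, while keeping every binomial/recovery band
comfortably powered.  NIPALS converges at relative score change 1e−12
(max 2000 iterations, rejection with diagnostics on failure); variance
floors, zero-p flooring in Fisher combination, and degenerate-input
rejections are noted in the relevant docstrings.

## Known limitations

* The generator's independence across features understates the
  correlation structure of real plasma profiles, which inflates the
  apparent stability of multivariate metrics.
* Half-minimum imputation biases strongly censored features toward
  larger |fold change| (about 10% at the defaults for the most suppressed
  metabolite); the ±20% recovery band absorbs this.
* Signed fold changes near ±1 are discontinuous by construction;
  averaging forms whose estimates straddle the boundary can yield
  near-zero means (flagged by the sign-consistency warning).
* Exact-mass annotation alone cannot separate isobars; ambiguity flags
  are the designed behavior, not a failure mode.
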