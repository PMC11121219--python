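# Methods

This document records the exact algorithms, parameter defaults and
numerical choices behind `capranir`, and what the synthetic cohort
generator does and does not emulate.

## 1. Spectral representation

A `WavenumberGrid` is a uniform grid defined by `start`, `stop`,
`spacing`; the default is 4000–10000 cm⁻¹ at 4 cm⁻¹, giving
(10000 − 4000)/4 + 1 = 1501 points. A `SpectraSet` holds an
(n_spectra × n_points) absorbance matrix plus per-row metadata
(`sample_id`, `replicate`, `breed`, `sex`); construction validates that
breed and sex are constant within a sample and that every sample has
the same replicate count. Decimation keeps every `step`-th point
starting at the first (step 10: 1501 → 151) and rescales the grid
spacing accordingly.

## 2. Pre-treatments

All treatments operate per spectrum unless noted, and chains of up to
two codes are written `A-B` (A applied first).

| Code | Operation | Parameters (defaults) |
|------|-----------|----------------------|
| `SM` | Savitzky–Golay smoothing | window 11 points, polynomial order 2, `mode="interp"` |
| `NORM` | unit-area normalisation | divides by the trapezoidal integral over the grid |
| `ALS` | asymmetric-least-squares baseline subtraction | λ = 10⁵ (second-difference penalty), p = 0.01 (asymmetry), 10 iterations, sparse Cholesky via `scipy.sparse` |
| `MSC` | multiplicative scatter correction | OLS of the spectrum on a reference; corrected = (x − a)/b. Reference = mean of the *fit rows* (calibration group) unless given explicitly |
| `SNV` | standard normal variate | (x − mean)/sd with sd computed with ddof = 1 |
| `DV1`, `DV2` | Savitzky–Golay derivatives | window 11, polyorder 2, `delta` = grid spacing, so units are AU·cm |

`fit_treatment(set, label, fit_rows)` fits any stateful step (MSC
reference) on `fit_rows` only and returns a `FittedTreatment` that can
be re-applied to new rows — this is how the pipeline avoids information
leaking from validation spectra into the pre-treatment.

Savitzky–Golay uses `mode="interp"` so edge points are evaluated on the
fitted local polynomial rather than padded data. The ALS smoother
solves (W + λDᵀD)z = Wx with D the second-difference operator and
asymmetric weights p (above baseline) / 1 − p (below), the standard
Whittaker formulation.

## 3. Partitioning

`kennard_stone(features, n_select)` implements classic max–min
selection with Euclidean distances: seed with the farthest pair, then
repeatedly add the candidate whose minimum distance to the selected set
is largest. Ties break to the smallest row index, making the output a
deterministic function of the feature matrix. The test suite checks the
implementation against an exhaustive oracle at small n.

`split_spectra` applies Kennard–Stone at the **sample** level so all
replicates of an animal land on the same side of the split. Features
are, by default, the z-scored reference attributes of each sample
(`feature_space="reference"`); `"spectra"` uses replicate-mean spectra
instead. With 32 samples and a 20/10 design, the 12 samples not ranked
into the calibration set exceed the requested test size, so the KS
ranking is simply continued past rank 20 and the next 10 become the
test set; the remaining 2 are withheld entirely. The returned
`PartitionResult` records the full selection order.

## 4. Support-vector models

**Regression.** `LinearSVRModel` wraps `sklearn.svm.SVR(kernel=
"linear")` with standardisation of X and y using *training* statistics;
ε is expressed in units of the target's training standard deviation
(default 0.1). `tune_C` fits the grid {1, 10, 30, 100} in ascending
order and keeps the C with the lowest training RMSE, requiring a strict
improvement to move off a smaller C.

`evaluate_regression` regresses predicted on observed values by OLS
(statsmodels) and reports RMSE, R², slope ± sd, intercept ± sd with
p-values, a t-test of slope = 1, and the residual standard error
relative to the observed mean. An intercept with p > 0.05 is rendered
`ns` in report tables. `select_best_model` keeps candidates with
R²_train > 0.95 and slope_train > 0.95 and R²_test > 0.90, then
minimises test RMSE (ties → higher test R²); it returns `None` when no
candidate qualifies rather than inventing a winner.

**Classification.** `LinearSVCModel` wraps `sklearn.svm.SVC(kernel=
"linear", C=1)` on standardised features. Reports are per replicate
spectrum: confusion matrix, accuracy, and one-vs-rest sensitivity and
specificity per class.

The SVR implementation is verified in the test suite against an
independent dual-QP solution (SLSQP) of the ε-SVR optimisation problem.

## 5. Quality equations

- Carcass yield (%) = 100 · ccw / lws, with the record validated so
  that ccw ≤ hcw ≤ lws.
- Chroma C\* = √(a\*² + b\*²); hue H\* = atan2(b\*, a\*) in degrees.
  (0, 0) is rejected as hue is undefined there.
- Atherogenicity IA = (C12:0 + 4·C14:0 + C16:0)/(ΣMUFA + ΣPUFA).
- Thrombogenicity IT = (C14:0 + C16:0 + C18:0) /
  (0.5·ΣMUFA + 0.5·Σn-6 + 3·Σn-3 + Σn-3/Σn-6).
- h/H = (C18:1n-9 + C18:2n-6 + C20:4n-6 + C18:3n-3 + C20:5n-3 +
  C22:5n-3 + C22:6n-3)/(C14:0 + C16:0).

`lipid_indices` computes the family sums from the profile itself unless
published sums are supplied via `sums=`. Note the aggregation-order
effect: the index of a mean profile is not the mean of per-animal
indices (the functions are ratios); `index_of_mean_vs_mean_of_index`
quantifies that gap on a cohort table.

## 6. Synthetic cohort generator

`generate_references` draws each attribute independently per animal
from a truncated normal with published breed-level means; the standard
deviation is reconstructed from the published standard errors as
SD = SEM·√n (n = 16 per breed for meat/fatty-acid attributes, 8 per
breed-and-sex cell for carcass weights). Truncation bounds keep values
physical (fractions in [0, 100], pH in [5, 7], etc.), and carcass ccw
is clipped to 0.95·lws so records always validate.

`generate_spectra` renders each animal's clean spectrum as

absorbance(ν) = Σ_c load_c · band_c(ν) + background(ν) ± breed_offset(ν)/2

with eight chromophoric constituents (moisture, protein, IMF, C14:0,
C16:0, C18:0, C18:1n-9, C18:2n-6), each owning one Gaussian band plus
small cross-loadings on neighbouring bands (0.25 / 0.125) so bands
overlap as real overtone regions do. The fixed broad background bands
are essential: SNV and MSC are scale-invariant per spectrum, so without
a constant spectral component the amplitude information that encodes
concentration would be annihilated by those treatments. Replicates are
gain·clean + offset + noise with gain ~ N(1, 0.05), offset ~ N(0, 0.02)
and detector noise sd 0.001 AU. `class_separation` scales a
breed-specific six-band offset; `active_constituents` restricts which
attributes are encoded (useful for single-factor recovery studies);
`sd_scale` scales all reference dispersions.

**What the generator does not emulate.** Non-chromophoric attributes
(pH, L\*, a\*, b\*, and all fatty acids outside the five encoded ones)
carry no spectral signal at all, so calibrations for them must fail —
they act as negative controls, whereas on real meat such attributes
correlate indirectly with composition. Attributes are drawn
independently, so the inter-attribute correlation structure of real
animals (e.g. IMF with fatty-acid totals) is absent. Truncation shifts
means slightly for attributes whose bounds are close (documented
tolerance in the tests). Bands are Gaussian and mixing is exactly
linear; real NIR spectra have non-Gaussian overtone shapes and mild
nonlinearity. The breed offset is a deterministic spectral shape, not
an emergent compositional difference.

## 7. Numerical and reproducibility choices

- All random draws flow from `numpy.random.default_rng(seed)`;
  reference tables and spectra use `seed` and `seed + 1` respectively
  so regenerating one does not perturb the other. Same seed ⇒
  byte-identical outputs.
- Kennard–Stone and C tuning are fully deterministic (explicit
  tie-breaks), so a pipeline run is a pure function of (data, config).
- Report tables round RMSE to 3 decimals and R² to 4, matching common
  chemometric reporting; underlying objects keep full precision.
- Problem sizes (16 animals/breed, 3 replicates, 20/10 split, 151
  retained points) are this package's defaults and can all be changed
  through `SyntheticConfig` and `PipelineConfig`.

## 8. Limitations

Linear SVR on 151 variables with 20 calibration samples is heavily
underdetermined; results depend on the pre-treatment regularising the
problem, and the selection criteria exist precisely to reject unstable
fits. The discrimination accuracy on synthetic data reflects the
configured `class_separation`, not an instrument's real resolving
power. The IT (thrombogenicity) published per-animal mean cannot be
reproduced from published mean profiles by any aggregation order we
tested; it is therefore reported but not used as a correctness check.
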