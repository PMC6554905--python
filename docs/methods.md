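# Methods

This note documents the models, the synthetic forward model, the numerical
choices and the known limitations of `grassspec`.

## The analysis chain and its assumptions

The pipeline assumes a line-scan acquisition: a cube indexed
(line, sample, band) with per-(sample, band) white and dark reference
frames broadcast along the scan axis (a Spectralon tile spans one line of
the stage, so each spatial column has its own reference; a scalar-per-band
mode would be a trivial special case of the same code path).  Calibration
is the two-point form `R = (I − D)/(W − D)`; pixels with `W − D ≤ 0` are
flagged invalid and excluded everywhere downstream.  Reflectance is *not*
clipped to [0, 1]: bright specular tissue (pseudostem) genuinely
calibrates above 1 and clipping would destroy signal.

Plant pixels are segmented by `R(1080 nm) ≥ 0.3` (inclusive).  Plant-level
spectra are per-band arithmetic means over the ROI, averaged unweighted
over the 1–3 replicate images of a plant; plants whose mean ROI pixel
count falls below a threshold (5000 at full instrument geometry) are
flagged excluded before the calibration/validation split.  SNV is applied
at plant level to the mean spectrum, using the sample (n−1) standard
deviation; when a wavelength range is restricted or bands are subsampled,
SNV is recomputed on the reduced band set, never inherited.

PLSR is single-response NIPALS with deflation of X only (inner tolerance
1e−10, at most 500 iterations — for one response the loop converges in one
pass), X centered (unit-variance scaling available but off by default,
since SNV already normalizes spectra), y centered.  Per-LV regression
vectors `B_A = W (P'W)^{-1} q` are retained so one fit serves a whole LV
grid during cross-validation.  If the predictor residual runs out of rank
the model truncates and records a warning.

Model selection: Monte-Carlo cross-validation draws a fresh random k-fold
partition per replicate (defaults: 10 folds, 100 replicates, LV 1–50);
held-out squared errors are pooled as mean squared error over all
predictions (then rooted), not averaged per-fold RMSEs — pooling is the
unbiased estimate.  Adjusted Wold selects the smallest k with
`press(k+1)/press(k) ≥ θ`; θ = 1 stops at the first non-improvement,
θ = 0.99 also stops when the improvement falls below 1%, so it can never
select more LVs.  If no ratio reaches θ the grid maximum is returned.

CARS follows the standard recipe: per run, fit PLS on a random 80% row
sample of the surviving bands, rank bands by |coefficient|; the enforced
retention fraction follows `r_i = a e^{−k i}` calibrated to `r_1 = 1` and
`r_N = 2/p`; adaptive reweighted sampling then draws the retained set with
probability ∝ |coefficient| (skipped on full-retention runs, where nothing
is eliminated); each run's subset is scored by 5-fold CV RMSE and the
global minimizer wins.  VIP selection keeps bands with `VIP ≥ 1` (the
mean-square-1 identity makes 1 the "above average" cutoff).

The comparison harness exposes eleven methods behind one adapter.  PLSR
variants use this package's core; GPR/SVM/RF/LASSO delegate to
scikit-learn, MLR/SMLR/RMLR to statsmodels OLS/stepwise/Huber-RLM.
MLR-family methods operate on an every-5th-band basis (47 of 235 bands):
with ~130 calibration samples a 235-column Gram matrix is singular, and
the subsample keeps them well-posed while spectra are smooth enough that
little information is lost.  SMLR uses forward–backward selection with
entry/exit p = 0.05/0.10.  Splits are at plant level (all tissues and
replicates of a plant stay on one side); calibration gets round(2n/3)
plants.

`R²` defaults to the squared Pearson correlation between observed and
predicted — the chemometrics convention when a separate slope/intercept/
bias triple is reported — with `1 − SS_res/SS_tot` available via
`r2_method="ss"`.  The validation regression is OLS of measured on
predicted with standard errors; bias is `mean(predicted − observed)`.

## Trait mapping

A plant-level calibration is applied per pixel: each pixel spectrum passes
through exactly the preprocessing pipeline recorded on the model and then
the regression vector.  Per-pixel SNV makes maps invariant to the
multiplicative lighting gradient of the stage.  Two masking rules: failed
segmentation, and mean reflectance below 0.05 ("very low reflectance").

Single pixels carry sensor noise that plant-mean calibration spectra do
not.  The noise inflates the per-pixel SNV scale estimate, shrinking the
standardized spectrum multiplicatively by ≈ `1 − σ_n²/(2σ_x²)`; a
large-norm PLS regression vector turns that into a concentration bias that
is worst for low-concentration tissue (measured on synthetic two-zone
plants: <1% zone-mean error without noise, up to ~11% with default noise).
`predict_map` therefore applies a masked 3×3 box filter before
preprocessing (`smooth_window=1` disables it): plant pixels are averaged
only with neighbouring plant pixels, normalized by local mask coverage, so
the filter is exact on uniform regions, background never bleeds in, and
the lighting-gradient invariance is preserved (neighbouring ramp factors
stay multiplicative).  With the filter the worst zone-mean error drops to
~6%.  Pixel-scale application of a plant-level calibration remains a
calibration transfer: on real canopies mixed pixels and specular geometry
can bias it in ways the synthetic scenes do not exercise.

## Tissue analyses

Contrasts are stored signed as BL − PS (one fixed convention prevents sign
bugs; magnitudes are reported alongside).  The test is a paired two-sided
t-test, since both tissues come from the same plants; when all
within-plant differences are identical the statistic is undefined and the
p-value degenerates to 1 (zero difference) or 0.  The partitioning ratio
`(lmw_bl/lmw_ps)/(hmw_bl/hmw_ps)` is scale-invariant by construction.
Crude protein is N × 6.25.

Canonical variate analysis runs on every-2nd-band spectra: generalized
eigenproblem `B v = λ W v` with the pooled within-group scatter
ridge-regularized by `1e−6 · trace(W)/p` (bands can outnumber samples).
Directions are scaled to unit within-group score variance — the metric
that makes scores exactly invariant (up to sign) under common affine maps
of all spectra.  Wilks' Λ = Π 1/(1+λ_i) over the nonzero eigenvalues; with
two groups only the first canonical variable carries separation, and Λ is
only meaningful when samples comfortably exceed bands.

## The synthetic-data generator

The generator defines the study conditions for every test.

**Attribute tables.**  Thirteen attributes with population min/max/mean/SD
taken from the published calibration summaries of the pooled
blades+pseudostems dataset (e.g. nitrogen: mean 3.2%, SD 0.7, range
0.4–4.65).  Because those pooled summaries are ~92% blade samples, the
spec mean is interpreted as the blade-tissue mean; the pseudostem marginal
is shifted by the published tissue offset (nitrogen −1.1%, total sugars
+93 mg/g, HMW +58, LMW +34) with the same SD.  Each tissue marginal is a
moment-matched Beta on [min, max] — a clipped normal would bias the
realized mean/SD wherever the published bounds sit within ~3 SD, while a
Beta reproduces any feasible (mean, sd) exactly and respects the bounds.
PS and BL are coupled through a Gaussian copula whose correlation is
solved (via a Hermite-polynomial expansion of the marginal transforms) so
the *Pearson* r² matches the published PS–BL value; for the strongly
skewed sugar marginals the comonotone ceiling of the equal-SD Beta pair is
slightly below the published r² (≈0.79 attainable vs 0.84 for total
sugars, ≈0.82 vs 0.89 for HMW) and the generator caps at that ceiling;
nitrogen (0.83) and LMW (0.50) are hit exactly.  Whole-plant values are
tissue-fraction-weighted means (default 30% pseudostem).  Attributes with
no published tissue contrast get zero shift and a moderate coupling
(r² = 0.7).

**Scenes.**  Foreground is a seeded, sinusoidally-lobed ellipse covering
the requested fraction of the frame.  Foreground reflectance is
`baseline_tissue(λ) · exp(−Σ_f amp_f · conc_f · G(λ; c_f, w_f))` — a
Beer–Lambert attenuation with Gaussian features, smooth and monotone in
concentration, hence invertible by a latent-variable regression.
Baselines emulate green vegetation: red edge near 710 nm, NIR plateau
(~0.7 for blades, ~1.1 for pseudostem over 800–1100 nm, the published
tissue signature), water dips at 1000/1200/1450 nm (deeper long-wave dips
for pseudostem), flat dark background (~0.12, safely below the 0.3
segmentation cutoff at 1080 nm).  Nitrogen features sit near 560, 700,
935, 1380 and 1600 nm and sugar features near 565, 705, 1400, 1590 and
1680 nm — inside the wavelength regions reported as informative for those
attributes.  Feature amplitudes are free parameters of the generator (no
quantitative coupling is published); they are set so absorption depths are
a few percent to ~15% of baseline over the attribute ranges, strong enough
for parameter recovery at the default noise.  A multiplicative linear ramp
along the scan axis (default ±10%) emulates the lighting gradient;
additive Gaussian noise (default SD 0.01 reflectance units) emulates the
sensor.  The white reference is a flat 0.99-reflectance-equivalent frame
and the dark reference a small positive offset with noise; raw irradiance
is reconstructed as `I = R(W − D) + D`, so calibration inverts the forward
model exactly in the noise-free case.

**What the generator does not emulate** — and therefore what passing tests
do *not* show about real data: leaf geometry, shading and specular
highlights; mixed boundary pixels (zones are crisp); diurnal sugar
dynamics (concentrations are static per plant); instrument stray light,
wavelength drift or detector nonlinearity; and any real covariance between
attributes beyond the PS–BL coupling (attributes are sampled
independently of each other).  Validation R² near 1 on synthetic studies
says the *pipeline* is correct, not that field R² would be high; the
published plant data remain necessary for that question.

## Problem sizes and defaults

The instrument geometry default is the full 400 lines × 320 samples × 235
bands.  The end-to-end study default (`StudyConfig`) uses 185 plants with
2–3 replicate images each, 15 of them with separate pseudostem
acquisitions, on a reduced 80 × 64-pixel scene with the pixel-exclusion
threshold scaled by the same pixel ratio (5000 · 5120/128000 = 200), and
Monte-Carlo CV at 15 replicates over LV 1–20.  These sizes keep a full
study around fifteen seconds while preserving every statistical property
the full geometry would exercise; per-image pixel counts scale, nothing
else changes.  Per-plant foreground fraction is driven by the plant's
visual-yield value (ground cover), which also makes pixel count an
informative predictor for the visual-yield model.

## Numerical details

* `band_index` resolves ties toward the lower wavelength; targets more
  than one grid spacing outside the grid are rejected.
* Thresholds print as inclusive (`≥ 0.3`, `< 5000`) and are implemented
  inclusively.
* ENVI I/O supports BIL/BIP/BSQ interleaves, float32/float64/uint16, both
  byte orders; read and write are exact inverses for all of them.
* Degenerate guards: constant spectra are rejected by SNV; constant
  predictions yield an undefined (NaN) R² and skip the validation
  regression; a constant pixel-count column is dropped from the
  visual-yield model, reducing it to the spectrum-only model; zero-range
  false-color channels map to 0.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration objects; identical seeds give bit-identical tables,
  cubes and reports.

## Known limitations

* The equal-SD constraint of the attribute schema caps attainable PS–BL
  Pearson correlation for skewed attributes (see above).
* The Beer–Lambert forward model is exponential, so even noise-free
  closed-loop recovery is not exactly linear: validation R² ≈ 0.998 rather
  than 1 (curvature plus 13-attribute cross-talk).
* The eleven-method harness fixes one sensible configuration per method;
  it is a comparison harness, not a tuning framework.
* Tissue CVA assumes two groups; genotype-level multi-factor MANOVA is out
  of scope.
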