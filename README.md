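# grassspec

Hyperspectral-imaging chemometrics for forage quality in perennial
ryegrass (*Lolium perenne*).

Forage composition — sugars, nitrogen/crude protein, fibre, digestibility,
energy — drives animal performance in pasture systems, but wet chemistry is
destructive, slow and expensive, which bottlenecks breeding programmes.
Line-scan hyperspectral imaging (HSI) offers a non-invasive alternative: a
full reflectance spectrum (here 235 bands, 550–1700 nm) at every pixel of a
plant image.  `grassspec` implements the complete plant-scale analysis
chain for this setting, for researchers in plant phenotyping and
chemometrics:

* **Radiometric calibration** of ENVI cubes against white/dark references,
  `R = (I − D)/(W − D)`;
* **ROI segmentation** of plant pixels (`R ≥ 0.3` at 1080 nm, a band
  little affected by water), plant-level mean spectra, replicate
  averaging, and the 5000-pixel exclusion rule;
* **SNV preprocessing** (per-spectrum standardization removing additive
  offsets and multiplicative lighting/scatter effects), wavelength-range
  restriction, and band subsampling;
* **PLSR (NIPALS)** with Monte-Carlo ten-fold cross-validation and
  **Adjusted Wold** latent-variable selection, plus **CARS** and **VIP**
  wavelength selection and an eleven-method comparison harness (PLSR
  variants, GPR, SVM, RF, MLR, SMLR, LASSO, RMLR);
* **Per-pixel trait maps** and 558/740/937 nm false-color composites;
* **Pseudostem (PS) vs blade (BL)** tissue statistics: paired contrasts,
  BL-on-PS regressions, crude protein = N × 6.25, and canonical variate
  classification of tissue from spectra;
* a **synthetic-data generator** that emulates the statistical and
  spectral structure of such a study (attribute distributions, PS–BL
  coupling, Gaussian absorption features under a Beer–Lambert forward
  model, lighting gradients, sensor noise), so the whole pipeline is
  testable without any instrument data.

## The model at the core

Mean ROI spectra `x ∈ R^235` are SNV-standardized,
`x_snv = (x − x̄)/s_x`, then regressed on a response `y` (one of 13
attributes) by partial least squares: components `a = 1..A` with weights
`w_a ∝ X_{a-1}' y`, scores `t_a = X_{a-1} w_a`, loadings
`p_a = X_{a-1}' t_a / t_a't_a`, `q_a = y' t_a / t_a't_a`, and deflation
`X_a = X_{a-1} − t_a p_a'`.  The LV count `A` is picked from the
Monte-Carlo CV error curve `press(k)` as the smallest `k` with
`press(k+1)/press(k) ≥ θ` (Adjusted Wold, `θ = 1` or `0.99`).  Band
importance is `VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` with
`SSY_a = q_a² t_a't_a`, so `mean(VIP²) = 1`.  Reported `R²` is the squared
Pearson correlation of observed and predicted (the chemometrics
convention; `1 − SS_res/SS_tot` is available as an option), alongside
RMSE, the validation regression `y_measured = a + b·y_predicted`, and
`bias = mean(ŷ − y)`.

## Worked example

`examples/` holds one short narrative script per capability.  For
instance, fitting nitrogen on a 60-plant synthetic study
(`python examples/02_plsr_latent_variable_selection.py`) prints

```
PLSR-AW      LV = 10  calibration R2 = 1.000 (n = 51)  validation R2 = 0.998, RMSE = 0.036% (n = 24)
PLSR-AW0.99  LV = 10  calibration R2 = 1.000 (n = 51)  validation R2 = 0.998, RMSE = 0.036% (n = 24)
```

— 51 plant-level calibration samples, 24 held-out validation plants, and a
validation RMSE of 0.036 percentage points of nitrogen: on clean synthetic
spectra the latent-variable model recovers the planted concentrations
almost exactly.  Per-pixel mapping of a two-zone plant
(`python examples/05_trait_mapping.py`) prints

```
Nitrogen blade zone    4.52 (truth    4.52), pseudostem zone    3.86 (truth    4.11) %
Sugars   blade zone   32.68 (truth   31.28), pseudostem zone  102.43 (truth   98.96) mg/g
```

reproducing the characteristic within-plant gradient: blades higher in
nitrogen, pseudostems several-fold richer in sugars.

A thin CLI wraps the same library:

```bash
grassspec simulate --n-plants 10 --seed 1 --out ds/        # ENVI cubes + CSV
grassspec fit --attribute Nitrogen --method plsr-aw --seed 1
grassspec run --config study.cfg --out study_out/
```

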