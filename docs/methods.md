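# Methods

`hyperphen` implements a plot-level hyperspectral phenotyping pipeline
for field trials: two push-broom cameras image each plot together with
a white reference panel, the image is segmented into material classes,
sunlit-leaf pixels are converted to reflectance against the panel, and
per-plot mean spectra feed partial least squares regression (PLSR)
models of photosynthetic traits whose ground truth comes from leaf
gas-exchange curve fitting.  This note records the models, the
defaults and the design choices, in pipeline order.

## Hypercube I/O and radiometric calibration

Cubes are stored as ENVI header + flat binary (BIL is the default
interleave — the native order of a push-broom line scanner; BIP and
BSQ are also supported).  Raw digital numbers (DN) are held as
unsigned 16-bit, everything downstream as 32-bit floats on disk and
doubles in memory.  Calibration to radiance is the affine contract

    L = (DN − dark_frame) · gain / integration_time + offset,

clipped below at zero, with per-band or per-band-per-spatial-channel
calibration shapes both accepted (manufacturer profiles come in either
layout).  Under unit gain, zero dark/offset and unit integration time
the transform is the identity, which is what the synthetic end-to-end
checks exploit.

## Synthetic scenes

`simulate_scene` is the package's study-condition generator, not a
test hack: its defaults define the conditions every downstream claim
is tested under.

* Camera grids: VNIR 400–900 nm in 2.1 nm steps and NIR 900–1800 nm in
  4.9 nm steps, generated from range and step (239 and 184 bands).
* Six material classes: sunlit leaf, shaded leaf, soil, reference
  panel (0.99 flat), platform shadow, non-biological matter (0.45 flat
  grey), with default area fractions 0.40/0.20/0.20/0.10/0.05/0.05.
* Sunlit and shaded leaves share one leaf endmember and differ only by
  an illumination scalar (1.0 vs 0.3); platform shadow is the soil
  endmember under the shaded scalar.  This makes sunlit-vs-shaded a
  pure brightness contrast — exactly the property that lets K-means
  separate them — and is the simplest mechanism consistent with how
  the classes behave in real scenes.
* Noise is multiplicative Gaussian on radiance (relative SD
  `noise_sd`), emulating shot-noise-like detector behaviour; trait
  noise is additive Gaussian.
* The leaf endmember is an analytic green-vegetation curve
  (chlorophyll troughs, 550 nm green bump, red-edge sigmoid at
  ~718 nm, NIR plateau, 1450 nm water dip).  It is a synthetic
  stand-in: it reproduces the qualitative features segmentation and
  reflectance recovery rely on, not any measured cultivar.

What the generator deliberately does not emulate: canopy radiative
transfer (PROSAIL-class mixing), BRDF/anisotropy, within-class
spectral variability beyond noise, soil moisture gradients, or
atmospheric path radiance.  Passing the recovery tests therefore
demonstrates the pipeline's correctness and self-consistency, not
field-level accuracy.

`simulate_trait_dataset` draws plot spectra as the mean leaf spectrum
perturbed by 40 smooth Gaussian bumps (correlation length of a few
bands) plus a global amplitude factor, keeping neighbouring bands
strongly collinear — the regime PLSR exists for — while leaving bands
a bump-width apart separately identifiable.  A trait is coupled as
y = intercept + Xβ + ε with a sparse, band-localized β.  When a target
R² is requested, the trait noise SD is set from the realized signal SD
(σ = sd(Xβ)·√((1−R²)/R²)) so "true R² = 0.9" means exactly that in the
emitted sample.

## Pixel classification

K-means (Lloyd's algorithm, k-means++ starts, Euclidean metric, best
of 10 restarts, fixed seed recorded in the output) runs on per-pixel
radiance spectra with k = 6; k is configurable for scenes missing
classes.  Clustering runs on radiance, before reflectance conversion,
matching the pipeline phase order.

Semantic labeling is heuristic (the classes themselves are standard;
the naming rules are this package's):

* panel = brightest cluster by mean broadband radiance (the panel is
  by construction the most reflective surface in the scene);
* a red-edge NDVI (R800−R670)/(R800+R670) on each centroid separates
  vegetation (> 0.5) from everything else — the ratio cancels
  illumination, so it works on radiance;
* vegetation at/above the vegetation-brightness median = sunlit leaf,
  below = shaded leaf;
* non-vegetation: darkest = platform shadow, brightest =
  non-biological, intermediates = soil when NDVI < 0.3.

Both thresholds are exposed as arguments.  Brightness ties break
toward the lower cluster id for reproducibility.  The NIR camera
(900–1800 nm) has no 670/800 nm bands, so its clusters inherit labels
from the co-registered, already-labeled VNIR map by per-cluster
majority vote (`transfer_semantics`).

## Reflectance and plot spectra

Reflectance is the band-wise panel ratio R = (S_sunlit/S_ref)·R_ref
with R_ref the panel's lab-calibrated reflectance (default 0.99).  Any
global illumination factor cancels in the ratio.  Zero or negative
panel radiance raises an error naming the offending band rather than
propagating infinities.

Per-plot aggregation is the arithmetic mean and population SD over all
sunlit pixels.  The two cameras' mean spectra are joined at a 900 nm
crossover (VNIR wins below, NIR at/above); the joined grid keeps each
camera's native step — no resampling, since the regression consumes
named wavelength columns and unequal spacing is harmless.  The joined
spectrum is Savitzky–Golay smoothed (window 11, order 2, edges
handled by polynomial fit on the truncated window) and then masked to
450–1700 nm with 1313–1440 nm removed (inclusive bounds); the sub-450
and above-1700 bands carry excess sensor noise and the dropped window
sits in the atmospheric water absorption feature.  Single-camera
(VNIR-only) runs mask to 450–900 nm.

Smoothing is applied to the plot-mean spectrum, not per pixel: the
filter is linear, so the mean is identical, at 1/n_pixels of the cost;
`plot_reflectance_pipeline(smooth=..., mask=...)` exposes the stages
so intermediate products (and the smooth-then-mask order) are
testable.  Smoothing before masking was chosen so the filter never
sees an artificial discontinuity at the water-band gap.

## Leaf-clip spectra QC

Field spectroradiometer replicates (nominally six per leaf) pass
through: splice correction, a clip-seal check, a deviation filter, and
replicate averaging.

* Splice correction removes detector-junction offsets (junctions at
  1000 and 1800 nm) by shifting each outer segment additively so its
  boundary band meets a straight line fitted to the five central
  (NIR-detector) bands nearest the junction; the central segment is
  the reference and never changes, making the correction idempotent.
* Seal check: reflectance at 450 nm above 0.10 (default, exposed)
  flags light leaking past the leaf clip — healthy leaves are very
  dark in the blue, so a bright 450 nm band means the clip was not
  sealed.  No absolute threshold is standard; 0.10 is roughly 3× a
  green leaf's blue reflectance.
* Deviation rule: replicates whose mean absolute deviation from the
  replicate mean exceeds 0.02 reflectance units (2 percentage points)
  are dropped.  The band-averaged absolute interpretation was chosen
  over 2% relative because relative deviation explodes in the visible
  trough where reflectance ≈ 0.03; the threshold is exposed.
* Leaves with fewer than 4 viable replicates are rejected — a recorded
  state, not an error.  QC flags replicates and never modifies
  spectra, and runs in a single pass (no iterative re-meaning).

Plot-level ground truth is the unweighted mean over accepted leaves,
for spectra and trait values alike.

## PLSR trait models

PLS1 NIPALS on mean-centered, unscaled data (reflectance bands share
units, so variance scaling would only amplify noisy bands).  The LV
count is selected at the minimum leave-one-out PRESS RMSE over
candidates 1..max_lv, ties broken toward fewer LVs; max_lv defaults to
min(15, n−2, p).  The selected model is composed into a single
coefficient vector B = W(PᵀW)⁻¹q applied as ŷ = ȳ + (x − x̄)B.

The LOO PRESS loop is exact but runs in the kernel (Gram-matrix) form
of PLS1: each fold's centered X'X and X'y are obtained from the
full-data cross-products by rank-one downdates, and components deflate
the p×p Gram matrix instead of the n×p data matrix
(X'ₐ₊₁Xₐ₊₁ = G − t't·pp', X'ₐ₊₁yₐ₊₁ = s − t't·q·p).  This is
algebraically identical to NIPALS — the tests verify agreement with a
naive fold-by-fold refit to 1e-8 — and lets all n folds run as one
vectorized computation.

Stability statistics come from `resample_validate`: n_resamples
(default 1000) random splits at holdout fraction 0.2 (the resampling
split is a package choice, exposed as an argument), each split
re-running the full LOO LV selection on its training part so no
information leaks from a full-data fit.  A sample's reported
prediction is the mean over all resamples in which it was held out;
CV R², RMSE and bias are computed on these mean predictions, RMSE% =
100·RMSE/(max(y)−min(y)) (range-normalized — the convention consistent
with how per-trait RMSE% relates to each trait's observed range), and
Train R² comes from the full-data fit at its selected LV count.
CV R² above Train R² triggers a warning, not a failure.

VIP scores use VIP_j = √(p·Σₐ SSYₐ·(w_jₐ/‖wₐ‖)²/Σₐ SSYₐ) with
SSYₐ = qₐ²·tₐ'tₐ the y-variance captured by component a; Σ VIP² = p
identically, which every fit asserts.

## Gas-exchange ground truth

A/Ci curves (CO₂ set points 400, 200, 50, 100, 300, 400, 600, 900,
1200, 1500, 1800, 2000 µmol mol⁻¹; saturating light 1800 µmol m⁻²
s⁻¹) are fitted with the Farquhar–von Caemmerer–Berry model:
A = min(Ac, Aj) − Rd with Ac = Vcmax(Cc−Γ*)/(Cc+Kc(1+O/Ko)) and
Aj = J(Cc−Γ*)/(4Cc+8Γ*), Cc = Ci − A/gm solved per limitation as a
quadratic in A (the physical root is evaluated in the
cancellation-free Citardauq form, which stays accurate as gm → ∞).
Mesophyll conductance is never fitted: it is constrained by the linear
tobacco temperature response gm = −0.44 + 0.058·T (mol m⁻² s⁻¹ bar⁻¹;
1.01 at 25 °C), with a 0.05 floor and a warning when the line goes
non-positive (T ≲ 7.6 °C).  Ci in µmol mol⁻¹ is treated as µbar at
~1 bar total pressure.

Kinetic constants (Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹,
Γ* = 42.75 µmol mol⁻¹ at 25 °C with activation energies 79.43, 36.38,
37.83 kJ mol⁻¹; O = 210 mbar) are the standard tobacco-derived
parameterization, held in an editable dataclass so every symbol in the
model has an auditable home.  No temperature normalization of Vcmax or
J to 25 °C is applied — models are built at ambient leaf temperature.

Fitting enumerates the Ci cutover between the Rubisco-limited low-Ci
region and the RuBP-regeneration-limited high-Ci region (at least 4
Rubisco points; a 1-point RuBP region is skipped as it cannot
constrain J), solves a bounded least squares over (Vcmax, J, Rd) per
assignment, and keeps the assignment with minimal total RSS, ties
toward more Rubisco-limited points.  J is reported as J1800 —
electron transport at the 1800 µmol m⁻² s⁻¹ measurement irradiance,
deliberately not called Jmax — and only when ≥ 2 points are RuBP
limited; low-Rubisco material that never becomes electron-transport
limited yields Vcmax with J1800 flagged unavailable.  Rd is fitted
(bounded ≥ 0) in both curve types.  TPU limitation is not modeled.

A/Q curves (light steps 2000, 1800, 1400, 1000, 600, 400, 200, 150,
100, 75, 50, 0 µmol m⁻² s⁻¹ at 400 µmol mol⁻¹ CO₂) are corrected to
absorbed irradiance Ia = Q·absorptance (default leaf absorptance 0.85,
a typical integrating-sphere value for healthy leaves) and fitted with
the non-rectangular hyperbola

    A(Ia) = [ϕIa + Pmax − √((ϕIa+Pmax)² − 4ϕIa·θ·Pmax)]/(2θ) − Rd,

bounded least squares over ϕ ∈ (0.01, 0.125], θ ∈ (0.01, 1],
Pmax > 0, Rd ≥ 0, initialized from the data (ϕ₀ = low-light slope,
Rd₀ = −A(0), Pmax₀ = max(A)+Rd₀, θ₀ = 0.7).  ϕ is freely fitted; the
apparent quantum yield ϕCO₂ is estimated separately as the
free-intercept OLS slope of A on Ia restricted to Ia < 150 µmol m⁻²
s⁻¹ and reported alongside.  On noiseless hyperbola data ϕCO₂ ≤ ϕ
(the secant under a concave curve), which the tests assert.

## Numerical choices and degenerate inputs

* K-means: fewer distinct spectra than clusters raises a
  degenerate-clustering error; a scene with no vegetation cluster
  raises a labeling error; requesting an unmapped class returns an
  empty set with a warning.
* NIPALS truncates honestly when the residual collapses (noiseless
  rank-k data cannot support more than k components); the PRESS curve
  then flattens and the tie rule still selects the true rank.
* Constant traits, < 4 samples, and non-finite values are rejected
  before fitting; grid mismatches at prediction time are errors, never
  silent interpolation.
* A/Ci trial parameters that admit no real Cc solution are handled by
  clipping the discriminant inside the optimizer only; the forward
  model proper raises.

## Problem sizes

Desk-scale defaults keep every check cheap while preserving the
statistical structure: 60×60 noiseless and 250×250 noisy scenes
(≥ 25 000 sunlit pixels), ten 100×100 scenes for the segmentation
oracle, n = 200 plots on a 60-band grid with 1000 resamples × 5 seeds
for PLSR recovery, and the printed instrument step grids for the
gas-exchange fitters.

## Known limitations

* Semantic labeling assumes one panel per scene and brightness
  orderings that hold for the simulated endmembers; unusual scenes
  (wet soil darker than shadow, no panel) need the thresholds adjusted
  or labels supplied externally.
* The two cameras are treated as co-registered per plot; real
  footprints differ, which is why joining happens at the plot-mean
  level rather than per pixel.
* Field-scale predictive skill (CV R² on real trait data) is outside
  what synthetic scenes can establish; the package validates the
  machinery, not the biology.
* Splice correction implements additive offsets referenced to the NIR
  detector; multiplicative-gain jump correction dialects are not
  implemented.
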