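# hyperphen

Plot-level hyperspectral phenotyping of photosynthesis for field
trials.  `hyperphen` takes raw push-broom hypercubes of crop plots —
imaged together with a white reference panel by a VNIR camera
(400–900 nm, 2.1 nm bands) and a NIR camera (900–1800 nm, 4.9 nm
bands) — and turns them into per-plot sunlit-leaf reflectance spectra
and trait predictions, alongside the leaf-level machinery that
produces the ground-truth traits.  It is written for plant
physiologists and phenotyping engineers who want to screen plots for
photosynthetic performance (V<sub>c,max</sub>, J<sub>1800</sub>,
P<sub>max</sub>, chlorophyll, Chl a:b, C, N, ϕCO₂) without
destructive sampling at scale.

The pipeline, in order:

1. **Radiometric calibration** — raw digital numbers to radiance,
   L = (DN − dark)·gain/t + offset (`hyperphen.envi`; ENVI
   header + flat binary I/O).
2. **Pixel classification** — K-means (k = 6) on per-pixel radiance
   separates sunlit leaves and the Teflon panel from shaded leaves,
   soil, platform shadow and non-biological matter; clusters are named
   from brightness and a red-edge NDVI on their centroids
   (`hyperphen.segment`).
3. **Reflectance** — band-wise ratio against the in-scene panel,
   R = (S<sub>sunlit</sub>/S<sub>ref</sub>)·R<sub>ref</sub>; per-plot
   mean ± SD over all sunlit pixels; the two cameras joined at 900 nm;
   Savitzky–Golay smoothing (window 11, order 2); bands kept in
   450–1700 nm minus the 1313–1440 nm water-absorption window
   (`hyperphen.reflectance`).
4. **PLSR trait models** — PLS1 NIPALS on mean-centered spectra, the
   latent-variable count chosen at the minimum leave-one-out PRESS
   RMSE, stability statistics from 1000× random resampling (CV R²,
   RMSE, RMSE% = 100·RMSE/(max−min), bias), and VIP band-importance
   scores with Σ VIP² = p (`hyperphen.plsr`).
5. **Gas-exchange ground truth** — FvCB fitting of A/Ci curves for
   V<sub>c,max</sub> and J<sub>1800</sub> with mesophyll conductance
   constrained by gm = −0.44 + 0.058·T, and non-rectangular-hyperbola
   fitting of A/Q curves for P<sub>max</sub>, ϕ, θ, R<sub>d</sub> plus
   the low-light slope ϕCO₂ (`hyperphen.gasex`).
6. **Synthetic scenes and curves** — `hyperphen.simulate` generates
   plot scenes, trait-coupled spectra and gas-exchange curves with
   known ground truth, so the whole pipeline is exercisable and
   testable at desk scale.  `hyperphen.leafclip` handles leaf-clip
   spectroradiometer QC (splice correction, 2-percentage-point
   deviation filter, <4-viable-replicate rejection).

## Worked example

```python
import numpy as np
from hyperphen import (
    SceneConfig, simulate_scene, plot_reflectance_pipeline,
    FvCBParams, simulate_gas_exchange, fit_aci, gm_at_temperature,
)
from hyperphen.simulate import default_leaf_reflectance

# a 100x100-pixel plot scene, 1% radiance noise, both cameras
cubes, truth = simulate_scene(SceneConfig(lines=100, samples=100,
                                          noise_sd=0.01, seed=42))
plot, class_maps = plot_reflectance_pipeline(cubes, plot_id="plot-1")
print(plot.n_pixels)                      # 4000 sunlit pixels
wl = plot.mean.wavelengths_nm
print(round(float(wl[0]), 1), round(float(wl[-1]), 1))   # 450.4 1698.7
band550 = np.argmin(np.abs(wl - 550))
print(round(float(plot.mean.values[band550]), 3))        # 0.12 (green bump)

# ground-truth trait from a simulated A/Ci curve on the instrument grid
curve = simulate_gas_exchange("ACi", FvCBParams(vcmax=100, j=150, rd=1.5))
fit = fit_aci(curve)
print(round(fit.vcmax, 1), round(fit.j1800, 1))          # 100.0 150.0
print(round(gm_at_temperature(25.0), 2))                 # 1.01
```

The plot spectrum spans the joined, masked grid (450–1700 nm with the
water band removed — the last retained band is 1698.7 nm on the NIR
camera's native step); 0.12 at 550 nm is the green-peak reflectance
of the simulated leaf endmember recovered through
segmentation and panel-ratio calibration.  The A/Ci fit returns the
generating V<sub>c,max</sub> and J<sub>1800</sub> exactly on noiseless
data, with gm fixed at its 25 °C tobacco value of 1.01 mol m⁻² s⁻¹
bar⁻¹.

A command-line interface covers the table-driven workflows:

```sh
hyperphen train --spectra plots.csv --traits traits.csv --trait vcmax \
    --range 450:900 --resamples 1000 --seed 1 --model-out vcmax.json
hyperphen predict --model vcmax.json --spectra new_plots.csv
hyperphen fit-aci --curve leaf7_aci.csv --leaf-t 27.5
hyperphen fit-aq  --curve leaf7_aq.csv --absorptance 0.85
```

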