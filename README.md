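# mitograph

Quantitative analysis of live-cell STED nanoscopy of mitochondria: the
inner membrane (IM) imaged at ~40 nm resolution and mtDNA nucleoids
imaged at confocal resolution in a second channel. The package is aimed
at microscopists and image analysts who want the whole measurement chain
— image formation, resolution estimation, segmentation, skeleton
morphometry and spatial statistics — as reusable, tested code, plus a
synthetic-scene generator so everything can be validated without
microscope data.

## What it computes

**Depletion physics.** Fluorescence under a depletion beam follows
F(I) = F0 / (1 + I/I_s), where the saturation power I_s is the power at
which the signal halves; the effective PSF obeys

d = d0 / √(1 + I_dep / I_s)

so a low-saturation dye (I_s ≈ 0.86 mW) driven at I_dep ≈ 35 mW turns a
250 nm confocal PSF into a ~39 nm STED PSF. `fit_saturation_power`
estimates I_s from a measured two-pass power series (excitation on/off,
with the depletion-only pass subtracted to remove secondary excitation).

**Resolution.** Fourier ring correlation between two frames (1/7
threshold) and Gaussian-fitted line-profile FWHM.

**Segmentation.** Cristae via a deterministic ridge-filter probability
map (or a trainable random-forest pixel classifier), whole mitochondria
via morphological closing and labeling, nucleoids via blob detection in
the confocal channel.

**Morphometry.** Per-mitochondrion skeleton length, tips and branch
points, cristae counts, areas, and the three-class morphology rule
(Class I: length < 2.5 µm and < 6 cristae; Class II: 2.5–5 µm or 6–12
cristae; Class III: > 5 µm or > 12 cristae) used to compare, e.g.,
healthy networks against ferroptotic fragments.

**Spatial statistics.** Landmark-to-nucleoid nearest distances, the
fraction below 0.6 µm, exponential-law fits (MLE + bootstrap CI + KS),
mtDNA/mitochondrion area ratios and nonparametric group comparisons.

**Synthetic scenes.** Tubular networks (200–700 nm diameter, transverse
cristae ~70 nm apart), nucleoids placed at tips/branch points with
occupancy 0.677 and an exponential nearest-distance law, rendered into
both channels with Poisson + read noise. See `docs/methods.md` for the
models and every default.

## Worked example

Fit a saturation power from a simulated two-pass depletion series and
predict the STED resolution:

```python
import numpy as np
from mitograph import (simulate_depletion_series, fit_saturation_power,
                       effective_fwhm)

series = simulate_depletion_series(0.864, np.linspace(0, 40, 12),
                                   noise_level=0.02, seed=1)
result = fit_saturation_power(series)
print(result.summary())
print(f"effective FWHM at 34.7 mW: "
      f"{effective_fwhm(250.0, 34.7, result.Is_mW):.1f} nm")
```

```
Saturation-power fit
====================
method:          model-fit
Is:              0.8683 mW
std err:         0.00839 mW
95% CI:          [0.8519, 0.8847] mW
n powers:        12

effective FWHM at 34.7 mW: 39.1 nm
```

The fitted saturation power (0.868 mW from a 2%-noise series generated
at 0.864 mW) predicts a 39 nm effective PSF at the live-cell depletion
power — a 6.4-fold enhancement over the confocal 250 nm.

Run the full synthetic pipeline (scene → acquisition → segmentation →
morphometry → statistics), from Python or the CLI:

```python
from mitograph.config import PipelineConfig
from mitograph.pipeline import run_pipeline

cfg = PipelineConfig()
cfg.scene.field_size_um = (12.0, 12.0)
cfg.scene.n_components = 3
cfg.nucleoids.interior_per_um = 0.55   # control-like nucleoid density
cfg.seed = 3
run_pipeline(cfg, outdir="out")
```

`out/mitochondria.csv` then holds one row per detected organelle:

```
 label  length_um  n_cristae class  mito_area_um2  cristae_area_um2  nucleoid_area_um2
     1   6.381909         48   III         3.4548            1.9484             0.3152
     2   4.638183         25   III         2.2644            1.3288             0.6312
     3   4.515290          4    II         1.4196            0.8244             0.7088
```

and `out/spatial_report.json` the distance and area statistics for this
field (e.g. mean mtDNA/mitochondrion area ratio 0.29; 11 of 13 tip
distances below 0.6 µm). The same stages are available as
`mitograph simulate | acquire | segment | run | satfit | frc | fwhm`
with `--config config.yaml --seed N --out DIR`; exit codes are 0 (ok),
1 (data/estimation error), 2 (configuration error).

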