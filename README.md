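# spectex

Spectral–spatial texture classification of tree species in high-resolution
multispectral canopy imagery.

## The problem

Mapping many co-occurring tree species from satellite imagery is hard:
a 4-band (blue/green/red/NIR) sensor gives each crown only a handful of
noisy spectral values, and the crowns of dozens of species overlap heavily
in that space. `spectex` implements a complete, tested pipeline for the
classical pixel-based attack on this problem:

1. **Radiometry** — digital numbers → at-sensor radiance
   (`L = a·k·DN/Δλ`) → surface reflectance via dark-object subtraction.
2. **Pansharpening** — principal-component substitution: the first
   component of the upsampled multispectral stack is replaced by the
   panchromatic band, linearly stretched onto the PC1 range, producing the
   high-resolution multispectral stack (HMS).
3. **Vegetation indices** — NDVI, SAVI, ARVI, VARI and EVI layers
   assembled into a 5-band index stack (HMS5VI).
4. **Lee-sigma texture** — each band replaced by the mean of window
   neighbors within `DN_c ± 2σ_local`, suppressing spikes while preserving
   edges (SpecTex); stacking HMS + HMS5VI + SpecTex gives the 13-band
   integrated dataset (HMS13B).
5. **Classification** — per-species multivariate-Gaussian signatures feed
   four native decision rules (maximum likelihood, Mahalanobis distance,
   spectral angle, spectral information divergence) plus a plug-in
   contract for external learners.
6. **Evaluation** — pairwise transformed divergence
   `TD = 2000·(1 − e^{−D/8})` for signature separability, error-matrix
   overall kappa (OKC) and per-species conditional kappa (SCKC), and the
   accuracy-improvement efficiency `AIE = (OKC − OKC_min)/OKC_min`
   analysed as a fixed-effects two-way factorial ANOVA with Duncan
   multiple-range grouping.

Because no suitable imagery is freely deposited, the package ships a
seeded synthetic canopy-scene generator (crown mosaics with
per-crown random effects, correlated texture, impulse noise, intra-canopy
gaps, and a two-resolution sensor model) so the whole pipeline is
exercisable and testable end to end.

## Worked example

Fit Gaussian signatures on a pansharpened synthetic scene and evaluate on
held-out crowns:

```python
import numpy as np
from spectex import (SceneConfig, generate_scene, pct_fuse,
                     SignatureModel, split_labels_by_crown)

cfg = SceneConfig(n_species=4, rows=24, cols=24, crowns_per_species=3,
                  crown_radius=(5, 7), seed=7)
scene = generate_scene(cfg)
hms = pct_fuse(scene.ms, scene.pan)
hms = hms.with_data(np.clip(hms.data, 0, 1))
train, test = split_labels_by_crown(scene.labels, scene.crown_ids, 0.5, seed=8)

res = SignatureModel.from_rasters(hms, train).fit()
print(res.summary())
rep = res.evaluate(hms, test, method="mlc")
print(f"test OKC {rep.okc:.3f}, overall accuracy {rep.overall_accuracy:.3f}")
```

prints

```
Gaussian signature model
========================
species: 4   bands: 4   training pixels: 900

 code species   n  mean_blue  sd_blue  mean_green  sd_green  mean_red  sd_red  mean_nir  sd_nir
    1    sp01 218     0.1022   0.0261      0.1501    0.0302    0.1420  0.0419    0.4174  0.0426
    2    sp02 213     0.0727   0.0248      0.0836    0.0279    0.1104  0.0386    0.3547  0.0389
    3    sp03 220     0.1210   0.0270      0.1642    0.0290    0.1635  0.0409    0.4468  0.0410
    4    sp04 249     0.0701   0.0242      0.1207    0.0260    0.0774  0.0388    0.3417  0.0347

Transformed-divergence separability (0-2000):
  separable (TD=2000): 4
  good (1900<=TD<2000): 1
  poor (TD<1900): 1
  worst pair: sp01-sp03 (TD=1476)

test OKC 0.885, overall accuracy 0.914
```

The summary is the fitted model: per-species mean reflectance and spread
per band, with the transformed-divergence tally showing which species
pairs the signatures can separate (TD saturates at 2000 for fully
separable pairs; values below 1900 flag confusable pairs — here sp01 vs
sp03, the two bright high-NIR species). The held-out kappa of 0.885 is
the chance-corrected agreement on crowns the model never saw.

The full four-dataset comparison (HMS, HMS5VI, SpecTex, HMS13B) runs in
one call:

```python
from spectex import run_synthetic_benchmark
result, scene = run_synthetic_benchmark(seed=1, classifiers=("mlc",))
print(result.okc_table().to_string(index=False, float_format="%.4f"))
```

```
classifier dataset   test  training  uncertainty
       mlc     HMS 0.6125    0.7525       0.1400
       mlc  HMS13B 0.6011    0.8089       0.2078
       mlc  HMS5VI 0.5132    0.6664       0.1531
       mlc SpecTex 0.6349    0.7646       0.1297
```

Training kappa orders HMS13B > SpecTex > HMS > HMS5VI — texture filtering
beats the raw bands, index-only classification trails both, and the
integrated 13-band stack is best — while every scheme loses accuracy on
the held-out crowns (the `uncertainty` column), because individual trees
of one species differ in brightness and greenness.

A command-line interface wraps the same pipeline for on-disk rasters:

```bash
spectex simulate --out-dir scene/ --seed 5
spectex fuse --ms scene/ms.tif --pan scene/pan.tif --out hms.tif
spectex indices --in hms.tif --out hms5vi.tif
spectex texture --in hms.tif --out spectex.tif --window 7
spectex classify --in hms.tif --train scene/labels_train.tif --method mlc --out pred.tif
spectex run --config experiment.yaml
```

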