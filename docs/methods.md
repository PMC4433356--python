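# Methods

This note documents the models implemented in `spectex`, the parameters
that matter, what the synthetic-scene generator does and does not
emulate, and the numerical choices made where the design was open.

## Radiometric model

Digital numbers are converted band-by-band to at-sensor spectral radiance

    L_i = a_i · k_i · DN_i / Δλ_i        [W m⁻² μm⁻¹ sr⁻¹]

with calibration gain `a_i`, revised factor `k_i` (exposure/TDI-level
dependent, hence a per-band config value) and nominal bandpass width
`Δλ_i`. Bandpass widths are carried in micrometers so the radiance units
come out as stated; the shipped defaults are the published 16-bit
QuickBird coefficients for 10 TDI levels (pan 0.0838188/0.06269/455 nm,
blue 0.0160412/0.01431/70 nm, green 0.0143847/0.01045/80 nm, red
0.0126735/0.00968/60 nm, NIR 0.0154242/0.01568/140 nm).

Surface reflectance uses dark-object subtraction,

    ρ = π (L − L_path) d² / (ESUN · cos θ_z),

with the per-band path radiance derived from a user-supplied dark-object
DN through the same calibration, Earth–Sun distance `d` in AU, solar
zenith `θ_z`, and band-averaged exoatmospheric irradiances (QuickBird
defaults shipped). This is a deliberate simplification of full
radiative-transfer correction: it preserves the contract that matters
downstream — reflectance in [0, 1] feeding ratio-based indices — without
an aerosol model. Negative post-subtraction values are clipped to 0
rather than masked so dark crown pixels stay usable; the output is also
clipped at 1.

## Principal-component pansharpening

The multispectral stack is upsampled to the pan grid (bilinear by
default; the resampling kernel is configurable because it is a free
choice), rotated into principal components of the covariance matrix over
valid pixels, and PC1 is replaced by the pan band stretched affinely so
its extrema match the PC1 extrema:

    H = pc1_min + (Pan − pan_min)(pc1_max − pc1_min)/(pan_max − pan_min).

Numerical choices: covariance (not correlation) PCT; PC1 sign fixed so
its loadings sum positive (deterministic orientation); extrema computed
globally over non-nodata pixels. A flat pan band is an error — there is
no spatial detail to inject. Substituting PC1 with itself reproduces the
upsampled stack exactly (orthonormal rotation), which the tests use as an
identity oracle.

## Vegetation indices

Five standard indices, computed from the fused reflectance stack and
stacked in the fixed order [NDVI, SAVI, EVI, ARVI, VARI]:

| index | form | defaults |
|---|---|---|
| NDVI | (ρn − ρr)/(ρn + ρr) | — |
| SAVI | (ρn − ρr)(1 + L)/(ρn + ρr + L) | L = 0.5 (moderate green cover) |
| ARVI | (ρn − ρrb)/(ρn + ρrb), ρrb = ρr − γ(ρb − ρr) | γ = 1 (aerosol model unknown) |
| VARI | (ρg − ρr)/(ρg + ρr − ρb) | — |
| EVI | G(ρn − ρr)/(ρn + C1·ρr − C2·ρb + L) | G = 2.5, C1 = 6, C2 = 7.5, L = 1 |

Denominators within `eps = 1e-6` of zero yield nodata pixels rather than
infinities; the index stack's mask is the union of the per-index masks.
NDVI, ARVI and VARI are invariant to a joint rescaling of the spectrum;
SAVI and EVI are not (additive constants) — a property the tests assert
per index, and one that matters for the synthetic benchmark below.

## Lee-sigma texture

For each pixel, the local standard deviation `σ_local` is the sample
standard deviation (n−1) of the unmasked window values; the output is the
mean of the window values inside `DN_c ± k·σ_local` (the center always
qualifies). Defaults: 7×7 window (the window size is not fixed by theory,
so it is a config value tested across {3, 5, 7, 9}) and `k = 2`. Windows
truncate at image borders — no padding values are invented — and masked
pixels are excluded from every window. When no neighbor is in range the
center value is kept: spikes in the *center* are preserved rather than
replaced with fabricated data, while spiky *neighbors* are excluded from
everyone else's average, which is what makes the filter an impulse-noise
suppressor that respects edges. On Gaussian noise the filter attenuates
the standard deviation by roughly 2.5× (the center-anchored acceptance
range keeps the output correlated with the center); on impulse noise the
suppression is near-total. Applying it to every band of an L-band image
yields the L-band "SpecTex" texture image.

## Gaussian signatures, separability, classifiers

Per-species signatures are the sample mean and sample covariance (n−1) of
the training pixels; a species must contribute more pixels than feature
bands. Ill-conditioned covariances (condition number > 1e10) get
`λ·(trace/B)·I` added with `λ = 1e-6`, escalating tenfold until the
condition number is workable — a minimal numerical safeguard, not a
statistical shrinkage.

Separability of two signatures uses the Gaussian divergence

    D = ½ tr[(Σ₁−Σ₂)(Σ₂⁻¹−Σ₁⁻¹)] + ½ tr[(Σ₁⁻¹+Σ₂⁻¹)(μ₁−μ₂)(μ₁−μ₂)ᵀ]

mapped to the saturating 0–2000 scale, `TD = 2000(1 − e^{−D/8})`, with
the conventional reading: 2000 (to integer rounding) separable,
[1900, 2000) good, below 1900 poor.

Four decision rules are native:

* **MLC** — argmax of `ln p_i − ½ln|Σ_i| − ½(x−μ_i)ᵀΣ_i⁻¹(x−μ_i)`;
  equal priors unless given; ties break toward the lowest species code
  (argmax over ascending-code columns).
* **MD** — minimum Mahalanobis distance under one pooled
  (training-count-weighted) covariance; per-class covariances would just
  reproduce MLC's quadratic term.
* **SAM** — minimum spectral angle to the class means; invariant to
  positive per-pixel rescaling; zero-norm pixels are masked.
* **SID** — symmetrized relative entropy between the pixel and mean
  spectra normalized to probability simplices; zeros floored at 1e-12
  before normalization, all-zero pixels masked.

External learners (SVM, neural networks) enter only through a plug-in
callable `(training samples, pixel matrix) → labels`; the package never
imports a learner itself.

## Accuracy assessment

The error matrix is predicted-by-reference counts with **rows =
predicted map class, columns = reference class** (the orientation is a
convention and is fixed here). Overall kappa (OKC) is
`(p_o − p_e)/(1 − p_e)`; the user's-accuracy-based conditional kappa of
species *i* (SCKC) is `(n·n_ii − n_i₊·n_₊i)/(n·n_i₊ − n_i₊·n_₊i)`.
Species absent from a map still get zero rows/columns so the matrix size
is stable across reports. Classification uncertainty is the plain
difference between training-sample and test-sample OKC. Hard-to-classify
species are those with training SCKC below 0.95. Kappa variance
estimators are out of scope.

## AIE and the factorial analysis

For each kind of OKC (performance = training samples, accuracy = test
samples) the baseline `OKC_min` is the *minimum* OKC among classifiers on
the plain HMS dataset, and every classifier × dataset cell is scored by
`AIE = (OKC − OKC_min)/OKC_min`. The AIE table is analysed as a balanced
fixed-effects two-way ANOVA with interaction
(`aie ~ C(dataset) * C(classifier)`, fitted via OLS). With one AIE per
cell the interaction would not be estimable; **the two OKC kinds serve as
the two replicates per cell**. This is an interpretation — the original
design's replication is not documented — so printed F values from other
analyses of the same design are not comparable targets. Significance is
judged at α = 0.05.

Duncan's new multiple range test groups factor levels: means sorted
descending, a stretch of p ordered means is homogeneous when its range is
at most `q(α_p, p, df_err)·√(MS_err/n)` with protection level
`α_p = 1 − (1−α)^{p−1}`; critical values come from the
studentized-range distribution (no hard-coded tables). Because the range
test is not monotone in stretch length, all stretch end points are
checked and letters are assigned to the maximal homogeneous stretches,
which makes the grouping order-consistent by construction.

## The synthetic scene generator

The generator emulates the statistical structure of a subtropical
overstorey mosaic at two sensor resolutions. The true scene lives on the
fine (pan) grid; the multispectral stack is its 4×4 block average and the
pan band is a weighted band sum (weights 0.10/0.25/0.25/0.40) plus sensor
noise. Crowns are non-overlapping discs; labels mark pure crown pixels on
the fine grid. Defaults (all per-band vectors ordered
blue/green/red/NIR):

* **Species means** — a base foliage spectrum (0.055, 0.090, 0.065,
  0.42) modulated by two controllable axes: a chromatic ring of radius
  0.038 in the plane of a green-vs-red contrast and an NIR-vs-visible
  contrast, and a brightness factor in 1 ± 0.22 that *alternates*
  dark/bright between chroma-adjacent species. The alternation makes the
  scene's difficulty deterministic: discriminating chromatic neighbors
  always involves the brightness axis, whatever the seed.
* **Within-crown texture** — a common-mode Gaussian field (correlation
  length 0.5 px, per-band sd 0.027/0.043/0.032/0.20) shared by all bands:
  crown micro-structure (leaf angles, self-shadowing) modulates all
  wavelengths together. 12% of fine pixels carry impulse spikes at 4×
  amplitude — the salt-and-pepper imperfections sigma filtering targets.
* **Individual-tree variation** — per-crown multiplicative brightness
  (sd 0.03) and additive chromatic tilt (sd 0.004).
* **Intra-canopy gaps** — with probability 0.06 a crown pixel is a convex
  mixture (mixing weight U(0.3, 1)) of the crown spectrum and a bright
  soil background (0.16, 0.20, 0.24, 0.30); gap pixels are unlabeled.
* **Pixel noise** — iid Gaussian, sd 0.008/0.010/0.008/0.025; pan sensor
  noise sd 0.05.
* **Scene size** — 10 species, 64×64 coarse pixels (256×256 fine,
  2.4 m/0.6 m), 8 crowns per species with radius 7–12 fine px.

The default benchmark (`run_synthetic_benchmark`) pansharpens the scene,
splits the reference crowns **by whole crowns** (training and test
samples come from distinct individual trees, mirroring field campaigns
that survey different trees for training and validation) and thins the
training labels to 110 pixels per species, the order of magnitude a
stratified field campaign yields. Pixel-level stratified sampling with
exact per-species counts is also available.

These defaults were calibrated once so the generated scenes reproduce the
qualitative behavior the pipeline is built to exhibit, and then frozen.
The mechanisms are worth stating because they are the scientific content
of the benchmark:

* fine-grained impulse/texture noise reaches the fused stack through the
  pan substitution (any fine-scale noise in the fused product is rank-1,
  along PC1); the sigma filter strips it, so **SpecTex beats HMS** on
  training kappa;
* ratio-based indices discard the brightness axis along with its noise,
  and with it the brightness separation between species, so **HMS5VI
  trails HMS**;
* the 13-band stack sees the same noise twice (raw and filtered), letting
  the full covariance partially cancel it, and its higher dimensionality
  fits the finite training sample more closely, so **HMS13B ≥ SpecTex**;
* per-crown random effects are not shared across the crown-disjoint
  split, so **test kappa < training kappa** for every scheme.

What the generator does *not* emulate: real crown shapes and adjacency
(discs never touch), sensor MTF and TDI effects, phenology, mixed pixels
at crown boundaries beyond what block averaging induces, and the actual
signature overlap structure of any particular forest. Passing benchmarks
therefore demonstrate that the pipeline's comparative orderings follow
from the stated noise mechanisms — not that any absolute kappa level
would be attained on real imagery.

## Problem sizes

The test suite and the acceptance script run the benchmark at the default
scene size (10 species, 256×256 fine pixels, ~2 000 labeled training
pixels per run), ten seeds for the ordering/uncertainty checks, twenty
seeds for parameter recovery (with gaps, texture, spikes and crown
effects disabled, trained means are pure sampling draws around the
generating means), and twenty simulated tables per ANOVA operating
characteristic. These sizes keep a full run in tens of seconds while
leaving the statistical margins comfortable.

## Known limitations

* The dark-object reflectance stand-in ignores aerosol scattering beyond
  a constant path radiance per band.
* MD uses a pooled covariance by definition; species with very unequal
  spreads are better served by MLC.
* SID and SAM ignore covariance information entirely; they are included
  as the classical spectral-matching baselines.
* The Duncan letters follow the protected-range rule exactly; with many
  levels and near-ties the grouping can be sensitive to `MS_err`.
* Kappa estimates carry no standard errors; comparisons across runs rely
  on reseeding rather than analytic variance.
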