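"""Seeded synthetic canopy scenes for end-to-end pipeline testing.

No imagery is deposited with the study this package emulates, so every
pipeline stage is exercised on generated scenes that carry the statistical
structure the analysis assumes:

* a mosaic of circular tree crowns from K species, each with a distinct
  4-band (blue/green/red/NIR) multivariate-Gaussian spectral signature;
* per-crown random effects (brightness and a small chromatic tilt),
  emulating individual trees of one species differing in foliage density
  and leaf greenness — the driver of train/test classification
  uncertainty when samples come from distinct trees;
* spatially correlated within-crown texture: a common-mode (brightness)
  field shared by all bands, plus a fraction of impulse spikes -- the
  salt-and-pepper imperfections sigma filtering is designed to suppress;
* intra-canopy gaps: crown pixels replaced with probability
  ``intra_gap_prob`` by a convex mixture of crown and background spectra
  (bright soil: high red, NIR well below foliage);
* two resolutions: the true scene lives on the fine (pan) grid; the
  multispectral stack is its block average at a coarser grid, and the
  panchromatic band is a weighted band sum on the fine grid plus noise.

Labels mark pure (non-gap) crown pixels on the fine grid.  Everything is
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .raster_io import LabelRaster, RasterStack

__all__ = [
    "SceneConfig",
    "SceneBundle",
    "generate_scene",
    "default_species_means",
    "stratified_sample",
    "split_labels_by_crown",
    "thin_labels",
]

BAND_NAMES = ("blue", "green", "red", "nir")

# broadleaf-canopy base reflectance: dark visible bands, bright NIR plateau
_BASE_FOLIAGE = np.array([0.055, 0.090, 0.065, 0.42])


@dataclass
class SceneConfig:
    """Parameters of the synthetic canopy mosaic.

    Sizes are in coarse multispectral pixels; the fine (pan) grid is
    ``resolution_ratio`` times denser.  Reflectance is dimensionless in
    [0, 1] throughout.
    """

    n_species: int = 10
    rows: int = 64
    cols: int = 64
    resolution_ratio: int = 4
    ms_pixel_size: float = 2.4

    crowns_per_species: int = 8
    crown_radius: tuple[int, int] = (7, 12)  # fine-grid pixels

    species_means: np.ndarray | None = None  # K x 4, generated when None
    chroma_scale: float = 0.038  # ring radius of chromatic separation
    brightness_spread: float = 0.22  # species brightness in 1 +/- spread

    band_noise_sd: tuple[float, ...] = (0.008, 0.010, 0.008, 0.025)
    texture_sd: tuple[float, ...] = (0.027, 0.043, 0.032, 0.20)
    texture_corr_length: float = 0.5  # fine-grid pixels

    spike_prob: float = 0.12  # impulse-noise fraction of fine pixels
    spike_scale: float = 4.0  # spike amplitude in units of the texture sd

    crown_brightness_sd: float = 0.03
    crown_chroma_sd: float = 0.004

    intra_gap_prob: float = 0.06
    gap_mix_range: tuple[float, float] = (0.3, 1.0)

    background_mean: tuple[float, ...] = (0.16, 0.20, 0.24, 0.30)
    background_sd: float = 0.02

    pan_weights: tuple[float, ...] = (0.10, 0.25, 0.25, 0.40)
    pan_noise_sd: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.intra_gap_prob <= 1.0:
            raise ValueError("intra_gap_prob must be a probability")
        if self.resolution_ratio < 1 or int(self.resolution_ratio) != self.resolution_ratio:
            raise ValueError("resolution_ratio must be a positive integer")
        if self.n_species < 1 or self.n_species > 40:
            raise ValueError("n_species must be in 1..40")
        if self.species_means is not None:
            m = np.asarray(self.species_means, dtype=float)
            if m.shape != (self.n_species, 4):
                raise ValueError("species_means must be n_species x 4")
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError("species means must be reflectances in [0, 1]")

    def with_(self, **kw) -> "SceneConfig":
        return replace(self, **kw)


@dataclass
class SceneBundle:
    """Everything :func:`generate_scene` produces.

    ``truth`` is the noise-realized fine-grid reflectance scene before the
    sensor step (block averaging / pan synthesis); labeled pixels of
    ``truth`` are exact draws from the species model, which is what
    parameter-recovery tests consume.
    """

    ms: RasterStack
    pan: RasterStack
    labels: LabelRaster
    truth: RasterStack
    crown_ids: np.ndarray
    species_means: np.ndarray
    config: SceneConfig


def default_species_means(
    n_species: int,
    rng: np.random.Generator,
    chroma_scale: float = 0.030,
    brightness_spread: float = 0.22,
) -> np.ndarray:
    """Species mean spectra: brightness ladder plus a chromatic ring.

    Species differ along two controllable axes: an overall brightness
    factor (alternating dark/bright around the ring) and a
    chromatic displacement on a ring of radius ``chroma_scale`` in the
    plane spanned by a green-vs-red contrast and an NIR contrast.  The
    ring makes the minimum pairwise chromatic distance a single knob.
    """
    base = _BASE_FOLIAGE
    # chroma-adjacent species alternate dark/bright so that neighbour
    # discrimination always involves the brightness axis; the slight ladder
    # on top keeps all K factors distinct
    idx = np.arange(n_species)
    bright = 1.0 + np.where(idx % 2 == 0, 1.0, -1.0) * brightness_spread * (
        0.6 + 0.4 * idx / max(n_species - 1, 1)
    )
    # orthonormal chromatic directions: green-red seesaw, nir-vs-visible
    d1 = np.array([0.0, 1.0, -1.0, 0.0]) / np.sqrt(2)
    d2 = np.array([-0.25, -0.25, -0.25, 0.93])
    d2 = d2 / np.linalg.norm(d2)
    angles = 2 * np.pi * (np.arange(n_species) + rng.uniform()) / n_species
    means = (
        base[None, :] * bright[:, None]
        + chroma_scale * (np.cos(angles)[:, None] * d1 + np.sin(angles)[:, None] * d2)
    )
    return np.clip(means, 0.01, 0.99)


def _correlated_field(
    shape: tuple[int, int], corr_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field (smoothed noise)."""
    white = rng.standard_normal(shape)
    if corr_length <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, corr_length, mode="reflect")
    sd = smooth.std()
    return smooth / (sd if sd > 0 else 1.0)


def _place_crowns(
    cfg: SceneConfig, shape: tuple[int, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Place non-overlapping discs; return (species map, crown-id map)."""
    species = np.zeros(shape, dtype=int)
    crown_id = np.zeros(shape, dtype=int)
    occupied = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    next_id = 1
    r_lo, r_hi = cfg.crown_radius
    for code in range(1, cfg.n_species + 1):
        for _ in range(cfg.crowns_per_species):
            for attempt in range(400):
                rad = int(rng.integers(r_lo, r_hi + 1))
                r0 = int(rng.integers(rad, shape[0] - rad))
                c0 = int(rng.integers(rad, shape[1] - rad))
                disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
                # one-pixel spacing so crowns of different trees never touch
                halo = (rr - r0) ** 2 + (cc - c0) ** 2 <= (rad + 1) ** 2
                if not occupied[halo].any():
                    species[disc] = code
                    crown_id[disc] = next_id
                    occupied |= halo
                    next_id += 1
                    break
            else:
                raise RuntimeError(
                    f"could not place crown {next_id} (species {code}); "
                    "scene too small for the requested crown layout"
                )
    return species, crown_id


def generate_scene(cfg: SceneConfig) -> SceneBundle:
    """Generate one seeded scene (fine truth, coarse MS, fine pan, labels)."""
    rng = np.random.default_rng(cfg.seed)
    ratio = int(cfg.resolution_ratio)
    fine_shape = (cfg.rows * ratio, cfg.cols * ratio)
    species_map, crown_id = _place_crowns(cfg, fine_shape, rng)

    means = (
        np.asarray(cfg.species_means, dtype=float)
        if cfg.species_means is not None
        else default_species_means(
            cfg.n_species, rng, cfg.chroma_scale, cfg.brightness_spread
        )
    )

    bg = np.asarray(cfg.background_mean)
    truth = np.empty(fine_shape + (4,))
    truth[:] = bg[None, None, :]
    truth += cfg.background_sd * rng.standard_normal(truth.shape)

    # per-crown random effects (individual-tree variation)
    n_crowns = int(crown_id.max())
    crown_bright = 1.0 + cfg.crown_brightness_sd * rng.standard_normal(n_crowns + 1)
    crown_chroma = cfg.crown_chroma_sd * rng.standard_normal((n_crowns + 1, 4))
    crown_bright[0] = 1.0
    crown_chroma[0] = 0.0

    in_crown = species_map > 0
    sp = species_map[in_crown]
    cid = crown_id[in_crown]
    crown_vals = (
        means[sp - 1] * crown_bright[cid, None]
        + crown_chroma[cid]
        + np.asarray(cfg.band_noise_sd)[None, :]
        * rng.standard_normal((in_crown.sum(), 4))
    )

    # spatially correlated texture: a common-mode (brightness) field shared
    # by all bands, scaled per band -- crown micro-structure (leaf angles,
    # self-shadowing) modulates all wavelengths together.  A fraction of
    # fine pixels additionally carries impulse spikes, the salt-and-pepper
    # imperfections sigma filtering is designed to suppress.
    field = _correlated_field(fine_shape, cfg.texture_corr_length, rng)
    if cfg.spike_prob > 0:
        spiky = rng.uniform(size=fine_shape) < cfg.spike_prob
        field = np.where(
            spiky, cfg.spike_scale * rng.standard_normal(fine_shape), field
        )
    tex = field[:, :, None] * np.asarray(cfg.texture_sd)[None, None, :]
    crown_vals += tex[in_crown]

    # intra-canopy gaps: convex crown/background mixtures
    gap = rng.uniform(size=in_crown.sum()) < cfg.intra_gap_prob
    if gap.any():
        alpha = rng.uniform(*cfg.gap_mix_range, size=int(gap.sum()))[:, None]
        bg_px = bg[None, :] + cfg.background_sd * rng.standard_normal(
            (int(gap.sum()), 4)
        )
        crown_vals[gap] = alpha * bg_px + (1 - alpha) * crown_vals[gap]

    truth[in_crown] = crown_vals
    truth = np.clip(truth, 0.0, 1.0)

    labels = np.zeros(fine_shape, dtype=int)
    rrcc = np.nonzero(in_crown)
    keep = ~gap
    labels[rrcc[0][keep], rrcc[1][keep]] = sp[keep]

    # sensor step: coarse MS = block mean; pan = weighted band sum + noise
    ms_data = truth.reshape(cfg.rows, ratio, cfg.cols, ratio, 4).mean(axis=(1, 3))
    pan_data = truth @ np.asarray(cfg.pan_weights)
    pan_data = pan_data + cfg.pan_noise_sd * rng.standard_normal(fine_shape)

    pan_px = cfg.ms_pixel_size / ratio
    species_table = {c: f"sp{c:02d}" for c in range(1, cfg.n_species + 1)}
    return SceneBundle(
        ms=RasterStack(ms_data, BAND_NAMES, pixel_size=cfg.ms_pixel_size),
        pan=RasterStack(pan_data[:, :, None], ["pan"], pixel_size=pan_px),
        labels=LabelRaster(labels, role="reference", species_table=species_table),
        truth=RasterStack(truth, BAND_NAMES, pixel_size=pan_px),
        crown_ids=crown_id,
        species_means=means,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def stratified_sample(
    labels: LabelRaster,
    counts: Mapping[int, int] | int,
    split: float = 0.5,
    seed: int = 0,
) -> tuple[LabelRaster, LabelRaster]:
    """Species-stratified random pixel sampling into disjoint train/test sets.

    ``counts`` is the total number of pixels requested per species (one
    integer for all species, or a per-code mapping); a fraction ``split``
    of each species' draw goes to training, the rest to test.  Errors name
    any species with too few labeled pixels.
    """
    if not 0.0 < split < 1.0:
        raise ValueError("split must be in (0, 1)")
    rng = np.random.default_rng(seed)
    codes = labels.codes
    if isinstance(counts, int):
        counts = {c: counts for c in codes}
    have = labels.counts()
    short = {c: (counts.get(c, 0), have.get(c, 0))
             for c in counts if have.get(c, 0) < counts[c]}
    if short:
        detail = ", ".join(
            f"{labels.species_table.get(c, c)} (need {n}, have {h})"
            for c, (n, h) in short.items()
        )
        raise ValueError(f"insufficient labeled pixels for: {detail}")
    train = np.zeros_like(labels.labels)
    test = np.zeros_like(labels.labels)
    for code in codes:
        n_req = counts.get(code, 0)
        if n_req == 0:
            continue
        rr, cc = np.nonzero(labels.labels == code)
        pick = rng.choice(len(rr), size=n_req, replace=False)
        n_train = int(round(split * n_req))
        tr, te = pick[:n_train], pick[n_train:]
        train[rr[tr], cc[tr]] = code
        test[rr[te], cc[te]] = code
    table = dict(labels.species_table)
    return (
        LabelRaster(train, role="training", species_table=table),
        LabelRaster(test, role="test", species_table=table),
    )


def thin_labels(
    labels: LabelRaster,
    per_species: int,
    seed: int = 0,
) -> LabelRaster:
    """Randomly keep at most ``per_species`` labeled pixels of each species.

    Emulates reference sampling: field campaigns identify a limited number
    of pixels per species, not every pixel of every crown.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros_like(labels.labels)
    for code in labels.codes:
        rr, cc = np.nonzero(labels.labels == code)
        if len(rr) <= per_species:
            out[rr, cc] = code
            continue
        pick = rng.choice(len(rr), size=per_species, replace=False)
        out[rr[pick], cc[pick]] = code
    return LabelRaster(
        out, role=labels.role, species_table=dict(labels.species_table)
    )


def split_labels_by_crown(
    labels: LabelRaster,
    crown_ids: np.ndarray,
    train_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[LabelRaster, LabelRaster]:
    """Split labeled pixels into train/test by whole crowns, per species.

    Emulates reference data collected from distinct individual trees:
    every crown's pixels go entirely to one side, so per-crown random
    effects are not shared between training and test.  Each species keeps
    at least one crown on each side (requires >= 2 crowns per species).
    """
    crown_ids = np.asarray(crown_ids)
    if crown_ids.shape != labels.labels.shape:
        raise ValueError("crown_ids shape must match labels")
    rng = np.random.default_rng(seed)
    train = np.zeros_like(labels.labels)
    test = np.zeros_like(labels.labels)
    for code in labels.codes:
        sel = labels.labels == code
        crowns = np.unique(crown_ids[sel])
        crowns = crowns[crowns > 0]
        if len(crowns) < 2:
            raise ValueError(
                f"species {labels.species_table.get(code, code)} has "
                f"{len(crowns)} crown(s); need >= 2 for a crown-level split"
            )
        perm = rng.permutation(crowns)
        n_train = min(max(int(round(train_fraction * len(crowns))), 1),
                      len(crowns) - 1)
        train_crowns = set(perm[:n_train].tolist())
        in_train = sel & np.isin(crown_ids, list(train_crowns))
        train[in_train] = code
        test[sel & ~in_train] = code
    table = dict(labels.species_table)
    return (
        LabelRaster(train, role="training", species_table=table),
        LabelRaster(test, role="test", species_table=table),
    )
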