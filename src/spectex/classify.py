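"""Per-pixel supervised classifiers over trained Gaussian signatures.

Four decision rules are implemented natively:

* **MLC** — Gaussian maximum likelihood: argmax of
  ``ln p_i - 1/2 ln|S_i| - 1/2 (x-m_i)^T S_i^-1 (x-m_i)`` (equal priors
  unless given).
* **MD** — Mahalanobis distance to each class mean under one pooled
  (n-weighted average) covariance; with equal class covariances and equal
  priors this reproduces MLC.
* **SAM** — spectral angle mapper: smallest angle between the pixel vector
  and each class mean (invariant to positive per-pixel rescaling).
* **SID** — spectral information divergence: pixel and mean are normalized
  to probability simplices and compared by symmetrized relative entropy.

External learners (SVM, neural nets, ...) enter only through a plug-in
callable contract; the package never imports one itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .raster_io import RasterStack, SampleSet
from .signatures import ClassSignature, _regularize

__all__ = [
    "ClassificationResult",
    "classify_mlc",
    "classify_md",
    "classify_sam",
    "classify_sid",
    "classify",
    "PluginClassifier",
]

_SID_EPS = 1e-12


@dataclass
class ClassificationResult:
    """Labeled map plus the winning per-pixel score (rule-dependent)."""

    label_map: np.ndarray
    score_map: np.ndarray | None
    classifier_name: str
    dataset_name: str = ""

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=int)


def _check_dims(stack: RasterStack, sigs: Sequence[ClassSignature]) -> None:
    if not sigs:
        raise ValueError("no signatures given")
    for s in sigs:
        if s.n_bands != stack.n_bands:
            raise ValueError(
                f"signature for species {s.species_code} has {s.n_bands} bands, "
                f"stack has {stack.n_bands}"
            )


def _assemble(
    stack: RasterStack,
    flat_idx: np.ndarray,
    labels: np.ndarray,
    scores: np.ndarray,
    name: str,
    dataset_name: str,
    extra_invalid: np.ndarray | None = None,
) -> ClassificationResult:
    label_map = np.zeros(stack.shape, dtype=int)
    score_map = np.full(stack.shape, np.nan)
    if extra_invalid is not None:
        flat_idx = flat_idx[~extra_invalid]
        labels = labels[~extra_invalid]
        scores = scores[~extra_invalid]
    rr, cc = np.unravel_index(flat_idx, stack.shape)
    label_map[rr, cc] = labels
    score_map[rr, cc] = scores
    return ClassificationResult(label_map, score_map, name, dataset_name)


def _argbest(scores: np.ndarray, codes: np.ndarray, maximize: bool) -> tuple:
    """Column-wise best class; ties broken toward the lowest species code.

    ``scores`` is n_pixels x K with columns already in ascending-code order,
    and numpy's argmax/argmin return the first maximum, so the tie-break
    falls out of the column ordering.
    """
    best = np.argmax(scores, axis=1) if maximize else np.argmin(scores, axis=1)
    return codes[best], scores[np.arange(len(best)), best]


def _sorted_sigs(sigs: Sequence[ClassSignature]) -> list[ClassSignature]:
    return sorted(sigs, key=lambda s: s.species_code)


def classify_mlc(
    stack: RasterStack,
    sigs: Sequence[ClassSignature],
    priors: dict[int, float] | None = None,
    dataset_name: str = "",
) -> ClassificationResult:
    """Gaussian maximum-likelihood classification (equal priors by default)."""
    _check_dims(stack, sigs)
    sigs = _sorted_sigs(sigs)
    codes = np.array([s.species_code for s in sigs])
    x, flat_idx = stack.pixel_matrix()
    disc = np.empty((len(x), len(sigs)))
    for j, s in enumerate(sigs):
        p = 1.0 / len(sigs) if priors is None else priors[s.species_code]
        cov = _regularize(s.covariance)
        cf = cho_factor(cov)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        d = x - s.mean
        maha = np.einsum("ij,ij->i", d, cho_solve(cf, d.T).T)
        disc[:, j] = np.log(p) - 0.5 * logdet - 0.5 * maha
    labels, scores = _argbest(disc, codes, maximize=True)
    return _assemble(stack, flat_idx, labels, scores, "mlc", dataset_name)


def pooled_covariance(sigs: Sequence[ClassSignature]) -> np.ndarray:
    """Training-count-weighted average of the class covariances."""
    w = np.array([s.n for s in sigs], dtype=float)
    covs = np.stack([s.covariance for s in sigs])
    return np.einsum("k,kij->ij", w / w.sum(), covs)


def classify_md(
    stack: RasterStack,
    sigs: Sequence[ClassSignature],
    dataset_name: str = "",
) -> ClassificationResult:
    """Minimum Mahalanobis distance under the pooled class covariance."""
    _check_dims(stack, sigs)
    sigs = _sorted_sigs(sigs)
    codes = np.array([s.species_code for s in sigs])
    x, flat_idx = stack.pixel_matrix()
    cov = _regularize(pooled_covariance(sigs))
    cf = cho_factor(cov)
    dist = np.empty((len(x), len(sigs)))
    for j, s in enumerate(sigs):
        d = x - s.mean
        dist[:, j] = np.einsum("ij,ij->i", d, cho_solve(cf, d.T).T)
    labels, scores = _argbest(dist, codes, maximize=False)
    return _assemble(stack, flat_idx, labels, scores, "md", dataset_name)


def classify_sam(
    stack: RasterStack,
    sigs: Sequence[ClassSignature],
    dataset_name: str = "",
) -> ClassificationResult:
    """Smallest spectral angle between pixel and class-mean vectors.

    Pixels (or means) with zero norm cannot subtend an angle; such pixels
    are masked (label 0) in the output.
    """
    _check_dims(stack, sigs)
    sigs = _sorted_sigs(sigs)
    codes = np.array([s.species_code for s in sigs])
    x, flat_idx = stack.pixel_matrix()
    xnorm = np.linalg.norm(x, axis=1)
    bad = xnorm == 0
    angles = np.empty((len(x), len(sigs)))
    for j, s in enumerate(sigs):
        mnorm = np.linalg.norm(s.mean)
        if mnorm == 0:
            raise ValueError(f"zero-norm mean for species {s.species_code}")
        cosang = (x @ s.mean) / np.where(bad, 1.0, xnorm) / mnorm
        angles[:, j] = np.arccos(np.clip(cosang, -1.0, 1.0))
    labels, scores = _argbest(angles, codes, maximize=False)
    return _assemble(
        stack, flat_idx, labels, scores, "sam", dataset_name, extra_invalid=bad
    )


def _to_simplex(v: np.ndarray) -> np.ndarray:
    """Floor at eps then normalize rows to unit sum (probability spectra)."""
    v = np.maximum(v, _SID_EPS)
    return v / v.sum(axis=-1, keepdims=True)


def sid_divergence(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Symmetrized relative entropy between probability spectra (rowwise)."""
    return np.sum(p * np.log(p / q) + q * np.log(q / p), axis=-1)


def classify_sid(
    stack: RasterStack,
    sigs: Sequence[ClassSignature],
    dataset_name: str = "",
) -> ClassificationResult:
    """Minimum spectral information divergence to each class-mean spectrum.

    Spectra must be nonnegative; zeros are floored at 1e-12 before simplex
    normalization.  All-zero pixels are masked in the output.
    """
    _check_dims(stack, sigs)
    sigs = _sorted_sigs(sigs)
    codes = np.array([s.species_code for s in sigs])
    x, flat_idx = stack.pixel_matrix()
    if np.any(x < -1e-9):
        raise ValueError("SID requires nonnegative spectra")
    bad = x.sum(axis=1) <= 0
    px = _to_simplex(np.clip(x, 0.0, None))
    div = np.empty((len(x), len(sigs)))
    for j, s in enumerate(sigs):
        if np.all(s.mean <= 0):
            raise ValueError(f"all-zero mean for species {s.species_code}")
        q = _to_simplex(np.clip(s.mean, 0.0, None))
        div[:, j] = sid_divergence(px, q[None, :])
    labels, scores = _argbest(div, codes, maximize=False)
    return _assemble(
        stack, flat_idx, labels, scores, "sid", dataset_name, extra_invalid=bad
    )


PluginClassifier = Callable[[SampleSet, np.ndarray], np.ndarray]
"""Plug-in contract: ``plugin(training_samples, pixel_matrix) -> labels``.

``pixel_matrix`` is n_pixels x B (valid pixels only, row-major order);
the return value must be a length-n_pixels integer label array.
"""

NATIVE_METHODS = ("mlc", "md", "sam", "sid")


def classify(
    stack: RasterStack,
    sigs: Sequence[ClassSignature],
    method: str = "mlc",
    priors: dict[int, float] | None = None,
    plugin: PluginClassifier | None = None,
    training: SampleSet | None = None,
    dataset_name: str = "",
) -> ClassificationResult:
    """Dispatch to a native rule or an external plug-in classifier."""
    if method == "mlc":
        return classify_mlc(stack, sigs, priors=priors, dataset_name=dataset_name)
    if method == "md":
        return classify_md(stack, sigs, dataset_name=dataset_name)
    if method == "sam":
        return classify_sam(stack, sigs, dataset_name=dataset_name)
    if method == "sid":
        return classify_sid(stack, sigs, dataset_name=dataset_name)
    if method == "plugin":
        if plugin is None or training is None:
            raise ValueError("plugin method needs a callable and training samples")
        x, flat_idx = stack.pixel_matrix()
        labels = np.asarray(plugin(training, x))
        if labels.shape != (len(x),):
            raise ValueError(
                f"plugin returned {labels.shape}, expected ({len(x)},)"
            )
        return _assemble(
            stack, flat_idx, labels.astype(int), np.full(len(x), np.nan),
            "plugin", dataset_name,
        )
    raise ValueError(f"unknown method {method!r}; use one of "
                     f"{NATIVE_METHODS + ('plugin',)}")
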