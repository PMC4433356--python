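"""Gaussian class signatures and transformed-divergence separability.

Each species is summarized by the sample mean vector and sample covariance
of its training pixels over the feature bands (a multivariate-Gaussian
signature, the input of the maximum-likelihood classifier).  Pairwise
statistical separability of two signatures is measured by the divergence

    D = 1/2 tr[(S1 - S2)(S2^-1 - S1^-1)]
      + 1/2 tr[(S1^-1 + S2^-1)(m1 - m2)(m1 - m2)^T]

and reported on the familiar saturating 0-2000 scale as the transformed
divergence

    TD = 2000 * (1 - exp(-D / 8)).

TD = 2000 means fully separable signatures; by the conventional reading of
the scale, 1900 <= TD < 2000 is "good" separation and TD < 1900 "poor".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster_io import SampleSet

__all__ = [
    "ClassSignature",
    "TDMatrix",
    "train_signatures",
    "transformed_divergence",
    "td_matrix",
    "TD_GOOD",
    "TD_MAX",
]

TD_MAX = 2000.0
TD_GOOD = 1900.0


@dataclass
class ClassSignature:
    """Per-species Gaussian signature over B feature bands."""

    species_code: int
    mean: np.ndarray
    covariance: np.ndarray
    n: int
    name: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        b = self.mean.size
        if self.covariance.shape != (b, b):
            raise ValueError("covariance shape must match mean length")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @property
    def n_bands(self) -> int:
        return self.mean.size


def _regularize(cov: np.ndarray, lam: float = 1e-6) -> np.ndarray:
    """Add lam * (trace/B) * I when the covariance is ill-conditioned."""
    b = cov.shape[0]
    scale = np.trace(cov) / b
    if scale <= 0:
        scale = 1.0
    cond_bad = True
    try:
        cond_bad = np.linalg.cond(cov) > 1e10
    except np.linalg.LinAlgError:
        pass
    if cond_bad:
        cov = cov + lam * scale * np.eye(b)
        # degenerate point clouds can need more than one nudge
        while np.linalg.cond(cov) > 1e12:
            lam *= 10.0
            cov = cov + lam * scale * np.eye(b)
    return cov


def train_signatures(
    samples: SampleSet, species_table: Mapping[int, str] | None = None
) -> list[ClassSignature]:
    """Estimate one Gaussian signature per species present in the samples.

    Uses the sample mean and sample covariance (n-1 denominator).  Every
    species must contribute more pixels than there are feature bands;
    offenders are reported together in one error.
    """
    table = species_table or dict(samples.species_table)
    b = samples.n_bands
    counts = samples.counts()
    thin = sorted(c for c, n in counts.items() if n <= b)
    if thin:
        raise ValueError(
            f"species {thin} have <= {b} training pixels; cannot estimate "
            f"a {b}x{b} covariance"
        )
    sigs = []
    for code in sorted(counts):
        x = samples.for_species(code)
        cov = np.cov(x, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        sigs.append(
            ClassSignature(
                species_code=code,
                mean=x.mean(axis=0),
                covariance=_regularize(cov),
                n=len(x),
                name=str(table.get(code, code)),
            )
        )
    return sigs


def transformed_divergence(s1: ClassSignature, s2: ClassSignature) -> float:
    """Transformed divergence of two Gaussian signatures, on [0, 2000]."""
    if s1.n_bands != s2.n_bands:
        raise ValueError("signatures have different dimensionality")
    c1 = _regularize(s1.covariance)
    c2 = _regularize(s2.covariance)
    i1 = np.linalg.inv(c1)
    i2 = np.linalg.inv(c2)
    dm = (s1.mean - s2.mean)[:, None]
    d = 0.5 * np.trace((c1 - c2) @ (i2 - i1)) + 0.5 * np.trace(
        (i1 + i2) @ (dm @ dm.T)
    )
    return float(TD_MAX * (1.0 - np.exp(-d / 8.0)))


@dataclass
class TDMatrix:
    """Pairwise transformed-divergence separability of K signatures."""

    codes: Sequence[int]
    td: np.ndarray
    names: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.codes = list(self.codes)
        self.td = np.asarray(self.td, dtype=float)
        k = len(self.codes)
        if self.td.shape != (k, k):
            raise ValueError("td must be K x K")
        if not self.names:
            self.names = [str(c) for c in self.codes]

    def pair(self, code_a: int, code_b: int) -> float:
        i, j = self.codes.index(code_a), self.codes.index(code_b)
        return float(self.td[i, j])

    def classify_pairs(self) -> pd.DataFrame:
        """All unordered pairs with their separability class.

        separable: TD = 2000 to integer rounding; good: 1900 <= TD < 2000;
        poor: TD < 1900.
        """
        rows = []
        k = len(self.codes)
        for i in range(k):
            for j in range(i + 1, k):
                td = self.td[i, j]
                if round(td) >= TD_MAX:
                    cls = "separable"
                elif td >= TD_GOOD:
                    cls = "good"
                else:
                    cls = "poor"
                rows.append(
                    {
                        "species_a": self.names[i],
                        "species_b": self.names[j],
                        "td": td,
                        "separability": cls,
                    }
                )
        return pd.DataFrame(rows)

    def to_dataframe(self) -> pd.DataFrame:
        """Square TD table rounded to integers, species abbreviations as axes."""
        return pd.DataFrame(
            np.round(self.td).astype(int), index=self.names, columns=self.names
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def td_matrix(sigs: Sequence[ClassSignature]) -> TDMatrix:
    """Fill the symmetric K x K transformed-divergence matrix."""
    if len(sigs) < 2:
        raise ValueError("need at least two signatures")
    k = len(sigs)
    td = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            td[i, j] = td[j, i] = transformed_divergence(sigs[i], sigs[j])
    return TDMatrix(
        codes=[s.species_code for s in sigs],
        td=td,
        names=[s.name or str(s.species_code) for s in sigs],
    )
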