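"""Error-matrix accuracy assessment: overall and conditional kappa.

The error matrix counts predicted-versus-reference pixels with rows =
predicted (map) class and columns = reference class.  From it:

* overall accuracy  p_o = trace / n;
* overall kappa (OKC)  kappa = (p_o - p_e) / (1 - p_e) with chance
  agreement  p_e = sum_i row_i * col_i / n^2;
* the user's-accuracy-based conditional kappa of species i (SCKC)

      kappa_i = (n*n_ii - n_i+*n_+i) / (n*n_i+ - n_i+*n_+i)

  where n_i+ and n_+i are the predicted-row and reference-column totals.

Classification uncertainty is the plain difference between a
training-sample OKC and an independent test-sample OKC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationResult
from .raster_io import LabelRaster

__all__ = [
    "ErrorMatrix",
    "AccuracyReport",
    "error_matrix",
    "overall_kappa",
    "overall_accuracy",
    "conditional_kappa_user",
    "accuracy_report",
]


@dataclass
class ErrorMatrix:
    """K x K predicted-vs-reference counts (rows = predicted)."""

    codes: Sequence[int]
    counts: np.ndarray
    names: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.codes = list(self.codes)
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.codes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not self.names:
            self.names = [str(c) for c in self.codes]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.names, columns=self.names)


def error_matrix(
    predicted: ClassificationResult | np.ndarray,
    reference: LabelRaster,
    codes: Sequence[int] | None = None,
) -> ErrorMatrix:
    """Tally predicted vs reference labels over reference-labeled pixels.

    Only pixels that carry a reference label *and* received a prediction
    (label > 0, i.e. not masked) are counted.  ``codes`` fixes the species
    axis so K stays stable across reports even when a species is absent
    from one map; by default it is the union of codes seen on either side.
    """
    pred = (
        predicted.label_map
        if isinstance(predicted, ClassificationResult)
        else np.asarray(predicted, dtype=int)
    )
    ref = reference.labels
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: predicted {pred.shape}, "
                         f"reference {ref.shape}")
    use = (ref > 0) & (pred > 0)
    if not use.any():
        raise ValueError("no countable pixels (no overlap of prediction "
                         "and reference labels)")
    if codes is None:
        codes = sorted(set(np.unique(ref[use])) | set(np.unique(pred[use])))
    codes = list(codes)
    k = len(codes)
    lookup = np.full(max(codes) + 1, -1, dtype=int)
    lookup[np.array(codes)] = np.arange(k)
    pv = lookup[pred[use]]
    rv = lookup[ref[use]]
    if np.any(pv < 0) or np.any(rv < 0):
        raise ValueError("labels outside the provided species codes")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (pv, rv), 1)
    names = [str(reference.species_table.get(c, c)) for c in codes]
    return ErrorMatrix(codes, counts, names)


def overall_accuracy(m: ErrorMatrix) -> float:
    if m.n == 0:
        raise ValueError("empty error matrix")
    return float(np.trace(m.counts) / m.n)


def overall_kappa(m: ErrorMatrix) -> float:
    """Chance-corrected overall agreement (OKC)."""
    n = m.n
    if n == 0:
        raise ValueError("empty error matrix")
    p_o = np.trace(m.counts) / n
    row = m.counts.sum(axis=1)
    col = m.counts.sum(axis=0)
    p_e = float(row @ col) / n**2
    if p_e >= 1.0:
        warnings.warn("degenerate error matrix (p_e = 1); kappa defined as 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def conditional_kappa_user(m: ErrorMatrix, code: int) -> float:
    """User's-accuracy-based conditional kappa of one species (SCKC).

    Undefined (NaN) when the species was never predicted (zero row total).
    """
    i = list(m.codes).index(code)
    n = m.n
    n_ii = m.counts[i, i]
    n_ip = m.counts[i, :].sum()  # predicted-row total
    n_pi = m.counts[:, i].sum()  # reference-column total
    if n_ip == 0:
        return float("nan")
    denom = n * n_ip - n_ip * n_pi
    if denom == 0:
        warnings.warn(f"conditional kappa undefined for species {code} "
                      "(chance denominator 0)")
        return float("nan")
    return float((n * n_ii - n_ip * n_pi) / denom)


@dataclass
class AccuracyReport:
    """OKC + per-species SCKC, tagged with classifier/dataset/sample role."""

    okc: float
    overall_accuracy: float
    sckc: dict[int, float]
    matrix: ErrorMatrix
    classifier_name: str = ""
    dataset_name: str = ""
    role: str = "training"
    species_names: dict[int, str] = field(default_factory=dict)

    def hca_species(self, threshold: float = 0.95) -> list[int]:
        """Hard-to-classify-accurately species: SCKC below the threshold."""
        return [c for c, v in self.sckc.items()
                if not np.isnan(v) and v < threshold]

    def to_dataframe(self) -> pd.DataFrame:
        """One row per species plus a summary row (OKC / overall accuracy)."""
        rows = [
            {
                "species": self.species_names.get(c, str(c)),
                "code": c,
                "sckc": v,
            }
            for c, v in self.sckc.items()
        ]
        rows.append(
            {"species": "OVERALL", "code": 0, "sckc": np.nan}
        )
        df = pd.DataFrame(rows)
        df["okc"] = self.okc
        df["overall_accuracy"] = self.overall_accuracy
        df["classifier"] = self.classifier_name
        df["dataset"] = self.dataset_name
        df["role"] = self.role
        return df


def accuracy_report(
    predicted: ClassificationResult,
    reference: LabelRaster,
    codes: Sequence[int] | None = None,
    classifier_name: str | None = None,
    dataset_name: str | None = None,
) -> AccuracyReport:
    """Assemble OKC, overall accuracy and the full SCKC vector."""
    m = error_matrix(predicted, reference, codes=codes)
    sckc = {c: conditional_kappa_user(m, c) for c in m.codes}
    return AccuracyReport(
        okc=overall_kappa(m),
        overall_accuracy=overall_accuracy(m),
        sckc=sckc,
        matrix=m,
        classifier_name=classifier_name or predicted.classifier_name,
        dataset_name=dataset_name or predicted.dataset_name,
        role=reference.role,
        species_names={c: str(reference.species_table.get(c, c)) for c in m.codes},
    )
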