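"""Model/Results front end for the Gaussian-signature classifier.

:class:`SignatureModel` is built from labeled training data (a
:class:`~spectex.raster_io.SampleSet`, or a raster + label pair via
:meth:`SignatureModel.from_rasters`); :meth:`SignatureModel.fit` estimates
the per-species Gaussian signatures and returns a
:class:`SignatureModelResults` carrying the estimates, their pairwise
transformed-divergence separability, classification methods for the four
native decision rules, accuracy evaluation against reference labels, and
a ``summary()`` table.

    >>> model = SignatureModel.from_rasters(stack, train_labels)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> report = res.evaluate(stack, test_labels, method="mlc")
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .accuracy import AccuracyReport, accuracy_report
from .classify import ClassificationResult, classify
from .raster_io import LabelRaster, RasterStack, SampleSet, extract_samples
from .signatures import ClassSignature, TDMatrix, td_matrix, train_signatures

__all__ = ["SignatureModel", "SignatureModelResults"]


class SignatureModel:
    """Supervised multivariate-Gaussian signature model of K species."""

    def __init__(self, samples: SampleSet):
        if len(samples.codes) == 0:
            raise ValueError("empty sample set")
        self.samples = samples

    @classmethod
    def from_rasters(cls, stack: RasterStack, labels: LabelRaster) -> "SignatureModel":
        return cls(extract_samples(stack, labels))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "species",
        feature_cols: Sequence[str] | None = None,
    ) -> "SignatureModel":
        """Build from a tidy frame: one row per pixel, one label column."""
        feats = feature_cols or [c for c in df.columns if c != label_col]
        return cls(
            SampleSet(
                codes=df[label_col].to_numpy(),
                features=df[feats].to_numpy(dtype=float),
                band_names=list(feats),
            )
        )

    def fit(self) -> "SignatureModelResults":
        sigs = train_signatures(self.samples)
        return SignatureModelResults(model=self, signatures=sigs)


@dataclass
class SignatureModelResults:
    """Fitted signatures plus diagnostics and downstream operations."""

    model: SignatureModel
    signatures: list[ClassSignature]
    _td: TDMatrix | None = field(default=None, repr=False)

    @property
    def codes(self) -> list[int]:
        return [s.species_code for s in self.signatures]

    def td_matrix(self) -> TDMatrix:
        """Pairwise transformed-divergence separability (cached)."""
        if self._td is None:
            if len(self.signatures) < 2:
                raise ValueError("separability needs >= 2 species")
            self._td = td_matrix(self.signatures)
        return self._td

    def classify(
        self, stack: RasterStack, method: str = "mlc", **kw
    ) -> ClassificationResult:
        return classify(
            stack, self.signatures, method=method,
            training=self.model.samples, **kw,
        )

    def evaluate(
        self, stack: RasterStack, reference: LabelRaster, method: str = "mlc",
        **kw,
    ) -> AccuracyReport:
        """Classify and score against reference labels in one step."""
        result = self.classify(stack, method=method, **kw)
        return accuracy_report(result, reference, codes=self.codes)

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.signatures:
            row = {"code": s.species_code, "species": s.name, "n": s.n}
            for b, name in enumerate(self.model.samples.band_names):
                row[f"mean_{name}"] = s.mean[b]
                row[f"sd_{name}"] = np.sqrt(s.covariance[b, b])
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable account of the fit: signatures and separability."""
        lines = [
            "Gaussian signature model",
            "=" * 24,
            f"species: {len(self.signatures)}   "
            f"bands: {self.model.samples.n_bands}   "
            f"training pixels: {len(self.model.samples.codes)}",
            "",
            self.params_frame().to_string(index=False, float_format="%.4f"),
        ]
        if len(self.signatures) >= 2:
            pairs = self.td_matrix().classify_pairs()
            counts = pairs["separability"].value_counts()
            lines += [
                "",
                "Transformed-divergence separability (0-2000):",
                f"  separable (TD=2000): {counts.get('separable', 0)}",
                f"  good (1900<=TD<2000): {counts.get('good', 0)}",
                f"  poor (TD<1900): {counts.get('poor', 0)}",
                f"  worst pair: "
                + "-".join(
                    pairs.loc[pairs['td'].idxmin(), ['species_a', 'species_b']]
                )
                + f" (TD={pairs['td'].min():.0f})",
            ]
        return "\n".join(lines)

    def plot_td_matrix(self, ax=None):
        """Heatmap of the pairwise transformed-divergence matrix."""
        import matplotlib.pyplot as plt

        tdm = self.td_matrix()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(tdm.td, vmin=0, vmax=2000, cmap="viridis")
        ax.set_xticks(range(len(tdm.names)), tdm.names, rotation=90, fontsize=7)
        ax.set_yticks(range(len(tdm.names)), tdm.names, fontsize=7)
        ax.figure.colorbar(im, ax=ax, label="transformed divergence")
        ax.set_title("Pairwise signature separability")
        return ax
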