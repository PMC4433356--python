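"""Multi-band raster containers and I/O.

The carrier type for every per-pixel operation in the package is
:class:`RasterStack`: a named, masked ``rows x cols x bands`` grid of real
values (digital numbers, radiance, reflectance or index values).  Labeled
reference samples travel as :class:`LabelRaster` (integer species codes on
the same grid) and are flattened to per-pixel feature vectors by
:func:`extract_samples`.

Rasters are stored as plain multi-band TIFF (band-interleaved, float or
integer) with a small JSON sidecar carrying band names, pixel size and the
nodata sentinel.  Geo-referencing (projections, transforms) is deliberately
out of scope; pixel coordinates are 0-based, row-major ``(row, col)`` with
the band axis last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "RasterStack",
    "LabelRaster",
    "SampleSet",
    "read_raster",
    "write_raster",
    "read_labels",
    "write_labels",
    "extract_samples",
    "rasterize_regions",
    "read_species_table",
]

_NODATA = -9999.0


@dataclass
class RasterStack:
    """A named multi-band grid with a nodata mask.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Pixel values.  Units depend on processing stage (DN counts,
        radiance in W m-2 um-1 sr-1, dimensionless reflectance, or index
        values).
    band_names : sequence of str
        One unique name per band, in band order.
    nodata_mask : ndarray of bool, shape (rows, cols), optional
        True where the pixel is invalid.  Nodata propagates: any derived
        layer is masked wherever its inputs are.
    pixel_size : float
        Ground size of a (square) pixel in meters.
    """

    data: np.ndarray
    band_names: Sequence[str]
    nodata_mask: np.ndarray | None = None
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3 or self.data.shape[2] == 0:
            raise ValueError("data must be rows x cols x bands with >= 1 band")
        self.band_names = list(self.band_names)
        if len(self.band_names) != self.data.shape[2]:
            raise ValueError(
                f"{len(self.band_names)} band names for {self.data.shape[2]} bands"
            )
        if len(set(self.band_names)) != len(self.band_names):
            raise ValueError("band names must be unique")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.data.shape[:2], dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.data.shape[:2]:
                raise ValueError("nodata_mask shape must match band shape")

    # -- basic introspection -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, name: str) -> np.ndarray:
        """Return one band as a 2-D view, by name."""
        try:
            idx = self.band_names.index(name)
        except ValueError:
            raise KeyError(
                f"band {name!r} not in stack (have {self.band_names})"
            ) from None
        return self.data[:, :, idx]

    def has_bands(self, names: Sequence[str]) -> bool:
        return all(n in self.band_names for n in names)

    def with_data(
        self,
        data: np.ndarray,
        band_names: Sequence[str] | None = None,
        extra_mask: np.ndarray | None = None,
    ) -> "RasterStack":
        """New stack on the same grid; nodata is the union with ``extra_mask``."""
        mask = self.nodata_mask.copy()
        if extra_mask is not None:
            mask |= extra_mask
        return RasterStack(
            data, band_names or self.band_names, mask, self.pixel_size
        )

    def concat(self, *others: "RasterStack") -> "RasterStack":
        """Stack bands of several rasters on one grid (mask union)."""
        stacks = (self, *others)
        for s in stacks[1:]:
            if s.shape != self.shape:
                raise ValueError("cannot concat stacks of different shapes")
        data = np.concatenate([s.data for s in stacks], axis=2)
        names = [n for s in stacks for n in s.band_names]
        mask = np.logical_or.reduce([s.nodata_mask for s in stacks])
        return RasterStack(data, names, mask, self.pixel_size)

    def pixel_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (valid-pixel feature matrix, flat index of valid pixels)."""
        valid = ~self.nodata_mask.ravel()
        flat = self.data.reshape(-1, self.n_bands)
        return flat[valid], np.flatnonzero(valid)


@dataclass
class LabelRaster:
    """Integer species codes on a raster grid; 0 = unlabeled/background."""

    labels: np.ndarray
    role: str = "training"
    species_table: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        present = set(np.unique(self.labels)) - {0}
        if self.species_table:
            missing = present - set(self.species_table)
            if missing:
                raise ValueError(f"codes {sorted(missing)} missing from species_table")
        else:
            self.species_table = {c: str(c) for c in sorted(present)}

    @property
    def codes(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})

    def counts(self) -> dict[int, int]:
        codes, n = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(codes.tolist(), n.tolist()))


@dataclass
class SampleSet:
    """Per-pixel feature vectors of labeled reference samples.

    ``codes[i]`` is the species code of row ``i`` of ``features``.
    Row order is the deterministic row-major scan of the label grid.
    """

    codes: np.ndarray
    features: np.ndarray
    band_names: Sequence[str]
    role: str = "training"
    species_table: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or len(self.codes) != len(self.features):
            raise ValueError("features must be n_samples x n_bands, aligned to codes")

    @property
    def n_bands(self) -> int:
        return self.features.shape[1]

    def counts(self) -> dict[int, int]:
        codes, n = np.unique(self.codes, return_counts=True)
        return dict(zip(codes.tolist(), n.tolist()))

    def for_species(self, code: int) -> np.ndarray:
        return self.features[self.codes == code]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(path: str | Path, stack: RasterStack) -> None:
    """Write a stack as band-interleaved multi-band TIFF + JSON sidecar.

    Nodata pixels are stored as the sentinel value -9999 and restored to a
    mask on read.
    """
    path = Path(path)
    data = stack.data.astype(np.float32).copy()
    data[stack.nodata_mask] = _NODATA
    tifffile.imwrite(path, np.moveaxis(data, 2, 0))  # bands first on disk
    meta = {
        "band_names": list(stack.band_names),
        "pixel_size": stack.pixel_size,
        "nodata": _NODATA,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_raster(path: str | Path) -> RasterStack:
    """Read a multi-band TIFF written by :func:`write_raster`.

    Files without a sidecar get bands named ``band_1 .. band_B`` and pixel
    size 1.0; any pixel equal to the nodata sentinel in *any* band is masked.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path).astype(float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    data = np.moveaxis(arr, 0, 2)
    names = [f"band_{i + 1}" for i in range(data.shape[2])]
    pixel_size, nodata = 1.0, _NODATA
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        names = meta.get("band_names", names)
        pixel_size = meta.get("pixel_size", 1.0)
        nodata = meta.get("nodata", _NODATA)
    mask = np.any(data == nodata, axis=2)
    data = data.copy()
    data[mask] = 0.0
    return RasterStack(data, names, mask, pixel_size)


def write_labels(path: str | Path, labels: LabelRaster) -> None:
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.int32))
    meta = {
        "role": labels.role,
        "species_table": {str(k): v for k, v in labels.species_table.items()},
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_labels(path: str | Path) -> LabelRaster:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path).astype(int)
    role, table = "training", {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        role = meta.get("role", "training")
        table = {int(k): v for k, v in meta.get("species_table", {}).items()}
    return LabelRaster(arr, role=role, species_table=table)


def read_species_table(path: str | Path) -> dict[int, str]:
    """Read a species table CSV with columns ``code,abbrev[,name]``."""
    df = pd.read_csv(path)
    return dict(zip(df["code"].astype(int), df["abbrev"].astype(str)))


# ---------------------------------------------------------------------------
# Sample extraction and simple region rasterization
# ---------------------------------------------------------------------------

def extract_samples(stack: RasterStack, labels: LabelRaster) -> SampleSet:
    """Extract one feature-vector record per labeled, non-nodata pixel.

    Pixels are scanned in row-major order so the record order is
    deterministic.  Labeled pixels under the nodata mask are excluded.
    """
    if labels.labels.shape != stack.shape:
        raise ValueError(
            f"label shape {labels.labels.shape} != stack shape {stack.shape}"
        )
    usable = (labels.labels > 0) & ~stack.nodata_mask
    if not usable.any():
        raise ValueError("no usable labeled pixels (all unlabeled or nodata)")
    rows, cols = np.nonzero(usable)  # np.nonzero scans row-major
    return SampleSet(
        codes=labels.labels[rows, cols],
        features=stack.data[rows, cols, :],
        band_names=stack.band_names,
        role=labels.role,
        species_table=dict(labels.species_table),
    )


def rasterize_regions(
    shape: tuple[int, int],
    regions: Sequence[tuple],
    species_table: Mapping[int, str] | None = None,
    role: str = "training",
) -> LabelRaster:
    """Burn simple labeled regions into a code raster.

    Each region is ``("rect", code, row0, col0, row1, col1)`` (half-open
    bounds) or ``("disc", code, row_center, col_center, radius)``.  A pixel
    gets a region's code when its center lies inside; later regions
    overwrite earlier ones.  This is deliberately minimal — enough to
    emulate crown polygons without vector-GIS machinery.
    """
    out = np.zeros(shape, dtype=int)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for region in regions:
        kind, code = region[0], int(region[1])
        if kind == "rect":
            _, _, r0, c0, r1, c1 = region
            out[max(r0, 0) : r1, max(c0, 0) : c1] = code
        elif kind == "disc":
            _, _, r, c, rad = region
            out[(rr - r) ** 2 + (cc - c) ** 2 <= rad**2] = code
        else:
            raise ValueError(f"unknown region kind {kind!r}")
    return LabelRaster(out, role=role, species_table=species_table or {})
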