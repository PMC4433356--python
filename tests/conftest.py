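import numpy as np
import pytest

from spectex import LabelRaster, RasterStack, SceneConfig, generate_scene

BANDS = ("blue", "green", "red", "nir")


@pytest.fixture(scope="session")
def small_scene_cfg():
    """A light scene for plumbing tests (not the benchmark conditions)."""
    return SceneConfig(
        n_species=4,
        rows=24,
        cols=24,
        crowns_per_species=3,
        crown_radius=(5, 7),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scene(small_scene_cfg):
    return generate_scene(small_scene_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def refl_stack(rng):
    """Random 4-band reflectance stack on a 12x12 grid."""
    data = rng.uniform(0.02, 0.8, size=(12, 12, 4))
    return RasterStack(data, BANDS, pixel_size=0.6)


def make_stack(values, band_names=BANDS, mask=None):
    """Stack from a dict {band: scalar-or-grid} broadcast to 4x4."""
    grids = []
    for name in band_names:
        v = np.asarray(values[name], dtype=float)
        grids.append(np.broadcast_to(v, (4, 4)).copy())
    return RasterStack(np.stack(grids, axis=2), band_names, nodata_mask=mask)


@pytest.fixture()
def labels_3x3():
    return LabelRaster(
        np.array([[1, 1, 0], [2, 2, 2], [0, 3, 3]]),
        species_table={1: "a", 2: "b", 3: "c"},
    )
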