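"""spectex: spectral-spatial texture classification of tree species.

A reusable implementation of a supervised multispectral classification
pipeline for mapping many tree species in high-resolution canopy imagery:
radiometric calibration, principal-component pansharpening, vegetation
indices, Lee-sigma texture, Gaussian-signature classifiers (MLC / MD /
SAM / SID), transformed-divergence separability, kappa-based accuracy
assessment, and an accuracy-improvement-efficiency factorial analysis —
exercisable end to end on seeded synthetic canopy scenes.
"""

from importlib import resources as _resources

import pandas as _pd

from .raster_io import (
    RasterStack, LabelRaster, SampleSet,
    read_raster, write_raster, read_labels, write_labels,
    extract_samples, rasterize_regions,
)
from .radiometry import (
    BandCalibration, CalibrationTable, ReflectanceParams,
    QUICKBIRD_CALIBRATION, QUICKBIRD_ESUN,
    dn_to_radiance, radiance_to_reflectance,
)
from .pansharpen import FusionTransform, pct_fuse, upsample
from .vegindex import VIParams, ndvi, savi, arvi, vari, evi, build_hms5vi
from .texture import LeeSigmaParams, lee_sigma_band, build_spectex
from .signatures import (
    ClassSignature, TDMatrix, train_signatures, transformed_divergence,
    td_matrix,
)
from .classify import (
    ClassificationResult, classify, classify_mlc, classify_md,
    classify_sam, classify_sid,
)
from .accuracy import (
    ErrorMatrix, AccuracyReport, error_matrix, overall_kappa,
    overall_accuracy, conditional_kappa_user, accuracy_report,
)
from .aie_stats import (
    aie, AIETable, build_aie_table, AnovaResult, two_way_anova,
    DuncanGrouping, duncan_groups, duncan_from_anova,
)
from .synthetic_scene import (
    SceneConfig, SceneBundle, generate_scene, stratified_sample,
    split_labels_by_crown,
)
from .pipeline import (
    SchemeSpec, SCHEMES, build_dataset, ExperimentResult, run_experiment,
    run_synthetic_benchmark,
)
from .model import SignatureModel, SignatureModelResults

__version__ = "0.1.0"


def species_reference() -> _pd.DataFrame:
    """The default 40-species subtropical overstorey inventory.

    Columns: code, abbrev, name, family, training_n, test_n — the
    per-species reference-pixel counts used as the template for
    emulated study-site scenes.
    """
    with _resources.files("spectex.data").joinpath(
        "species_reference.csv"
    ).open() as fh:
        return _pd.read_csv(fh)
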