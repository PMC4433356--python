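"""End-to-end orchestration of the four classification schemes.

From one pansharpened 4-band reflectance stack (HMS), four datasets are
derived and compared:

====== ========== ===== =========================================
scheme dataset    bands recipe
====== ========== ===== =========================================
1      HMS          4   the pansharpened reflectance stack itself
2      HMS5VI       5   vegetation-index layers of the HMS
3      SpecTex      4   Lee-sigma texture transform of each band
4      HMS13B      13   HMS + HMS5VI + SpecTex, stacked in order
====== ========== ===== =========================================

:func:`run_experiment` trains Gaussian signatures per scheme, classifies
with each requested rule, scores training and test accuracy reports,
assembles the AIE table and runs the factorial ANOVA with Duncan
groupings.  Failures are isolated per classifier x scheme combination.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .accuracy import AccuracyReport, accuracy_report
from .aie_stats import (
    AIETable,
    AnovaResult,
    DuncanGrouping,
    build_aie_table,
    duncan_from_anova,
    two_way_anova,
)
from .classify import NATIVE_METHODS, classify
from .pansharpen import pct_fuse
from .raster_io import LabelRaster, RasterStack, extract_samples
from .signatures import TDMatrix, td_matrix, train_signatures
from .synthetic_scene import SceneBundle, SceneConfig, generate_scene, \
    split_labels_by_crown, stratified_sample, thin_labels
from .texture import LeeSigmaParams, build_spectex
from .vegindex import VIParams, build_hms5vi

logger = logging.getLogger("spectex")

__all__ = [
    "SchemeSpec",
    "SCHEMES",
    "build_dataset",
    "ExperimentResult",
    "run_experiment",
    "run_synthetic_benchmark",
]


@dataclass(frozen=True)
class SchemeSpec:
    scheme_id: int
    dataset_name: str
    n_bands: int


SCHEMES: dict[int, SchemeSpec] = {
    1: SchemeSpec(1, "HMS", 4),
    2: SchemeSpec(2, "HMS5VI", 5),
    3: SchemeSpec(3, "SpecTex", 4),
    4: SchemeSpec(4, "HMS13B", 13),
}


def build_dataset(
    scheme: SchemeSpec | int,
    hms: RasterStack,
    vi_params: VIParams = VIParams(),
    lee_params: LeeSigmaParams = LeeSigmaParams(),
) -> RasterStack:
    """Derive one scheme's feature stack from the 4-band HMS."""
    if isinstance(scheme, int):
        scheme = SCHEMES[scheme]
    if hms.n_bands != 4:
        raise ValueError(f"HMS must have 4 bands, got {hms.n_bands}")
    if scheme.scheme_id == 1:
        out = hms
    elif scheme.scheme_id == 2:
        out = build_hms5vi(hms, vi_params)
    elif scheme.scheme_id == 3:
        out = build_spectex(hms, lee_params)
    elif scheme.scheme_id == 4:
        out = hms.concat(build_hms5vi(hms, vi_params), build_spectex(hms, lee_params))
    else:
        raise ValueError(f"unknown scheme {scheme.scheme_id}")
    assert out.n_bands == scheme.n_bands
    return out


@dataclass
class ExperimentResult:
    """All artifacts of one classifier x scheme comparison run."""

    reports: list[AccuracyReport]
    td_matrices: dict[str, TDMatrix]
    aie_table: AIETable | None
    anova: AnovaResult | None
    duncan: dict[str, DuncanGrouping]
    manifest: dict
    failures: dict[str, str] = field(default_factory=dict)

    def report(self, dataset: str, classifier: str, role: str) -> AccuracyReport:
        for r in self.reports:
            if (
                r.dataset_name == dataset
                and r.classifier_name == classifier
                and r.role == role
            ):
                return r
        raise KeyError(f"no report for {classifier}/{dataset}/{role}")

    def okc_table(self) -> pd.DataFrame:
        """OKC of every combination, wide on role (plus uncertainty)."""
        df = pd.DataFrame(
            [
                {
                    "classifier": r.classifier_name,
                    "dataset": r.dataset_name,
                    "role": r.role,
                    "okc": r.okc,
                    "overall_accuracy": r.overall_accuracy,
                }
                for r in self.reports
            ]
        )
        wide = df.pivot_table(
            index=["classifier", "dataset"], columns="role", values="okc"
        ).reset_index()
        if {"training", "test"} <= set(wide.columns):
            wide["uncertainty"] = wide["training"] - wide["test"]
        return wide

    def summary(self) -> str:
        lines = ["Classification experiment summary", "=" * 34]
        lines.append(self.okc_table().to_string(index=False,
                                                float_format="%.4f"))
        if self.anova is not None:
            lines.append("")
            lines.append("Two-way factorial ANOVA of AIE "
                         f"(alpha={self.anova.alpha:g})")
            lines.append(self.anova.to_dataframe().to_string(
                float_format="%.4f"))
        for factor, grouping in self.duncan.items():
            lines.append("")
            lines.append(f"Duncan grouping of mean AIE by {factor}")
            lines.append(grouping.to_dataframe().to_string(
                index=False, float_format="%.4f"))
        if self.failures:
            lines.append("")
            lines.append("Failed combinations: " + ", ".join(
                f"{k} ({v})" for k, v in self.failures.items()))
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.okc_table().to_csv(out / "okc_table.csv", index=False)
        for name, tdm in self.td_matrices.items():
            tdm.to_csv(out / f"td_{name}.csv")
        if self.aie_table is not None:
            self.aie_table.table.to_csv(out / "aie_table.csv", index=False)
        if self.anova is not None:
            self.anova.to_dataframe().to_csv(out / "anova.csv")
        for factor, grouping in self.duncan.items():
            grouping.to_dataframe().to_csv(
                out / f"duncan_{factor}.csv", index=False
            )
        pd.concat([r.to_dataframe() for r in self.reports]).to_csv(
            out / "sckc_reports.csv", index=False
        )
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _manifest(config: dict) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "config": config,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
    }


def run_experiment(
    hms: RasterStack,
    train_labels: LabelRaster,
    test_labels: LabelRaster,
    classifiers: Sequence[str] = NATIVE_METHODS,
    schemes: Sequence[int] = (1, 2, 3, 4),
    vi_params: VIParams = VIParams(),
    lee_params: LeeSigmaParams = LeeSigmaParams(),
    with_stats: bool = True,
    manifest_extra: dict | None = None,
) -> ExperimentResult:
    """Train, classify and score every classifier x scheme combination.

    One failing combination is recorded in ``failures`` and does not abort
    the run.  The AIE/ANOVA stage needs baseline-dataset (HMS) reports and
    both sample roles; it is skipped (with a log message) when they are
    unavailable.
    """
    reports: list[AccuracyReport] = []
    td_matrices: dict[str, TDMatrix] = {}
    failures: dict[str, str] = {}
    all_codes = sorted(set(train_labels.codes) | set(test_labels.codes))

    for scheme_id in schemes:
        spec = SCHEMES[scheme_id]
        t0 = time.perf_counter()
        try:
            data = build_dataset(spec, hms, vi_params, lee_params)
            samples = extract_samples(data, train_labels)
            sigs = train_signatures(samples)
            if len(sigs) >= 2:
                td_matrices[spec.dataset_name] = td_matrix(sigs)
        except Exception as exc:  # noqa: BLE001 - per-combination isolation
            failures[spec.dataset_name] = str(exc)
            logger.warning("scheme %s failed outright: %s", spec.dataset_name, exc)
            continue
        logger.info(
            "scheme %s: %d bands, trained %d signatures in %.2fs",
            spec.dataset_name, data.n_bands, len(sigs), time.perf_counter() - t0,
        )
        for method in classifiers:
            key = f"{method}/{spec.dataset_name}"
            t1 = time.perf_counter()
            try:
                result = classify(
                    data, sigs, method=method, dataset_name=spec.dataset_name
                )
                reports.append(
                    accuracy_report(result, train_labels, codes=all_codes)
                )
                reports.append(
                    accuracy_report(result, test_labels, codes=all_codes)
                )
            except Exception as exc:  # noqa: BLE001
                failures[key] = str(exc)
                logger.warning("combination %s failed: %s", key, exc)
                continue
            logger.info("  %s: %.2fs", key, time.perf_counter() - t1)

    aie_table = anova = None
    duncan: dict[str, DuncanGrouping] = {}
    if with_stats:
        try:
            aie_table = build_aie_table(reports)
            anova = two_way_anova(aie_table)
            duncan = {
                f: duncan_from_anova(aie_table, anova, f)
                for f in ("dataset", "classifier")
            }
        except Exception as exc:  # noqa: BLE001
            logger.warning("AIE/ANOVA stage skipped: %s", exc)

    manifest = _manifest(
        {
            "classifiers": list(classifiers),
            "schemes": list(schemes),
            **(manifest_extra or {}),
        }
    )
    return ExperimentResult(
        reports, td_matrices, aie_table, anova, duncan, manifest, failures
    )


def run_synthetic_benchmark(
    cfg: SceneConfig | None = None,
    classifiers: Sequence[str] = ("mlc",),
    schemes: Sequence[int] = (1, 2, 3, 4),
    split: str = "crown",
    train_fraction: float = 0.5,
    train_px_per_species: int | None = 110,
    seed: int | None = None,
    with_stats: bool = False,
) -> tuple[ExperimentResult, SceneBundle]:
    """Generate a scene, pansharpen it, and run the full comparison.

    ``split='crown'`` keeps whole crowns on one side (distinct individual
    trees in training vs test, the study-design reading); ``split='pixel'``
    draws a species-stratified random pixel split instead.  Training
    labels are then thinned to ``train_px_per_species`` pixels per species
    (None keeps all), matching the limited per-species reference sampling
    of a field campaign; test pixels are kept in full.
    """
    cfg = cfg or SceneConfig()
    if seed is not None:
        cfg = cfg.with_(seed=seed)
    scene = generate_scene(cfg)
    hms = pct_fuse(scene.ms, scene.pan)
    hms = hms.with_data(np.clip(hms.data, 0.0, 1.0))
    if split == "crown":
        train_labels, test_labels = split_labels_by_crown(
            scene.labels, scene.crown_ids, train_fraction, seed=cfg.seed + 1
        )
    elif split == "pixel":
        have = scene.labels.counts()
        counts = {c: n for c, n in have.items()}
        train_labels, test_labels = stratified_sample(
            scene.labels, counts, split=train_fraction, seed=cfg.seed + 1
        )
    else:
        raise ValueError("split must be 'crown' or 'pixel'")
    if train_px_per_species is not None:
        train_labels = thin_labels(
            train_labels, train_px_per_species, seed=cfg.seed + 2
        )
    result = run_experiment(
        hms,
        train_labels,
        test_labels,
        classifiers=classifiers,
        schemes=schemes,
        with_stats=with_stats,
        manifest_extra={"seed": cfg.seed, "scene": asdict(cfg)},
    )
    return result, scene
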