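"""Quantitative outputs and pipeline orchestration.

Cell abundance is reported as a density — class frequency (count) per
tubular area in mm² — per image and class. Across a series of sections,
total cell count is expected to scale with segmented tubular area; an
ordinary least squares fit of count on area (slope, r², two-sided p)
provides the audit surface, and images whose standardised residual from
that fit is extreme are flagged (never dropped) as candidate staining or
damage artefacts.

``run_pipeline`` chains the stages — optional classifier training, pixel
segmentation, cell detection, marker classification, zone partition,
neighbour graph, DNA-content indexing, and summary export — with every
stage logged and any failure reported with the stage name. Outputs are
deterministic given the configured seeds.
"""

from __future__ import annotations

import contextlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import cellclass, cellseg, cycle as cycle_mod, pixelclass, spatial
from .errors import TubulopyError
from .imgio import ROISet, CalibratedImage, write_measurements, write_rois_geojson

__all__ = [
    "density",
    "summarise_image",
    "area_count_regression",
    "qc_flag_outliers",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]

log = logging.getLogger("tubulopy")


def density(count: int, area_mm2: float) -> float:
    """Cells per mm² of tubular area."""
    if area_mm2 <= 0:
        raise TubulopyError("area must be > 0 for a density")
    return count / area_mm2


def summarise_image(
    image_id: str,
    rois: ROISet,
    detections: list[cellseg.CellDetection],
) -> pd.DataFrame:
    """Per-class counts, tubular area and densities for one image."""
    area_um2 = sum(r.area_um2 for r in rois.by_class("tubule"))
    area_mm2 = area_um2 / 1e6
    classes = sorted({d.class_label or "" for d in detections})
    rows = []
    for cls in classes:
        n = sum(1 for d in detections if (d.class_label or "") == cls)
        rows.append(
            {
                "image_id": image_id,
                "class": cls if cls else "(unclassified-stage)",
                "count": n,
                "tubule_area_um2": area_um2,
                "tubule_area_mm2": area_mm2,
                "density_per_mm2": density(n, area_mm2) if area_mm2 > 0 else np.nan,
            }
        )
    rows.append(
        {
            "image_id": image_id,
            "class": "all",
            "count": len(detections),
            "tubule_area_um2": area_um2,
            "tubule_area_mm2": area_mm2,
            "density_per_mm2": density(len(detections), area_mm2)
            if area_mm2 > 0
            else np.nan,
        }
    )
    return pd.DataFrame(rows)


def area_count_regression(
    summaries: pd.DataFrame,
    class_name: str = "all",
    area_col: str = "tubule_area_um2",
) -> dict[str, float]:
    """OLS of per-image count on tubular area for one class.

    Returns slope, intercept, r2 and the two-sided p-value for the slope.
    """
    sub = summaries[summaries["class"] == class_name]
    if len(sub) < 3:
        raise TubulopyError("regression needs >= 3 images")
    x = sub[area_col].to_numpy(float)
    y = sub["count"].to_numpy(float)
    if np.ptp(x) == 0:
        raise TubulopyError("zero variance in area")
    fit = stats.linregress(x, y)
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r2": fit.rvalue**2,
        "p": fit.pvalue,
        "n": len(sub),
    }


def qc_flag_outliers(
    summaries: pd.DataFrame,
    class_name: str = "all",
    area_col: str = "tubule_area_um2",
    z_bound: float = 3.0,
) -> pd.DataFrame:
    """Flag images far off the area-count line (flag, never drop).

    Standardised residuals from the OLS fit; |z| > ``z_bound`` flags the
    image. Scale-invariant: changing area units rescales the fit and the
    residuals together.
    """
    sub = summaries[summaries["class"] == class_name].copy()
    fit = area_count_regression(summaries, class_name, area_col)
    resid = sub["count"] - (fit["slope"] * sub[area_col] + fit["intercept"])
    sd = resid.std(ddof=2)
    z = resid / sd if sd > 0 else resid * 0.0
    sub["residual_z"] = z
    sub["qc_flag"] = z.abs() > z_bound
    return sub[["image_id", "class", "count", area_col, "residual_z", "qc_flag"]]


@dataclass
class PipelineConfig:
    """Everything ``run_pipeline`` needs beyond the images themselves."""

    rules: cellclass.ClassifierSpec | None = None
    model: pixelclass.PixelClassifierModel | None = None
    training_set: list | None = None  # (image, annotations) pairs
    feature_config: pixelclass.FeatureConfig | None = None
    mlp_config: pixelclass.MLPConfig | None = None
    roi_config: pixelclass.RoiExtractionConfig = field(
        default_factory=pixelclass.RoiExtractionConfig
    )
    watershed_config: cellseg.WatershedConfig = field(
        default_factory=cellseg.WatershedConfig
    )
    partition_config: spatial.RegionPartitionConfig = field(
        default_factory=spatial.RegionPartitionConfig
    )
    neighbour_config: spatial.NeighbourConfig = field(
        default_factory=spatial.NeighbourConfig
    )
    cycle_config: cycle_mod.CycleConfig = field(default_factory=cycle_mod.CycleConfig)
    backend: str = "watershed"
    seed: int = 0
    out_dir: str | Path | None = None


@dataclass
class PipelineResult:
    rois: dict[str, ROISet]
    detections: dict[str, list]
    summaries: pd.DataFrame
    mitotic_table: pd.DataFrame
    threshold_rfu: float
    model: pixelclass.PixelClassifierModel | None
    written: list[Path] = field(default_factory=list)


@contextlib.contextmanager
def _stage(name: str, **params):
    log.info("stage %s: %s", name, params or "")
    try:
        yield
    except TubulopyError as e:
        raise TubulopyError(f"[{name}] {e}") from e


def run_pipeline(
    images: list[CalibratedImage],
    config: PipelineConfig,
    rois_by_image: dict[str, ROISet] | None = None,
) -> PipelineResult:
    """Run the full workflow over a list of calibrated images.

    ROIs come from the pixel classifier (trained here if a training set
    is given, else ``config.model``) unless precomputed ROISets are
    passed in ``rois_by_image``. Deterministic given the config seeds;
    CSV/GeoJSON outputs are written under ``config.out_dir`` when set.
    """
    model = config.model
    if model is None and config.training_set is not None:
        with _stage("train", n_images=len(config.training_set), seed=config.seed):
            model = pixelclass.train_pixel_classifier(
                config.training_set,
                feat_cfg=config.feature_config,
                mlp_cfg=config.mlp_config,
                seed=config.seed,
            )
    all_rois: dict[str, ROISet] = {}
    all_dets: dict[str, list] = {}
    summaries = []
    for img in images:
        if rois_by_image is not None and img.image_id in rois_by_image:
            rois = rois_by_image[img.image_id]
        elif model is not None:
            with _stage("segment", image=img.image_id):
                pred = pixelclass.predict_pixels(model, img)
                rois = pixelclass.extract_rois(
                    pred, img.pixel_size_um, config.roi_config, image_id=img.image_id
                )
        else:
            raise TubulopyError(
                f"[segment] no model, training set or precomputed ROIs for "
                f"{img.image_id}"
            )
        all_rois[img.image_id] = rois
        with _stage("cells", image=img.image_id, backend=config.backend):
            dets = cellseg.detect_cells(
                img, rois, backend=config.backend, cfg=config.watershed_config
            )
        with _stage("classify", image=img.image_id):
            if config.rules is None:
                raise TubulopyError("no class rules configured")
            cellclass.classify_cells(dets, config.rules)
        with _stage("partition", image=img.image_id):
            partitions = {
                r.roi_id: spatial.partition_tubule(r.polygon, config.partition_config)
                for r in rois.by_class("tubule")
            }
            spatial.assign_regions(dets, partitions)
        with _stage("graph", image=img.image_id):
            spatial.build_neighbour_graph(dets, config.neighbour_config)
        all_dets[img.image_id] = dets
        summaries.append(summarise_image(img.image_id, rois, dets))
    pooled = [d for dets in all_dets.values() for d in dets]
    with _stage("cycle"):
        threshold = cycle_mod.derive_threshold(pooled, config.cycle_config)
        classes = sorted(
            {
                d.class_label
                for d in pooled
                if d.class_label and d.class_label != config.rules.unclassified_label
            }
        )
        mitotic = cycle_mod.mitotic_index(
            pooled, threshold, classes=classes, cfg=config.cycle_config
        )
    summary_df = (
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    )
    result = PipelineResult(
        rois=all_rois,
        detections=all_dets,
        summaries=summary_df,
        mitotic_table=mitotic,
        threshold_rfu=threshold,
        model=model,
    )
    if config.out_dir is not None:
        with _stage("report", out_dir=str(config.out_dir)):
            result.written = _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for image_id, rois in sorted(result.rois.items()):
        p = out_dir / f"{image_id}.rois.geojson"
        write_rois_geojson(rois, p)
        written.append(p)
    det_tables = [
        cellseg.detections_to_table(dets)
        for _, dets in sorted(result.detections.items())
    ]
    det_df = (
        pd.concat(det_tables, ignore_index=True) if det_tables else pd.DataFrame()
    )
    for name, df in (
        ("detections.csv", det_df),
        ("summaries.csv", result.summaries),
        ("mitotic_index.csv", result.mitotic_table),
    ):
        p = out_dir / name
        write_measurements(df, p)
        written.append(p)
    if result.model is not None:
        p = out_dir / "pixel_classifier.json"
        result.model.save(p)
        written.append(p)
    return written
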