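"""Calibrated image, ROI and measurement-table I/O.

The pipeline standardises on open desk-scale formats: multi-page/OME TIFF
for images, GeoJSON FeatureCollections for region-of-interest polygons
(coordinates in micrometres) and RFC-4180 CSV for measurement tables.
Every micrometre-denominated parameter downstream relies on the
``pixel_size_um`` calibration carried here; it is a required input, never
assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, mapping, shape as shapely_shape

from .errors import CalibrationError, TubulopyError

__all__ = [
    "CalibratedImage",
    "ROI",
    "ROISet",
    "read_image",
    "write_image",
    "read_rois_geojson",
    "write_rois_geojson",
    "read_measurements",
    "write_measurements",
]


@dataclass
class CalibratedImage:
    """A named-channel fluorescence raster with μm/px calibration.

    ``pixels`` has shape (n_channels, height, width); intensities are
    non-negative relative fluorescence units (RFU). Channel identity is by
    name everywhere downstream — classifiers refuse images whose channel
    set differs from their training set.
    """

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    image_id: str = "image"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise TubulopyError("pixels must be (channels, height, width)")
        if len(self.channel_names) != self.pixels.shape[0]:
            raise TubulopyError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise TubulopyError("duplicate channel names")
        if self.pixel_size_um is None or self.pixel_size_um <= 0:
            raise CalibrationError(
                f"pixel size must be positive, got {self.pixel_size_um}"
            )
        if self.pixels.size == 0:
            raise TubulopyError("zero-sized image")
        if (self.pixels < 0).any():
            raise TubulopyError("negative intensities")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.pixels[self.channel_names.index(name)]
        except ValueError:
            raise TubulopyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None


@dataclass
class ROI:
    """One classed polygon with geometry stats in μm."""

    class_label: str
    polygon: Polygon
    area_um2: float = 0.0
    perimeter_um: float = 0.0
    roi_id: int = 0

    def __post_init__(self) -> None:
        if self.area_um2 == 0.0:
            self.area_um2 = self.polygon.area
        if self.perimeter_um == 0.0:
            self.perimeter_um = self.polygon.length


@dataclass
class ROISet:
    """Classed polygons (tubule / tissue / background) for one image."""

    rois: list[ROI] = field(default_factory=list)
    image_id: str = "image"

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def by_class(self, class_label: str) -> list[ROI]:
        return [r for r in self.rois if r.class_label == class_label]

    @property
    def classes(self) -> set[str]:
        return {r.class_label for r in self.rois}


def read_image(
    path: str | Path, pixel_size_override: float | None = None
) -> CalibratedImage:
    """Read a single- or multi-page TIFF into a CalibratedImage.

    Channel names come from OME/ImageJ metadata when present, else
    ``ch0..chN``. Calibration is taken from resolution metadata unless
    overridden; an image with neither is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        pixel_size = _pixel_size_from_tiff(tf)
        names = _channel_names_from_tiff(tf)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] > 8:
        arr = np.moveaxis(arr, -1, 0)  # interleaved RGB(A)
    elif arr.ndim > 3:
        arr = arr.reshape(-1, *arr.shape[-2:])
    if arr.size == 0:
        raise TubulopyError(f"zero-sized image: {path}")
    if pixel_size_override is not None:
        pixel_size = pixel_size_override
    if pixel_size is None:
        raise CalibrationError(
            f"missing calibration: {path} has no resolution metadata and no "
            "pixel_size_override was given"
        )
    if names is None or len(names) != arr.shape[0]:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    return CalibratedImage(
        pixels=arr.astype(float),
        channel_names=names,
        pixel_size_um=pixel_size,
        image_id=path.stem,
    )


def write_image(img: CalibratedImage, path: str | Path) -> None:
    """Write channels as TIFF pages with ImageJ-style μm calibration."""
    tifffile.imwrite(
        Path(path),
        img.pixels.astype(np.float32),
        imagej=True,
        resolution=(1.0 / img.pixel_size_um, 1.0 / img.pixel_size_um),
        metadata={
            "unit": "um",
            "axes": "CYX",
            "Labels": list(img.channel_names),
        },
    )


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    page = tf.pages[0]
    res = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if res is None:
        return None
    num, den = res.value
    if num == 0 or den == 0:
        return None
    px_per_unit = num / den
    if px_per_unit == 1.0:
        return None  # (1, 1) is the writer default, not a calibration
    unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", 1), 1.0)
    if tf.is_imagej and tf.imagej_metadata:
        if tf.imagej_metadata.get("unit") in ("um", "micron", "µm"):
            unit_um = 1.0
    size = unit_um / px_per_unit
    return size if size > 0 else None


def _channel_names_from_tiff(tf: tifffile.TiffFile) -> list[str] | None:
    if tf.is_imagej and tf.imagej_metadata:
        labels = tf.imagej_metadata.get("Labels")
        if labels:
            return list(labels)
    if tf.is_ome and tf.ome_metadata:
        import re

        names = re.findall(r'Channel[^>]*Name="([^"]+)"', tf.ome_metadata)
        if names:
            return names
    return None


def write_rois_geojson(rois: ROISet, path: str | Path) -> None:
    """Write an ROISet as a GeoJSON FeatureCollection (coordinates in μm)."""
    features = []
    for roi in rois:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(roi.polygon),
                "properties": {
                    "class": roi.class_label,
                    "roi_id": roi.roi_id,
                    "area_um2": roi.area_um2,
                    "perimeter_um": roi.perimeter_um,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "image_id": rois.image_id,
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_rois_geojson(path: str | Path) -> ROISet:
    """Read a FeatureCollection of classed polygons.

    Areas and perimeters are recomputed from the geometry, not trusted
    from properties.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("type") != "FeatureCollection":
        raise TubulopyError(f"{path}: not a GeoJSON FeatureCollection")
    rois = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = shapely_shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise TubulopyError(
                f"{path}: feature {i} is {geom.geom_type}, expected Polygon"
            )
        props = feat.get("properties") or {}
        if "class" not in props:
            raise TubulopyError(f"{path}: feature {i} missing class property")
        rois.append(
            ROI(
                class_label=props["class"],
                polygon=geom,
                area_um2=geom.area,
                perimeter_um=geom.length,
                roi_id=props.get("roi_id", i),
            )
        )
    return ROISet(rois=rois, image_id=doc.get("image_id", Path(path).stem))


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table as plain UTF-8 CSV, stable column order."""
    if table.index.duplicated().any():
        raise TubulopyError("duplicate object keys in measurement table")
    table.to_csv(Path(path), index=False, lineterminator="\n")


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
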