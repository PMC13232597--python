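"""Raster <-> vector helpers.

Conventions used throughout the package: rasters are indexed [row, col]
(y-down); continuous coordinates are micrometres with the origin at the
top-left corner of pixel (0, 0), so the centre of pixel (r, c) sits at
((c + 0.5) * px, (r + 0.5) * px).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from shapely import contains_xy
from shapely.geometry import Polygon
from skimage import measure


def contour_to_um(contour: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Map a skimage (row, col) contour to (x, y) μm coordinates."""
    xy = np.empty_like(contour)
    xy[:, 0] = (contour[:, 1] + 0.5) * pixel_size_um
    xy[:, 1] = (contour[:, 0] + 0.5) * pixel_size_um
    return xy


def mask_to_polygon(mask: np.ndarray, pixel_size_um: float) -> Polygon | None:
    """Trace one connected foreground component as a polygon with holes.

    Contours are marching-squares level-0.5 curves: the largest is the
    exterior, the rest are holes. Returns None for an empty mask.
    """
    if not mask.any():
        return None
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5, fully_connected="high")
    if not contours:
        return None
    rings = []
    for c in contours:
        c = c - 1.0  # undo pad
        if len(c) >= 4:
            rings.append(contour_to_um(c, pixel_size_um))
    rings.sort(key=lambda r: abs(Polygon(r).area), reverse=True)
    poly = Polygon(rings[0], holes=rings[1:] if len(rings) > 1 else None)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def labels_to_polygons(
    labels: np.ndarray, pixel_size_um: float
) -> dict[int, Polygon]:
    """Trace every positive label of a label image, cropping to bboxes."""
    out: dict[int, Polygon] = {}
    objects = ndi.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        poly = mask_to_polygon(mask, pixel_size_um)
        if poly is None:
            continue
        dy, dx = sl[0].start * pixel_size_um, sl[1].start * pixel_size_um
        out[lab] = Polygon(
            [(x + dx, y + dy) for x, y in poly.exterior.coords],
            holes=[
                [(x + dx, y + dy) for x, y in ring.coords]
                for ring in poly.interiors
            ],
        )
    return out


def rasterise_polygon(
    poly, shape: tuple[int, int], pixel_size_um: float
) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon."""
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(minx / pixel_size_um) - 1, 0)
    c1 = min(int(maxx / pixel_size_um) + 2, w)
    r0 = max(int(miny / pixel_size_um) - 1, 0)
    r1 = min(int(maxy / pixel_size_um) + 2, h)
    mask = np.zeros(shape, dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    xs = (cols + 0.5) * pixel_size_um
    ys = (rows + 0.5) * pixel_size_um
    inside = contains_xy(poly, xs.ravel(), ys.ravel()).reshape(rows.shape)
    mask[r0:r1, c0:c1] = inside
    return mask


def disc_mask(
    shape: tuple[int, int], center_rc: tuple[float, float], radius_px: float
) -> np.ndarray:
    """Boolean disc: pixel centres within radius of an (row, col) centre."""
    h, w = shape
    r0 = max(int(center_rc[0] - radius_px) - 1, 0)
    r1 = min(int(center_rc[0] + radius_px) + 2, h)
    c0 = max(int(center_rc[1] - radius_px) - 1, 0)
    c1 = min(int(center_rc[1] + radius_px) + 2, w)
    mask = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    rr, cc = np.mgrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] = (rr - center_rc[0]) ** 2 + (
        cc - center_rc[1]
    ) ** 2 <= radius_px**2
    return mask
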