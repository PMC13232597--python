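"""Synthetic testis immunofluorescence scenes with full ground truth.

The generator emulates the geometry and photometry the pipeline is built
for: seminiferous tubules (discs with a peritubular-myoid ring) embedded
in interstitial tissue over dark background; a Hoechst counterstain whose
nuclear mean intensity encodes DNA content — a G1 peak near 9,000 RFU
(truncated normal on [6,000, 14,000]) and a mitotic tail uniform on
[14,000, 30,000] — and nuclear or cytosolic marker channels (SOX9,
MAGE-A, MVH, COUP-TFII, PLZF) rendered per cell class. Every rendered
nucleus has a ground-truth record (class, zone, cycle state), so each
downstream stage can be scored without any real data.

Scenes are deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from ._raster import disc_mask
from .errors import PackingError, TubulopyError
from .imgio import ROI, ROISet, CalibratedImage

__all__ = [
    "SceneSpec",
    "CellRecord",
    "GroundTruth",
    "REGION_CODES",
    "generate_scene",
    "sparse_annotations_from_truth",
    "render_control_image",
]

REGION_CODES = {"background": 0, "tissue": 1, "tubule": 2}

COUNTERSTAIN = "Hoechst"
UNCLASSIFIED = "unclassified"


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Geometry is in μm; intensities in RFU. The defaults describe a
    prepubertal-testis-like section at 0.5 μm/px: a handful of tubules of
    45-70 μm radius with a 5 μm peritubular ring, Sertoli (SOX9) and
    spermatogonial (MAGE-A) cells mixed in the membrane band, germ-cell
    clusters towards the lumen, and unmarked interstitial cells between
    tubules.
    """

    size_px: int = 1024
    pixel_size_um: float = 0.5
    n_tubules: int = 5
    tubule_radius_um: tuple[float, float] = (45.0, 70.0)
    ptm_ring_width_um: float = 5.0
    min_gap_um: float = 12.0
    cell_radius_um: float = 4.0
    # packing: cells per μm² of tubule / interstitial area
    cell_density_per_um2: float = 0.007
    interstitial_density_per_um2: float = 0.0015
    membrane_depth_um: float = 35.0
    # markers: channel name -> compartment ("nuclear" | "cytosolic")
    markers: dict[str, str] = field(
        default_factory=lambda: {"SOX9": "nuclear", "MAGE-A": "nuclear"}
    )
    # class mix per zone; keys are marker-class names (or "unclassified")
    membrane_mix: dict[str, float] = field(
        default_factory=lambda: {"SOX9": 0.5, "MAGE-A": 0.5}
    )
    luminal_mix: dict[str, float] = field(
        default_factory=lambda: {"SOX9": 0.45, "MAGE-A": 0.55}
    )
    # luminal germ cells arrive in tight cliques of this size (clustering
    # towards the lumen is the organisational signal the neighbour graph
    # is meant to pick up); 1 disables clustering
    luminal_cluster_size: int = 5
    marker_positive_rfu: tuple[float, float] = (5000.0, 800.0)
    marker_negative_rfu: tuple[float, float] = (300.0, 120.0)
    hoechst_g1_mean: float = 9000.0
    hoechst_g1_sd: float = 1500.0
    hoechst_g1_range: tuple[float, float] = (6000.0, 14000.0)
    hoechst_mitotic_range: tuple[float, float] = (14000.0, 30000.0)
    mitotic_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "SOX9": 0.11,
            "MAGE-A": 0.50,
            UNCLASSIFIED: 0.20,
        }
    )
    # diffuse autofluorescence baselines that make the three region
    # classes optically distinct, as tissue is against coverslip glass
    tubule_baseline_rfu: float = 1200.0
    ptm_baseline_rfu: float = 2000.0
    tissue_baseline_rfu: float = 500.0
    background_noise_sd: float = 200.0
    # min centre-to-centre separation, as a multiple of cell radius;
    # 2.1 keeps nucleus discs disjoint, lower values stress watershed
    min_separation_factor: float = 2.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.cell_radius_um <= 0:
            raise TubulopyError("sizes must be positive")
        for mix in (self.membrane_mix, self.luminal_mix):
            if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise TubulopyError("class mix must sum to 1")
        for f in self.mitotic_fraction.values():
            if not 0.0 <= f <= 1.0:
                raise TubulopyError("mitotic fractions must be in [0, 1]")

    @property
    def channel_names(self) -> list[str]:
        return [COUNTERSTAIN, *self.markers]


@dataclass
class CellRecord:
    """Ground truth for one rendered nucleus."""

    cell_id: int
    x_um: float
    y_um: float
    true_class: str
    true_zone: str  # membrane | luminal | interstitial
    true_cycle: str  # G1 | mitotic
    hoechst_rfu: float
    tubule_id: int  # -1 for interstitial cells

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x_um, self.y_um)


@dataclass
class GroundTruth:
    """Per-pixel region labels plus per-cell records for one scene."""

    region_labels: np.ndarray  # uint8, REGION_CODES
    cells: list[CellRecord]
    tubule_polygons: list[Polygon]
    pixel_size_um: float
    image_id: str = "synthetic"

    def cells_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.cells],
                "x_um": [c.x_um for c in self.cells],
                "y_um": [c.y_um for c in self.cells],
                "true_class": [c.true_class for c in self.cells],
                "true_zone": [c.true_zone for c in self.cells],
                "true_cycle": [c.true_cycle for c in self.cells],
                "hoechst_rfu": [c.hoechst_rfu for c in self.cells],
                "tubule_id": [c.tubule_id for c in self.cells],
            }
        )

    def tubule_roiset(self) -> ROISet:
        """Ground-truth tubule outlines as an ROISet (for pipeline stages
        downstream of pixel classification)."""
        rois = [
            ROI(class_label="tubule", polygon=p, roi_id=i)
            for i, p in enumerate(self.tubule_polygons)
        ]
        return ROISet(rois=rois, image_id=self.image_id)

    def region_mask(self, class_label: str) -> np.ndarray:
        return self.region_labels == REGION_CODES[class_label]


def _place_tubules(spec: SceneSpec, rng: np.random.Generator):
    """Non-overlapping tubule discs inside the tissue ellipse."""
    w_um = spec.size_px * spec.pixel_size_um
    cx, cy = w_um / 2, w_um / 2
    ax, ay = 0.46 * w_um, 0.44 * w_um  # tissue ellipse semi-axes
    # whole-configuration restarts: an awkward early placement can make
    # the remaining tubules unplaceable even when a joint solution exists
    for _restart in range(40):
        placed: list[tuple[float, float, float]] = []
        for _ in range(spec.n_tubules):
            ok = False
            for _attempt in range(800):
                r = rng.uniform(*spec.tubule_radius_um)
                if 2 * r >= w_um:
                    continue
                x = rng.uniform(r, w_um - r)
                y = rng.uniform(r, w_um - r)
                # fully inside tissue ellipse, with the inter-tubule gap
                # as margin so interstitium separates tubule from
                # background
                margin = r + spec.min_gap_um
                if (
                    ax <= margin
                    or ay <= margin
                    or ((x - cx) / (ax - margin)) ** 2
                    + ((y - cy) / (ay - margin)) ** 2
                    > 1.0
                ):
                    continue
                if any(
                    math.hypot(x - px, y - py) < r + pr + spec.min_gap_um
                    for px, py, pr in placed
                ):
                    continue
                placed.append((x, y, r))
                ok = True
                break
            if not ok:
                break
        if len(placed) == spec.n_tubules:
            return placed, (cx, cy, ax, ay)
    raise PackingError(
        f"could not place {spec.n_tubules} tubules of radius "
        f"{spec.tubule_radius_um} with gap {spec.min_gap_um} μm"
    )


def _region_labels(spec: SceneSpec, tubules, ellipse) -> np.ndarray:
    n = spec.size_px
    px = spec.pixel_size_um
    yy, xx = np.mgrid[0:n, 0:n]
    x_um = (xx + 0.5) * px
    y_um = (yy + 0.5) * px
    cx, cy, ax, ay = ellipse
    labels = np.zeros((n, n), dtype=np.uint8)
    tissue = ((x_um - cx) / ax) ** 2 + ((y_um - cy) / ay) ** 2 <= 1.0
    labels[tissue] = REGION_CODES["tissue"]
    for tx, ty, tr in tubules:
        inside = (x_um - tx) ** 2 + (y_um - ty) ** 2 <= tr**2
        labels[inside] = REGION_CODES["tubule"]
    return labels


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    sampler,
    min_sep: float,
    existing: list[tuple[float, float]],
    max_tries: int = 200,
) -> list[tuple[float, float]]:
    """Rejection-sample n points with a minimum pairwise separation."""
    pts: list[tuple[float, float]] = []
    all_pts = list(existing)
    for _ in range(n):
        for _t in range(max_tries):
            x, y = sampler(rng)
            if all(
                (x - qx) ** 2 + (y - qy) ** 2 >= min_sep**2
                for qx, qy in all_pts
            ):
                pts.append((x, y))
                all_pts.append((x, y))
                break
        # silently under-fills when the zone saturates; counts are
        # ground truth, not targets
    return pts


def _pick_classes(rng, mix: dict[str, float], n: int) -> list[str]:
    if not mix or n == 0:
        return [UNCLASSIFIED] * n
    names = sorted(mix)
    probs = np.array([mix[k] for k in names])
    return [names[i] for i in rng.choice(len(names), size=n, p=probs)]


def _cluster_layout(center, circumradius: float, k: int):
    """k points on a regular polygon around a centre (tight clique)."""
    cx, cy = center
    return [
        (
            cx + circumradius * math.cos(2 * math.pi * j / k),
            cy + circumradius * math.sin(2 * math.pi * j / k),
        )
        for j in range(k)
    ]


def _build_scene(spec: SceneSpec):
    """Place geometry and cells; returns (signal, noise, ground truth).

    ``signal`` maps channel name -> noise-free raster; noise is drawn
    from per-channel child streams so a control render can reuse them.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_structure, ss_noise = root.spawn(2)
    rng = np.random.default_rng(ss_structure)
    n = spec.size_px
    px = spec.pixel_size_um

    tubules, ellipse = _place_tubules(spec, rng)
    labels = _region_labels(spec, tubules, ellipse)

    min_sep = spec.min_separation_factor * spec.cell_radius_um
    records: list[CellRecord] = []
    placements: list[tuple[float, float, str, str, int]] = []

    for tid, (tx, ty, tr) in enumerate(tubules):
        inner = tr - spec.ptm_ring_width_um - spec.cell_radius_um
        if inner <= 0:
            continue
        lum_r = max(tr - spec.membrane_depth_um, 0.0)
        area_mem = math.pi * (inner**2 - min(lum_r, inner) ** 2)
        area_lum = math.pi * min(lum_r, inner) ** 2
        existing: list[tuple[float, float]] = []

        def annulus_sampler(r0, r1):
            def _s(rng):
                rad = math.sqrt(rng.uniform(r0**2, r1**2))
                th = rng.uniform(0, 2 * math.pi)
                return tx + rad * math.cos(th), ty + rad * math.sin(th)

            return _s

        # membrane band: dispersed cells
        n_mem = int(round(area_mem * spec.cell_density_per_um2))
        mem_pts = _sample_positions(
            rng, n_mem, annulus_sampler(min(lum_r, inner), inner), min_sep, existing
        )
        existing += mem_pts
        mem_cls = _pick_classes(rng, spec.membrane_mix, len(mem_pts))
        for (x, y), cls in zip(mem_pts, mem_cls):
            placements.append((x, y, cls, "membrane", tid))

        # luminal zone: germ-cell cliques plus dispersed cells
        n_lum = int(round(area_lum * spec.cell_density_per_um2))
        lum_cls = _pick_classes(rng, spec.luminal_mix, n_lum)
        k = max(spec.luminal_cluster_size, 1)
        circum = 1.015 * min_sep / (2 * math.sin(math.pi / k)) if k > 1 else 0.0
        if k > 1:
            clustered = [c for c in lum_cls if c == "MAGE-A"]
            dispersed = [c for c in lum_cls if c != "MAGE-A"]
        else:
            clustered, dispersed = [], list(lum_cls)
        # place germ-cell cliques; an unplaceable clique is dropped
        i = 0
        while i < len(clustered):
            size = min(k, len(clustered) - i)
            if lum_r - circum - spec.cell_radius_um <= 0:
                break
            centre_pts = _sample_positions(
                rng,
                1,
                annulus_sampler(0, max(lum_r - circum - spec.cell_radius_um, 1.0)),
                2 * circum + min_sep,
                existing,
            )
            if centre_pts:
                pts = _cluster_layout(centre_pts[0], circum, size)
                if all(
                    all(
                        (x - qx) ** 2 + (y - qy) ** 2 >= min_sep**2
                        for qx, qy in existing
                    )
                    for x, y in pts
                ):
                    for (x, y), cls in zip(pts, clustered[i : i + size]):
                        placements.append((x, y, cls, "luminal", tid))
                    existing += pts
            i += size
        for cls in dispersed:
            pts = _sample_positions(
                rng, 1, annulus_sampler(0, max(lum_r - spec.cell_radius_um, 0.5)), min_sep, existing
            )
            if pts:
                placements.append((pts[0][0], pts[0][1], cls, "luminal", tid))
                existing += pts

    # interstitial cells: tissue pixels outside tubules
    tissue_area = float((labels == REGION_CODES["tissue"]).sum()) * px * px
    n_int = int(round(tissue_area * spec.interstitial_density_per_um2))
    tissue_pts: list[tuple[float, float]] = []

    def tissue_sampler(rng):
        w_um = n * px
        return rng.uniform(0, w_um), rng.uniform(0, w_um)

    pad = spec.cell_radius_um
    got = 0
    tries = 0
    while got < n_int and tries < n_int * 300:
        tries += 1
        x, y = tissue_sampler(rng)
        r_idx = min(int(y / px), n - 1)
        c_idx = min(int(x / px), n - 1)
        if labels[r_idx, c_idx] != REGION_CODES["tissue"]:
            continue
        # keep whole nucleus inside interstitium (away from tubule rims)
        near = False
        for tx, ty, tr in tubules:
            if math.hypot(x - tx, y - ty) < tr + pad:
                near = True
                break
        if near:
            continue
        if any(
            (x - qx) ** 2 + (y - qy) ** 2 < min_sep**2 for qx, qy in tissue_pts
        ):
            continue
        tissue_pts.append((x, y))
        placements.append((x, y, UNCLASSIFIED, "interstitial", -1))
        got += 1

    # cycle state + Hoechst intensity per cell
    g1_lo, g1_hi = spec.hoechst_g1_range
    for cid, (x, y, cls, zone, tid) in enumerate(placements):
        frac = spec.mitotic_fraction.get(cls, 0.0)
        mitotic = rng.random() < frac
        if mitotic:
            rfu = rng.uniform(*spec.hoechst_mitotic_range)
        else:
            rfu = rng.normal(spec.hoechst_g1_mean, spec.hoechst_g1_sd)
            while not (g1_lo <= rfu <= g1_hi):
                rfu = rng.normal(spec.hoechst_g1_mean, spec.hoechst_g1_sd)
        records.append(
            CellRecord(
                cell_id=cid,
                x_um=x,
                y_um=y,
                true_class=cls,
                true_zone=zone,
                true_cycle="mitotic" if mitotic else "G1",
                hoechst_rfu=rfu,
                tubule_id=tid,
            )
        )

    # --- render ---
    shape = (n, n)
    signal: dict[str, np.ndarray] = {}
    hoechst = np.zeros(shape)
    hoechst[labels == REGION_CODES["tissue"]] = spec.tissue_baseline_rfu
    hoechst[labels == REGION_CODES["tubule"]] = spec.tubule_baseline_rfu
    for tx, ty, tr in tubules:  # brighter peritubular ring
        ring = disc_mask(shape, (ty / px - 0.5, tx / px - 0.5), tr / px) & ~disc_mask(
            shape, (ty / px - 0.5, tx / px - 0.5), (tr - spec.ptm_ring_width_um) / px
        )
        hoechst[ring] = spec.ptm_baseline_rfu

    marker_sig = {m: np.zeros(shape) for m in spec.markers}
    r_nuc_px = spec.cell_radius_um / px
    r_cell_px = (spec.cell_radius_um + 3.0) / px
    pos_mu, pos_sd = spec.marker_positive_rfu
    neg_mu, neg_sd = spec.marker_negative_rfu
    for rec in records:
        rc = (rec.y_um / px - 0.5, rec.x_um / px - 0.5)
        nuc = disc_mask(shape, rc, r_nuc_px)
        hoechst[nuc] = np.maximum(hoechst[nuc], rec.hoechst_rfu)
        for m, compartment in spec.markers.items():
            positive = rec.true_class == m
            level = max(
                rng.normal(pos_mu, pos_sd) if positive else rng.normal(neg_mu, neg_sd),
                0.0,
            )
            if compartment == "nuclear":
                tgt = nuc
            else:
                tgt = disc_mask(shape, rc, r_cell_px) & ~nuc
            marker_sig[m][tgt] = np.maximum(marker_sig[m][tgt], level)

    signal[COUNTERSTAIN] = hoechst
    signal.update(marker_sig)

    noise: dict[str, np.ndarray] = {}
    for ch, ss in zip(spec.channel_names, ss_noise.spawn(len(spec.channel_names))):
        noise[ch] = np.random.default_rng(ss).normal(
            0.0, spec.background_noise_sd, shape
        )

    tub_polys = [
        Point(tx, ty).buffer(tr, quad_segs=64) for tx, ty, tr in tubules
    ]
    gt = GroundTruth(
        region_labels=labels,
        cells=records,
        tubule_polygons=tub_polys,
        pixel_size_um=px,
        image_id=f"synthetic-seed{spec.seed}",
    )
    return signal, noise, gt


def _compose(spec: SceneSpec, signal, noise, omit=()) -> CalibratedImage:
    chans = []
    for ch in spec.channel_names:
        base = noise[ch].copy() if ch in omit else signal[ch] + noise[ch]
        chans.append(np.clip(base, 0.0, None))
    return CalibratedImage(
        pixels=np.stack(chans),
        channel_names=spec.channel_names,
        pixel_size_um=spec.pixel_size_um,
        image_id=f"synthetic-seed{spec.seed}",
    )


def generate_scene(spec: SceneSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Render one calibrated scene plus its ground truth (deterministic)."""
    signal, noise, gt = _build_scene(spec)
    return _compose(spec, signal, noise), gt


def render_control_image(
    spec: SceneSpec, omit_markers: list[str]
) -> tuple[CalibratedImage, GroundTruth]:
    """Antibody-control render: same geometry and counterstain at the same
    seed, but the omitted marker channels carry background noise only."""
    if COUNTERSTAIN in omit_markers:
        raise TubulopyError("cannot omit the counterstain channel")
    unknown = set(omit_markers) - set(spec.markers)
    if unknown:
        raise TubulopyError(f"unknown marker channels: {sorted(unknown)}")
    signal, noise, gt = _build_scene(spec)
    return _compose(spec, signal, noise, omit=set(omit_markers)), gt


def sparse_annotations_from_truth(
    gt: GroundTruth,
    k_per_class: int = 3,
    seed: int = 0,
    radius_um: float = 8.0,
) -> ROISet:
    """Small disc annotations per region class, as a human annotator would
    draw for classifier training: ``k_per_class`` discs each fully inside
    a correctly-labelled region (three per class is the working default).
    """
    from scipy import ndimage as ndi

    rng = np.random.default_rng(seed)
    px = gt.pixel_size_um
    r_px = int(np.ceil(radius_um / px)) + 1
    rois: list[ROI] = []
    rid = 0
    for cls in ("tubule", "tissue", "background"):
        mask = gt.region_mask(cls)
        if not mask.any():
            raise TubulopyError(f"class {cls!r} absent from scene")
        eroded = ndi.binary_erosion(mask, iterations=r_px, border_value=(cls == "background"))
        rr, cc = np.nonzero(eroded)
        if len(rr) == 0:
            raise TubulopyError(
                f"class {cls!r} has no area that can hold a {radius_um} μm disc"
            )
        idx = rng.choice(len(rr), size=min(k_per_class, len(rr)), replace=False)
        for i in np.atleast_1d(idx):
            x = (cc[i] + 0.5) * px
            y = (rr[i] + 0.5) * px
            rois.append(
                ROI(
                    class_label=cls,
                    polygon=Point(x, y).buffer(radius_um, quad_segs=32),
                    roi_id=rid,
                )
            )
            rid += 1
    return ROISet(rois=rois, image_id=gt.image_id)


def scene_pair_with_controls(
    spec: SceneSpec, n_stained: int = 2, n_controls_per_marker: int = 2
) -> list[tuple[CalibratedImage, GroundTruth, list[str]]]:
    """Convenience: a training set shaped like the study's — fully stained
    scenes plus single-marker antibody controls, at consecutive seeds."""
    out = []
    seed = spec.seed
    for i in range(n_stained):
        s = replace(spec, seed=seed)
        img, gt = generate_scene(s)
        out.append((img, gt, []))
        seed += 1
    for marker in spec.markers:
        others = [m for m in spec.markers if m != marker]
        for i in range(n_controls_per_marker):
            s = replace(spec, seed=seed)
            img, gt = render_control_image(s, omit_markers=others)
            out.append((img, gt, others))
            seed += 1
    return out
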