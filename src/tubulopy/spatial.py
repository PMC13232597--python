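"""Tubule zone partition and same-class neighbour networks.

Two spatial reductions of classified detections: (i) each tubule is
split into a membrane-associated band (within 35 μm of the tubule
boundary, about two cell diameters) and the remaining luminal core by an
inward polygon buffer; (ii) cells of the same class whose nucleus
centroids lie within 15 μm form an undirected 'neighbour' graph whose
per-cell degree summarises local clustering. Degrees are computed
against all same-class cells before any region filtering — a membrane
cell can be the neighbour of a luminal one — and region subsets only
select which cells' degrees enter a histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .cellseg import CellDetection
from .errors import EmptySubsetError, TubulopyError

__all__ = [
    "RegionPartitionConfig",
    "NeighbourConfig",
    "NeighbourGraph",
    "partition_tubule",
    "assign_regions",
    "build_neighbour_graph",
    "neighbour_distribution",
]

MEMBRANE = "membrane"
LUMINAL = "luminal"


@dataclass
class RegionPartitionConfig:
    membrane_depth_um: float = 35.0

    def __post_init__(self) -> None:
        if self.membrane_depth_um <= 0:
            raise TubulopyError("membrane depth must be > 0")


@dataclass
class NeighbourConfig:
    radius_um: float = 15.0
    same_class_only: bool = True

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise TubulopyError("radius must be > 0")


def partition_tubule(
    tubule: Polygon, cfg: RegionPartitionConfig | None = None
):
    """Split a tubule polygon into (membrane zone, luminal zone).

    The luminal zone is the inward buffer of the tubule by the membrane
    depth; the membrane zone is the remainder, so the two cover the
    tubule exactly. Tubules narrower than twice the depth have an empty
    luminal zone.
    """
    cfg = cfg or RegionPartitionConfig()
    if tubule.is_empty or not tubule.is_valid:
        raise TubulopyError("invalid tubule polygon")
    luminal = tubule.buffer(-cfg.membrane_depth_um)
    membrane = tubule.difference(luminal)
    return membrane, luminal


def assign_regions(
    detections: list[CellDetection],
    partitions: dict[int, tuple],
) -> list[CellDetection]:
    """Label each detection membrane/luminal by nucleus centroid.

    ``partitions`` maps the detection's parent ROI id to its
    (membrane, luminal) pair. Centroids exactly on the 35 μm line go to
    membrane (only strictly interior luminal points count as luminal).
    """
    for det in detections:
        if det.roi_id not in partitions:
            raise TubulopyError(
                f"detection {det.cell_id} has no partitioned parent tubule "
                f"(roi {det.roi_id})"
            )
        _, luminal = partitions[det.roi_id]
        pt = Point(det.x_um, det.y_um)
        det.region_label = (
            LUMINAL if (not luminal.is_empty and luminal.contains(pt)) else MEMBRANE
        )
    return detections


@dataclass
class NeighbourGraph:
    """Undirected same-class proximity graph over detections."""

    node_ids: list[int]
    edges: set[tuple[int, int]]  # (min_id, max_id)
    degrees: dict[int, int]
    radius_um: float

    def degree(self, cell_id: int) -> int:
        return self.degrees[cell_id]


def build_neighbour_graph(
    detections: list[CellDetection], cfg: NeighbourConfig | None = None
) -> NeighbourGraph:
    """Edges between classified same-class cells with centroid distance
    <= radius (inclusive); unclassified cells are excluded as nodes."""
    cfg = cfg or NeighbourConfig()
    nodes = [
        d
        for d in detections
        if d.class_label is not None and d.class_label != "unclassified"
    ]
    edges: set[tuple[int, int]] = set()
    degrees = {d.cell_id: 0 for d in nodes}
    # distances only make sense within one image; class grouping applies
    # on top when same_class_only
    groups: dict[tuple, list[CellDetection]] = {}
    for d in nodes:
        key = (d.image_id, d.class_label if cfg.same_class_only else None)
        groups.setdefault(key, []).append(d)
    for members in groups.values():
        if len(members) < 2:
            continue
        pts = np.array([[d.x_um, d.y_um] for d in members])
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(cfg.radius_um):
            a, b = members[i].cell_id, members[j].cell_id
            edges.add((min(a, b), max(a, b)))
            degrees[a] += 1
            degrees[b] += 1
    # annotate detections with their degree for downstream export
    for d in nodes:
        d.n_neighbours = degrees[d.cell_id]
    return NeighbourGraph(
        node_ids=[d.cell_id for d in nodes],
        edges=edges,
        degrees=degrees,
        radius_um=cfg.radius_um,
    )


def neighbour_distribution(
    graph: NeighbourGraph,
    detections: list[CellDetection],
    class_name: str,
    region: str = "total",
) -> tuple[dict[int, int], int]:
    """Degree histogram and mode for one class/region subset.

    ``region`` is 'total', 'membrane' or 'luminal'; the subset picks
    which cells are counted, but each cell's degree still reflects all
    its same-class neighbours regardless of their region. Ties in the
    mode resolve to the smallest degree.
    """
    subset = [
        d
        for d in detections
        if d.class_label == class_name
        and d.cell_id in graph.degrees
        and (region == "total" or d.region_label == region)
    ]
    if not subset:
        raise EmptySubsetError(
            f"no {class_name!r} cells in region {region!r}"
        )
    hist: dict[int, int] = {}
    for d in subset:
        k = graph.degrees[d.cell_id]
        hist[k] = hist.get(k, 0) + 1
    mode = min(
        (k for k in hist if hist[k] == max(hist.values()))
    )
    return dict(sorted(hist.items())), mode
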