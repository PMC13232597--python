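"""Zone partition geometry and neighbour-graph properties."""

import numpy as np
import pytest
from shapely.geometry import Point

from tubulopy import spatial
from tubulopy.cellseg import CellDetection
from tubulopy.errors import EmptySubsetError, TubulopyError
from tubulopy.spatial import (
    NeighbourConfig,
    RegionPartitionConfig,
    assign_regions,
    build_neighbour_graph,
    neighbour_distribution,
    partition_tubule,
)


def _cell(cell_id, x, y, cls="MAGE-A", roi_id=0):
    return CellDetection(
        cell_id=cell_id,
        image_id="t",
        roi_id=roi_id,
        x_um=float(x),
        y_um=float(y),
        nucleus_polygon=None,
        cell_polygon=None,
        nucleus_area_um2=50.0,
        cell_area_um2=150.0,
        nuclear_stats={"Hoechst": {"mean": 9000.0, "sum": 0, "sd": 0, "max": 0}},
        cytosolic_stats={"Hoechst": {"mean": 0.0, "sum": 0, "sd": 0, "max": 0}},
        class_label=cls,
    )


class TestPartition:
    def test_circular_tubule_reproduces_analytic_annulus(self):
        tubule = Point(0, 0).buffer(100, quad_segs=256)
        membrane, luminal = partition_tubule(tubule, RegionPartitionConfig(35.0))
        assert luminal.area == pytest.approx(np.pi * 65**2, rel=0.01)
        assert membrane.area == pytest.approx(np.pi * (100**2 - 65**2), rel=0.01)

    def test_membrane_plus_luminal_equals_tubule(self):
        tubule = Point(3, -7).buffer(80, quad_segs=64)
        membrane, luminal = partition_tubule(tubule)
        assert membrane.area + luminal.area == pytest.approx(tubule.area, rel=1e-6)
        assert membrane.intersection(luminal).area == pytest.approx(0.0, abs=1e-6)

    def test_narrow_tubule_has_empty_lumen(self):
        tubule = Point(0, 0).buffer(30, quad_segs=64)
        membrane, luminal = partition_tubule(tubule, RegionPartitionConfig(35.0))
        assert luminal.is_empty
        assert membrane.area == pytest.approx(tubule.area, rel=1e-9)

    def test_invalid_depth_rejected(self):
        with pytest.raises(TubulopyError):
            RegionPartitionConfig(0.0)


class TestAssignRegions:
    def test_centroid_positions_map_to_regions(self):
        tubule = Point(0, 0).buffer(100, quad_segs=256)
        parts = {0: partition_tubule(tubule)}
        near_edge = _cell(0, 90, 0)  # 10 um from boundary
        centre = _cell(1, 0, 0)
        assign_regions([near_edge, centre], parts)
        assert near_edge.region_label == "membrane"
        assert centre.region_label == "luminal"

    def test_missing_parent_tubule_rejected(self):
        with pytest.raises(TubulopyError, match="parent"):
            assign_regions([_cell(0, 0, 0, roi_id=9)], {})

    def test_region_counts_sum_per_tubule(self, classified_detections):
        dets, _, _ = classified_detections
        for roi_id in {d.roi_id for d in dets}:
            sub = [d for d in dets if d.roi_id == roi_id]
            n_mem = sum(d.region_label == "membrane" for d in sub)
            n_lum = sum(d.region_label == "luminal" for d in sub)
            assert n_mem + n_lum == len(sub)


class TestNeighbourGraph:
    def test_single_cell_has_degree_zero(self):
        g = build_neighbour_graph([_cell(0, 0, 0)])
        assert g.degrees == {0: 0} and g.edges == set()

    def test_three_collinear_cells_spaced_10um(self):
        cells = [_cell(i, 10 * i, 0) for i in range(3)]
        g = build_neighbour_graph(cells)
        assert [g.degree(i) for i in range(3)] == [1, 2, 1]

    def test_edge_distance_is_inclusive(self):
        g = build_neighbour_graph([_cell(0, 0, 0), _cell(1, 15, 0)])
        assert g.degree(0) == 1  # exactly 15 um counts

    def test_different_classes_never_connect(self):
        g = build_neighbour_graph([_cell(0, 0, 0, "SOX9"), _cell(1, 5, 0, "MAGE-A")])
        assert g.degrees == {0: 0, 1: 0}

    def test_unclassified_cells_excluded(self):
        g = build_neighbour_graph(
            [_cell(0, 0, 0, "unclassified"), _cell(1, 5, 0, "unclassified")]
        )
        assert g.node_ids == [] and g.edges == set()

    def test_brute_force_equivalence_on_random_cells(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 120, (200, 2))
        classes = rng.choice(["SOX9", "MAGE-A"], 200)
        cells = [_cell(i, *pts[i], classes[i]) for i in range(200)]
        g = build_neighbour_graph(cells, NeighbourConfig(15.0))
        brute = set()
        for i in range(200):
            for j in range(i + 1, 200):
                if classes[i] == classes[j] and np.hypot(*(pts[i] - pts[j])) <= 15.0:
                    brute.add((i, j))
        assert g.edges == brute
        degs = {i: 0 for i in range(200)}
        for a, b in brute:
            degs[a] += 1
            degs[b] += 1
        assert g.degrees == degs

    def test_degree_monotone_in_radius(self):
        rng = np.random.default_rng(7)
        cells = [_cell(i, *rng.uniform(0, 80, 2)) for i in range(100)]
        prev = None
        for r in (5.0, 10.0, 15.0, 25.0):
            g = build_neighbour_graph(cells, NeighbourConfig(r))
            if prev is not None:
                assert all(g.degrees[i] >= prev[i] for i in prev)
            prev = g.degrees


class TestNeighbourDistribution:
    def test_isolated_cells_mode_zero(self):
        cells = [_cell(i, 100 * i, 0) for i in range(4)]
        g = build_neighbour_graph(cells)
        hist, mode = neighbour_distribution(g, cells, "MAGE-A")
        assert hist == {0: 4} and mode == 0

    def test_five_clique_has_mode_four(self):
        # five mutually-close cells: the luminal germ-cell clique motif
        ang = np.linspace(0, 2 * np.pi, 5, endpoint=False)
        cells = [
            _cell(i, 6 * np.cos(a), 6 * np.sin(a)) for i, a in enumerate(ang)
        ]
        g = build_neighbour_graph(cells)
        hist, mode = neighbour_distribution(g, cells, "MAGE-A")
        assert hist == {4: 5} and mode == 4

    def test_tie_resolves_to_smallest_degree(self):
        # two isolated cells + one pair: histogram {0: 2, 1: 2} -> mode 0
        cells = [
            _cell(0, 0, 0),
            _cell(1, 200, 0),
            _cell(2, 400, 0),
            _cell(3, 410, 0),
        ]
        g = build_neighbour_graph(cells)
        hist, mode = neighbour_distribution(g, cells, "MAGE-A")
        assert hist == {0: 2, 1: 2} and mode == 0

    def test_empty_subset_is_signalled(self):
        cells = [_cell(0, 0, 0, "SOX9")]
        g = build_neighbour_graph(cells)
        with pytest.raises(EmptySubsetError):
            neighbour_distribution(g, cells, "MAGE-A")

    def test_luminal_germ_cells_cluster_more_than_membrane(
        self, classified_detections
    ):
        """The generator plants luminal germ-cell cliques; the degree mode
        of luminal MAGE-A cells must exceed the membrane mode."""
        dets, graph, _ = classified_detections
        _, lum_mode = neighbour_distribution(graph, dets, "MAGE-A", "luminal")
        _, mem_mode = neighbour_distribution(graph, dets, "MAGE-A", "membrane")
        assert lum_mode > mem_mode

    def test_degrees_counted_before_region_filter(self):
        """A luminal cell's membrane neighbour still contributes to its
        degree even though it is outside the luminal subset."""
        tubule = Point(0, 0).buffer(45, quad_segs=64)
        parts = {0: partition_tubule(tubule, RegionPartitionConfig(35.0))}
        inner = _cell(0, 0, 0)  # luminal (45-35=10 um core)
        outer = _cell(1, 12, 0)  # membrane, within 15 um of inner
        assign_regions([inner, outer], parts)
        assert (inner.region_label, outer.region_label) == ("luminal", "membrane")
        g = build_neighbour_graph([inner, outer])
        hist, mode = neighbour_distribution(g, [inner, outer], "MAGE-A", "luminal")
        assert hist == {1: 1} and mode == 1
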