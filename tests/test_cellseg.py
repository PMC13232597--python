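"""Watershed nucleus segmentation, cell expansion and detection."""

import numpy as np
import pytest
from shapely.geometry import Point

from tubulopy import cellseg
from tubulopy.cellseg import WatershedConfig
from tubulopy.errors import CapabilityError, TubulopyError
from tubulopy.imgio import CalibratedImage, ROISet


def _disc_image(centres_um, radius_um=4.0, value=9000.0, size=128, px=0.5, base=500.0):
    arr = np.full((size, size), base)
    yy, xx = np.mgrid[0:size, 0:size]
    for cx, cy in centres_um:
        d2 = ((xx + 0.5) * px - cx) ** 2 + ((yy + 0.5) * px - cy) ** 2
        arr[d2 <= radius_um**2] = value
    return CalibratedImage(arr[None], ["Hoechst"], px)


FIXED = WatershedConfig(threshold_method="fixed", fixed_threshold_rfu=3000.0)


class TestWatershed:
    def test_noise_only_counterstain_yields_no_detections(self):
        rng = np.random.default_rng(0)
        arr = np.clip(rng.normal(0, 200, (256, 256)), 0, None)
        img = CalibratedImage(arr[None], ["Hoechst"], 0.5)
        labels, polys = cellseg.segment_nuclei_watershed(
            img, Point(64, 64).buffer(50), WatershedConfig()
        )
        assert labels.max() == 0 and polys == {}

    def test_synthetic_nuclei_found_with_accurate_centroids(self, default_scene):
        spec, img, gt = default_scene
        truth = gt.cells_table()
        roi = gt.tubule_roiset().rois[0]
        sub = truth[truth.tubule_id == 0]
        dets = cellseg.detect_cells(img, ROISet([roi]), with_polygons=False)
        assert len(dets) == len(sub)
        from scipy.spatial import cKDTree

        tree = cKDTree(sub[["x_um", "y_um"]].to_numpy())
        d, _ = tree.query(np.array([[c.x_um, c.y_um] for c in dets]))
        assert d.max() < 2.0

    def test_two_fused_nuclei_12um_apart_split_into_two(self):
        img = _disc_image([(20, 32), (32, 32)])
        labels, polys = cellseg.segment_nuclei_watershed(
            img, Point(26, 32).buffer(25), FIXED
        )
        assert labels.max() == 2
        assert len(polys) == 2

    def test_missing_counterstain_rejected(self):
        img = CalibratedImage(np.zeros((1, 32, 32)), ["SOX9"], 0.5)
        with pytest.raises(TubulopyError, match="counterstain"):
            cellseg.segment_nuclei_watershed(img, Point(8, 8).buffer(4), FIXED)

    def test_roi_outside_image_rejected(self):
        img = _disc_image([(20, 20)])
        with pytest.raises(TubulopyError, match="outside"):
            cellseg.segment_nuclei_watershed(img, Point(500, 500).buffer(10), FIXED)

    def test_raising_lower_area_bound_never_increases_count(self, default_scene):
        _, img, gt = default_scene
        roi = gt.tubule_roiset().rois[0]
        counts = []
        for lo in (5.0, 20.0, 45.0, 60.0):
            cfg = WatershedConfig(nucleus_area_um2=(lo, 400.0))
            labels, _ = cellseg.segment_nuclei_watershed(img, roi.polygon, cfg)
            counts.append(labels.max())
        assert counts == sorted(counts, reverse=True)


class TestExpandCells:
    def test_isolated_nucleus_expands_to_analytic_disc(self):
        img = _disc_image([(32, 32)])
        labels, _ = cellseg.segment_nuclei_watershed(img, Point(32, 32).buffer(30), FIXED)
        roi_mask = np.ones(img.shape, bool)
        cells = cellseg.expand_cells(labels, roi_mask, 5.0, img.pixel_size_um)
        area = (cells == 1).sum() * 0.25
        assert area == pytest.approx(np.pi * 9.0**2, rel=0.05)

    def test_zero_expansion_is_identity(self):
        img = _disc_image([(32, 32)])
        labels, _ = cellseg.segment_nuclei_watershed(img, Point(32, 32).buffer(30), FIXED)
        assert np.array_equal(
            cellseg.expand_cells(labels, np.ones(img.shape, bool), 0.0, 0.5), labels
        )

    def test_competing_nuclei_split_at_equal_distance(self):
        img = _disc_image([(22, 32), (32, 32)])
        labels, _ = cellseg.segment_nuclei_watershed(img, Point(27, 32).buffer(26), FIXED)
        assert labels.max() == 2
        roi_mask = np.ones(img.shape, bool)
        cells = cellseg.expand_cells(labels, roi_mask, 8.0, img.pixel_size_um)
        # disjoint by construction; verify against the pixelwise
        # nearest-nucleus oracle away from exact ties
        from scipy import ndimage as ndi

        d1 = ndi.distance_transform_edt(labels != 1) * 0.5
        d2 = ndi.distance_transform_edt(labels != 2) * 0.5
        both = (cells > 0) & (np.abs(d1 - d2) > 0.5)
        assert np.array_equal(cells[both] == 1, (d1 < d2)[both])
        # nucleus always inside its cell
        assert np.array_equal(cells[labels > 0], labels[labels > 0])

    def test_negative_expansion_rejected(self):
        with pytest.raises(TubulopyError):
            cellseg.expand_cells(np.zeros((4, 4), int), np.ones((4, 4), bool), -1.0, 0.5)


class TestDetectCells:
    def test_interstitial_cells_excluded(self, default_scene):
        _, img, gt = default_scene
        truth = gt.cells_table()
        n_tubule_true = int((truth.tubule_id >= 0).sum())
        dets = cellseg.detect_cells(img, gt.tubule_roiset(), with_polygons=False)
        assert len(dets) == pytest.approx(n_tubule_true, rel=0.05)
        # and nothing detected outside tubules: every centroid inside one
        for d in dets:
            assert any(
                p.contains(Point(d.x_um, d.y_um)) for p in gt.tubule_polygons
            )

    def test_empty_roiset_gives_no_detections(self, default_scene):
        _, img, _ = default_scene
        assert cellseg.detect_cells(img, ROISet([])) == []

    def test_cell_partition_property(self, classified_detections):
        dets, _, _ = classified_detections
        # nucleus within cell, areas consistent, stats non-negative
        for d in dets:
            assert d.cell_area_um2 >= d.nucleus_area_um2
            if d.nucleus_polygon is not None and d.cell_polygon is not None:
                inter = d.nucleus_polygon.intersection(d.cell_polygon).area
                assert inter >= 0.95 * d.nucleus_polygon.area
            for ch_stats in d.nuclear_stats.values():
                assert all(v >= 0 for v in ch_stats.values())

    def test_unknown_backend_rejected(self, default_scene):
        _, img, gt = default_scene
        with pytest.raises(TubulopyError, match="backend"):
            cellseg.detect_cells(img, gt.tubule_roiset(), backend="cnn")

    def test_plugin_backend_without_plugin_is_capability_error(self, default_scene):
        _, img, gt = default_scene
        with pytest.raises(CapabilityError):
            cellseg.detect_cells(img, gt.tubule_roiset(), backend="plugin")

    def test_plugin_label_map_gives_identical_masks_and_stats(self, default_scene):
        """An external detector supplying the same label map must yield
        the same measurements (segmentation-backend invariance)."""
        _, img, gt = default_scene
        roi = gt.tubule_roiset().rois[0]
        ws = cellseg.detect_cells(img, ROISet([roi]), with_polygons=False)
        labels, _ = cellseg.segment_nuclei_watershed(img, roi.polygon)
        plug = cellseg.detect_cells(
            img, ROISet([roi]), backend="plugin", plugin=labels, with_polygons=False
        )
        assert len(plug) == len(ws)
        for a, b in zip(ws, plug):
            assert a.nuclear_stats == b.nuclear_stats
            assert (a.x_um, a.y_um) == (b.x_um, b.y_um)


class TestMeasurementTable:
    def test_table_round_trip(self, classified_detections, tmp_path):
        from tubulopy import imgio

        dets, _, _ = classified_detections
        table = cellseg.detections_to_table(dets)
        assert len(table) == len(dets)
        p = tmp_path / "dets.csv"
        imgio.write_measurements(table, p)
        back = cellseg.detections_from_table(imgio.read_measurements(p))
        assert len(back) == len(dets)
        for a, b in zip(dets, back):
            assert b.class_label == a.class_label
            assert b.region_label == a.region_label
            assert b.nuclear("Hoechst") == pytest.approx(a.nuclear("Hoechst"), rel=1e-6)
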