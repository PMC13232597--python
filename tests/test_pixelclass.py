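"""Feature stack, MLP training/prediction, ROI extraction."""

import numpy as np
import pytest

from tubulopy import pixelclass, synthdata
from tubulopy.errors import ChannelMismatchError, TubulopyError
from tubulopy.imgio import CalibratedImage
from tubulopy.pixelclass import (
    FeatureConfig,
    MLPConfig,
    PredictionMap,
    RoiExtractionConfig,
    extract_rois,
    rasterise_rois,
)


def _img(arr, names=None, px=0.5):
    arr = np.asarray(arr, float)
    if arr.ndim == 2:
        arr = arr[None]
    return CalibratedImage(arr, names or [f"ch{i}" for i in range(arr.shape[0])], px)


def _map(labels, classes=("background", "tubule")):
    labels = np.asarray(labels, int)
    probs = np.stack([(labels == i).astype(float) for i in range(len(classes))], -1)
    return PredictionMap(list(classes), labels, probs)


class TestFeatureStack:
    def test_flat_field_kills_derivative_features(self):
        stack = pixelclass.compute_feature_stack(
            _img(np.full((64, 64), 123.0)), FeatureConfig(scales_px=(1, 2))
        )
        # order per scale: gaussian, gradient, coherence, hessian det
        for s in range(2):
            base = s * 4
            assert np.allclose(stack[base], 123.0)
            assert np.allclose(stack[base + 1], 0.0, atol=1e-9)
            assert np.allclose(stack[base + 2], 0.0, atol=1e-9)
            assert np.allclose(stack[base + 3], 0.0, atol=1e-9)

    def test_feature_count_is_channels_x_scales_x_kinds(self):
        img = _img(np.random.default_rng(0).uniform(0, 1, (1, 32, 32)))
        stack = pixelclass.compute_feature_stack(img, FeatureConfig())
        assert stack.shape == (1 * 4 * 4, 32, 32)

    def test_vertical_edge_has_high_coherence(self):
        arr = np.zeros((64, 64))
        arr[:, 32:] = 1000.0
        stack = pixelclass.compute_feature_stack(
            _img(arr), FeatureConfig(kinds=("structure_tensor_coherence",), scales_px=(1,))
        )
        # an ideal straight edge is perfectly oriented: coherence -> 1
        assert stack[0][10:54, 30:34].min() > 0.95

    def test_missing_channel_rejected(self):
        with pytest.raises(ChannelMismatchError):
            pixelclass.compute_feature_stack(
                _img(np.zeros((8, 8))), FeatureConfig(channels=("Hoechst",))
            )

    @pytest.mark.parametrize("bad", [dict(scales_px=()), dict(kinds=("nope",))])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(TubulopyError):
            FeatureConfig(**bad)


class TestTrainingAndPrediction:
    def test_training_is_deterministic(self):
        spec = synthdata.SceneSpec(
            size_px=384, n_tubules=1, tubule_radius_um=(40, 50), seed=7
        )
        img, gt = synthdata.generate_scene(spec)
        ann = synthdata.sparse_annotations_from_truth(gt, seed=7)
        cfg = MLPConfig(hidden_width=16, max_iter=60)
        m1 = pixelclass.train_pixel_classifier([(img, ann)], mlp_cfg=cfg, seed=4)
        m2 = pixelclass.train_pixel_classifier([(img, ann)], mlp_cfg=cfg, seed=4)
        for a, b in zip(m1.coefs, m2.coefs):
            assert np.array_equal(a, b)
        assert m1.training_accuracy == m2.training_accuracy

    def test_missing_class_annotations_rejected(self):
        spec = synthdata.SceneSpec(
            size_px=384, n_tubules=1, tubule_radius_um=(40, 50), seed=7
        )
        img, gt = synthdata.generate_scene(spec)
        ann = synthdata.sparse_annotations_from_truth(gt, seed=7)
        only_tubule = type(ann)(
            rois=[r for r in ann if r.class_label == "tubule"], image_id=ann.image_id
        )
        with pytest.raises(TubulopyError, match="zero annotated pixels"):
            pixelclass.train_pixel_classifier([(img, only_tubule)], seed=0)

    def test_held_out_annotation_pixels_classified_accurately(
        self, trained_classifier, eval_scene_prediction
    ):
        # annotations drawn on a scene the model never saw
        _, gt, pred = eval_scene_prediction
        ann = synthdata.sparse_annotations_from_truth(gt, seed=77)
        from tubulopy._raster import rasterise_polygon

        correct = total = 0
        for roi in ann:
            mask = rasterise_polygon(roi.polygon, gt.region_labels.shape, gt.pixel_size_um)
            correct += (pred.class_mask(roi.class_label) & mask).sum()
            total += mask.sum()
        assert correct / total >= 0.95

    def test_prediction_is_bit_identical_between_runs(
        self, trained_classifier, eval_scene_prediction
    ):
        model, _ = trained_classifier
        img, _, pred = eval_scene_prediction
        again = pixelclass.predict_pixels(model, img)
        assert np.array_equal(pred.labels, again.labels)
        assert np.array_equal(pred.probabilities, again.probabilities)

    def test_probabilities_sum_to_one(self, eval_scene_prediction):
        _, _, pred = eval_scene_prediction
        sums = pred.probabilities.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-6)
        assert np.array_equal(pred.labels, pred.probabilities.argmax(axis=-1))

    def test_different_channel_set_rejected(self, trained_classifier):
        model, _ = trained_classifier
        extra = _img(np.zeros((4, 64, 64)), ["Hoechst", "SOX9", "MAGE-A", "MVH"])
        with pytest.raises(ChannelMismatchError, match="retrain"):
            pixelclass.predict_pixels(model, extra)

    def test_model_save_load_round_trip(self, trained_classifier, tmp_path):
        model, _ = trained_classifier
        p = tmp_path / "model.json"
        model.save(p)
        back = pixelclass.PixelClassifierModel.load(p)
        assert back.classes == model.classes
        assert back.channel_names == model.channel_names
        for a, b in zip(back.coefs, model.coefs):
            assert np.array_equal(a, b)
        X = np.random.default_rng(0).normal(size=(50, len(model.feature_mean)))
        assert np.array_equal(model.predict_proba(X), back.predict_proba(X))


class TestExtractRois:
    def test_min_object_size_boundary(self):
        # at 0.5 um/px: 1600 px = 400 um2 -> kept; 1596 px = 399 um2 -> removed
        lab = np.zeros((120, 260), int)
        lab[10:50, 10:50] = 1  # 40 x 40 = 1600 px
        lab[10:48, 160:202] = 1  # 38 x 42 = 1596 px
        rois = extract_rois(_map(lab), 0.5)
        assert len(rois) == 1
        assert rois.rois[0].polygon.bounds[0] < 30  # the 400 um2 blob

    def test_min_hole_size_boundary(self):
        lab = np.zeros((300, 300), int)
        lab[10:210, 10:210] = 1
        lab[50:74, 50:75] = 0  # 600 px = 150 um2 -> filled
        lab[120:145, 120:160] = 0  # 1000 px = 250 um2 -> kept
        rois = extract_rois(_map(lab), 0.5)
        assert len(rois) == 1
        poly = rois.rois[0].polygon
        assert len(poly.interiors) == 1
        assert poly.area == pytest.approx((200 * 200 - 1000) * 0.25, rel=0.01)

    def test_all_background_gives_empty_roiset(self):
        assert len(extract_rois(_map(np.zeros((50, 50), int)), 0.5)) == 0

    def test_idempotent_on_own_rasterisation(self):
        lab = np.zeros((300, 300), int)
        lab[10:210, 10:210] = 1
        lab[120:145, 120:160] = 0
        rois = extract_rois(_map(lab), 0.5)
        ras = rasterise_rois(rois, (300, 300), 0.5, class_order=("background", "tubule"))
        rois2 = extract_rois(_map(ras), 0.5)
        assert len(rois2) == len(rois)
        a1 = sorted(r.area_um2 for r in rois)
        a2 = sorted(r.area_um2 for r in rois2)
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_total_area_monotone_in_min_object_size(self, eval_scene_prediction):
        img, _, pred = eval_scene_prediction
        areas = []
        for min_obj in (0.0, 200.0, 400.0, 2000.0, 10000.0):
            rois = extract_rois(
                pred, img.pixel_size_um, RoiExtractionConfig(min_object_area_um2=min_obj)
            )
            areas.append(sum(r.area_um2 for r in rois.by_class("tubule")))
        assert areas == sorted(areas, reverse=True)
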