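"""Shared fixtures: synthetic scenes, detections and a trained classifier.

Expensive artefacts (scene rendering, watershed detection, classifier
training) are session-scoped; tests that mutate detections must deep-copy.
"""

from __future__ import annotations

from dataclasses import replace

import pytest

from tubulopy import cellclass, cellseg, pixelclass, spatial, synthdata

DEFAULT_RULES = cellclass.ClassifierSpec(
    rules=[
        cellclass.ClassRule("SOX9", "SOX9", "nuclear", "mean", 2000.0),
        cellclass.ClassRule("MAGE-A", "MAGE-A", "nuclear", "mean", 2000.0),
    ]
)

# classifier-stage scenes are smaller than the detection-stage default so
# six trainings + predictions stay quick
CLASSIFIER_SPEC = synthdata.SceneSpec(
    size_px=640, n_tubules=2, tubule_radius_um=(40.0, 55.0), seed=100
)


@pytest.fixture(scope="session")
def default_scene():
    spec = synthdata.SceneSpec(seed=3)
    img, gt = synthdata.generate_scene(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def classified_detections(default_scene):
    """Watershed detections on ground-truth tubule ROIs, classified,
    zoned and graphed (the shared downstream substrate)."""
    _, img, gt = default_scene
    dets = cellseg.detect_cells(img, gt.tubule_roiset())
    cellclass.classify_cells(dets, DEFAULT_RULES)
    partitions = {
        r.roi_id: spatial.partition_tubule(r.polygon)
        for r in gt.tubule_roiset().by_class("tubule")
    }
    spatial.assign_regions(dets, partitions)
    graph = spatial.build_neighbour_graph(dets)
    return dets, graph, gt


@pytest.fixture(scope="session")
def trained_classifier():
    """Pixel classifier trained the way the study trained: two fully
    stained scenes plus two antibody controls per marker, three disc
    annotations per class per image."""
    training_set = []
    for i, (img, gt, _omitted) in enumerate(
        synthdata.scene_pair_with_controls(CLASSIFIER_SPEC)
    ):
        ann = synthdata.sparse_annotations_from_truth(gt, k_per_class=3, seed=1000 + i)
        training_set.append((img, ann))
    model = pixelclass.train_pixel_classifier(training_set, seed=0)
    return model, training_set


@pytest.fixture(scope="session")
def eval_scene_prediction(trained_classifier):
    """A held-out stained scene and its prediction map."""
    model, _ = trained_classifier
    img, gt = synthdata.generate_scene(replace(CLASSIFIER_SPEC, seed=200))
    pred = pixelclass.predict_pixels(model, img)
    return img, gt, pred
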