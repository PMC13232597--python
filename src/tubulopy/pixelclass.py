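"""Multiscale-feature MLP pixel classification and ROI extraction.

Pixels are described by four filter families computed per channel at a
small set of Gaussian scales — smoothed intensity, gradient magnitude
(edges), structure-tensor coherence (local orientation strength) and the
Hessian determinant (blob-likeness) — and classified into region classes
(tubule / tissue / background) by a small multilayer perceptron trained
on sparse disc annotations. Training and prediction are exactly
reproducible under a fixed seed, and a trained model refuses images whose
channel set differs from its training set: the feature vector is
channel-set-specific, so a per-marker-panel model is retrained rather
than silently misapplied.

The class prediction map is turned into measurable ROIs by connected
components with a minimum object size of 400 μm² and minimum hole size of
200 μm² (small holes are filled, small objects dropped, both inclusive
keep-if-≥).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import (
    hessian_matrix,
    structure_tensor,
    structure_tensor_eigenvalues,
)
from sklearn.neural_network import MLPClassifier

from ._raster import mask_to_polygon, rasterise_polygon
from .errors import ChannelMismatchError, TubulopyError
from .imgio import ROI, ROISet, CalibratedImage

__all__ = [
    "FeatureConfig",
    "MLPConfig",
    "RoiExtractionConfig",
    "PixelClassifierModel",
    "PredictionMap",
    "compute_feature_stack",
    "train_pixel_classifier",
    "predict_pixels",
    "extract_rois",
    "rasterise_rois",
]

FEATURE_KINDS = (
    "gaussian",
    "gradient_magnitude",
    "structure_tensor_coherence",
    "hessian_determinant",
)

DEFAULT_CLASSES = ("tubule", "tissue", "background")


@dataclass
class FeatureConfig:
    """Which filters, at which Gaussian scales, on which channels."""

    kinds: tuple[str, ...] = FEATURE_KINDS
    scales_px: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    channels: tuple[str, ...] | None = None  # None = all image channels

    def __post_init__(self) -> None:
        if not self.kinds or not self.scales_px:
            raise TubulopyError("need at least one feature kind and scale")
        bad = set(self.kinds) - set(FEATURE_KINDS)
        if bad:
            raise TubulopyError(f"unknown feature kinds: {sorted(bad)}")
        if any(s <= 0 for s in self.scales_px):
            raise TubulopyError("scales must be positive")

    def n_features(self, n_channels: int) -> int:
        return n_channels * len(self.scales_px) * len(self.kinds)


@dataclass
class MLPConfig:
    """One hidden layer of logistic units, softmax output; width defaults
    to max(32, 2 x n_features)."""

    hidden_width: int | None = None
    max_iter: int = 300
    alpha: float = 1e-4
    learning_rate_init: float = 1e-3


@dataclass
class RoiExtractionConfig:
    min_object_area_um2: float = 400.0
    min_hole_area_um2: float = 200.0
    background_class: str = "background"
    opening_um: float = 0.0  # optional morphological opening, off by default

    def __post_init__(self) -> None:
        if self.min_object_area_um2 < 0 or self.min_hole_area_um2 < 0:
            raise TubulopyError("area thresholds must be >= 0")


def _channel_features(ch: np.ndarray, sigma: float) -> dict[str, np.ndarray]:
    # reflective boundaries throughout: a flat field must give exactly
    # zero edge/orientation/blob response, padding with zeros would not
    g = ndi.gaussian_filter(ch, sigma)
    grad = ndi.gaussian_gradient_magnitude(ch, sigma)
    A = structure_tensor(ch, sigma=sigma, mode="reflect", order="rc")
    l1, l2 = structure_tensor_eigenvalues(A)
    s = l1 + l2
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(s > 0, (l1 - l2) / np.where(s > 0, s, 1.0), 0.0)
    Hrr, Hrc, Hcc = hessian_matrix(
        ch, sigma=sigma, mode="reflect", order="rc", use_gaussian_derivatives=True
    )
    hdet = Hrr * Hcc - Hrc**2
    return {
        "gaussian": g,
        "gradient_magnitude": grad,
        "structure_tensor_coherence": coherence,
        "hessian_determinant": hdet,
    }


def compute_feature_stack(
    img: CalibratedImage, cfg: FeatureConfig
) -> np.ndarray:
    """Per-pixel feature volume of shape (n_features, H, W).

    Feature order is (channel, scale, kind), all loops in config order.
    """
    channels = cfg.channels or tuple(img.channel_names)
    missing = set(channels) - set(img.channel_names)
    if missing:
        raise ChannelMismatchError(f"channels not in image: {sorted(missing)}")
    planes = []
    for name in channels:
        ch = img.channel(name).astype(float)
        for sigma in cfg.scales_px:
            feats = _channel_features(ch, sigma)
            for kind in cfg.kinds:
                planes.append(feats[kind])
    return np.stack(planes)


@dataclass
class PredictionMap:
    """Per-pixel argmax labels plus class probabilities."""

    class_names: list[str]
    labels: np.ndarray  # int, (H, W), index into class_names
    probabilities: np.ndarray  # float, (H, W, n_classes)

    def class_mask(self, class_name: str) -> np.ndarray:
        return self.labels == self.class_names.index(class_name)


@dataclass
class PixelClassifierModel:
    """Trained pixel classifier: feature config, channel contract,
    standardisation stats and MLP weights."""

    feature_config: FeatureConfig
    channel_names: list[str]
    classes: list[str]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    seed: int
    training_accuracy: float = float("nan")
    meta: dict = field(default_factory=dict)

    def _forward(self, X: np.ndarray) -> np.ndarray:
        a = X
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            a = 1.0 / (1.0 + np.exp(-(a @ W + b)))
        z = a @ self.coefs[-1] + self.intercepts[-1]
        if z.shape[1] == 1:  # binary: logistic output unit
            p1 = 1.0 / (1.0 + np.exp(-z[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.feature_mean) / self.feature_sd
        out = np.empty((X.shape[0], len(self.classes)))
        for i in range(0, X.shape[0], 262144):
            out[i : i + 262144] = self._forward(Xs[i : i + 262144])
        return out

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "tubulopy-pixel-classifier/1",
            "feature_config": {
                "kinds": list(self.feature_config.kinds),
                "scales_px": list(self.feature_config.scales_px),
                "channels": list(self.feature_config.channels)
                if self.feature_config.channels
                else None,
            },
            "channel_names": self.channel_names,
            "classes": self.classes,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "coefs": [W.tolist() for W in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "seed": self.seed,
            "training_accuracy": self.training_accuracy,
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(doc), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifierModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        fc = doc["feature_config"]
        return cls(
            feature_config=FeatureConfig(
                kinds=tuple(fc["kinds"]),
                scales_px=tuple(fc["scales_px"]),
                channels=tuple(fc["channels"]) if fc["channels"] else None,
            ),
            channel_names=doc["channel_names"],
            classes=doc["classes"],
            feature_mean=np.asarray(doc["feature_mean"]),
            feature_sd=np.asarray(doc["feature_sd"]),
            coefs=[np.asarray(W) for W in doc["coefs"]],
            intercepts=[np.asarray(b) for b in doc["intercepts"]],
            seed=doc["seed"],
            training_accuracy=doc["training_accuracy"],
            meta=doc.get("meta", {}),
        )


def _annotation_pixels(
    img: CalibratedImage, annotations: ROISet, classes: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (row, col) indices and class indices under annotation discs."""
    rows, cols, labels = [], [], []
    for roi in annotations:
        if roi.class_label not in classes:
            continue
        mask = rasterise_polygon(roi.polygon, img.shape, img.pixel_size_um)
        rr, cc = np.nonzero(mask)
        rows.append(rr)
        cols.append(cc)
        labels.append(np.full(len(rr), classes.index(roi.class_label)))
    if not rows:
        return np.empty((0,), int), np.empty((0,), int)
    return (
        np.concatenate([np.stack([r, c]) for r, c in zip(rows, cols)], axis=1),
        np.concatenate(labels),
    )


def train_pixel_classifier(
    training_set: list[tuple[CalibratedImage, ROISet]],
    feat_cfg: FeatureConfig | None = None,
    mlp_cfg: MLPConfig | None = None,
    seed: int = 0,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
) -> PixelClassifierModel:
    """Train the pixel classifier from sparse annotations.

    ``training_set`` pairs images with their annotation ROISets (typically
    three small discs per class per image, over a handful of fully stained
    and antibody-control images). All images must share one channel set.
    Features are z-scored from the training pixels; the MLP fit is
    deterministic given ``seed``.
    """
    feat_cfg = feat_cfg or FeatureConfig()
    mlp_cfg = mlp_cfg or MLPConfig()
    if not training_set:
        raise TubulopyError("empty training set")
    channel_names = list(training_set[0][0].channel_names)
    class_list = list(classes)
    X_parts, y_parts = [], []
    for img, ann in training_set:
        if list(img.channel_names) != channel_names:
            raise ChannelMismatchError(
                f"channel mismatch across training images: "
                f"{img.channel_names} vs {channel_names}"
            )
        stack = compute_feature_stack(img, feat_cfg)
        rc, y = _annotation_pixels(img, ann, class_list)
        if y.size:
            X_parts.append(stack[:, rc[0], rc[1]].T)
            y_parts.append(y)
    X = np.concatenate(X_parts) if X_parts else np.empty((0, 1))
    y = np.concatenate(y_parts) if y_parts else np.empty((0,), int)
    for i, cls in enumerate(class_list):
        if (y == i).sum() == 0:
            raise TubulopyError(f"class with zero annotated pixels: {cls!r}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    width = mlp_cfg.hidden_width or max(32, 2 * X.shape[1])
    mlp = MLPClassifier(
        hidden_layer_sizes=(width,),
        activation="logistic",
        solver="adam",
        alpha=mlp_cfg.alpha,
        learning_rate_init=mlp_cfg.learning_rate_init,
        max_iter=mlp_cfg.max_iter,
        random_state=int(seed),
        shuffle=True,
    )
    mlp.fit(Xs, y)
    model = PixelClassifierModel(
        feature_config=feat_cfg,
        channel_names=channel_names,
        classes=class_list,
        feature_mean=mean,
        feature_sd=sd,
        coefs=[np.asarray(W) for W in mlp.coefs_],
        intercepts=[np.asarray(b) for b in mlp.intercepts_],
        seed=int(seed),
        meta={"n_training_pixels": int(y.size), "hidden_width": width},
    )
    # sklearn orders output units by sorted label; our labels are already
    # 0..k-1 so columns align with class_list
    acc = (model.predict_proba(X).argmax(axis=1) == y).mean()
    model.training_accuracy = float(acc)
    return model


def predict_pixels(
    model: PixelClassifierModel, img: CalibratedImage
) -> PredictionMap:
    """Apply a trained model; refuses a different channel set."""
    if set(img.channel_names) != set(model.channel_names):
        raise ChannelMismatchError(
            f"model was trained on channels {model.channel_names}, image has "
            f"{img.channel_names}; retrain for this marker panel"
        )
    # evaluate features in the model's channel order
    cfg = FeatureConfig(
        kinds=model.feature_config.kinds,
        scales_px=model.feature_config.scales_px,
        channels=tuple(model.channel_names),
    )
    stack = compute_feature_stack(img, cfg)
    h, w = img.shape
    X = stack.reshape(stack.shape[0], -1).T
    probs = model.predict_proba(X).reshape(h, w, len(model.classes))
    labels = probs.argmax(axis=2)
    return PredictionMap(
        class_names=list(model.classes), labels=labels, probabilities=probs
    )


def extract_rois(
    pred: PredictionMap,
    pixel_size_um: float,
    cfg: RoiExtractionConfig | None = None,
    image_id: str = "image",
) -> ROISet:
    """Connected components of each non-background class, size-filtered.

    Components (8-connected) smaller than ``min_object_area_um2`` are
    dropped; interior holes smaller than ``min_hole_area_um2`` are filled
    (both thresholds inclusive: a component or hole exactly at the
    threshold survives). Area filters are applied on exact pixel-count
    areas; the recorded area/perimeter come from the traced polygon.
    """
    cfg = cfg or RoiExtractionConfig()
    px_area = pixel_size_um**2
    rois: list[ROI] = []
    rid = 0
    for cls in pred.class_names:
        if cls == cfg.background_class:
            continue
        mask = pred.class_mask(cls)
        if cfg.opening_um > 0:
            it = max(int(round(cfg.opening_um / pixel_size_um)), 1)
            mask = ndi.binary_opening(mask, iterations=it)
        labels, n = ndi.label(mask, structure=np.ones((3, 3), bool))
        for sl, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
            comp = labels[sl] == lab
            if comp.sum() * px_area < cfg.min_object_area_um2:
                continue
            filled = ndi.binary_fill_holes(comp)
            holes = filled & ~comp
            if holes.any():
                hlab, hn = ndi.label(holes)  # holes are 4-connected
                for hsl, hl in zip(ndi.find_objects(hlab), range(1, hn + 1)):
                    if (hlab[hsl] == hl).sum() * px_area >= cfg.min_hole_area_um2:
                        filled[hlab == hl] = False
            poly = mask_to_polygon(filled, pixel_size_um)
            if poly is None:
                continue
            dy = sl[0].start * pixel_size_um
            dx = sl[1].start * pixel_size_um
            from shapely.affinity import translate

            poly = translate(poly, xoff=dx, yoff=dy)
            rois.append(ROI(class_label=cls, polygon=poly, roi_id=rid))
            rid += 1
    return ROISet(rois=rois, image_id=image_id)


def refined_class_map(
    pred: PredictionMap,
    pixel_size_um: float,
    cfg: RoiExtractionConfig | None = None,
) -> np.ndarray:
    """Class raster after ROI extraction: the stage's actual segmentation.

    Applies the minimum-object and minimum-hole filters per class and
    rasterises the surviving polygons back (tubule over tissue over
    background), so isolated misclassified islands below the object size
    and speckle holes below the hole size are gone. Returns indices into
    ``pred.class_names``; unpainted pixels get the background class.
    """
    cfg = cfg or RoiExtractionConfig()
    rois = extract_rois(pred, pixel_size_um, cfg)
    shape = pred.labels.shape
    order = [cfg.background_class] + [
        c for c in pred.class_names if c != cfg.background_class
    ]
    painted = rasterise_rois(rois, shape, pixel_size_um, class_order=tuple(order))
    remap = np.array([pred.class_names.index(c) for c in order])
    return remap[painted]


def rasterise_rois(
    rois: ROISet,
    shape: tuple[int, int],
    pixel_size_um: float,
    class_order: tuple[str, ...] = ("background", "tissue", "tubule"),
) -> np.ndarray:
    """Paint ROI polygons back to a class-index raster.

    Classes are painted in ``class_order`` so later (higher-priority)
    classes overwrite earlier ones where polygons overlap; the returned
    array holds indices into ``class_order`` (0 is also the unpainted
    default).
    """
    out = np.zeros(shape, dtype=np.uint8)
    for idx, cls in enumerate(class_order):
        for roi in rois.by_class(cls):
            out[rasterise_polygon(roi.polygon, shape, pixel_size_um)] = idx
    return out
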