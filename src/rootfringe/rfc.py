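"""Random-forest pixel segmentation: the desk-scale front end.

A forest is trained on one representative annotated image and applied to
further images from the same rig.  Features are an ilastik-style bank:
per-channel raw intensity plus Gaussian-smoothed intensity and Gaussian
gradient magnitude at a small set of scales, so the feature count is
``channels * (1 + 2 * len(scales))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .errors import InputError, ModelError
from .io import VALID_LABELS, LabeledMask, RawImage

DEFAULT_SCALES = (1.0, 2.0, 4.0)
_FORMAT = "rootfringe-rfc"
_VERSION = 1


def extract_features(image: RawImage, scales=DEFAULT_SCALES) -> np.ndarray:
    """Per-pixel feature matrix, shape (H*W, channels * (1 + 2*len(scales))).

    Feature order per channel: raw, then Gaussian-smoothed at each scale,
    then gradient magnitude at each scale.
    """
    if not len(scales):
        raise InputError("need at least one feature scale")
    px = image.pixels.astype(np.float32)
    feats = []
    for ch in range(px.shape[2]):
        plane = px[:, :, ch]
        feats.append(plane)
        for s in scales:
            feats.append(ndimage.gaussian_filter(plane, s))
        for s in scales:
            feats.append(ndimage.gaussian_gradient_magnitude(plane, s))
    stack = np.stack(feats, axis=-1)
    return stack.reshape(-1, stack.shape[-1])


@dataclass
class RFCModel:
    """A trained forest plus the feature configuration it expects."""

    classifier: RandomForestClassifier | None = None
    scales: tuple = DEFAULT_SCALES
    n_features: int = 0
    training_accuracy: float = float("nan")

    def require_trained(self) -> None:
        if self.classifier is None:
            raise ModelError("model has not been trained")


def train_rfc(
    image: RawImage,
    mask: LabeledMask,
    seed: int = 0,
    scales=DEFAULT_SCALES,
    n_trees: int = 100,
    max_samples_per_class: int = 20000,
) -> RFCModel:
    """Train a per-pixel forest on one annotated image.

    All three classes must be present.  At most ``max_samples_per_class``
    pixels per class are drawn (seeded) to keep the fit fast; the
    training-image pixel accuracy of the fitted model is stored on the model.
    """
    if image.pixels.shape[:2] != mask.labels.shape:
        raise InputError("image and mask shapes differ")
    present = set(np.unique(mask.labels).tolist())
    missing = sorted(VALID_LABELS - present)
    if missing:
        raise ModelError(f"training mask lacks class(es) {missing}")

    X = extract_features(image, scales)
    y = mask.labels.ravel()
    rng = np.random.default_rng(seed)
    idx = []
    for cls in sorted(VALID_LABELS):
        where = np.flatnonzero(y == cls)
        if len(where) > max_samples_per_class:
            where = rng.choice(where, max_samples_per_class, replace=False)
        idx.append(where)
    idx = np.concatenate(idx)
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, min_samples_leaf=2
    )
    clf.fit(X[idx], y[idx])
    model = RFCModel(classifier=clf, scales=tuple(scales), n_features=X.shape[1])
    pred = predict_mask(model, image)
    model.training_accuracy = float((pred.labels == mask.labels).mean())
    return model


def predict_mask(model: RFCModel, image: RawImage) -> LabeledMask:
    """Predict a {0,1,2} mask for an image with a trained model."""
    model.require_trained()
    X = extract_features(image, model.scales)
    if X.shape[1] != model.n_features:
        raise ModelError(
            f"feature configuration mismatch: model expects {model.n_features} "
            f"features, image yields {X.shape[1]}"
        )
    pred = model.classifier.predict(X).astype(np.uint8)
    return LabeledMask(pred.reshape(image.pixels.shape[:2]))


def segmentation_scores(pred: LabeledMask, truth: LabeledMask) -> dict[int, dict[str, float]]:
    """Per-class Dice and IoU between a predicted and a reference mask.

    Dice = 2|A∩B| / (|A| + |B|), IoU = |A∩B| / |A∪B|; a class empty in both
    masks scores 1 by convention.
    """
    if pred.labels.shape != truth.labels.shape:
        raise InputError("prediction and reference shapes differ")
    out = {}
    for cls in sorted(VALID_LABELS):
        a = pred.labels == cls
        b = truth.labels == cls
        inter = int((a & b).sum())
        union = int((a | b).sum())
        size = int(a.sum()) + int(b.sum())
        if union == 0:
            out[cls] = {"dice": 1.0, "iou": 1.0}
        else:
            out[cls] = {"dice": 2.0 * inter / size, "iou": inter / union}
    return out


def save_model(model: RFCModel, path) -> None:
    model.require_trained()
    joblib.dump(
        {
            "format": _FORMAT,
            "version": _VERSION,
            "scales": model.scales,
            "n_features": model.n_features,
            "training_accuracy": model.training_accuracy,
            "classifier": model.classifier,
        },
        path,
    )


def load_model(path) -> RFCModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelError(f"cannot load RFC model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _FORMAT:
        raise ModelError(f"{path} is not a {_FORMAT} model file")
    return RFCModel(
        classifier=payload["classifier"],
        scales=tuple(payload["scales"]),
        n_features=int(payload["n_features"]),
        training_accuracy=float(payload["training_accuracy"]),
    )
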