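"""Semi-supervised pixelwise colour segmentation of canopy images.

Each pixel is represented by six colour coordinates — its RGB channels and
its CIELAB coordinates (sRGB primaries, D65 white point, channels scaled
from [0, 255], the convention of the common conversion implementations) —
and classified into one of the seven canopy classes by an unregularised
multinomial logistic regression.  The model is parameterised relative to a
reference class n: for classes i = 1..n-1,

    pi_i = exp(b_i0 + sum_j b_ij x_j) / (1 + sum_l exp(b_l0 + sum_j b_lj x_j))
    pi_n = 1 / (1 + sum_l exp(...)) = 1 - sum_l pi_l

One model is intended per image set (variety/vineyard): colour calibration
does not transfer between acquisition conditions, so pooling sets degrades
the segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab
from sklearn.linear_model import LogisticRegression

from .fixtures import CLASS_NAMES

__all__ = [
    "MLRModel",
    "SegmentationMap",
    "pixel_features",
    "predict_probabilities",
    "segment",
    "train_mlr",
]

_N_FEATURES = 6


def pixel_features(image: np.ndarray, coords=None) -> np.ndarray:
    """6-d colour features [R, G, B, L, a, b] for pixels of an RGB image.

    Parameters
    ----------
    image : (H, W, 3) uint8 array
    coords : (n, 2) array of (row, col), optional
        If omitted, features for every pixel are returned as (H*W, 6) in
        row-major order.

    Raises
    ------
    IndexError
        For an out-of-bounds coordinate; the message carries its index.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be (H, W, 3) RGB")
    lab = rgb2lab(image)  # sRGB / D65
    rgb = image.astype(float)
    if coords is None:
        return np.concatenate(
            [rgb.reshape(-1, 3), lab.reshape(-1, 3)], axis=1
        )
    coords = np.asarray(coords, dtype=int)
    h, w = image.shape[:2]
    for idx, (r, c) in enumerate(coords):
        if not (0 <= r < h and 0 <= c < w):
            raise IndexError(
                f"coordinate {idx} = ({r}, {c}) outside {h}x{w} image"
            )
    return np.concatenate(
        [rgb[coords[:, 0], coords[:, 1]], lab[coords[:, 0], coords[:, 1]]], axis=1
    )


@dataclass
class MLRModel:
    """Multinomial logistic regression in reference-class parameterisation.

    ``coefficients`` is (n_classes - 1, 7): column 0 holds the intercepts
    b_i0 and columns 1..6 the weights on the standardised 6-d colour
    feature; the reference class has implicit all-zero coefficients.
    ``feature_mean``/``feature_scale`` is the affine standardisation fitted
    on the training pixels and applied before the linear predictor.
    """

    class_names: tuple[str, ...]
    reference_class: str
    coefficients: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.class_names)
        if self.reference_class not in self.class_names:
            raise ValueError("reference class must be one of class_names")
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (n - 1, _N_FEATURES + 1):
            raise ValueError(
                f"coefficients must be ({n - 1}, {_N_FEATURES + 1})"
            )

    @property
    def nonreference_classes(self) -> tuple[str, ...]:
        return tuple(c for c in self.class_names if c != self.reference_class)


def train_mlr(
    features: np.ndarray,
    labels: np.ndarray,
    class_names: tuple[str, ...] = CLASS_NAMES,
    reference_class: str | None = None,
    *,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> MLRModel:
    """Fit the multinomial logistic model on labelled pixel features.

    ``labels`` are class indices into ``class_names``.  The fit maximises
    the multinomial log-likelihood (optionally with a small ridge penalty
    for separable degenerate inputs, off by default).  Features are
    standardised to zero mean / unit variance from the training pixels; the
    transform is stored in the model so prediction is self-contained.

    The reference class defaults to the last listed class ("trellis" in the
    canonical order) — the choice is arbitrary and does not affect the
    predicted probabilities.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or features.shape[1] != _N_FEATURES:
        raise ValueError(f"features must be (n, {_N_FEATURES})")
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("training requires at least 2 classes")
    if reference_class is None:
        reference_class = class_names[-1]

    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    scale[scale == 0] = 1.0
    z = (features - mean) / scale

    c_value = 1.0 / ridge if ridge > 0 else np.inf  # C=inf: plain ML fit
    clf = LogisticRegression(C=c_value, tol=tol, max_iter=max_iter)
    clf.fit(z, labels)

    # expand to the full class list (classes absent from training keep -inf
    # logits via very negative intercepts is NOT done: absent classes are an
    # error for the 7-class pipeline, but 2-class toy fits are allowed)
    n = len(class_names)
    full_coef = np.zeros((n, _N_FEATURES + 1))
    fitted = {int(c): i for i, c in enumerate(clf.classes_)}
    trained_mask = np.zeros(n, bool)
    for ci in range(n):
        if ci in fitted:
            i = fitted[ci]
            if clf.classes_.size == 2:
                # sklearn stores a single logit row (second class vs first)
                if i == 1:
                    full_coef[ci, 0] = clf.intercept_[0]
                    full_coef[ci, 1:] = clf.coef_[0]
            else:
                full_coef[ci, 0] = clf.intercept_[i]
                full_coef[ci, 1:] = clf.coef_[i]
            trained_mask[ci] = True
    if not trained_mask.all():
        missing = [class_names[i] for i in range(n) if not trained_mask[i]]
        if set(class_names) == set(CLASS_NAMES) and len(missing) > 0:
            raise ValueError(f"classes missing from training data: {missing}")
    # re-express relative to the reference class
    ref_idx = class_names.index(reference_class)
    rel = full_coef - full_coef[ref_idx]
    coefficients = np.delete(rel, ref_idx, axis=0)
    return MLRModel(
        class_names=tuple(class_names),
        reference_class=reference_class,
        coefficients=coefficients,
        feature_mean=mean,
        feature_scale=scale,
    )


def predict_probabilities(model: MLRModel, features: np.ndarray) -> np.ndarray:
    """Class probabilities for 6-d colour features, in ``class_names`` order.

    Probabilities are positive and sum to 1 within 1e-9 per sample; the
    reference class receives 1 - sum of the others.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != _N_FEATURES:
        raise ValueError(f"feature length must be {_N_FEATURES}")
    z = (features - model.feature_mean) / model.feature_scale
    eta = model.coefficients[:, 0] + z @ model.coefficients[:, 1:].T  # (n, c-1)
    # softmax over [eta_1..eta_{c-1}, 0] evaluated stably
    full = np.concatenate([eta, np.zeros((eta.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    probs_relative = e / e.sum(axis=1, keepdims=True)
    # reinsert the reference class at its canonical position
    ref_idx = model.class_names.index(model.reference_class)
    out = np.empty((features.shape[0], len(model.class_names)))
    nonref = [i for i in range(len(model.class_names)) if i != ref_idx]
    out[:, nonref] = probs_relative[:, :-1]
    out[:, ref_idx] = probs_relative[:, -1]
    return out


@dataclass
class SegmentationMap:
    """Per-pixel class labels with the full probability layers."""

    labels: np.ndarray  # (H, W) uint8 index into class_names
    probabilities: np.ndarray  # (H, W, n_classes)
    class_names: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def segment(model: MLRModel, image: np.ndarray) -> SegmentationMap:
    """Label every pixel with its maximal-probability class.

    Ties break to the lowest class index in the canonical order; the result
    is deterministic for fixed inputs.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image must be non-empty")
    h, w = image.shape[:2]
    feats = pixel_features(image)
    probs = predict_probabilities(model, feats)
    labels = np.argmax(probs, axis=1).astype(np.uint8)  # argmax -> lowest index on ties
    return SegmentationMap(
        labels=labels.reshape(h, w),
        probabilities=probs.reshape(h, w, -1),
        class_names=model.class_names,
    )
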