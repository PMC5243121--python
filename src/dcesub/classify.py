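"""Soft-margin RBF-kernel SVM voxel classification with posterior probabilities.

The classifier solves the usual soft-margin objective — minimize
||w||^2 / 2 + C * sum(xi_i) subject to y_i (w.x_i + b) >= 1 - xi_i — with a
radial-basis-function kernel exp(-gamma |x_i - x_j|^2), at the working point
C = 200, gamma = 0.2.  Decision values are mapped to posterior class
probabilities by a cross-validated Platt-type sigmoid, and a voxel is
assigned to the low-blood-volume class when P(c-LBV) exceeds 0.5 strictly.
Features are z-scored with training statistics before both training and
prediction.  Training sets are stratified-subsampled to a per-class cap so
desk-scale RBF training stays tractable on large curve collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LBV_CLASS",
    "HBV_CLASS",
    "TrainedClassifier",
    "train_svm",
    "predict_proba",
    "assign_labels",
]

#: Label conventions: 0 = low blood volume (c-LBV), 1 = high blood volume.
LBV_CLASS = 0
HBV_CLASS = 1

DEFAULT_C = 200.0
DEFAULT_GAMMA = 0.2
DEFAULT_PER_CLASS_CAP = 20_000


@dataclass
class TrainedClassifier:
    """A trained, calibrated SVM plus its standardization statistics.

    ``svc`` is a cross-validation-calibrated wrapper around the RBF SVC: the
    decision values of out-of-fold predictions are mapped to posterior
    probabilities by a fitted sigmoid, then a single calibrated model is kept.
    """

    scaler: StandardScaler
    svc: CalibratedClassifierCV
    C: float
    gamma: float
    seed: int
    n_features: int

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Posterior probability of c-LBV for each row of ``features``."""
        return predict_proba(self, features)


def _stratified_cap(labels: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    keep = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    *,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
    per_class_cap: int = DEFAULT_PER_CLASS_CAP,
    class_weight=None,
) -> TrainedClassifier:
    """Train the calibrated RBF SVM on (n_samples, k) features with binary labels."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("features must be a 2-D matrix with at least one column")
    if len(y) != x.shape[0]:
        raise ValueError("labels length must match features")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate-labels: both classes must be present")
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")

    rng = np.random.default_rng(seed)
    keep = _stratified_cap(y, per_class_cap, rng)
    x, y = x[keep], y[keep]

    scaler = StandardScaler().fit(x)
    base = SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weight)
    counts = np.bincount(np.searchsorted(np.unique(y), y))
    cv = int(min(5, counts.min()))
    if cv < 2:
        raise ValueError("degenerate-labels: need at least 2 samples per class")
    svc = CalibratedClassifierCV(base, method="sigmoid", cv=cv, ensemble=False)
    svc.fit(scaler.transform(x), y)
    return TrainedClassifier(
        scaler=scaler, svc=svc, C=C, gamma=gamma, seed=int(seed), n_features=x.shape[1]
    )


def predict_proba(model: TrainedClassifier, features: np.ndarray) -> np.ndarray:
    """Posterior P(c-LBV) per sample; P(c-LBV) + P(c-HBV) = 1 by construction."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.n_features:
        raise ValueError("feature dimension does not match the trained model")
    proba = model.svc.predict_proba(model.scaler.transform(x))
    col = int(np.flatnonzero(model.svc.classes_ == LBV_CLASS)[0])
    return proba[:, col]


def assign_labels(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Assign c-LBV where P(c-LBV) strictly exceeds the threshold.

    A probability exactly at the threshold is assigned c-HBV ("> 0.5 or not").
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.where(p > threshold, LBV_CLASS, HBV_CLASS).astype(np.int8)
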