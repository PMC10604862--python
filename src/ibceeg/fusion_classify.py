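"""Linear-SVM classifiers with probability outputs, fused at decision level.

One classifier is trained per feature space (the raw DE features and the IBC
features).  Each is a linear-kernel max-margin classifier whose per-class
probabilities come from Platt-style sigmoid calibration fitted by internal
cross-validation on the training fold.  Decision-level fusion sums the two
probability vectors per epoch (optionally weighted) and predicts the class
with the largest sum; exact ties break to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["ProbabilisticClassifier", "FusionResult", "train_classifier", "predict_proba", "fuse"]


@dataclass
class ProbabilisticClassifier:
    """A fitted linear-SVM + Platt-calibration pipeline with its feature
    standardization, tagged by the feature space it was trained on."""

    pipeline: Pipeline
    feature_tag: str
    class_count: int
    n_features: int

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return predict_proba(self, features)

    def predict(self, features: np.ndarray) -> np.ndarray:
        p = predict_proba(self, features)
        return np.argmax(p, axis=1)


@dataclass
class FusionResult:
    """Per-epoch probabilities of both classifiers and the fused labels."""

    p_de: np.ndarray
    p_ibc: np.ndarray
    fused_label: np.ndarray
    label_de: np.ndarray
    label_ibc: np.ndarray
    weights: tuple[float, float]


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    c: int | None = None,
    seed: int = 0,
    cost: float = 1.0,
    feature_tag: str = "DE",
) -> ProbabilisticClassifier:
    """Train a linear-kernel SVM with calibrated class probabilities.

    Features are standardized internally (offsets/scales stored in the
    pipeline and reused at prediction time).  ``cost`` is the SVM penalty C.
    Every class 0..c-1 must appear in ``labels``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or features.shape[0] != len(labels):
        raise ValueError("features must be (n, d) row-aligned with labels")
    present = np.unique(labels)
    if c is None:
        c = int(present.max()) + 1
    missing = sorted(set(range(c)) - set(present.tolist()))
    if missing:
        raise ValueError(f"class(es) {missing} absent from training labels")
    if features.shape[0] < c:
        raise ValueError("need at least one sample per class")

    # Platt sigmoid calibration fitted by internal stratified CV on the
    # training fold; the fold split is the only randomness, seeded below.
    n_folds = min(5, int(np.min(np.bincount(labels, minlength=c))), features.shape[0])
    calibrated = CalibratedClassifierCV(
        SVC(kernel="linear", C=cost),
        method="sigmoid",
        cv=StratifiedKFold(n_splits=max(2, n_folds), shuffle=True, random_state=seed),
        ensemble=False,
    )
    pipeline = Pipeline([("scale", StandardScaler()), ("svm", calibrated)])
    pipeline.fit(features, labels)
    return ProbabilisticClassifier(
        pipeline=pipeline,
        feature_tag=feature_tag,
        class_count=c,
        n_features=features.shape[1],
    )


def predict_proba(clf: ProbabilisticClassifier, features: np.ndarray) -> np.ndarray:
    """Per-class probability rows (non-negative, summing to 1) in class order
    0..c-1; an empty input yields an empty (0, c) matrix."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != clf.n_features:
        raise ValueError(
            f"expected {clf.n_features} features, got shape {features.shape}"
        )
    if features.shape[0] == 0:
        return np.empty((0, clf.class_count))
    raw = clf.pipeline.predict_proba(features)
    # place columns at class indices (classes_ is sorted but may be a subset
    # of 0..c-1 only when c was given explicitly; guard anyway)
    out = np.zeros((features.shape[0], clf.class_count))
    classes = clf.pipeline.named_steps["svm"].classes_
    out[:, classes] = raw
    return out


def fuse(
    p_de: np.ndarray,
    p_ibc: np.ndarray,
    weights: tuple[float, float] = (1.0, 1.0),
) -> FusionResult:
    """Sum-rule decision fusion: label = argmax_k (w1*p_de + w2*p_ibc).

    Ties break to the lowest class index (np.argmax's first-maximum rule).
    """
    p_de = np.asarray(p_de, dtype=float)
    p_ibc = np.asarray(p_ibc, dtype=float)
    if p_de.shape != p_ibc.shape:
        raise ValueError(f"shape mismatch: {p_de.shape} vs {p_ibc.shape}")
    if np.any(p_de < 0) or np.any(p_ibc < 0):
        raise ValueError("probability matrices must be non-negative")
    w1, w2 = weights
    fused = w1 * p_de + w2 * p_ibc
    return FusionResult(
        p_de=p_de,
        p_ibc=p_ibc,
        fused_label=np.argmax(fused, axis=1),
        label_de=np.argmax(p_de, axis=1),
        label_ibc=np.argmax(p_ibc, axis=1),
        weights=(float(w1), float(w2)),
    )
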