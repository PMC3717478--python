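"""Reference-pattern-based activity classification.

Each child performs a short protocol of known activities while wearing
the device; a multiclass support-vector machine with an RBF kernel is
trained on that child's own labeled frames (an *individual* model), so
the child's idiosyncratic movement signature is learned.  A *general*
model pooled over all participating children covers children without a
reference session.  Hyperparameters follow the common library defaults
(regularization weight C = 1, kernel width gamma = 1/n_features = 1/12,
one-vs-one voting with deterministic tie-break by class order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import EPOCH_SECONDS, LabeledEpochs
from .frames import FEATURE_COLUMNS
from .kinds import ALL_KINDS, ActivityKind

__all__ = [
    "ReferenceSet", "ClassifierModel", "train_model", "select_model",
    "predict_epochs", "save_model", "load_model",
]

N_FEATURES = len(FEATURE_COLUMNS)
MIN_FRAMES_PER_CLASS = 5


@dataclass
class ReferenceSet:
    """Labeled training frames for one child (or the pooled set)."""

    child_id: str  # "pooled" for the general model
    features: np.ndarray  # (n, 12)
    labels: np.ndarray  # ActivityKind codes, (n,)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise ValueError(f"features must have shape (n, {N_FEATURES})")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels must have the same length")

    @classmethod
    def from_session(cls, features: pd.DataFrame, epochs: LabeledEpochs) -> "ReferenceSet":
        """Build a reference set from a feature table and aligned labels."""
        X = features[list(FEATURE_COLUMNS)].to_numpy(float)
        if len(X) != len(epochs):
            raise ValueError("feature table and epoch labels are not aligned")
        return cls(epochs.child_id, X, epochs.labels)

    @staticmethod
    def pooled(refsets: "list[ReferenceSet]") -> "ReferenceSet":
        """Concatenate several children's reference sets."""
        return ReferenceSet(
            "pooled",
            np.vstack([r.features for r in refsets]),
            np.concatenate([r.labels for r in refsets]),
        )


@dataclass
class ClassifierModel:
    """A fitted activity classifier: standardization + RBF-SVM."""

    scope: str  # "individual" or "general"
    child_id: str
    scaler: StandardScaler
    svc: SVC
    hyperparameters: dict
    training_accuracy: float
    # retained for persistence (the saved file stores training data and
    # hyperparameters; loading refits, which is deterministic)
    _train_X: np.ndarray = field(repr=False, default=None)
    _train_y: np.ndarray = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"expected feature vectors of length {N_FEATURES}")
        if len(X) == 0:
            return np.empty(0, dtype=np.int8)
        return self.svc.predict(self.scaler.transform(X)).astype(np.int8)


def train_model(
    refset: ReferenceSet,
    C: float = 1.0,
    gamma: float = 1.0 / N_FEATURES,
    kernel: str = "rbf",
    scope: str | None = None,
) -> ClassifierModel:
    """Train a standardized RBF-SVM on a reference set.

    All seven classes must be present with at least 5 frames each.
    Standardization (zero mean, unit scale; zero-variance features keep
    unit scale) is fitted on the training data only and frozen.
    """
    present, counts = np.unique(refset.labels, return_counts=True)
    missing = set(k.value for k in ALL_KINDS) - set(present.tolist())
    if missing:
        names = sorted(ActivityKind(m).name for m in missing)
        raise ValueError(f"missing class in reference set: {names}")
    thin = {ActivityKind(k).name: int(c) for k, c in zip(present, counts)
            if c < MIN_FRAMES_PER_CLASS}
    if thin:
        raise ValueError(f"fewer than {MIN_FRAMES_PER_CLASS} frames for: {thin}")
    scaler = StandardScaler().fit(refset.features)
    svc = SVC(C=C, gamma=gamma, kernel=kernel, decision_function_shape="ovo")
    Xs = scaler.transform(refset.features)
    svc.fit(Xs, refset.labels)
    acc = float((svc.predict(Xs) == refset.labels).mean())
    return ClassifierModel(
        scope=scope or ("general" if refset.child_id == "pooled" else "individual"),
        child_id=refset.child_id,
        scaler=scaler,
        svc=svc,
        hyperparameters={"kernel": kernel, "C": C, "gamma": gamma},
        training_accuracy=acc,
        _train_X=refset.features,
        _train_y=refset.labels,
    )


def select_model(
    child_id: str,
    individual_models: dict[str, ClassifierModel],
    general_model: ClassifierModel,
) -> ClassifierModel:
    """The child's own model when a reference session exists, else the
    pooled general model."""
    if general_model is None:
        raise ValueError("a general model is required")
    return individual_models.get(child_id, general_model)


def predict_epochs(model: ClassifierModel, features: pd.DataFrame) -> LabeledEpochs:
    """Label every frame of a feature table; one label per 2.5 s epoch,
    in frame order."""
    X = features[list(FEATURE_COLUMNS)].to_numpy(float)
    labels = model.predict(X)
    child = str(features["child_id"].iloc[0]) if len(features) else model.child_id
    start = features["start_time"].iloc[0] if len(features) else pd.Timestamp(0)
    return LabeledEpochs(child, start, labels, epoch_s=EPOCH_SECONDS)


_FORMAT_VERSION = 1


def save_model(model: ClassifierModel, path) -> None:
    """Persist a model as a self-describing versioned JSON file.

    The file stores hyperparameters and the training set; loading refits
    the (deterministic) SVM, so the stored form is independent of the
    fitting library's internal representation.
    """
    if model._train_X is None:
        raise ValueError("model was not created by train_model; cannot persist")
    doc = {
        "format": "actiflux-classifier",
        "version": _FORMAT_VERSION,
        "scope": model.scope,
        "child_id": model.child_id,
        "hyperparameters": model.hyperparameters,
        "training_features": model._train_X.tolist(),
        "training_labels": model._train_y.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ClassifierModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "actiflux-classifier" or doc.get("version") != _FORMAT_VERSION:
        raise ValueError("unrecognized model file format")
    refset = ReferenceSet(
        doc["child_id"],
        np.array(doc["training_features"], dtype=float),
        np.array(doc["training_labels"], dtype=np.int8),
    )
    hp = doc["hyperparameters"]
    return train_model(refset, C=hp["C"], gamma=hp["gamma"], kernel=hp["kernel"],
                       scope=doc["scope"])
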