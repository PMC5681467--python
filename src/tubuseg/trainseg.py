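"""Random-forest voxel classification from sparse manual labels.

A handful of annotated slices — a few airways and vessels marked as
foreground (wall plus lumen, since the enclosed edges are the easiest
evidence for filter banks) and a few background regions — are enough to
train a forest that is then applied to every block of the scan.  The
output is a per-voxel probability of belonging to the foreground class;
lumen voxels picked up because walls were annotated with their interior
are removed later by intensity refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .blockstore import Volume
from .features import FeatureSpec, build_feature_stack

__all__ = [
    "LabelSet",
    "ClassifierModel",
    "FingerprintMismatchError",
    "extract_training_set",
    "train_classifier",
    "predict_block",
    "save_model",
    "load_model",
]

DEFAULT_CLASSES = ("background", "vessel")


class FingerprintMismatchError(RuntimeError):
    """Feature spec used for prediction differs from the training one."""


@dataclass
class LabelSet:
    """Sparse voxel annotations: (z, y, x) coordinates with class ids.

    Class 0 is background; class 1 is the foreground (vessel/airway wall
    including the lumen).  Duplicate coordinates are retained as duplicate
    training samples.
    """

    z: np.ndarray
    y: np.ndarray
    x: np.ndarray
    class_id: np.ndarray
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.int64)
        self.class_id = np.asarray(self.class_id, dtype=np.int64)
        n = len(self.z)
        if not (len(self.y) == len(self.x) == len(self.class_id) == n):
            raise ValueError("label coordinate arrays must have equal length")

    def __len__(self) -> int:
        return len(self.z)

    @classmethod
    def from_table(cls, path: str | Path,
                   classes: tuple[str, ...] = DEFAULT_CLASSES) -> "LabelSet":
        """Read a plain-text table with columns z y x class (whitespace- or
        comma-separated; lines starting with # are ignored)."""
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if parts[0].lower() in ("z", "slice"):
                continue
            rows.append([int(float(v)) for v in parts[:4]])
        arr = np.asarray(rows, dtype=np.int64).reshape(-1, 4)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], classes=classes)

    def to_table(self, path: str | Path) -> None:
        lines = ["# z y x class"]
        lines += [f"{z} {y} {x} {c}" for z, y, x, c
                  in zip(self.z, self.y, self.x, self.class_id)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_label_volume(cls, labels: np.ndarray,
                          classes: tuple[str, ...] = DEFAULT_CLASSES) -> "LabelSet":
        """Build from a label volume where 0 = unlabeled and 1..K map to
        class ids 0..K-1."""
        zz, yy, xx = np.nonzero(labels)
        return cls(zz, yy, xx, labels[zz, yy, xx] - 1, classes=classes)


@dataclass
class ClassifierModel:
    """A trained forest bound to the feature spec it was trained with."""

    forest: RandomForestClassifier
    classes: tuple[str, ...]
    spec_fingerprint: str
    n_trees: int
    seed: int
    samples_per_class: dict[int, int] = field(default_factory=dict)


def extract_training_set(volume: Volume, labels: LabelSet,
                         spec: FeatureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Compute feature vectors for every labelled voxel.

    Features are computed only on the slices that carry labels, never on
    the whole volume.  Returns (X, y) with one row per label entry, in
    label order; duplicates are retained.
    """
    nz, ny, nx = volume.dims
    for i, (z, y, x) in enumerate(zip(labels.z, labels.y, labels.x)):
        if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
            raise IndexError(
                f"label entry {i} at (z={z}, y={y}, x={x}) lies outside "
                f"volume dims {volume.dims}")
    X = np.empty((len(labels), spec.feature_count()), dtype=np.float32)
    for z in np.unique(labels.z):
        stack = build_feature_stack(volume.data[z], spec)
        sel = labels.z == z
        X[sel] = stack.data[labels.y[sel], labels.x[sel]]
    return X, labels.class_id.copy()


def train_classifier(X: np.ndarray, y: np.ndarray, n_trees: int = 200,
                     seed: int = 17, spec: FeatureSpec | None = None,
                     classes: Sequence[str] = DEFAULT_CLASSES) -> ClassifierModel:
    """Train a random forest on labelled feature vectors.

    Deterministic given (X, y, n_trees, seed).  Labels are used exactly as
    given — no resampling or class balancing, matching the small curated
    label sets this workflow relies on.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError(
            f"training needs >= 2 classes, got only class(es) {present.tolist()}")
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1)
    forest.fit(X, y)
    counts = {int(c): int((y == c).sum()) for c in present}
    fp = spec.fingerprint() if spec is not None else ""
    return ClassifierModel(forest=forest, classes=tuple(classes),
                           spec_fingerprint=fp, n_trees=n_trees, seed=seed,
                           samples_per_class=counts)


def predict_proba_block(block: np.ndarray, model: ClassifierModel,
                        spec: FeatureSpec) -> np.ndarray:
    """Per-voxel class probabilities, shape block.shape + (n_classes,).

    Probabilities are the soft votes averaged over trees and sum to 1 per
    voxel.  Refuses feature specs whose fingerprint differs from the one
    the model was trained with.
    """
    if model.spec_fingerprint and spec.fingerprint() != model.spec_fingerprint:
        raise FingerprintMismatchError(
            "feature spec fingerprint differs from the model's training spec")
    stack = build_feature_stack(block, spec)
    proba = model.forest.predict_proba(stack.as_matrix())
    return proba.reshape(stack.data.shape[:-1] + (proba.shape[1],))


def predict_block(block: np.ndarray, model: ClassifierModel,
                  spec: FeatureSpec, foreground_class: int = 1) -> np.ndarray:
    """Foreground probability map for one block (values in [0, 1])."""
    proba = predict_proba_block(block, model, spec)
    cls_index = list(model.forest.classes_).index(foreground_class)
    return proba[..., cls_index]


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Persist the forest with its fingerprint and seed in one archive."""
    joblib.dump({
        "forest": model.forest,
        "classes": model.classes,
        "spec_fingerprint": model.spec_fingerprint,
        "n_trees": model.n_trees,
        "seed": model.seed,
        "samples_per_class": model.samples_per_class,
    }, path)


def load_model(path: str | Path) -> ClassifierModel:
    d = joblib.load(path)
    return ClassifierModel(forest=d["forest"], classes=tuple(d["classes"]),
                           spec_fingerprint=d["spec_fingerprint"],
                           n_trees=d["n_trees"], seed=d["seed"],
                           samples_per_class=d["samples_per_class"])
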