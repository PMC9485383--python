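"""Per-pixel feature fusion and decision-tree classification.

For every ROI pixel a 7-element descriptor is assembled — the 4 network
score-map values (background, edema, necrosis, enhancing) followed by
the 3 windowed texture values (ASM, contrast, correlation) — and fed to
an axis-aligned decision tree. Predicted class indices are mapped back
to BRATS labels inside the ROI; pixels outside the ROI are never
classified and stay 0.

The tree is scikit-learn's CART; it is serialized to a plain JSON node
list so an independent traversal can replay its decisions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .exceptions import FusionError, TrainingError
from .preprocess import from_class_index

FEATURE_NAMES = (
    "score_background",
    "score_edema",
    "score_necrosis",
    "score_enhancing",
    "asm",
    "contrast",
    "correlation",
)


@dataclass
class DTConfig:
    """Decision-tree hyperparameters; depth 100 is the default "fine tree"."""

    d_tree: int = 100
    split_criterion: str = "gini"
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.d_tree < 1:
            raise FusionError("d_tree must be >= 1")


@dataclass
class FeatureTable:
    """Row-major per-pixel feature vectors over an ROI."""

    features: np.ndarray  # (N, 7)
    pixels: np.ndarray  # (N, 2) (y, x), row-major order
    labels: Optional[np.ndarray] = None  # (N,) class indices, when GT given
    subject_id: Optional[str] = None


def assemble_features(
    score_maps: np.ndarray,
    texture_maps: np.ndarray,
    roi_mask: np.ndarray,
    gt_class_index: Optional[np.ndarray] = None,
    subject_id: Optional[str] = None,
) -> FeatureTable:
    """One 7-vector per true ROI pixel, in row-major pixel order."""
    score_maps = np.asarray(score_maps, dtype=np.float64)
    texture_maps = np.asarray(texture_maps, dtype=np.float64)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    shape = roi_mask.shape
    if score_maps.shape != (4, *shape) or texture_maps.shape != (3, *shape):
        raise FusionError(
            f"raster shapes disagree: scores {score_maps.shape}, "
            f"texture {texture_maps.shape}, roi {shape}"
        )
    ys, xs = np.nonzero(roi_mask)
    features = np.concatenate(
        [score_maps[:, ys, xs], texture_maps[:, ys, xs]]
    ).T.copy()
    if not np.all(np.isfinite(features)):
        raise FusionError("non-finite feature values")
    labels = None
    if gt_class_index is not None:
        gt_class_index = np.asarray(gt_class_index)
        if gt_class_index.shape != shape:
            raise FusionError("ground-truth shape does not match ROI")
        labels = gt_class_index[ys, xs]
    return FeatureTable(
        features=features,
        pixels=np.stack([ys, xs], axis=1),
        labels=labels,
        subject_id=subject_id,
    )


@dataclass
class TrainedTree:
    tree: DecisionTreeClassifier
    config: DTConfig
    train_accuracy: float
    classes: np.ndarray = field(default_factory=lambda: np.arange(4))


def train_dt(
    features: np.ndarray, labels: np.ndarray, config: DTConfig = DTConfig()
) -> TrainedTree:
    """Fit an axis-aligned tree of depth <= d_tree on pooled pixel vectors."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    present = np.unique(labels)
    if present.size < 2:
        missing = sorted(set(range(4)) - set(present.tolist()))
        raise TrainingError(
            f"decision tree needs >= 2 classes; only {present.tolist()} present, "
            f"missing {missing}"
        )
    tree = DecisionTreeClassifier(
        max_depth=config.d_tree,
        criterion=config.split_criterion,
        min_samples_leaf=config.min_leaf,
        random_state=config.seed,
    )
    tree.fit(features, labels)
    acc = float((tree.predict(features) == labels).mean())
    return TrainedTree(
        tree=tree, config=config, train_accuracy=acc, classes=tree.classes_
    )


def classify_pixels(trained: TrainedTree, features: np.ndarray) -> np.ndarray:
    """Class index per vector; empty input yields empty output."""
    features = np.asarray(features, dtype=np.float64)
    if features.size == 0:
        return np.zeros(0, dtype=np.int64)
    if features.ndim != 2 or features.shape[1] != len(FEATURE_NAMES):
        raise FusionError(
            f"expected (N, {len(FEATURE_NAMES)}) feature matrix, got {features.shape}"
        )
    return trained.tree.predict(features).astype(np.int64)


def reconstruct_label_map(
    classes: np.ndarray, roi_mask: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Scatter per-pixel class indices back to a BRATS label raster.

    ``classes`` must be in the same row-major ROI order that
    :func:`assemble_features` produced.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    classes = np.asarray(classes)
    if roi_mask.shape != tuple(shape):
        raise FusionError("roi_mask shape does not match requested shape")
    n_roi = int(roi_mask.sum())
    if classes.shape != (n_roi,):
        raise FusionError(f"got {classes.shape[0] if classes.ndim else 0} classes "
                          f"for {n_roi} ROI pixels")
    out = np.zeros(shape, dtype=np.int64)
    if n_roi:
        ys, xs = np.nonzero(roi_mask)
        out[ys, xs] = from_class_index(classes)
    return out


# -- portable serialization ------------------------------------------------


def tree_to_dict(trained: TrainedTree) -> dict:
    """Flat node-list form of the fitted tree (JSON-serializable)."""
    t = trained.tree.tree_
    return {
        "feature_names": list(FEATURE_NAMES),
        "classes": trained.classes.tolist(),
        "config": trained.config.__dict__.copy(),
        "train_accuracy": trained.train_accuracy,
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value[:, 0, :].tolist(),
    }


def save_tree(trained: TrainedTree, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(tree_to_dict(trained)) + "\n")


def descend_tree(doc: dict, vector: np.ndarray) -> int:
    """Classify one vector by walking a serialized tree (reference path).

    Mirrors CART's rule: go left when ``x[feature] <= threshold``.
    """
    node = 0
    while doc["children_left"][node] != -1:
        if vector[doc["feature"][node]] <= doc["threshold"][node]:
            node = doc["children_left"][node]
        else:
            node = doc["children_right"][node]
    return int(doc["classes"][int(np.argmax(doc["value"][node]))])
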