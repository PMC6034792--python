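"""Random-forest pixel classification of avascular vs vascularized tissue.

The model is trained on annotated pixels only (balanced subsampling up to
a per-class cap) and predicts a per-pixel avascular probability as the
forest vote fraction. Everything is deterministic given the config seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from octaquant.errors import ValidationError
from octaquant.feature_bank import FeatureStack
from octaquant.octa_io import (
    LABEL_AVASCULAR,
    LABEL_VASCULAR,
    AnnotationSet,
    PipelineConfig,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: class order used throughout: index 0 = avascular, index 1 = vascular
CLASS_ORDER = ("avascular", "vascular")


@dataclass
class ClassifierModel:
    """A fitted pixel classifier plus the metadata needed to audit it."""

    forest: RandomForestClassifier
    feature_names: list[str]
    seed: int
    training_accuracy: float = float("nan")
    oob_accuracy: float | None = None

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "forest": self.forest,
                "feature_names": self.feature_names,
                "seed": self.seed,
                "training_accuracy": self.training_accuracy,
                "oob_accuracy": self.oob_accuracy,
            },
            Path(path),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        payload = joblib.load(Path(path))
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValidationError(
                f"unsupported model format version {payload.get('format_version')}"
            )
        return cls(
            forest=payload["forest"],
            feature_names=payload["feature_names"],
            seed=payload["seed"],
            training_accuracy=payload["training_accuracy"],
            oob_accuracy=payload["oob_accuracy"],
        )


@dataclass
class SegmentationMask:
    """Binary avascular mask plus the probability map it was thresholded from."""

    mask: np.ndarray
    probability: np.ndarray
    threshold: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.probability = np.asarray(self.probability, dtype=np.float64)
        if self.mask.shape != self.probability.shape:
            raise ValidationError("mask and probability map must share a shape")
        if self.probability.min() < 0 or self.probability.max() > 1:
            raise ValidationError("probabilities must lie in [0, 1]")


def _subsample(indices: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    if len(indices) <= cap:
        return indices
    return rng.choice(indices, size=cap, replace=False)


def train(
    stack: FeatureStack,
    annotations: AnnotationSet,
    config: PipelineConfig,
) -> ClassifierModel:
    """Fit a random forest on the annotated pixels of ``stack``.

    Per-class subsampling (cap ``config.train_cap_per_class``) uses the
    config seed, as does the forest itself, so training is reproducible.
    Classes with fewer than 10 annotated pixels trigger a warning but
    training proceeds.
    """
    if annotations.label_image.shape != stack.grid_shape:
        raise ValidationError(
            f"annotation shape {annotations.label_image.shape} does not match "
            f"feature grid {stack.grid_shape}"
        )
    labels = annotations.label_image.ravel()
    X_all = stack.as_matrix()
    rng = np.random.default_rng(config.seed)

    parts_X, parts_y = [], []
    for lbl, name in ((LABEL_AVASCULAR, "avascular"), (LABEL_VASCULAR, "vascular")):
        idx = np.flatnonzero(labels == lbl)
        if len(idx) == 0:
            raise ValidationError(f"no annotated pixels for class {name}")
        if len(idx) < 10:
            warnings.warn(
                f"only {len(idx)} annotated pixels for class {name}; "
                "training proceeds but may be unstable",
                stacklevel=2,
            )
        idx = np.sort(_subsample(idx, config.train_cap_per_class, rng))
        parts_X.append(X_all[idx])
        parts_y.append(np.full(len(idx), lbl, dtype=np.int64))

    X = np.concatenate(parts_X)
    y = np.concatenate(parts_y)

    use_oob = len(y) >= 20
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        max_depth=config.max_depth,
        oob_score=use_oob,
        random_state=config.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        forest.fit(X, y)
    train_acc = float(np.mean(forest.predict(X) == y))
    oob = float(forest.oob_score_) if use_oob else None
    logger.info("trained forest: train_acc=%.4f oob=%s", train_acc, oob)
    return ClassifierModel(
        forest=forest,
        feature_names=list(stack.feature_names),
        seed=config.seed,
        training_accuracy=train_acc,
        oob_accuracy=oob,
    )


def predict(
    model: ClassifierModel,
    stack: FeatureStack,
    threshold: float = 0.5,
) -> SegmentationMask:
    """Per-pixel avascular probability map thresholded into a binary mask.

    The probability is the forest's vote fraction for the avascular class;
    pixels with probability exactly equal to the threshold are assigned to
    the avascular class (``>=`` comparison).
    """
    if list(stack.feature_names) != list(model.feature_names):
        missing = set(model.feature_names) - set(stack.feature_names)
        raise ValidationError(
            "feature stack does not match the model's training features; "
            f"missing: {sorted(missing) if missing else 'order mismatch'}"
        )
    if not (0 <= threshold <= 1):
        raise ValidationError("threshold must lie in [0, 1]")
    proba = model.forest.predict_proba(stack.as_matrix())
    class_index = {c: i for i, c in enumerate(model.forest.classes_)}
    p_avascular = proba[:, class_index[LABEL_AVASCULAR]].reshape(stack.grid_shape)
    mask = p_avascular >= threshold
    return SegmentationMask(mask=mask, probability=p_avascular, threshold=float(threshold))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap score 2|A∩B| / (|A| + |B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("masks must share a shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
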