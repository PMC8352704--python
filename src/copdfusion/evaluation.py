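"""Confusion-matrix accounting and the recognition / sensitivity / specificity
metrics (positive class = 1).

    recognition = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Undefined margins (no true positives+false negatives, or no true
negatives+false positives) yield NaN plus a warning, never a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import fusion as fusion_mod
from . import lenet
from .fusion import FusionModel
from .lenet import NetworkParams
from .synthetic_data import LabeledImagePair

__all__ = ["ConfusionCounts", "MetricsTriple", "confusion", "metrics", "evaluate", "predict_labels"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsTriple:
    recognition: float
    sensitivity: float
    specificity: float

    def as_percent(self) -> dict[str, float]:
        return {
            "recognition": 100.0 * self.recognition,
            "sensitivity": 100.0 * self.sensitivity,
            "specificity": 100.0 * self.specificity,
        }


def confusion(
    predicted: Sequence[int], truth: Sequence[int], positive_class: int = 1
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over binary label sequences."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("predicted and true labels must be equal-length 1-D sequences")
    for arr, name in ((pred, "predicted"), (true, "true")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must all be in {{0, 1}}")
    p = pred == positive_class
    t = true == positive_class
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        TN=int(np.sum(~p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def metrics(counts: ConfusionCounts) -> MetricsTriple:
    """The three ratio metrics from confusion counts."""
    if counts.total < 1:
        raise ValueError("need at least one sample")
    recognition = (counts.TP + counts.TN) / counts.total
    if counts.TP + counts.FN == 0:
        warnings.warn("no positive samples in truth: sensitivity undefined", stacklevel=2)
        sensitivity = float("nan")
    else:
        sensitivity = counts.TP / (counts.TP + counts.FN)
    if counts.TN + counts.FP == 0:
        warnings.warn("no negative samples in truth: specificity undefined", stacklevel=2)
        specificity = float("nan")
    else:
        specificity = counts.TN / (counts.TN + counts.FP)
    return MetricsTriple(recognition, sensitivity, specificity)


def predict_labels(model, pairs: Sequence[LabeledImagePair]) -> np.ndarray:
    """Predicted labels for a sequence of pairs.

    ``model`` may be a single-modal ``NetworkParams`` (the image is selected
    by its modality_tag), a ``FusionModel``, or any callable pair -> label.
    """
    if isinstance(model, NetworkParams):
        images = np.stack(
            [p.ct_image if model.modality_tag == "CT" else p.xray_image for p in pairs]
        )
        probs, _ = lenet.forward_batch(model, images)
        return np.argmax(probs, axis=1)
    if isinstance(model, FusionModel):
        ct = np.stack([p.ct_image for p in pairs])
        xr = np.stack([p.xray_image for p in pairs])
        probs = fusion_mod.fusion_forward_batch(model, ct, xr)
        return np.argmax(probs, axis=1)
    if callable(model):
        return np.array([int(model(p)) for p in pairs])
    raise TypeError(f"cannot evaluate model of type {type(model)!r}")


def evaluate(model, test_set: Sequence[LabeledImagePair]) -> tuple[ConfusionCounts, MetricsTriple]:
    """Run the model on the full test set and compute counts + metrics."""
    if not test_set:
        raise ValueError("test set must be nonempty")
    pred = predict_labels(model, test_set)
    truth = [p.label for p in test_set]
    counts = confusion(pred, truth)
    return counts, metrics(counts)
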