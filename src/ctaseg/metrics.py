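"""Voxel-overlap metrics between a predicted mask and a reference mask.

With A the reference (true) foreground and B the prediction:

* Jaccard = |A ∩ B| / |A ∪ B| = TP / (TP + FP + FN)
* Dice    = 2|A ∩ B| / (|A| + |B|) = 2 TP / (2 TP + FP + FN)
* Sensitivity = TP / (TP + FN)   (foreground recall)
* Specificity = TN / (TN + FP)   (background recall)

All four lie in [0, 1]; Dice = 2J / (1 + J) identically.  Any 0/0 ratio
is reported as 1 when both masks are empty of the relevant class (two
empty masks agree perfectly) and 0 otherwise, with a warning either way.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .volume_io import BinaryMask

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Voxelwise TP/FP/TN/FN tallies."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Overlap metrics plus the counts they were computed from."""

    jaccard: float
    dice: float
    sensitivity: float
    specificity: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _as_bool(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    return data.astype(bool)


def confusion(reference: BinaryMask | np.ndarray,
              predicted: BinaryMask | np.ndarray) -> ConfusionCounts:
    """TP/FP/TN/FN voxel counts; both masks must share one shape."""
    ref = _as_bool(reference)
    pred = _as_bool(predicted)
    if ref.shape != pred.shape:
        raise ValueError(f"shape mismatch: reference {ref.shape} vs predicted {pred.shape}")
    tp = int(np.count_nonzero(ref & pred))
    fp = int(np.count_nonzero(~ref & pred))
    fn = int(np.count_nonzero(ref & ~pred))
    tn = ref.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(numerator: int, denominator: int, both_empty: bool, name: str) -> float:
    if denominator == 0:
        value = 1.0 if both_empty else 0.0
        logger.warning("%s is 0/0; reporting %s (both masks %s of the relevant class)",
                       name, value, "empty" if both_empty else "NOT both empty")
        return value
    return numerator / denominator


def evaluate(reference: BinaryMask | np.ndarray,
             predicted: BinaryMask | np.ndarray) -> EvalReport:
    """Jaccard, Dice, sensitivity and specificity of a prediction."""
    c = confusion(reference, predicted)
    ref_fg, pred_fg = c.tp + c.fn, c.tp + c.fp
    ref_bg, pred_bg = c.tn + c.fp, c.tn + c.fn
    union = c.tp + c.fp + c.fn
    if union == 0:
        # both masks empty: perfect (vacuous) agreement on foreground
        logger.warning("both masks are empty; foreground metrics reported as 1")
        jaccard = dice = 1.0
    else:
        jaccard = c.tp / union
        dice = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    sensitivity = _ratio(c.tp, ref_fg, ref_fg == 0 and pred_fg == 0, "sensitivity")
    specificity = _ratio(c.tn, ref_bg, ref_bg == 0 and pred_bg == 0, "specificity")
    return EvalReport(jaccard=jaccard, dice=dice, sensitivity=sensitivity,
                      specificity=specificity, counts=c)
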