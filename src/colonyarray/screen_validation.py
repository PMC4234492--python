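"""Screen performance estimation: sensitivity and precision.

A screen's hit list contains true positives (TP, genuine interactions
correctly identified), false positives (FP), and misses (FN).  With

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)

a new screen can be calibrated against a reference hit set whose
precision and sensitivity are already known (for SGA screens, the
genome-scale reference interaction datasets): the reference's TP count
follows from its hit count and precision, the total number of true
interactions from its TP count and sensitivity, and the new screen's
TP count from the overlap with the reference scaled by the reference
sensitivity.  All remaining confusion counts then follow by
subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ConfusionEstimate",
    "precision",
    "sensitivity",
    "calibrate_against_reference",
]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ConfusionEstimate:
    """Confusion counts plus derived rates for one screen."""

    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    estimated_total_interactions: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if not (0 <= self.sensitivity <= 1 and 0 <= self.precision <= 1):
            raise ValueError("rates must lie in [0, 1]")


def precision(tp: int, fp: int) -> float:
    """Fraction of reported hits that are genuine: TP / (TP + FP)."""
    if tp + fp <= 0:
        raise ValueError("precision undefined: no reported hits")
    return tp / (tp + fp)


def sensitivity(tp: int, fn: int) -> float:
    """Fraction of genuine interactions recovered: TP / (TP + FN)."""
    if tp + fn <= 0:
        raise ValueError("sensitivity undefined: no true interactions")
    return tp / (tp + fn)


def calibrate_against_reference(
    ref_hits: int,
    ref_precision: float,
    ref_sensitivity: float,
    our_hits: int,
    shared_true: int,
) -> tuple[ConfusionEstimate, ConfusionEstimate]:
    """Estimate confusion counts for a screen from a calibrated reference.

    Parameters
    ----------
    ref_hits:
        Number of hits reported by the reference screen.
    ref_precision, ref_sensitivity:
        The reference screen's experimentally determined rates.
    our_hits:
        Number of hits reported by the screen being calibrated.
    shared_true:
        Hits shared between the two screens, taken as genuine.

    Derivation (intermediate quantities rounded half-away-from-zero):
    reference TP = ref_precision * ref_hits and FP = ref_hits - TP; the
    estimated total number of true interactions is T = TP /
    ref_sensitivity; our TP = shared_true / ref_sensitivity (the shared
    hits are the ref-sensitivity-sized visible fraction of our true
    positives), our FP = our_hits - our TP, and our FN = T - our TP.

    Returns (reference estimate, our estimate).
    """
    if not (0 < ref_precision <= 1 and 0 < ref_sensitivity <= 1):
        raise ValueError("reference rates must lie in (0, 1]")
    if shared_true > our_hits:
        raise ValueError("shared hits cannot exceed our hit count")
    ref_tp = _round_half_away(ref_precision * ref_hits)
    ref_fp = ref_hits - ref_tp
    total = _round_half_away(ref_tp / ref_sensitivity)
    ref_fn = total - ref_tp
    our_tp = _round_half_away(shared_true / ref_sensitivity)
    our_fp = our_hits - our_tp
    our_fn = total - our_tp
    if min(ref_fp, ref_fn, our_fp, our_fn) < 0:
        raise ValueError("inconsistent reference parameters: negative "
                         "intermediate confusion count")
    reference = ConfusionEstimate(
        tp=ref_tp, fp=ref_fp, fn=ref_fn,
        sensitivity=sensitivity(ref_tp, ref_fn),
        precision=precision(ref_tp, ref_fp),
        estimated_total_interactions=total,
    )
    ours = ConfusionEstimate(
        tp=our_tp, fp=our_fp, fn=our_fn,
        sensitivity=sensitivity(our_tp, our_fn),
        precision=precision(our_tp, our_fp),
        estimated_total_interactions=total,
    )
    return reference, ours
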