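"""FDR / power evaluation of DE calls against simulation truth.

FDR = FP / (TP + FP) (defined as 0 when no calls are made) and
power = TP / (TP + FN). The evaluation unit is a (feature, topic) test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvalCurve",
    "confusion_at",
    "fdr_power_curve",
    "signed_tests_filter",
]


@dataclass
class EvalCurve:
    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    fdr: np.ndarray
    power: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "tn": self.tn,
                "fn": self.fn,
                "fdr": self.fdr,
                "power": self.power,
            }
        )


def confusion_at(truth, scores, threshold, direction: str = "le"):
    """(tp, fp, tn, fn) when calling scores <= / >= threshold."""
    truth = np.asarray(truth, dtype=bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if truth.size != scores.size:
        raise ValueError("truth and scores must have equal length")
    if direction == "le":
        calls = scores <= threshold
    elif direction == "ge":
        calls = scores >= threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    tn = int(np.sum(~calls & ~truth))
    fn = int(np.sum(~calls & truth))
    return tp, fp, tn, fn


def fdr_power_curve(truth, scores, direction: str = "le") -> EvalCurve:
    """Sweep every distinct score as a threshold; power is monotone in the
    loosening direction."""
    truth = np.asarray(truth, dtype=bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    thresholds = np.unique(scores)
    if direction == "ge":
        thresholds = thresholds[::-1]
    tp = np.empty(thresholds.size, dtype=int)
    fp = np.empty_like(tp)
    tn = np.empty_like(tp)
    fn = np.empty_like(tp)
    for i, t in enumerate(thresholds):
        tp[i], fp[i], tn[i], fn[i] = confusion_at(truth, scores, t, direction)
    calls = tp + fp
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(calls > 0, fp / np.maximum(calls, 1), 0.0)
        pos = tp + fn
        power = np.where(pos > 0, tp / np.maximum(pos, 1), 0.0)
    return EvalCurve(thresholds, tp, fp, tn, fn, fdr, power)


def signed_tests_filter(truth_effects, mode: str = "all") -> np.ndarray:
    """Boolean mask of tests retained for evaluation.

    ``positive_only`` restricts the evaluation universe to tests whose true
    effect is >= 0 (zero-effect tests count as nulls and are kept).
    """
    effects = np.asarray(truth_effects, dtype=float).ravel()
    if mode == "all":
        return np.ones(effects.size, dtype=bool)
    if mode == "positive_only":
        return effects >= 0
    raise ValueError(f"unknown mode {mode!r}")
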