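"""Sample-based agreement statistics between detections and reference scoring.

Every time sample is labeled event / non-event for both the detector and
the reference; the confusion counts over samples give sensitivity, positive
predictive value (PPV), Matthews correlation coefficient (MCC), Cohen's
kappa and F1.  Sample-based scoring credits partial overlaps in proportion
to their duration, unlike window-matching schemes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "events_to_sample_labels",
    "confusion_counts",
    "metric_set",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Sample counts: true/false positives and negatives."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Agreement scores; ``degenerate`` names any metric whose denominator
    was zero and was reported as 0 by convention."""

    sensitivity: float
    ppv: float
    mcc: float
    kappa: float
    f1: float
    degenerate: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "mcc": self.mcc,
            "kappa": self.kappa,
            "f1": self.f1,
            "degenerate": list(self.degenerate),
        }


def events_to_sample_labels(events, n_samples: int, fs: float) -> np.ndarray:
    """Boolean per-sample labels: sample ``k`` is True iff its time ``k/fs``
    lies inside any event interval (half-open; overlaps union).

    ``events`` are objects with ``onset``/``offset`` attributes or plain
    ``(onset, offset)`` pairs, in seconds.
    """
    labels = np.zeros(n_samples, dtype=bool)
    dur = n_samples / fs
    for ev in events:
        onset, offset = (ev if isinstance(ev, tuple) else (ev.onset, ev.offset))
        if onset < -1e-9 or offset > dur + 1e-9:
            raise ValueError(
                f"event [{onset}, {offset}) outside the scored range [0, {dur})"
            )
        i0 = max(int(np.ceil(onset * fs - 1e-9)), 0)
        i1 = min(int(np.ceil(offset * fs - 1e-9)), n_samples)
        labels[i0:i1] = True
    return labels


def confusion_counts(ref_labels: np.ndarray, det_labels: np.ndarray) -> ConfusionCounts:
    """Sample confusion counts of detector labels against reference labels."""
    ref = np.asarray(ref_labels, dtype=bool)
    det = np.asarray(det_labels, dtype=bool)
    if ref.shape != det.shape:
        raise ValueError(f"label length mismatch: {ref.shape} vs {det.shape}")
    tp = int(np.sum(ref & det))
    fp = int(np.sum(~ref & det))
    fn = int(np.sum(ref & ~det))
    tn = int(np.sum(~ref & ~det))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metric_set(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, PPV, MCC, Cohen's kappa and F1 from confusion counts.

    Ratios with zero denominators are reported as 0 and flagged in
    ``degenerate``.
    """
    n = c.total
    if n == 0:
        raise ValueError("no scored samples")
    tp, fp, tn, fn = (float(c.tp), float(c.fp), float(c.tn), float(c.fn))
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    ppv = ratio(tp, tp + fp, "ppv")
    f1 = ratio(2.0 * ppv * sens, ppv + sens, "f1")
    mcc = ratio(tp * tn - fp * fn,
                math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)), "mcc")
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = ratio(po - pe, 1.0 - pe, "kappa")
    return MetricSet(sensitivity=sens, ppv=ppv, mcc=mcc, kappa=kappa, f1=f1,
                     degenerate=tuple(degenerate))
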