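"""Whole-display change-detection capacity: Pashler's k.

k = (H - FA) / (1 - FA) * N, where H and FA are hit and false-alarm rates
and N is the display set size. The clamped value (to [0, N]) is the headline
estimate; the raw value is retained alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectionSummary",
    "PashlerK",
    "rates_from_counts",
    "pashler_k",
    "summarize_detection_trials",
]


@dataclass(frozen=True)
class DetectionSummary:
    hit_rate: float
    false_alarm_rate: float
    set_size: int
    n_change_trials: int = 0
    n_match_trials: int = 0

    def __post_init__(self):
        if not (0.0 <= self.hit_rate <= 1.0 and 0.0 <= self.false_alarm_rate <= 1.0):
            raise ValueError("rates must be in [0, 1]")
        if self.n_change_trials < 0 or self.n_match_trials < 0:
            raise ValueError("trial counts must be >= 0")


@dataclass(frozen=True)
class PashlerK:
    k: float
    k_raw: float
    set_size: int
    method: str = "pashler_k"


def rates_from_counts(
    hits: int,
    misses: int,
    false_alarms: int,
    correct_rejections: int,
    set_size: int,
    loglinear: bool = False,
) -> DetectionSummary:
    """Hit/false-alarm rates from response counts.

    ``loglinear=True`` applies the 0.5 / (n + 1) adjustment that keeps rates
    off 0 and 1; it is off by default (no correction is applied upstream).
    """
    n_change = hits + misses
    n_match = false_alarms + correct_rejections
    if n_change < 1 or n_match < 1:
        raise ValueError("need at least one change trial and one match trial")
    if min(hits, misses, false_alarms, correct_rejections) < 0:
        raise ValueError("counts must be >= 0")
    if loglinear:
        h = (hits + 0.5) / (n_change + 1.0)
        fa = (false_alarms + 0.5) / (n_match + 1.0)
    else:
        h = hits / n_change
        fa = false_alarms / n_match
    return DetectionSummary(
        hit_rate=h,
        false_alarm_rate=fa,
        set_size=set_size,
        n_change_trials=n_change,
        n_match_trials=n_match,
    )


def pashler_k(summary: DetectionSummary, clamp: bool = True) -> PashlerK:
    """Pashler's whole-display capacity estimate from a detection summary."""
    h, fa, n = summary.hit_rate, summary.false_alarm_rate, summary.set_size
    if fa >= 1.0:
        raise ValueError("false-alarm rate of 1 leaves Pashler's k undefined")
    raw = (h - fa) / (1.0 - fa) * n
    k = float(np.clip(raw, 0.0, n)) if clamp else float(raw)
    return PashlerK(k=k, k_raw=float(raw), set_size=n)


def summarize_detection_trials(change_trial, responded_change, set_size: int) -> DetectionSummary:
    """Build a :class:`DetectionSummary` from per-trial booleans."""
    change_trial = np.asarray(change_trial, dtype=bool)
    responded_change = np.asarray(responded_change, dtype=bool)
    if change_trial.shape != responded_change.shape:
        raise ValueError("trial arrays must have the same shape")
    hits = int(np.sum(change_trial & responded_change))
    misses = int(np.sum(change_trial & ~responded_change))
    fas = int(np.sum(~change_trial & responded_change))
    crs = int(np.sum(~change_trial & ~responded_change))
    return rates_from_counts(hits, misses, fas, crs, set_size)
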