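"""One-zero sampling scores and integer MI-threshold calibration.

One-zero sampling scores a recording session as the fraction of sampling
intervals in which the target behaviour (play) occurred at all.  The MI
analogue counts intervals whose MI meets or exceeds a threshold.  The
calibration step searches whole-integer thresholds (the logger reports MI
in whole integers) for the one whose equivalent score is closest to the
visual one-zero score, breaking ties toward the larger threshold — a higher
threshold has higher specificity, and false positives distort a one-zero
score more than false negatives do.  The chosen threshold is then validated
on a second, held-out group of calves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cutpoints import PLAY, BinaryIntervalSeries, CutpointError, _check_same_grid
from .motion import MISeries

__all__ = [
    "OneZeroScore",
    "CalibrationResult",
    "one_zero_score",
    "mi_one_zero_score",
    "calibrate_threshold",
    "validate_threshold",
]


@dataclass(frozen=True)
class OneZeroScore:
    """Positive-interval count over total sampled intervals."""

    positives: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise CutpointError("one-zero score needs at least one interval")
        if not 0 <= self.positives <= self.total:
            raise CutpointError("positives must lie in [0, total]")

    @property
    def score(self) -> float:
        return self.positives / self.total

    def rounded(self, ndigits: int = 3) -> float:
        """Score as reported: 3 decimal places."""
        return round(self.score, ndigits)


@dataclass(frozen=True)
class CalibrationResult:
    resolution_s: int
    threshold: int
    visual: OneZeroScore
    mi_equiv: OneZeroScore
    passed: bool | None = None  # set by validate_threshold

    @property
    def abs_diff(self) -> float:
        return abs(self.visual.score - self.mi_equiv.score)


def one_zero_score(labels: BinaryIntervalSeries) -> OneZeroScore:
    """Visual one-zero score: play-positive intervals / sampled intervals
    (excluded intervals count in neither)."""
    keep = labels.included
    total = int(keep.sum())
    if total == 0:
        raise CutpointError("all intervals excluded: one-zero score undefined")
    positives = int(np.sum(labels.labels[keep] == PLAY))
    return OneZeroScore(positives, total)


def mi_one_zero_score(
    mi: MISeries,
    cutpoint: float,
    labels: BinaryIntervalSeries | None = None,
) -> OneZeroScore:
    """MI-equivalent one-zero score: intervals with MI >= cutpoint / total.

    When ``labels`` is given, its excluded intervals are removed from the MI
    stream in lockstep, so both scores cover the same sampled intervals.
    """
    if labels is not None:
        _check_same_grid(labels, mi)
        values = mi.values[labels.included]
    else:
        values = mi.values
    total = len(values)
    if total == 0:
        raise CutpointError("no intervals to score")
    return OneZeroScore(int(np.sum(values >= cutpoint)), total)


def calibrate_threshold(
    labels: BinaryIntervalSeries,
    mi: MISeries,
    search_range: tuple[int, int] | None = None,
) -> CalibrationResult:
    """Exhaustive integer-threshold search for the best one-zero match.

    Scans every whole-integer threshold in ``search_range`` (inclusive;
    defaults 1..200 at 1 min, 1..500 at 15 min) and returns the one whose
    MI-equivalent score is closest to the visual score, ties broken toward
    the larger (more specific) threshold.
    """
    if search_range is None:
        search_range = (1, 200) if labels.resolution_s == 60 else (1, 500)
    lo, hi = search_range
    if hi < lo:
        raise CutpointError(f"empty threshold search range {search_range}")
    visual = one_zero_score(labels)
    # visual and equivalent scores share the same denominator, so comparing
    # positive-interval counts compares the scores exactly (no float ties)
    best: tuple[int, int] | None = None
    for t in range(lo, hi + 1):
        equiv = mi_one_zero_score(mi, t, labels)
        diff = abs(visual.positives - equiv.positives)
        if best is None or diff <= best[0]:  # <=: larger threshold wins ties
            best = (diff, t)
    assert best is not None
    threshold = best[1]
    return CalibrationResult(
        resolution_s=labels.resolution_s,
        threshold=threshold,
        visual=visual,
        mi_equiv=mi_one_zero_score(mi, threshold, labels),
    )


def validate_threshold(
    threshold: int,
    labels2: BinaryIntervalSeries,
    mi2: MISeries,
    tolerance: float = 0.1,
) -> CalibrationResult:
    """Apply a calibrated threshold to a held-out dataset.

    The validation passes iff the absolute difference between the visual
    and MI-equivalent one-zero scores is below ``tolerance`` (default 0.1).
    """
    if labels2.resolution_s != mi2.resolution_s:
        raise CutpointError(
            f"resolution mismatch: labels {labels2.resolution_s}s vs "
            f"MI {mi2.resolution_s}s"
        )
    visual = one_zero_score(labels2)
    equiv = mi_one_zero_score(mi2, threshold, labels2)
    result = CalibrationResult(
        resolution_s=labels2.resolution_s,
        threshold=int(threshold),
        visual=visual,
        mi_equiv=equiv,
    )
    return CalibrationResult(
        resolution_s=result.resolution_s,
        threshold=result.threshold,
        visual=visual,
        mi_equiv=equiv,
        passed=result.abs_diff < tolerance,
    )
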