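"""Interval-level play detection from MI cut points.

Visual observations are reduced to one-zero interval labels (play observed /
not observed, with out-of-view intervals excluded), and the matched MI value
per interval is thresholded: an interval is predicted play-positive iff its
MI equals or exceeds the cut point.  The module computes 2x2 contingency
tables, sensitivity Se = TP/(TP+FN), specificity Sp = TN/(TN+FP) and
balanced accuracy (Se+Sp)/2 over grids of cut points, ROC points, and a
single Gini-optimal threshold (the two-node classification tree) with
stratified 10-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .ethogram import EventLog
from .motion import MISeries

__all__ = [
    "PLAY",
    "NO_PLAY",
    "EXCLUDED",
    "BinaryIntervalSeries",
    "ContingencyTable",
    "CutpointMetrics",
    "StumpModel",
    "binarize_play",
    "contingency",
    "metrics",
    "balanced_accuracy",
    "metric_grid",
    "roc_points",
    "gini_stump",
    "cross_validate_stump",
    "CutpointError",
]

logger = logging.getLogger(__name__)

PLAY, NO_PLAY, EXCLUDED = 1, 0, -1

#: Sampling-interval durations used for one-zero scoring.
STANDARD_RESOLUTIONS_S = (60, 900)


class CutpointError(ValueError):
    """Raised for invalid binarization or tally inputs."""


@dataclass
class BinaryIntervalSeries:
    """Per-interval play labels on the same grid as a paired MISeries."""

    resolution_s: int
    anchor_s: float
    labels: np.ndarray  # values in {PLAY, NO_PLAY, EXCLUDED}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        bad = ~np.isin(self.labels, (PLAY, NO_PLAY, EXCLUDED))
        if bad.any():
            raise CutpointError("labels must be play/no_play/excluded")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def included(self) -> np.ndarray:
        return self.labels != EXCLUDED


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise CutpointError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class CutpointMetrics:
    """Se/Sp/balanced accuracy at one cut point; ``None`` marks a metric
    whose denominator was empty (never silently reported as 0)."""

    cutpoint: float
    se: float | None
    sp: float | None
    balanced_accuracy: float | None


@dataclass(frozen=True)
class StumpModel:
    """Two-node classification tree: one Gini-optimal MI threshold."""

    threshold: float
    gini_decrease: float
    cv_se: float | None = None
    cv_sp: float | None = None


# ---------------------------------------------------------------------------
# binarization


def binarize_play(
    log: EventLog,
    resolution_s: int,
    anchor_s: float = 0.0,
    span: tuple[float, float] | None = None,
    sampling_on_s: float | None = None,
    sampling_off_s: float | None = None,
    allow_any_resolution: bool = False,
) -> BinaryIntervalSeries:
    """One-zero labels per sampling interval.

    An interval is ``play`` iff any play event overlaps it (half-open
    intervals; a point event marks presence at its start).  Intervals
    touched by out-of-view/management events are ``excluded``, which takes
    precedence.  With ``sampling_on_s``/``sampling_off_s`` set, an
    intermittent watch schedule (e.g. 1 h observed every 4 h) is applied:
    intervals outside observed blocks are excluded.
    """
    if resolution_s not in STANDARD_RESOLUTIONS_S and not allow_any_resolution:
        raise CutpointError(
            f"resolution {resolution_s}s not in {STANDARD_RESOLUTIONS_S} "
            "(pass allow_any_resolution=True to override)"
        )
    if span is None:
        span = (anchor_s, log.obs_end_s)
    lo, hi = span
    if lo < log.obs_start_s or hi > log.obs_end_s:
        raise CutpointError("span outside observation period")
    if (lo - anchor_s) % resolution_s != 0:
        raise CutpointError("span start not aligned to the interval grid")
    n = int((hi - lo) // resolution_s)  # trailing partial interval dropped
    starts = lo + resolution_s * np.arange(n)
    ends = starts + resolution_s
    labels = np.full(n, NO_PLAY, dtype=np.int8)

    def overlapping(ev_start: float, ev_end: float) -> np.ndarray:
        if ev_end > ev_start:
            return (ev_start < ends) & (ev_end > starts)
        return (starts <= ev_start) & (ev_start < ends)  # point event

    for ev in log.events:
        if ev.category == "play":
            labels[overlapping(ev.start_s, ev.end_s)] = PLAY
    for ev in log.events:
        if ev.category == "meta":
            labels[overlapping(ev.start_s, ev.end_s)] = EXCLUDED
    if sampling_on_s is not None:
        off = sampling_off_s or 0.0
        cycle = sampling_on_s + off
        phase = (starts - anchor_s) % cycle
        observed = (phase + resolution_s) <= sampling_on_s + 1e-9
        labels[~observed] = EXCLUDED
    return BinaryIntervalSeries(resolution_s, float(lo), labels)


def _check_same_grid(labels: BinaryIntervalSeries, mi: MISeries) -> None:
    if (
        labels.resolution_s != mi.resolution_s
        or labels.anchor_s != mi.start_s
        or len(labels) != len(mi)
    ):
        raise CutpointError(
            "label and MI series are on different grids: "
            f"({labels.resolution_s}s @ {labels.anchor_s}, n={len(labels)}) vs "
            f"({mi.resolution_s}s @ {mi.start_s}, n={len(mi)})"
        )


# ---------------------------------------------------------------------------
# contingency and metrics


def contingency(
    labels: BinaryIntervalSeries, mi: MISeries, cutpoint: float
) -> ContingencyTable:
    """2x2 tally: predicted positive iff MI >= cutpoint; excluded intervals
    are removed from both streams before counting."""
    _check_same_grid(labels, mi)
    keep = labels.included
    truth = labels.labels[keep] == PLAY
    pred = mi.values[keep] >= cutpoint
    return ContingencyTable(
        tp=int(np.sum(truth & pred)),
        fp=int(np.sum(~truth & pred)),
        tn=int(np.sum(~truth & ~pred)),
        fn=int(np.sum(truth & ~pred)),
    )


def metrics(ct: ContingencyTable, cutpoint: float = float("nan")) -> CutpointMetrics:
    """Se, Sp and balanced accuracy from a contingency table."""
    se = ct.tp / (ct.tp + ct.fn) if ct.tp + ct.fn > 0 else None
    sp = ct.tn / (ct.tn + ct.fp) if ct.tn + ct.fp > 0 else None
    ba = balanced_accuracy(se, sp)
    return CutpointMetrics(cutpoint=cutpoint, se=se, sp=sp, balanced_accuracy=ba)


def balanced_accuracy(se: float | None, sp: float | None) -> float | None:
    """(Se + Sp)/2, undefined if either input is."""
    if se is None or sp is None:
        return None
    return (se + sp) / 2.0


def metric_grid(
    labels: BinaryIntervalSeries, mi: MISeries, cutpoints
) -> list[CutpointMetrics]:
    """Se/Sp/balanced accuracy at each cut point of a grid."""
    cutpoints = list(cutpoints)
    if not cutpoints:
        raise CutpointError("empty cut-point grid")
    return [metrics(contingency(labels, mi, c), c) for c in cutpoints]


def roc_points(grid: list[CutpointMetrics]) -> np.ndarray:
    """(1-Sp, Se) pairs for ROC plotting; undefined rows are dropped."""
    pts = [
        (1.0 - m.sp, m.se)
        for m in grid
        if m.se is not None and m.sp is not None
    ]
    return np.asarray(pts, dtype=float)


# ---------------------------------------------------------------------------
# Gini decision stump


def _gini_best_split(values: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Best midpoint threshold by Gini impurity decrease.

    Candidates are midpoints between consecutive distinct sorted MI values;
    ties in impurity decrease break toward the smaller threshold.  Returns
    ``(threshold, gini_decrease)``.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = truth[order].astype(float)
    n = len(v)
    n_pos = y.sum()
    p = n_pos / n
    g_parent = 1.0 - p**2 - (1.0 - p) ** 2

    # split after position k: left = v[:k+1] (< threshold), right = v[k+1:]
    cum_pos = np.cumsum(y)
    ks = np.flatnonzero(v[:-1] < v[1:])  # boundaries between distinct values
    if len(ks) == 0:
        raise CutpointError("all MI values identical: no split possible")
    n_left = ks + 1.0
    n_right = n - n_left
    pos_left = cum_pos[ks]
    pos_right = n_pos - pos_left
    p_l = pos_left / n_left
    p_r = pos_right / n_right
    g_l = 1.0 - p_l**2 - (1.0 - p_l) ** 2
    g_r = 1.0 - p_r**2 - (1.0 - p_r) ** 2
    decrease = g_parent - (n_left / n) * g_l - (n_right / n) * g_r
    best = int(np.argmax(decrease))  # argmax takes the first = smaller threshold
    k = ks[best]
    return float((v[k] + v[k + 1]) / 2.0), float(decrease[best])


def gini_stump(labels: BinaryIntervalSeries, mi: MISeries) -> StumpModel:
    """Fit the two-node tree: the single MI threshold maximising Gini
    impurity decrease over midpoints between distinct observed MI values."""
    _check_same_grid(labels, mi)
    keep = labels.included
    truth = labels.labels[keep] == PLAY
    values = mi.values[keep]
    if truth.all() or not truth.any():
        raise CutpointError("need both play and no-play intervals to fit a stump")
    threshold, decrease = _gini_best_split(values, truth)
    return StumpModel(threshold=threshold, gini_decrease=decrease)


def _stratified_folds(
    truth: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Deterministic class-stratified k folds (round-robin deal after a
    seeded shuffle within each class)."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (True, False):
        idx = np.flatnonzero(truth == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def cross_validate_stump(
    labels: BinaryIntervalSeries,
    mi: MISeries,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, float, tuple[float, float]]:
    """Stratified k-fold cross-validation of the Gini stump.

    Per fold the stump is refit on the other folds and the held-out fold is
    tallied; pooled counts give out-of-sample Se and Sp, returned with the
    ROC point ``(1-Sp, Se)``.  A fold whose training data is single-class is
    merged with its neighbour and the merge is logged.
    """
    _check_same_grid(labels, mi)
    keep = labels.included
    truth = labels.labels[keep] == PLAY
    values = mi.values[keep]
    n = len(values)
    if n < k:
        raise CutpointError(f"need at least k={k} intervals, got {n}")
    if truth.all() or not truth.any():
        raise CutpointError("need both classes for cross-validation")

    folds = _stratified_folds(truth, k, seed)
    pooled = ContingencyTable(0, 0, 0, 0)
    i = 0
    while i < len(folds):
        test_idx = folds[i]
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_truth = truth[train_mask]
        if train_truth.all() or not train_truth.any():
            # degenerate training split: merge this fold into a neighbour
            j = i + 1 if i + 1 < len(folds) else i - 1
            logger.warning("merging CV fold %d into fold %d (single-class training)", i, j)
            folds[j] = np.concatenate([folds[j], test_idx])
            folds.pop(i)
            continue
        threshold, _ = _gini_best_split(values[train_mask], train_truth)
        pred = values[test_idx] >= threshold
        t = truth[test_idx]
        pooled = pooled + ContingencyTable(
            tp=int(np.sum(t & pred)),
            fp=int(np.sum(~t & pred)),
            tn=int(np.sum(~t & ~pred)),
            fn=int(np.sum(t & ~pred)),
        )
        i += 1
    m = metrics(pooled)
    assert m.se is not None and m.sp is not None
    return m.se, m.sp, (1.0 - m.sp, m.se)
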