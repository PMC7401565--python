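"""Binarization, contingency tallies, metric grids, and the Gini stump."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calfplay.cutpoints import (
    EXCLUDED,
    NO_PLAY,
    PLAY,
    BinaryIntervalSeries,
    ContingencyTable,
    CutpointError,
    binarize_play,
    contingency,
    cross_validate_stump,
    gini_stump,
    metric_grid,
    metrics,
    roc_points,
)
from calfplay.ethogram import BehaviourEvent, EventLog
from calfplay.motion import MISeries
from tests.conftest import make_random_log


def _labels(values, resolution=60):
    return BinaryIntervalSeries(resolution, 0.0, np.asarray(values))


def _mi(values, resolution=60):
    return MISeries("c0", resolution, 0.0, np.asarray(values, dtype=float))


def _play_log(intervals, horizon=3600.0):
    events = [
        BehaviourEvent("c0", "p", "play", s, e) for s, e in intervals
    ]
    return EventLog("c0", 0.0, horizon, events)


# ---------------------------------------------------------------------------
# binarization


class TestBinarizePlay:
    def test_single_event_labels_its_interval(self):
        labels = binarize_play(_play_log([(10, 14)]), 60)
        assert labels.labels[0] == PLAY
        assert np.all(labels.labels[1:] == NO_PLAY)

    def test_boundary_spanning_event_labels_both_intervals(self):
        labels = binarize_play(_play_log([(59, 61)]), 60)
        assert labels.labels[0] == PLAY and labels.labels[1] == PLAY

    def test_point_event_marks_presence(self):
        labels = binarize_play(_play_log([(120, 120)]), 60)
        assert labels.labels[2] == PLAY

    def test_out_of_view_excludes_interval(self):
        log = EventLog(
            "c0",
            0.0,
            3600.0,
            [
                BehaviourEvent("c0", "p", "play", 10, 14),
                BehaviourEvent("c0", "O", "meta", 0, 30),
            ],
        )
        labels = binarize_play(log, 60)
        assert labels.labels[0] == EXCLUDED

    def test_nonstandard_resolution_needs_override(self):
        log = _play_log([(10, 14)])
        with pytest.raises(CutpointError, match="resolution"):
            binarize_play(log, 30)
        labels = binarize_play(log, 30, allow_any_resolution=True)
        assert labels.resolution_s == 30

    def test_intermittent_sampling_excludes_unobserved_blocks(self):
        # 1 h observed every 4 h over 8 h
        log = _play_log([(10, 14)], horizon=8 * 3600.0)
        labels = binarize_play(log, 900, sampling_on_s=3600, sampling_off_s=3 * 3600)
        observed = labels.labels != EXCLUDED
        assert observed.sum() == 8  # two observed hours of four 15 min intervals
        assert observed[:4].all() and observed[16:20].all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_1s_rasterization_oracle(self, seed):
        log = make_random_log(np.random.default_rng(seed), n_events=80)
        labels = binarize_play(log, 60)
        raster_play = np.zeros(3600, dtype=bool)
        raster_meta = np.zeros(3600, dtype=bool)
        for ev in log.events:
            sl = slice(int(ev.start_s), int(ev.end_s))
            if ev.category == "play":
                raster_play[sl] = True
            elif ev.category == "meta":
                raster_meta[sl] = True
        for k in range(len(labels)):
            block = slice(60 * k, 60 * (k + 1))
            expected = (
                EXCLUDED
                if raster_meta[block].any()
                else (PLAY if raster_play[block].any() else NO_PLAY)
            )
            assert labels.labels[k] == expected


# ---------------------------------------------------------------------------
# contingency and metrics


class TestContingency:
    def test_all_play_all_flagged(self):
        ct = contingency(_labels([PLAY] * 5), _mi([10] * 5), 5)
        assert (ct.tp, ct.fp, ct.tn, ct.fn) == (5, 0, 0, 0)

    def test_cutpoint_zero_flags_everything(self):
        labels = _labels([PLAY, NO_PLAY, NO_PLAY, PLAY])
        ct = contingency(labels, _mi([0, 1, 0, 3]), 0)
        assert ct.tp + ct.fp == 4

    def test_equality_counts_as_positive(self):
        ct = contingency(_labels([PLAY, NO_PLAY]), _mi([7, 7]), 7)
        assert (ct.tp, ct.fp) == (1, 1)

    def test_excluded_intervals_dropped(self):
        labels = _labels([PLAY, EXCLUDED, NO_PLAY])
        ct = contingency(labels, _mi([9, 9, 1]), 5)
        assert ct.n == 2

    def test_grid_mismatch_rejected(self):
        with pytest.raises(CutpointError, match="grid"):
            contingency(_labels([PLAY] * 4), _mi([1] * 4, resolution=900), 1)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(9)
        n = 396
        truth = rng.random(n) < 0.13
        labels = _labels(np.where(truth, PLAY, NO_PLAY))
        mi = _mi(rng.integers(0, 50, n))
        cut = 12
        ct = contingency(labels, mi, cut)
        tp = sum(1 for i in range(n) if truth[i] and mi.values[i] >= cut)
        fp = sum(1 for i in range(n) if not truth[i] and mi.values[i] >= cut)
        tn = sum(1 for i in range(n) if not truth[i] and mi.values[i] < cut)
        fn = sum(1 for i in range(n) if truth[i] and mi.values[i] < cut)
        assert (ct.tp, ct.fp, ct.tn, ct.fn) == (tp, fp, tn, fn)


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ContingencyTable(tp=5, fp=0, tn=10, fn=0))
        assert (m.se, m.sp, m.balanced_accuracy) == (1.0, 1.0, 1.0)

    def test_undefined_se_flagged_not_zero(self):
        m = metrics(ContingencyTable(tp=0, fp=3, tn=7, fn=0))
        assert m.se is None and m.balanced_accuracy is None
        assert m.sp == 0.7

    def test_grid_of_one_equals_direct_call(self):
        labels = _labels([PLAY, NO_PLAY, NO_PLAY, PLAY])
        mi = _mi([9, 1, 5, 6])
        grid = metric_grid(labels, mi, [5])
        direct = metrics(contingency(labels, mi, 5), 5)
        assert grid == [direct]

    def test_roc_endpoints(self):
        labels = _labels([PLAY, NO_PLAY, NO_PLAY, PLAY])
        mi = _mi([9, 1, 5, 6])
        grid = metric_grid(labels, mi, [-np.inf, np.inf])
        assert (grid[0].se, grid[0].sp) == (1.0, 0.0)
        assert (grid[1].se, grid[1].sp) == (0.0, 1.0)
        pts = roc_points(grid)
        assert pts.tolist() == [[1.0, 1.0], [0.0, 0.0]]

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_se_nonincreasing_sp_nondecreasing_in_cutpoint(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        labels = _labels(np.where(rng.random(n) < 0.3, PLAY, NO_PLAY))
        mi = _mi(rng.integers(0, 40, n))
        grid = metric_grid(labels, mi, np.arange(0, 45, 1.0))
        ses = [m.se for m in grid if m.se is not None]
        sps = [m.sp for m in grid if m.sp is not None]
        assert all(a >= b - 1e-12 for a, b in zip(ses, ses[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(sps, sps[1:]))


# ---------------------------------------------------------------------------
# Gini stump


def _oracle_stump(values, truth):
    """Independent exhaustive search: direct Gini arithmetic per midpoint."""
    def gini(y):
        if len(y) == 0:
            return 0.0
        p = np.mean(y)
        return 1 - p**2 - (1 - p) ** 2

    n = len(values)
    parent = gini(truth)
    best_t, best_d = None, -np.inf
    for t in sorted(set((a + b) / 2 for a, b in zip(sorted(set(values)), sorted(set(values))[1:]))):
        left = truth[values < t]
        right = truth[values >= t]
        d = parent - len(left) / n * gini(left) - len(right) / n * gini(right)
        if d > best_d + 1e-12:
            best_t, best_d = t, d
    return best_t, best_d


class TestGiniStump:
    def test_perfectly_separating_midpoint(self):
        labels = _labels([NO_PLAY, NO_PLAY, PLAY, PLAY])
        mi = _mi([0, 1, 10, 12])
        stump = gini_stump(labels, mi)
        assert stump.threshold == 5.5

    def test_identical_mi_everywhere_rejected(self):
        labels = _labels([PLAY, NO_PLAY, PLAY, NO_PLAY])
        with pytest.raises(CutpointError, match="identical"):
            gini_stump(labels, _mi([4, 4, 4, 4]))

    def test_single_class_rejected(self):
        with pytest.raises(CutpointError, match="both"):
            gini_stump(_labels([PLAY, PLAY]), _mi([1, 2]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        truth = rng.random(n) < 0.2
        values = np.where(
            truth, rng.normal(20, 6, n), rng.normal(5, 4, n)
        ).round(1)
        values = np.clip(values, 0, None)
        labels = _labels(np.where(truth, PLAY, NO_PLAY))
        stump = gini_stump(labels, _mi(values))
        t_oracle, d_oracle = _oracle_stump(values, truth)
        assert stump.threshold == pytest.approx(t_oracle)
        assert stump.gini_decrease == pytest.approx(d_oracle)

    def test_matches_sklearn_depth_one_tree(self):
        sklearn = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(17)
        n = 400
        truth = rng.random(n) < 0.25
        values = np.where(truth, rng.normal(30, 8, n), rng.normal(8, 5, n))
        labels = _labels(np.where(truth, PLAY, NO_PLAY))
        stump = gini_stump(labels, _mi(np.clip(values, 0, None)))
        tree = sklearn.DecisionTreeClassifier(max_depth=1, criterion="gini")
        tree.fit(np.clip(values, 0, None).reshape(-1, 1), truth)
        # sklearn works in float32 feature space; agree to that precision
        assert stump.threshold == pytest.approx(tree.tree_.threshold[0], abs=1e-4)


class TestCrossValidation:
    def test_perfectly_separable_data(self):
        n = 200
        truth = np.arange(n) < 40
        labels = _labels(np.where(truth, PLAY, NO_PLAY))
        mi = _mi(np.where(truth, 50.0, 2.0) + np.tile([0, 0.5], n // 2))
        cv_se, cv_sp, roc = cross_validate_stump(labels, mi, k=10, seed=0)
        assert cv_se == 1.0 and cv_sp == 1.0
        assert roc == (0.0, 1.0)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(23)
        n = 300
        truth = rng.random(n) < 0.2
        labels = _labels(np.where(truth, PLAY, NO_PLAY))
        mi = _mi(rng.integers(0, 60, n))
        a = cross_validate_stump(labels, mi, k=10, seed=5)
        b = cross_validate_stump(labels, mi, k=10, seed=5)
        assert a == b

    def test_cv_se_close_to_training_se_on_simulated_data(self, default_cohort):
        from calfplay.pipeline import pooled_intervals

        labels, mi = pooled_intervals(default_cohort, 60)
        stump = gini_stump(labels, mi)
        train = metrics(contingency(labels, mi, stump.threshold))
        cv_se, _, _ = cross_validate_stump(labels, mi, k=10, seed=1)
        assert abs(cv_se - train.se) < 0.03
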