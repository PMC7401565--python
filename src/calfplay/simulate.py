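"""Seeded simulator of newborn-calf behaviour and matched leg-sensor MI.

Calves under 48 h old spend the large majority of their time lying, and
locomotor play is rare and brief.  The generator emulates this structure:

* posture alternates between lying and standing as a renewal process with
  exponential bout durations, rescaled so the expected lying fraction hits
  a target (default 0.80 over 48 h);
* locomotor play occurs only while standing (it requires the calf to be on
  its feet) and is temporally clustered: play *sessions* arrive as a Poisson
  process within standing time and each session holds a short burst of
  bouts a few tens of seconds apart.  Bout durations are log-normal with a
  median of a few seconds.  The marginal bout rate per standing hour is the
  configured ``play_bout_rate_per_h``;
* the per-second MI is Poisson with a category-specific rate
  (lying << standing << play), plus a fixed spike at every posture
  transition — the sensor registers the lying-to-standing (and back)
  movement itself, which is why cumulative MI can correlate with the number
  of lying bouts even though lying itself is near-motionless;
* occasional out-of-view episodes are overlaid as meta events.

Each calf draws from an independent random stream derived from
``(seed, calf_index)``, so cohorts are reproducible and calves exchangeable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ethogram import BehaviourEvent, EventLog
from .motion import MISeries

__all__ = ["SimulationConfig", "simulate_calf", "simulate_cohort"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults describe ten group-housed calves observed for 48 h: lying
    ~80% of time in ~30 min bouts, ~7 play bouts per standing hour arriving
    in sessions of ~2.7 bouts, play bouts with a 6 s median duration, and
    MI rates ordered lying < active < play.
    """

    n_calves: int = 10
    duration_s: int = 172_800  # 48 h
    seed: int = 0
    lying_fraction_target: float = 0.80
    mean_lying_bout_s: float = 1800.0
    mean_active_bout_s: float = 450.0
    play_bout_rate_per_h: float = 9.0  # marginal rate per hour of standing
    bouts_per_session_mean: float = 2.7
    within_session_gap_s: float = 40.0
    play_bout_duration_median_s: float = 6.0
    play_bout_duration_sigma: float = 0.5
    mi_rate_lying: float = 0.005  # expected MI counts per second while lying
    mi_rate_active: float = 0.5
    mi_rate_play: float = 60.0
    transition_spike_mi: float = 30.0
    out_of_view_rate_per_h: float = 0.1
    out_of_view_duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.n_calves < 1 or self.duration_s <= 0:
            raise ValueError("need at least one calf and a positive duration")
        if not 0.0 < self.lying_fraction_target < 1.0:
            raise ValueError("lying_fraction_target must be in (0, 1)")
        rates = (
            self.play_bout_rate_per_h,
            self.out_of_view_rate_per_h,
            self.transition_spike_mi,
        )
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if not (
            self.mi_rate_play > self.mi_rate_active > self.mi_rate_lying >= 0.0
        ):
            raise ValueError("MI rates must satisfy play > active > lying >= 0")
        if self.mean_lying_bout_s <= 0 or self.mean_active_bout_s <= 0:
            raise ValueError("mean bout durations must be positive")
        if self.bouts_per_session_mean < 1.0:
            raise ValueError("sessions hold at least one bout on average")

    def rescaled_bout_means(self) -> tuple[float, float]:
        """Lying/active bout means rescaled so the expected lying fraction
        equals the target while preserving the mean cycle length."""
        cycle = self.mean_lying_bout_s + self.mean_active_bout_s
        return (
            self.lying_fraction_target * cycle,
            (1.0 - self.lying_fraction_target) * cycle,
        )


def _calf_rng(config: SimulationConfig, calf_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, calf_index])


def _posture_intervals(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[str, float, float]]:
    """Alternating (state, start, end) covering [0, duration_s)."""
    mean_lie, mean_stand = config.rescaled_bout_means()
    out: list[tuple[str, float, float]] = []
    t = 0.0
    state = "lying" if rng.random() < config.lying_fraction_target else "standing"
    while t < config.duration_s:
        mean = mean_lie if state == "lying" else mean_stand
        dur = rng.exponential(mean)
        end = min(t + dur, config.duration_s)
        if end > t:
            out.append((state, t, end))
        t = end
        state = "standing" if state == "lying" else "lying"
    return out


def _play_bouts_in_standing(
    config: SimulationConfig,
    rng: np.random.Generator,
    start: float,
    end: float,
) -> list[tuple[float, float]]:
    """Clustered play bouts within one standing period.

    Sessions arrive Poisson at rate (bout rate / bouts per session); each
    session is a burst of bouts separated by short gaps (> 1 s, so bouts
    remain distinct episodes), truncated at the end of the standing period.
    """
    if config.play_bout_rate_per_h <= 0:
        return []
    session_rate_per_s = (
        config.play_bout_rate_per_h / config.bouts_per_session_mean / 3600.0
    )
    n_sessions = rng.poisson(session_rate_per_s * (end - start))
    mu = math.log(config.play_bout_duration_median_s)
    bouts: list[tuple[float, float]] = []
    for s0 in np.sort(rng.uniform(start, end, size=n_sessions)):
        n_bouts = 1 + rng.poisson(config.bouts_per_session_mean - 1.0)
        t = s0
        for _ in range(n_bouts):
            dur = rng.lognormal(mu, config.play_bout_duration_sigma)
            b_end = min(t + dur, end)
            if b_end - t >= 0.5:
                bouts.append((t, b_end))
            if b_end >= end:
                break
            t = b_end + 1.5 + rng.exponential(config.within_session_gap_s)
            if t >= end:
                break
    return _dedupe_sorted(bouts)


def _dedupe_sorted(bouts: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Sort and clip overlaps from adjacent sessions (keep bouts disjoint,
    separated by > 1 s so they are distinct episodes)."""
    out: list[tuple[float, float]] = []
    for s, e in sorted(bouts):
        if out and s < out[-1][1] + 1.1:
            s = out[-1][1] + 1.1
        if e - s >= 0.5:
            out.append((s, e))
    return out


def simulate_calf(
    config: SimulationConfig, calf_index: int
) -> tuple[EventLog, MISeries]:
    """Generate one calf's 48 h event log and matched 1 s MI series."""
    rng = _calf_rng(config, calf_index)
    calf_id = f"calf{calf_index:02d}"
    T = int(config.duration_s)

    posture = _posture_intervals(config, rng)
    events: list[BehaviourEvent] = []
    play_all: list[tuple[float, float]] = []
    transitions: list[float] = []

    for k, (state, start, end) in enumerate(posture):
        if k > 0:
            transitions.append(start)
        if state == "lying":
            events.append(BehaviourEvent(calf_id, "l", "resting", start, end))
            continue
        bouts = _play_bouts_in_standing(config, rng, start, end)
        play_all.extend(bouts)
        # carve standing around play: behaviours are mutually exclusive
        t = start
        for b_start, b_end in bouts:
            if b_start > t:
                events.append(BehaviourEvent(calf_id, "t", "active", t, b_start))
            events.append(BehaviourEvent(calf_id, "p", "play", b_start, b_end))
            t = b_end
        if end > t:
            events.append(BehaviourEvent(calf_id, "t", "active", t, end))

    # out-of-view episodes overlay everything else
    n_oov = rng.poisson(config.out_of_view_rate_per_h * T / 3600.0)
    for s0 in np.sort(rng.uniform(0, T, size=n_oov)):
        e0 = min(s0 + rng.exponential(config.out_of_view_duration_s), T)
        if e0 > s0:
            events.append(BehaviourEvent(calf_id, "O", "meta", s0, e0))

    log = EventLog(calf_id, 0.0, float(T), events)

    # per-second MI: Poisson with category-occupancy-weighted rate
    rate = np.full(T, config.mi_rate_lying, dtype=float)
    for state, start, end in posture:
        if state == "standing":
            _add_occupancy(rate, start, end, config.mi_rate_active - config.mi_rate_lying)
    for b_start, b_end in play_all:
        _add_occupancy(rate, b_start, b_end, config.mi_rate_play - config.mi_rate_active)
    mi = rng.poisson(rate).astype(float)
    for t in transitions:
        sec = min(int(t), T - 1)
        mi[sec] += config.transition_spike_mi
    return log, MISeries(calf_id, 1, 0.0, mi)


def _add_occupancy(rate: np.ndarray, start: float, end: float, delta: float) -> None:
    """Add ``delta`` weighted by fractional overlap with each 1 s bin."""
    i0, i1 = int(math.floor(start)), int(math.ceil(end))
    if i1 <= i0:
        return
    idx = np.arange(i0, min(i1, len(rate)))
    overlap = np.minimum(idx + 1, end) - np.maximum(idx, start)
    rate[idx] += delta * np.clip(overlap, 0.0, 1.0)


def simulate_cohort(
    config: SimulationConfig, calf_indices: list[int] | None = None
) -> list[tuple[EventLog, MISeries]]:
    """Simulate ``n_calves`` independent calves (deterministic given seed)."""
    if calf_indices is None:
        calf_indices = list(range(config.n_calves))
    return [simulate_calf(config, i) for i in calf_indices]
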