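"""Motion-index (MI) time series from a leg-mounted tri-axial accelerometer.

The MI is a single non-negative integer per sampling interval summarising
leg movement — it grows with both the duration and the vigour of movement,
and is derived from the vector sum of tri-axial acceleration.  Commercial
loggers export it at fixed resolutions (1 s up to 1 week); the device's own
formula is proprietary, so :func:`surrogate_mi` provides a documented
stand-in used by the simulator: per interval, the summed absolute deviation
of the acceleration magnitude from its per-interval median (the gravity
baseline), scaled and rounded to a whole integer.  A motionless trace yields
MI = 0 regardless of sensor orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISeries",
    "AccelTrace",
    "ALLOWED_RESOLUTIONS_S",
    "read_mi_series",
    "write_mi_series",
    "aggregate_mi",
    "cumulative_mi",
    "surrogate_mi",
    "MISeriesError",
]

#: Export resolutions supported by the logger: 1 s, 1 min, 15 min, 1 h,
#: 2 h, 1 d, 1 week.
ALLOWED_RESOLUTIONS_S = (1, 60, 900, 3600, 7200, 86400, 604800)

SAMPLE_RATE_HZ = 16


class MISeriesError(ValueError):
    """Raised for invalid MI series data."""


@dataclass
class MISeries:
    """Regularly gridded MI values for one calf.

    ``values[k]`` covers the half-open interval
    ``[start_s + k*resolution_s, start_s + (k+1)*resolution_s)``.
    """

    calf_id: str
    resolution_s: int
    start_s: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.resolution_s not in ALLOWED_RESOLUTIONS_S:
            raise MISeriesError(
                f"resolution {self.resolution_s}s not in {ALLOWED_RESOLUTIONS_S}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise MISeriesError("values must be one-dimensional")
        if np.any(self.values < 0):
            raise MISeriesError("MI values must be non-negative")
        if self.start_s % self.resolution_s != 0:
            raise MISeriesError(
                f"grid anchor {self.start_s} not aligned to {self.resolution_s}s grid"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end_s(self) -> float:
        return self.start_s + len(self.values) * self.resolution_s

    def interval_starts(self) -> np.ndarray:
        return self.start_s + self.resolution_s * np.arange(len(self.values))


@dataclass
class AccelTrace:
    """Raw tri-axial acceleration sampled at 16 Hz (arbitrary units)."""

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate_hz: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise MISeriesError("axis arrays must have equal length")
        if self.sample_rate_hz != SAMPLE_RATE_HZ:
            raise MISeriesError(f"sample rate fixed at {SAMPLE_RATE_HZ} Hz")

    def __len__(self) -> int:
        return len(self.ax)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)


def read_mi_series(path) -> MISeries:
    """Read an MI series export: columns ``calf_id,timestamp_s,mi``.

    Rows must be equally spaced at one of the supported resolutions; a
    missing interval is a hard error (calves with sensor gaps are excluded
    from analysis rather than imputed).
    """
    frame = pd.read_csv(path, dtype={"calf_id": str})
    required = {"calf_id", "timestamp_s", "mi"}
    missing = required - set(frame.columns)
    if missing:
        raise MISeriesError(f"{path}: missing columns {sorted(missing)}")
    if len(frame) < 2:
        raise MISeriesError(f"{path}: need at least two rows to infer resolution")
    ts = frame["timestamp_s"].to_numpy(dtype=float)
    gaps = np.diff(ts)
    resolution = gaps.min()
    if resolution <= 0:
        raise MISeriesError(f"{path}: non-increasing timestamps")
    if not np.all(gaps == resolution):
        k = int(np.argmax(gaps != resolution))
        raise MISeriesError(
            f"{path}: gap in series at timestamp {ts[k]} "
            f"(expected spacing {resolution}s, found {gaps[k]}s)"
        )
    if int(resolution) != resolution or int(resolution) not in ALLOWED_RESOLUTIONS_S:
        raise MISeriesError(f"{path}: unsupported resolution {resolution}s")
    calf_ids = frame["calf_id"].unique()
    if len(calf_ids) != 1:
        raise MISeriesError(f"{path}: multiple calf ids {sorted(calf_ids)}")
    values = frame["mi"].to_numpy(dtype=float)
    if np.any(values < 0):
        k = int(np.argmax(values < 0))
        raise MISeriesError(f"{path}: negative MI at timestamp {ts[k]}")
    return MISeries(str(calf_ids[0]), int(resolution), float(ts[0]), values)


def write_mi_series(series: MISeries, path) -> None:
    frame = pd.DataFrame(
        {
            "calf_id": series.calf_id,
            "timestamp_s": series.interval_starts().astype(int),
            "mi": series.values,
        }
    )
    frame.to_csv(path, index=False)


def aggregate_mi(series: MISeries, target_resolution_s: int) -> MISeries:
    """Re-grid to a coarser resolution by summing constituent values.

    MI accumulates over its interval, so coarse values are the sum of the
    fine values they cover.  A trailing partial interval is dropped
    (analysis starts at the first complete interval and uses only complete
    ones).
    """
    if target_resolution_s % series.resolution_s != 0:
        raise MISeriesError(
            f"target resolution {target_resolution_s}s is not a multiple of "
            f"{series.resolution_s}s"
        )
    if series.start_s % target_resolution_s != 0:
        raise MISeriesError("series anchor not aligned to target grid")
    factor = target_resolution_s // series.resolution_s
    n_out = len(series.values) // factor
    values = series.values[: n_out * factor].reshape(n_out, factor).sum(axis=1)
    return MISeries(series.calf_id, int(target_resolution_s), series.start_s, values)


def cumulative_mi(series: MISeries, window: tuple[float, float]) -> float:
    """Total MI accumulated over an aligned window (e.g., a 24 h or 48 h
    sample period)."""
    lo, hi = window
    if lo % series.resolution_s != 0 or hi % series.resolution_s != 0:
        raise MISeriesError("window must be aligned to the series grid")
    if hi < lo:
        raise MISeriesError("window ends before it starts")
    if lo < series.start_s or hi > series.end_s:
        raise MISeriesError(
            f"window [{lo}, {hi}] outside series span "
            f"[{series.start_s}, {series.end_s}]"
        )
    i = int((lo - series.start_s) // series.resolution_s)
    j = int((hi - series.start_s) // series.resolution_s)
    return float(series.values[i:j].sum())


def surrogate_mi(
    trace: AccelTrace,
    resolution_s: int,
    calf_id: str = "trace",
    scale: float = 0.25,
    round_to_int: bool = True,
) -> MISeries:
    """Documented surrogate for the proprietary on-device MI computation.

    Per interval: ``MI = scale * sum(|magnitude - g0|)`` over the interval's
    samples, where ``g0`` is the per-interval median acceleration magnitude
    (the gravity baseline) and magnitude is the vector sum
    ``sqrt(ax^2+ay^2+az^2)``.  The result is rounded to whole integers,
    matching how the logger reports MI.  A perfectly still trace gives 0 in
    every interval, whatever the sensor orientation; doubling the deviation
    amplitude doubles the (unrounded) MI.
    """
    samples_per_interval = resolution_s * trace.sample_rate_hz
    n_intervals = len(trace) // samples_per_interval
    if n_intervals == 0:
        raise MISeriesError(
            f"trace shorter than one {resolution_s}s interval "
            f"({len(trace)} < {samples_per_interval} samples)"
        )
    mag = trace.magnitude()[: n_intervals * samples_per_interval]
    mag = mag.reshape(n_intervals, samples_per_interval)
    g0 = np.median(mag, axis=1, keepdims=True)
    mi = scale * np.abs(mag - g0).sum(axis=1)
    if round_to_int:
        mi = np.round(mi)
    return MISeries(calf_id, int(resolution_s), 0.0, mi)
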