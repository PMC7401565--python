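"""End-to-end pipeline: simulate -> correlate -> metrics -> calibrate -> report.

Each stage writes delimited-text tables into the output directory:

* ``correlations.csv`` — cumulative-MI vs behaviour-budget correlations per
  observation window (coefficient, p-value, method, significance flag);
* ``cutpoints_1min.csv`` / ``cutpoints_15min.csv`` — Se/Sp/balanced-accuracy
  grids over MI cut points, percentages to 1 decimal place, plus ROC point
  files and the cross-validated Gini stump;
* ``onezero.csv`` — one-zero calibration: visual vs MI-equivalent scores
  (3 decimal places), calibrated integer thresholds, held-out validation.

Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation import correlation_report, run_correlation_table
from .cutpoints import (
    BinaryIntervalSeries,
    binarize_play,
    cross_validate_stump,
    gini_stump,
    metric_grid,
    roc_points,
)
from .ethogram import EventLog, read_event_log, write_event_log
from .motion import MISeries, aggregate_mi, read_mi_series, write_mi_series
from .onezero import calibrate_threshold, validate_threshold
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "pooled_intervals", "load_cohort"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "correlate", "metrics", "calibrate", "report")

DEFAULT_GRID_1MIN = (3, 5, 10, 20, 30, 40, 50, 60)
DEFAULT_GRID_15MIN = (20, 25, 30, 35, 40, 45, 50, 100, 200, 300)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: Path
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    simulation: SimulationConfig | None = None
    input_manifest: Path | None = None  # alternative to simulating
    resolutions: tuple[int, ...] = (60, 900)
    grid_1min: tuple[float, ...] = DEFAULT_GRID_1MIN
    grid_15min: tuple[float, ...] = DEFAULT_GRID_15MIN
    cv_folds: int = 10
    calibration_tolerance: float = 0.1
    train_calves: tuple[int, ...] | None = None  # explicit split; else first half

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages {sorted(unknown)}")
        if self.simulation is None and "simulate" in self.stages:
            self.simulation = SimulationConfig(seed=self.seed)

    @classmethod
    def from_file(cls, path: Path) -> "PipelineConfig":
        """Load a JSON config; keys mirror the dataclass fields, with an
        optional nested ``simulation`` object."""
        raw = json.loads(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(
            out_dir=Path(raw.pop("out_dir", "results")),
            stages=tuple(raw.pop("stages", STAGES)),
            simulation=SimulationConfig(**sim) if sim else None,
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.items()
            },
        )
        return cfg


def pooled_intervals(
    cohort: list[tuple[EventLog, MISeries]],
    resolution_s: int,
) -> tuple[BinaryIntervalSeries, MISeries]:
    """Binarize and aggregate every calf, then pool intervals cohort-wide.

    The paper-style analysis treats each (calf, interval) pair as one sample
    point; pooling concatenates the per-calf streams on a common nominal
    grid."""
    labels_parts, mi_parts = [], []
    for log, mi in cohort:
        labels = binarize_play(log, resolution_s)
        mi_coarse = aggregate_mi(mi, resolution_s)
        n = min(len(labels), len(mi_coarse))
        labels_parts.append(labels.labels[:n])
        mi_parts.append(mi_coarse.values[:n])
    return (
        BinaryIntervalSeries(resolution_s, 0.0, np.concatenate(labels_parts)),
        MISeries("pooled", resolution_s, 0.0, np.concatenate(mi_parts)),
    )


def load_cohort(manifest_path: Path) -> list[tuple[EventLog, MISeries]]:
    """Load (event-log, MI-series) file pairs listed in a JSON manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    base = Path(manifest_path).parent
    cohort = []
    for entry in manifest["calves"]:
        log = read_event_log(base / entry["events"])
        mi = read_mi_series(base / entry["mi"])
        cohort.append((log, mi))
    return cohort


def _write_cohort(
    cohort: list[tuple[EventLog, MISeries]], out: Path, config: PipelineConfig
) -> Path:
    data_dir = out / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for log, mi in cohort:
        ev_name = f"{log.calf_id}_events.csv"
        mi_name = f"{log.calf_id}_mi_1s.csv"
        write_event_log(log, data_dir / ev_name)
        write_mi_series(mi, data_dir / mi_name)
        entries.append({"calf_id": log.calf_id, "events": ev_name, "mi": mi_name})
    manifest = {
        "seed": config.seed,
        "simulation": dataclasses.asdict(config.simulation) if config.simulation else None,
        "calves": entries,
    }
    path = data_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _resolution_tag(resolution_s: int) -> str:
    return {60: "1min", 900: "15min"}.get(resolution_s, f"{resolution_s}s")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in order; returns the artifact map."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"out_dir": str(out)}
    row_counts: dict[str, int] = {}

    cohort: list[tuple[EventLog, MISeries]] | None = None
    try:
        if "simulate" in config.stages:
            assert config.simulation is not None
            cohort = simulate_cohort(config.simulation)
            artifacts["manifest"] = str(_write_cohort(cohort, out, config))
            row_counts["calves"] = len(cohort)
        elif config.input_manifest is not None:
            cohort = load_cohort(config.input_manifest)
            row_counts["calves"] = len(cohort)

        needs_cohort = {"correlate", "metrics", "calibrate"} & set(config.stages)
        if needs_cohort and cohort is None:
            raise PipelineError(
                f"stages {sorted(needs_cohort)} need input data: run the "
                "simulate stage or provide input_manifest"
            )

        if "correlate" in config.stages:
            assert cohort is not None
            results = run_correlation_table(cohort)
            frame = correlation_report(results)
            frame.to_csv(out / "correlations.csv", index=False)
            artifacts["correlations"] = str(out / "correlations.csv")
            row_counts["correlations"] = len(frame)

        if "metrics" in config.stages:
            assert cohort is not None
            for res in config.resolutions:
                tag = _resolution_tag(res)
                labels, mi = pooled_intervals(cohort, res)
                grid = config.grid_1min if res == 60 else config.grid_15min
                rows = metric_grid(labels, mi, grid)
                frame = pd.DataFrame(
                    {
                        "cutpoint": [m.cutpoint for m in rows],
                        "sensitivity_pct": [_pct(m.se) for m in rows],
                        "specificity_pct": [_pct(m.sp) for m in rows],
                        "balanced_accuracy_pct": [_pct(m.balanced_accuracy) for m in rows],
                    }
                )
                frame.to_csv(out / f"cutpoints_{tag}.csv", index=False)
                pts = roc_points(rows)
                pd.DataFrame(pts, columns=["fpr", "se"]).to_csv(
                    out / f"roc_{tag}.csv", index=False
                )
                stump = gini_stump(labels, mi)
                cv_se, cv_sp, _ = cross_validate_stump(
                    labels, mi, k=config.cv_folds, seed=config.seed
                )
                (out / f"stump_{tag}.json").write_text(
                    json.dumps(
                        {
                            "threshold": stump.threshold,
                            "gini_decrease": stump.gini_decrease,
                            "cv_se": cv_se,
                            "cv_sp": cv_sp,
                            "cv_balanced_accuracy": (cv_se + cv_sp) / 2,
                        },
                        indent=2,
                        sort_keys=True,
                    )
                    + "\n"
                )
                artifacts[f"cutpoints_{tag}"] = str(out / f"cutpoints_{tag}.csv")
                artifacts[f"stump_{tag}"] = str(out / f"stump_{tag}.json")
                row_counts[f"cutpoints_{tag}"] = len(frame)

        if "calibrate" in config.stages:
            assert cohort is not None
            train_ids = (
                set(config.train_calves)
                if config.train_calves is not None
                else set(range(len(cohort) // 2))
            )
            train = [c for i, c in enumerate(cohort) if i in train_ids]
            test = [c for i, c in enumerate(cohort) if i not in train_ids]
            records = []
            for res in config.resolutions:
                tag = _resolution_tag(res)
                labels1, mi1 = pooled_intervals(train, res)
                calib = calibrate_threshold(labels1, mi1)
                records.append(_onezero_row(tag, "train", "visual", calib.visual, None))
                records.append(
                    _onezero_row(tag, "train", f"MI>={calib.threshold}", calib.mi_equiv, calib.threshold)
                )
                if test:
                    labels2, mi2 = pooled_intervals(test, res)
                    valid = validate_threshold(
                        calib.threshold, labels2, mi2, config.calibration_tolerance
                    )
                    records.append(_onezero_row(tag, "holdout", "visual", valid.visual, None))
                    row = _onezero_row(
                        tag, "holdout", f"MI>={valid.threshold}", valid.mi_equiv, valid.threshold
                    )
                    row["passed"] = valid.passed
                    records.append(row)
            frame = pd.DataFrame(records)
            frame.to_csv(out / "onezero.csv", index=False)
            artifacts["onezero"] = str(out / "onezero.csv")
            row_counts["onezero"] = len(frame)

        if "report" in config.stages:
            expected = [
                out / "correlations.csv",
                out / "onezero.csv",
            ] + [out / f"cutpoints_{_resolution_tag(r)}.csv" for r in config.resolutions]
            missing = [str(p) for p in expected if not p.exists()]
            if missing:
                raise PipelineError(f"report stage: missing inputs {missing}")
            log_lines = [
                f"calfplay {__version__}",
                f"seed: {config.seed}",
                f"stages: {','.join(config.stages)}",
            ] + [f"rows[{k}]: {v}" for k, v in sorted(row_counts.items())]
            (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
            artifacts["run_log"] = str(out / "run_log.txt")
    except Exception:
        (out / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise
    return artifacts


def _pct(x: float | None) -> float | None:
    return None if x is None else round(100.0 * x, 1)


def _onezero_row(tag, dataset, method, score, threshold) -> dict:
    return {
        "resolution": tag,
        "dataset": dataset,
        "method": method,
        "positives": score.positives,
        "total": score.total,
        "score": score.rounded(),
        "threshold": threshold,
    }
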