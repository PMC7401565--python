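"""Normality-gated correlation of cumulative MI with behaviour budgets.

For each observation window the cumulative MI per calf is correlated with
each behaviour group's total duration and bout count across calves.  The
method is chosen per pair: Pearson's r when at least one of the two samples
passes an Anderson-Darling normality check at the 5% level, Spearman's rank
correlation otherwise.  Significance is flagged at p < 0.05 (two-sided).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ethogram import BEHAVIOUR_GROUPS, EventLog, time_budget
from .motion import MISeries, cumulative_mi

__all__ = [
    "CorrelationResult",
    "anderson_darling_normal",
    "select_method",
    "correlate",
    "run_correlation_table",
    "DEFAULT_WINDOWS",
    "AD_CRITICAL_5PCT",
]

#: 5% critical value for the Anderson-Darling statistic A2* with both mean
#: and variance estimated from the sample (Stephens' tabulation).
AD_CRITICAL_5PCT = 0.752

#: Four consecutive 12 h windows plus the combined 48 h window, in seconds.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "0-12h": (0.0, 43_200.0),
    "12-24h": (43_200.0, 86_400.0),
    "24-36h": (86_400.0, 129_600.0),
    "36-48h": (129_600.0, 172_800.0),
    "0-48h": (0.0, 172_800.0),
}


@dataclass(frozen=True)
class CorrelationResult:
    behaviour_group: str
    measure: str  # duration | bout_count
    window: str
    method: str  # pearson | spearman
    coefficient: float
    p_value: float
    n: int
    significant: bool


def anderson_darling_normal(x: np.ndarray) -> tuple[float, bool]:
    """Anderson-Darling test of composite normality.

    Returns ``(A2_star, is_normal)`` where ``A2*`` carries the small-sample
    correction ``A2 * (1 + 0.75/n + 2.25/n^2)`` for estimated mean and
    variance, and the sample is declared normal iff A2* is below the 5%
    critical value 0.752.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 observations, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("Anderson-Darling statistic undefined for a constant sample")
    y = np.sort((x - x.mean()) / sd)
    cdf = stats.norm.cdf(y)
    # clip away exact 0/1 from extreme standardised values
    cdf = np.clip(cdf, 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1])))
    a2_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    return float(a2_star), bool(a2_star < AD_CRITICAL_5PCT)


def select_method(x: np.ndarray, y: np.ndarray) -> str:
    """Pearson iff at least one sample looks normal; Spearman otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")

    def _normal(v: np.ndarray) -> bool:
        try:
            return anderson_darling_normal(v)[1]
        except ValueError:  # constant sample is certainly not normal
            return False

    return "pearson" if _normal(x) or _normal(y) else "spearman"


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p for Spearman's r_s (n <= 9)."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    r_perm = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(r_perm) >= abs(observed) - 1e-12))


def correlate(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    Pearson uses the t-distribution p-value.  Spearman uses average ranks
    for ties, with an exact permutation p-value for n <= 9 and the
    t-approximation for larger samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if method == "spearman":
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        r, p = stats.pearsonr(rx, ry)
        if n <= 9:
            p = _exact_spearman_p(rx, ry, r)
        return float(r), float(p)
    raise ValueError(f"unknown method {method!r}")


def run_correlation_table(
    cohort: list[tuple[EventLog, MISeries]],
    windows: dict[str, tuple[float, float]] | None = None,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Correlate cumulative MI against behaviour budgets across calves.

    One result per behaviour group x measure x window.  A calf whose MI
    series does not cover a window is dropped from that window only.
    Windows with fewer than three calves, or with a constant variable, yield
    an undefined (NaN) result.
    """
    if windows is None:
        windows = DEFAULT_WINDOWS
    results: list[CorrelationResult] = []
    for win_name, (lo, hi) in windows.items():
        mi_vals: list[float] = []
        budgets = []
        for log, mi in cohort:
            if mi.start_s > lo or mi.end_s < hi:
                continue  # missing MI for this window: drop the calf here only
            mi_vals.append(cumulative_mi(mi, (lo, hi)))
            budgets.append(time_budget(log, (lo, hi)))
        x = np.asarray(mi_vals)
        for group in BEHAVIOUR_GROUPS:
            for measure in ("duration", "bout_count"):
                y = np.asarray(
                    [
                        b[group].duration_s if measure == "duration" else b[group].bout_count
                        for b in budgets
                    ],
                    dtype=float,
                )
                n = len(y)
                try:
                    if n < 3:
                        raise ValueError("fewer than 3 calves")
                    method = select_method(x, y)
                    coef, p = correlate(x, y, method)
                except ValueError:
                    results.append(
                        CorrelationResult(
                            group, measure, win_name, "undefined",
                            float("nan"), float("nan"), n, False,
                        )
                    )
                    continue
                results.append(
                    CorrelationResult(
                        group, measure, win_name, method, coef, p, n, p < alpha
                    )
                )
    return results


def correlation_report(results: list[CorrelationResult]) -> pd.DataFrame:
    """Render results as a wide table: one row per behaviour x measure,
    coefficient and p-value per window, significance starred."""
    frame = pd.DataFrame([r.__dict__ for r in results])
    frame["coefficient"] = frame["coefficient"].round(3)
    frame["p_value"] = frame["p_value"].round(3)
    frame["flag"] = np.where(frame["significant"], "*", "")
    return frame
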