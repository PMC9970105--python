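"""Restoration assessment against historical reference conditions.

The historical range of variation (HRV) for stand basal area and density is
the reconstruction mean +/- 1 SD.  For each severity on the sweep grid the
fraction of simulated stand x iteration outcomes inside the HRV defines a
restoration probability; the restorative severity window at a threshold
(0.90 / 0.75 / 0.50) is the longest contiguous run of grid severities meeting
it.  Windows generalize across forests via the interquartile range of pooled
in-window severities, and validation uses mean bias error, empirical 95%
prediction-interval coverage (with near-zero lower bounds rounded to zero),
and restorative-range classification accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HistoricalReference",
    "RestorativeRange",
    "ValidationMetrics",
    "METRIC_COLUMNS",
    "hrv_bounds",
    "proportion_within",
    "proportions_by_severity",
    "restorative_range",
    "average_range",
    "generalized_range",
    "window_fraction",
    "validate",
]

#: assessed stand metric -> outcomes-table column
METRIC_COLUMNS = {"basal_area": "ba_live", "density": "tph_live"}


@dataclass(frozen=True)
class HistoricalReference:
    """Historical reference condition for one forest x forest type."""

    forest: str
    forest_type: str
    ba_mean: float  # m^2/ha
    ba_sd: float
    tph_mean: float  # trees/ha
    tph_sd: float
    composition: dict  # basal-area proportions by composition group

    def __post_init__(self) -> None:
        for name in ("ba_mean", "ba_sd", "tph_mean", "tph_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition proportions must sum to 1, got {total}")


@dataclass(frozen=True)
class RestorativeRange:
    """Severity window meeting a restoration-probability threshold.

    ``lo``/``hi`` are None for an empty window.
    """

    metric: str
    threshold: float
    lo: float | None
    hi: float | None
    forest: str = ""
    forest_type: str = ""

    def __post_init__(self) -> None:
        if (self.lo is None) != (self.hi is None):
            raise ValueError("lo and hi must both be set or both be None")
        if self.lo is not None and self.lo > self.hi:
            raise ValueError("lo must be <= hi")

    @property
    def empty(self) -> bool:
        return self.lo is None

    def contains(self, severity) -> np.ndarray:
        """Inclusive membership test (vectorized)."""
        severity = np.asarray(severity, dtype=float)
        if self.empty:
            return np.zeros(severity.shape, dtype=bool)
        return (severity >= self.lo) & (severity <= self.hi)


@dataclass(frozen=True)
class ValidationMetrics:
    """Stand-level validation summary.

    MBE is mean(observed - modeled mean): negative values mean the model
    overestimates.  Coverage is the fraction of records inside the empirical
    95% prediction band; accuracy is agreement between observed-in-HRV and
    severity-in-restorative-range.
    """

    mbe_ba: float
    mbe_tph: float
    coverage_ba: float
    coverage_tph: float
    accuracy_ba: float
    accuracy_tph: float
    n_used: int
    n_excluded: int


def hrv_bounds(ref: HistoricalReference, metric: str) -> tuple[float, float]:
    """HRV interval for a metric: (mean - SD, mean + SD), floored at zero."""
    if metric == "basal_area":
        mean, sd = ref.ba_mean, ref.ba_sd
    elif metric == "density":
        mean, sd = ref.tph_mean, ref.tph_sd
    else:
        raise ValueError(f"metric must be 'basal_area' or 'density', got {metric!r}")
    return max(0.0, mean - sd), mean + sd


def proportion_within(outcomes: pd.DataFrame, bounds: tuple[float, float], metric: str) -> float:
    """Fraction of outcomes whose metric lies inside [lo, hi] (inclusive)."""
    if outcomes.empty:
        raise ValueError("empty outcomes")
    values = outcomes[METRIC_COLUMNS[metric]].to_numpy(dtype=float)
    lo, hi = bounds
    return float(np.mean((values >= lo) & (values <= hi)))


def proportions_by_severity(
    outcomes: pd.DataFrame, bounds: tuple[float, float], metric: str
) -> pd.Series:
    """Restoration probability per grid severity (index severity -> fraction)."""
    if outcomes.empty:
        raise ValueError("empty outcomes")
    col = METRIC_COLUMNS[metric]
    lo, hi = bounds
    inside = outcomes[col].between(lo, hi)
    return inside.groupby(outcomes["severity"]).mean()


def restorative_range(
    proportions: pd.Series | dict,
    threshold: float,
    *,
    metric: str = "basal_area",
    forest: str = "",
    forest_type: str = "",
) -> RestorativeRange:
    """Longest contiguous run of grid severities with fraction >= threshold.

    Ties between equal-length runs break toward lower severity; an empty
    window is returned when no grid point qualifies.
    """
    if isinstance(proportions, dict):
        proportions = pd.Series(proportions)
    sev = proportions.index.to_numpy(dtype=float)
    order = np.argsort(sev)
    sev = sev[order]
    ok = proportions.to_numpy(dtype=float)[order] >= threshold
    best = None  # (length, start, end) of best run in grid indices
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            length = i - start
            if best is None or length > best[0]:
                best = (length, start, i - 1)
            start = None
    kw = dict(metric=metric, threshold=threshold, forest=forest, forest_type=forest_type)
    if best is None:
        return RestorativeRange(lo=None, hi=None, **kw)
    return RestorativeRange(lo=float(sev[best[1]]), hi=float(sev[best[2]]), **kw)


def average_range(ranges: list[RestorativeRange]) -> tuple[float, float]:
    """Unweighted mean of window endpoints across forest x type groups.

    Empty member windows are excluded with a warning.
    """
    nonempty = [r for r in ranges if not r.empty]
    dropped = len(ranges) - len(nonempty)
    if dropped:
        warnings.warn(f"excluded {dropped} empty restorative range(s) from averaging", UserWarning)
    if not nonempty:
        raise ValueError("no nonempty ranges to average")
    return (
        float(np.mean([r.lo for r in nonempty])),
        float(np.mean([r.hi for r in nonempty])),
    )


def generalized_range(
    ranges: list[RestorativeRange], grid: np.ndarray
) -> tuple[float, float]:
    """Interquartile range of grid severities pooled over all member windows.

    Each window contributes every grid severity it contains (with multiplicity
    across groups); the 25th-75th percentiles use linear interpolation.
    """
    grid = np.asarray(grid, dtype=float)
    pool = []
    for r in ranges:
        if not r.empty:
            pool.append(grid[r.contains(grid)])
    if not pool:
        raise ValueError("no grid severities fall inside any range")
    pooled = np.concatenate(pool)
    if pooled.size == 0:
        raise ValueError("no grid severities fall inside any range")
    lo, hi = np.percentile(pooled, [25.0, 75.0])
    return float(lo), float(hi)


def window_fraction(rng: RestorativeRange, observed_span: tuple[float, float]) -> int:
    """Window width as a nearest-integer percent of the observed severity span."""
    if rng.empty:
        raise ValueError("empty restorative range has no width")
    lo, hi = observed_span
    if hi - lo <= 0:
        raise ValueError("observed span must have positive width")
    return int(round(100.0 * (rng.hi - rng.lo) / (hi - lo)))


_ZERO_FLOOR = {"basal_area": 1.0, "density": 5.0}  # near-zero lower-bound rounding


def _prediction_band(values: np.ndarray, metric: str) -> tuple[float, float]:
    lo, hi = np.percentile(values, [2.5, 97.5])
    if lo < _ZERO_FLOOR[metric]:
        lo = 0.0
    return float(lo), float(hi)


def validate(
    records: pd.DataFrame,
    sweep: pd.DataFrame,
    ranges75: dict,
    refs: dict,
) -> ValidationMetrics:
    """Validation metrics against independent post-fire observations.

    Each record (columns severity, forest, forest_type, ba_obs, tph_obs) is
    matched to the simulated outcomes of its forest x forest type at the
    nearest grid severity.  ``ranges75`` and ``refs`` map
    (forest, forest_type) to the >=75% restorative window per metric (nested
    dict by metric) and the historical reference.
    """
    grid = np.unique(sweep["severity"])
    obs_col = {"basal_area": "ba_obs", "density": "tph_obs"}
    diffs = {m: [] for m in METRIC_COLUMNS}
    covered = {m: [] for m in METRIC_COLUMNS}
    agree = {m: [] for m in METRIC_COLUMNS}
    n_excluded = 0
    grouped = sweep.groupby(["forest", "forest_type", "severity"])
    for rec in records.itertuples(index=False):
        key = (rec.forest, rec.forest_type)
        sev = grid[np.argmin(np.abs(grid - rec.severity))]
        try:
            matched = grouped.get_group((rec.forest, rec.forest_type, sev))
        except KeyError:
            n_excluded += 1
            continue
        if key not in refs or key not in ranges75:
            n_excluded += 1
            continue
        for metric, col in METRIC_COLUMNS.items():
            sims = matched[col].to_numpy(dtype=float)
            obs = float(getattr(rec, obs_col[metric]))
            diffs[metric].append(obs - sims.mean())
            lo, hi = _prediction_band(sims, metric)
            covered[metric].append(lo <= obs <= hi)
            in_hrv = hrv_bounds(refs[key], metric)[0] <= obs <= hrv_bounds(refs[key], metric)[1]
            in_window = bool(ranges75[key][metric].contains(rec.severity))
            agree[metric].append(in_hrv == in_window)
    n_used = len(diffs["basal_area"])
    if n_used == 0:
        raise ValueError("no validation records could be matched to simulated outcomes")
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} unmatched validation record(s)", UserWarning)
    return ValidationMetrics(
        mbe_ba=float(np.mean(diffs["basal_area"])),
        mbe_tph=float(np.mean(diffs["density"])),
        coverage_ba=float(np.mean(covered["basal_area"])),
        coverage_tph=float(np.mean(covered["density"])),
        accuracy_ba=float(np.mean(agree["basal_area"])),
        accuracy_tph=float(np.mean(agree["density"])),
        n_used=n_used,
        n_excluded=n_excluded,
    )
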