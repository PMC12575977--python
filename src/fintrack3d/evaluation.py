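"""Behavioural distance statistics over pipeline trajectory output.

Implements the evaluation surface shared by all pipelines: the per-frame
closest-fish distance series, per-case aggregation across replicate runs,
mean absolute error with a Student-t 95% confidence interval against an
independent reference, depth-based ranking of individuals, and
Savitzky-Golay trajectory smoothing.

Aggregation pools per-frame minima across replicates by default (the
variability printed by field studies of this kind is frame-level);
``agg='replicate-means'`` averages replicate means instead.  The distance
metric defaults to the Euclidean norm from the left-camera origin, with
``metric='z'`` using the depth coordinate alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import t as student_t

from .pipelines import TrajectoryRecord

__all__ = [
    "CaseSummary",
    "ErrorReport",
    "DepthRanking",
    "min_distance_series",
    "summarize_case",
    "mae_with_ci",
    "rank_depths",
    "smooth_trajectory",
]


@dataclass(frozen=True)
class CaseSummary:
    """Mean +/- sd of the per-frame minimum distance for one case."""

    case_label: str
    mean_min_dist: float
    sd_min_dist: float
    n_frames: int
    n_replicates: int

    def __post_init__(self) -> None:
        if self.sd_min_dist < 0 or self.n_frames < 1:
            raise ValueError("invalid summary")


@dataclass(frozen=True)
class ErrorReport:
    """MAE and two-sided Student-t confidence interval versus a reference."""

    mae: float
    ci_low: float
    ci_high: float
    n_cases: int
    alpha: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mae <= self.ci_high):
            raise ValueError("confidence interval must bracket the MAE")


@dataclass(frozen=True)
class DepthRanking:
    """Individuals ordered closest -> furthest by depth."""

    order: tuple[tuple[int, float], ...]

    @property
    def closest(self) -> tuple[int, float]:
        return self.order[0]

    @property
    def furthest(self) -> tuple[int, float]:
        return self.order[-1]

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.order)


def min_distance_series(
    records: Iterable[TrajectoryRecord] | pd.DataFrame, metric: str = "euclidean"
) -> pd.Series:
    """Per-frame minimum distance; frames with no records are missing.

    Accepts either a list of :class:`TrajectoryRecord` or a trajectory
    DataFrame with columns ``frame``/``distance_m``/``Z``.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            {
                "frame": [r.frame for r in records],
                "distance_m": [r.distance_m for r in records],
                "Z": [r.point.Z for r in records],
            }
        )
    if df.empty:
        return pd.Series(dtype=float, name="min_distance_m")
    col = {"euclidean": "distance_m", "z": "Z"}.get(metric)
    if col is None:
        raise ValueError(f"unknown metric {metric!r}")
    series = df.groupby("frame")[col].min().sort_index()
    series.name = "min_distance_m"
    return series


def summarize_case(
    replicate_series: Sequence[pd.Series],
    case_label: str = "",
    agg: str = "pooled",
) -> CaseSummary:
    """Aggregate per-frame minima from replicate runs into one case summary.

    ``agg='pooled'`` computes mean and sample sd over all per-frame minima
    pooled across replicates; ``agg='replicate-means'`` computes them over
    the replicate means.  Replicates with no usable frames are dropped (and
    ``n_replicates`` reflects the usable count).
    """
    usable = [s.dropna() for s in replicate_series]
    usable = [s for s in usable if len(s) > 0]
    if not usable:
        raise ValueError("all replicates are empty")
    if agg == "pooled":
        values = np.concatenate([s.to_numpy(dtype=float) for s in usable])
    elif agg == "replicate-means":
        values = np.array([float(s.mean()) for s in usable])
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return CaseSummary(
        case_label=case_label,
        mean_min_dist=float(values.mean()),
        sd_min_dist=sd,
        n_frames=int(sum(len(s) for s in usable)),
        n_replicates=len(usable),
    )


def mae_with_ci(
    case_means: Sequence[float],
    reference: Sequence[float],
    alpha: float = 0.05,
) -> ErrorReport:
    """MAE of per-case means versus reference, with a Student-t CI.

    ``CI = MAE +/- t(1 - alpha/2, n-1) * sd(e) / sqrt(n)`` over the per-case
    absolute errors ``e``, with the sample standard deviation.
    """
    a = np.asarray(case_means, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("case means and reference must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least two cases")
    errors = np.abs(a - b)
    mae = float(errors.mean())
    sd = float(errors.std(ddof=1))
    half = float(student_t.ppf(1.0 - alpha / 2.0, n - 1)) * sd / np.sqrt(n)
    return ErrorReport(
        mae=mae, ci_low=mae - half, ci_high=mae + half, n_cases=n, alpha=alpha
    )


def rank_depths(id_to_depth: Mapping[int, float]) -> DepthRanking:
    """Order individuals by ascending depth; ties break to the lower id."""
    if not id_to_depth:
        raise ValueError("empty depth mapping")
    for key, depth in id_to_depth.items():
        if not (np.isfinite(depth) and depth > 0):
            raise ValueError(f"invalid depth {depth!r} for id {key}")
    order = tuple(sorted(id_to_depth.items(), key=lambda kv: (kv[1], kv[0])))
    return DepthRanking(order)


def smooth_trajectory(
    points: np.ndarray, window: int = 7, polyorder: int = 2
) -> np.ndarray:
    """Per-coordinate Savitzky-Golay smoothing of an (n, d) point series.

    Endpoints are handled by a polynomial fit on the truncated window
    (``mode='interp'``).  Series shorter than the window are returned
    unsmoothed with a warning.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if window % 2 == 0 or polyorder >= window:
        raise ValueError("window must be odd and polyorder < window")
    if points.shape[0] < window:
        warnings.warn(
            f"series of length {points.shape[0]} shorter than window {window}; "
            "returned unsmoothed",
            stacklevel=2,
        )
        return points.copy()
    return savgol_filter(points, window, polyorder, axis=0, mode="interp")
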