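"""Per-well metric trajectories: baseline normalisation, death events, AUC.

Each well yields one trajectory per metric: the per-day mean over that
well's FOVs, divided by the first imaging day's value.  A culture is
declared dead at the first day whose well-average fluorescence drops by
strictly more than 10% relative to the previous day; the trajectory is
truncated there (the death day itself is excluded by default, since the
culture is non-viable at that timepoint).  The time-averaged summary of
a trajectory is the trapezoidal area under the normalised curve over the
surviving days, using the true day spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

logger = logging.getLogger(__name__)

#: Fractional drop between successive scans that marks a death event.
DEATH_THRESHOLD = 0.10


@dataclass
class MetricTrajectory:
    """One well's time series for one metric.

    ``normalized_values`` are raw values divided by the first-day value
    (1.0 at the first day whenever the baseline is nonzero).  Values at
    and after ``death_day`` are excluded from the AUC.
    """

    well_id: str
    metric_name: str
    days: np.ndarray
    raw_values: np.ndarray
    normalized_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    death_day: int | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days)
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        if len(self.days) != len(self.raw_values):
            raise ParameterError("days: length mismatch with raw_values")
        if np.any(np.diff(self.days) <= 0):
            raise ParameterError("days: must be strictly increasing")
        if self.normalized_values is None:
            self.normalized_values = normalize_to_baseline(self.raw_values)
        else:
            self.normalized_values = np.asarray(self.normalized_values, dtype=float)

    @property
    def auc(self) -> float:
        return trajectory_auc(self)


def normalize_to_baseline(raw_series: np.ndarray) -> np.ndarray:
    """Divide a series by its first value.

    A zero baseline makes normalisation undefined: the whole series is
    returned as NaN with a logged warning.
    """
    raw = np.asarray(raw_series, dtype=float)
    if raw.size == 0:
        return raw.copy()
    if raw[0] == 0:
        logger.warning("normalize_to_baseline: zero baseline, series marked missing")
        return np.full_like(raw, np.nan)
    return raw / raw[0]


def detect_death_event(
    intensity_series: np.ndarray,
    days: np.ndarray | None = None,
    threshold: float = DEATH_THRESHOLD,
) -> int | None:
    """First day whose fluorescence drops by more than ``threshold``.

    The rule is strict: day d is a death event when
    ``(I_d - I_{d-1}) / I_{d-1} < -threshold``.  Returns the day value
    (from ``days``, or the 0-based index when days are not given), or
    None when the culture never dies.  Steps with a zero predecessor are
    skipped with a log message.
    """
    series = np.asarray(intensity_series, dtype=float)
    if series.size < 2:
        raise ParameterError(f"intensity_series: need >= 2 points, got {series.size}")
    if days is None:
        days_arr = np.arange(series.size)
    else:
        days_arr = np.asarray(days)
        if days_arr.size != series.size:
            raise ParameterError("days: length mismatch with intensity_series")
    for d in range(1, series.size):
        prev = series[d - 1]
        if prev == 0:
            logger.info("detect_death_event: zero intensity at step %d, comparison skipped", d - 1)
            continue
        if (series[d] - prev) / prev < -threshold:
            return int(days_arr[d])
    return None


def trajectory_auc(
    trajectory: MetricTrajectory,
    include_death_day: bool = False,
) -> float:
    """Trapezoidal area under the normalised trajectory, in metric-days.

    Integration runs over the surviving timepoints only: days strictly
    before ``death_day`` (or up to and including it when
    ``include_death_day`` is set).  Day gaps contribute by their actual
    spacing.  Fewer than 2 surviving points make the area undefined (NaN).
    """
    days = trajectory.days
    values = trajectory.normalized_values
    if trajectory.death_day is not None:
        keep = days < trajectory.death_day if not include_death_day else days <= trajectory.death_day
        days, values = days[keep], values[keep]
    if len(days) < 2:
        logger.warning("trajectory_auc: fewer than 2 surviving points, returning NaN")
        return float("nan")
    return float(np.trapezoid(values, days))


def assemble_trajectories(
    per_image_metrics: pd.DataFrame,
    metrics: list[str] | None = None,
    death_threshold: float = DEATH_THRESHOLD,
    include_death_day: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build per-well trajectories and AUC summaries from per-image rows.

    ``per_image_metrics`` is tidy with columns well, condition, day, fov
    and one column per metric (mean_fluorescence must be present — it
    drives death detection).  The per-well value for a day is the mean
    over that well's FOVs (missing FOVs ignored).  Returns the tidy
    trajectory table (well, condition, metric, day, raw, normalized,
    dead) and the AUC summary (well, condition, metric, auc, death_day).
    """
    if "mean_fluorescence" not in per_image_metrics.columns:
        raise ParameterError("per_image_metrics: column 'mean_fluorescence' required")
    if metrics is None:
        id_cols = {"well", "condition", "plate", "day", "fov"}
        metrics = [c for c in per_image_metrics.columns if c not in id_cols]

    daily = (
        per_image_metrics.groupby(["well", "condition", "day"], as_index=False)[metrics]
        .mean()
        .sort_values(["well", "day"])
    )

    traj_rows, auc_rows = [], []
    for (well, cond), grp in daily.groupby(["well", "condition"]):
        days = grp["day"].to_numpy()
        fluor = grp["mean_fluorescence"].to_numpy()
        death_day = (
            detect_death_event(fluor, days, threshold=death_threshold) if len(fluor) >= 2 else None
        )
        for metric in metrics:
            raw = grp[metric].to_numpy(dtype=float)
            traj = MetricTrajectory(
                well_id=well, metric_name=metric, days=days, raw_values=raw, death_day=death_day
            )
            dead = (days >= death_day).astype(int) if death_day is not None else np.zeros(len(days), int)
            for d, r, nv, dd in zip(days, raw, traj.normalized_values, dead):
                traj_rows.append(
                    {"well": well, "condition": cond, "metric": metric, "day": int(d),
                     "raw": r, "normalized": nv, "dead": int(dd)}
                )
            auc_rows.append(
                {"well": well, "condition": cond, "metric": metric,
                 "auc": trajectory_auc(traj, include_death_day=include_death_day),
                 "death_day": death_day if death_day is not None else np.nan}
            )
    return pd.DataFrame(traj_rows), pd.DataFrame(auc_rows)
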