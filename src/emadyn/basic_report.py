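"""The descriptive "basic report": equidistant gridding, low-pass trend,
time-of-day and weekday profiles, and category-mean dependencies.

The low-pass filter is a missing-aware centered moving average whose window
is ``window_days`` times the daily prompt count; it is transparent, exactly
reproducible by a direct windowed mean, and shrinks at the series edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compliance import deduplicate_records
from .errors import (
    CorruptRecordsError,
    InsufficientDataError,
    ParameterError,
    UnknownVariableError,
)
from .synthetic_cohort import EmaDataset

__all__ = [
    "GriddedSeries",
    "TrendDecomposition",
    "TimeProfiles",
    "CategoryDependency",
    "to_equidistant_grid",
    "lowpass_trend",
    "time_profiles",
    "categorical_dependency",
]


@dataclass(frozen=True)
class GriddedSeries:
    """One variable aligned to the full prompt schedule; NaN marks an
    unanswered prompt."""

    variable: str
    values: np.ndarray  # float, NaN = missing
    day_index: np.ndarray
    clock_minutes: np.ndarray
    slot_of_day: np.ndarray
    weekday: np.ndarray
    is_weekend: np.ndarray
    first_of_day: np.ndarray
    per_day_count: int
    n_days: int
    scale: str  # 'vas' | 'categorical'

    def __len__(self) -> int:
        return len(self.values)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())


@dataclass(frozen=True)
class TrendDecomposition:
    """trend + residual = observed at every non-missing occasion."""

    trend: np.ndarray
    residual: np.ndarray
    window_days: float
    window_occasions: int


def to_equidistant_grid(dataset: EmaDataset, variable: str) -> GriddedSeries:
    """Place answered values on the schedule grid; unanswered slots are NaN.

    Records at a (day, time) not on the schedule mean corrupt input and
    raise.
    """
    try:
        item = dataset.design.item(variable)
    except KeyError:
        raise UnknownVariableError(
            f"{variable!r} is not an item of the study design"
        ) from None
    sched = dataset.schedule
    index = sched.slot_index()
    values = np.full(len(sched), np.nan)
    rec = deduplicate_records(dataset.records)
    rec = rec[rec["item_id"] == variable]
    for d, c, v in zip(
        rec["day_index"].to_numpy(), rec["clock_time"].to_numpy(), rec["value"].to_numpy()
    ):
        key = (int(d), int(c))
        if key not in index:
            raise CorruptRecordsError(
                f"record for {variable!r} at day {d}, minute {c} is not on the prompt schedule"
            )
        values[index[key]] = float(v)
    return GriddedSeries(
        variable=variable,
        values=values,
        day_index=sched.day_index,
        clock_minutes=sched.clock_minutes,
        slot_of_day=sched.slot_of_day,
        weekday=sched.weekday,
        is_weekend=sched.is_weekend,
        first_of_day=sched.first_of_day,
        per_day_count=sched.per_day_count,
        n_days=sched.n_days,
        scale=item.scale,
    )


def lowpass_trend(series: GriddedSeries, window_days: float = 3.0) -> TrendDecomposition:
    """Missing-aware centered moving average over ``window_days`` worth of
    occasions (forced odd so the window is symmetric); the window shrinks at
    the edges and skips missing slots."""
    if window_days <= 0:
        raise ParameterError(f"window_days must be positive, got {window_days}")
    if series.n_days < 2 * window_days:
        raise InsufficientDataError(
            f"low-pass trend needs at least {2 * window_days:g} days of data, "
            f"design spans {series.n_days}"
        )
    w = int(round(window_days * series.per_day_count))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    trend = (
        pd.Series(series.values)
        .rolling(window=w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    residual = series.values - trend
    return TrendDecomposition(
        trend=trend, residual=residual, window_days=window_days, window_occasions=w
    )


@dataclass(frozen=True)
class TimeProfiles:
    """Mean scores per prompt clock time and per weekday (0 = Monday by
    design convention); groups with no data carry n = 0 and NaN mean."""

    hour: pd.DataFrame  # columns: clock_minutes, mean, n
    weekday: pd.DataFrame  # columns: weekday, mean, n, empty


def time_profiles(series: GriddedSeries) -> TimeProfiles:
    obs = series.observed
    if not obs.any():
        raise InsufficientDataError(f"series {series.variable!r} has no observed values")
    df = pd.DataFrame(
        {
            "value": series.values,
            "clock_minutes": series.clock_minutes,
            "weekday": series.weekday,
        }
    )
    hour = (
        df.groupby("clock_minutes")["value"]
        .agg(mean="mean", n="count")
        .reset_index()
    )
    wk = (
        df.groupby("weekday")["value"]
        .agg(mean="mean", n="count")
        .reindex(range(7), fill_value=0)
        .reset_index()
    )
    wk.loc[wk["n"] == 0, "mean"] = np.nan
    wk["empty"] = wk["n"] == 0
    return TimeProfiles(hour=hour, weekday=wk)


@dataclass(frozen=True)
class CategoryDependency:
    """Mean of a continuous variable within each level of a categorical
    context variable; levels with fewer than ``min_n`` co-observations are
    flagged low-support rather than dropped."""

    variable: str
    context: str
    table: pd.DataFrame  # columns: level, mean, n, low_support
    min_n: int


def categorical_dependency(
    series: GriddedSeries, context: GriddedSeries, min_n: int = 5
) -> CategoryDependency:
    if context.scale != "categorical":
        raise ParameterError(f"context variable {context.variable!r} is not categorical")
    both = series.observed & context.observed
    if not both.any():
        raise InsufficientDataError(
            f"no occasions where both {series.variable!r} and {context.variable!r} are observed"
        )
    df = pd.DataFrame(
        {"value": series.values[both], "level": context.values[both].astype(int)}
    )
    table = df.groupby("level")["value"].agg(mean="mean", n="count").reset_index()
    table["low_support"] = table["n"] < min_n
    return CategoryDependency(
        variable=series.variable, context=context.variable, table=table, min_n=min_n
    )
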