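"""Compliance accounting: notifications sent vs answered, days used, and
the measurement-adequacy rule (>=50 answered prompts and >=3 per day).

A "measurement" is an answered prompt, not an answered item; the per-day
average divides by the scheduled period by default (configurable to days
actually used).  Duplicate rows for one prompt — the kind of artifact a
delivery platform can produce for expired surveys — are dropped on
(day, time, item), keeping the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EmadynError
from .synthetic_cohort import EmaDataset

__all__ = [
    "ComplianceSummary",
    "MIN_TOTAL_MEASUREMENTS",
    "MIN_PER_DAY",
    "compute_compliance",
    "check_measurement_adequacy",
    "compliance_time_course",
    "fit_decay_slope",
]

MIN_TOTAL_MEASUREMENTS = 50
MIN_PER_DAY = 3.0


@dataclass(frozen=True)
class ComplianceSummary:
    n_sent: int
    n_answered: int
    rate: float
    days_in_period: int
    days_used: int
    mean_answered_per_day: float
    adequate: bool

    def to_dict(self) -> dict:
        return {
            "n_sent": self.n_sent,
            "n_answered": self.n_answered,
            "rate": self.rate,
            "days_in_period": self.days_in_period,
            "days_used": self.days_used,
            "mean_answered_per_day": self.mean_answered_per_day,
            "adequate": self.adequate,
        }


def deduplicate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate (day_index, clock_time, item_id) rows, keeping the first."""
    return records.drop_duplicates(
        subset=["day_index", "clock_time", "item_id"], keep="first"
    ).reset_index(drop=True)


def compute_compliance(dataset: EmaDataset, per_day: str = "scheduled") -> ComplianceSummary:
    """Summarize sent/answered prompts and day usage for one subject.

    ``per_day`` chooses the denominator of the per-day average:
    ``"scheduled"`` (the whole study period, default) or ``"used"`` (days
    with at least one answered prompt).
    """
    if len(dataset.schedule) == 0:
        raise EmadynError("compliance is undefined for an empty prompt schedule")
    if per_day not in ("scheduled", "used"):
        raise ValueError(f"per_day must be 'scheduled' or 'used', got {per_day!r}")

    rec = deduplicate_records(dataset.records)
    answered = rec[["day_index", "clock_time"]].drop_duplicates()
    n_sent = len(dataset.schedule)
    n_answered = len(answered)
    if n_answered > n_sent:
        raise EmadynError("more answered prompts than sent prompts; corrupt records")
    days_in_period = dataset.schedule.n_days
    days_used = int(answered["day_index"].nunique())
    denom = days_in_period if per_day == "scheduled" else max(days_used, 1)
    mean_per_day = n_answered / denom
    summary = ComplianceSummary(
        n_sent=n_sent,
        n_answered=n_answered,
        rate=n_answered / n_sent,
        days_in_period=days_in_period,
        days_used=days_used,
        mean_answered_per_day=mean_per_day,
        adequate=False,
    )
    return ComplianceSummary(**{**summary.to_dict(), "adequate": check_measurement_adequacy(summary)})


def check_measurement_adequacy(
    summary: ComplianceSummary,
    min_total: int = MIN_TOTAL_MEASUREMENTS,
    min_per_day: float = MIN_PER_DAY,
) -> bool:
    """True iff at least ``min_total`` answered prompts and an average of at
    least ``min_per_day`` per day."""
    return summary.n_answered >= min_total and summary.mean_answered_per_day >= min_per_day


def compliance_time_course(cohort: list[EmaDataset]) -> np.ndarray:
    """Total answered prompts across subjects per study day.

    Length equals the longest study period in the cohort; days without any
    scheduled or answered prompt contribute zero.
    """
    if not cohort:
        raise EmadynError("compliance_time_course needs a non-empty cohort")
    n_days = max(ds.schedule.n_days for ds in cohort)
    counts = np.zeros(n_days, dtype=int)
    for ds in cohort:
        rec = deduplicate_records(ds.records)
        answered = rec[["day_index", "clock_time"]].drop_duplicates()
        per_day = answered.groupby("day_index").size()
        counts[per_day.index.to_numpy()] += per_day.to_numpy()
    return counts


def fit_decay_slope(counts: np.ndarray) -> tuple[float, float]:
    """OLS slope (and its SE) of log(daily count) on study day.

    Under geometric compliance decay the expected slope is
    ``log(daily_decay)``.  Zero-count days are dropped.
    """
    counts = np.asarray(counts, dtype=float)
    days = np.arange(len(counts), dtype=float)
    ok = counts > 0
    if ok.sum() < 3:
        raise EmadynError("need at least 3 non-empty days to fit a decay slope")
    x = sm.add_constant(days[ok])
    fit = sm.OLS(np.log(counts[ok]), x).fit()
    return float(fit.params[1]), float(fit.bse[1])
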