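"""Descriptive statistics tables (mean/SD, median/IQR, min-max).

Conventions, chosen once and documented: sample SD with the n-1 denominator
(0 for a singleton), quartiles by linear interpolation between order
statistics (the default rule in mainstream statistical software).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

#: Stat columns of every emitted summary table, in order.
STAT_COLUMNS = ("n", "mean", "sd", "median", "q1", "q3", "min", "max")

#: Grouping dimensions understood by :func:`grouped_summary`.
GROUP_DIMENSIONS = ("day_of_week", "region", "duration_class")

_DAY_GROUPS = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday and Sunday")


@dataclass(frozen=True)
class SummaryStats:
    """Order statistics and moments of one batch of values."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float


def summarize(values) -> SummaryStats:
    """Descriptive statistics of a non-empty collection of finite reals."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("cannot summarize an empty collection")
    if not np.all(np.isfinite(arr)):
        raise DomainError("values must be finite")
    q1, median, q3 = np.percentile(arr, [25.0, 50.0, 75.0])  # linear interpolation
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        median=float(median),
        q1=float(q1),
        q3=float(q3),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def _group_labels(frame: pd.DataFrame, dimension: str) -> pd.Series:
    if dimension == "day_of_week":
        dow = frame["start_utc"].dt.dayofweek
        names = frame["start_utc"].dt.day_name()
        return names.where(dow < 5, "Saturday and Sunday")
    if dimension == "region":
        return frame["region"]
    if dimension == "duration_class":
        if "duration_class" in frame.columns:
            return frame["duration_class"]
        from .sampling import SHORT_LONG_BOUNDARY_MIN

        return pd.Series(
            np.where(frame["duration_min"] <= SHORT_LONG_BOUNDARY_MIN, "short", "long"),
            index=frame.index,
        )
    raise ConfigurationError(
        f"unknown grouping dimension {dimension!r}; expected one of {GROUP_DIMENSIONS}"
    )


def grouped_summary(frame: pd.DataFrame, value_column: str, dimension: str) -> pd.DataFrame:
    """One :class:`SummaryStats` row per group plus an ``Overall`` row.

    Group sizes always sum to the total and the overall row equals
    :func:`summarize` on the ungrouped values; both are invariant to row
    order.
    """
    labels = _group_labels(frame, dimension)
    rows = []
    for group in sorted(labels.dropna().unique()):
        stats = summarize(frame.loc[labels == group, value_column])
        rows.append({"group": group, **stats.__dict__})
    rows.append({"group": "Overall", **summarize(frame[value_column]).__dict__})
    out = pd.DataFrame(rows, columns=["group", *STAT_COLUMNS])
    return out


def distance_summary_tables(frame: pd.DataFrame, value_column: str = "round_trip_miles"):
    """Round-trip distance summaries by day of week, region, and duration
    class — the study's descriptive-table layout."""
    return {dim: grouped_summary(frame, value_column, dim) for dim in GROUP_DIMENSIONS}


def per_session_summary_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Overall summaries of the per-session travel and emissions quantities."""
    quantities = (
        ("round_trip_hours", "Travel time, round trip (h)"),
        ("round_trip_miles", "Travel distance, round trip (miles)"),
        ("savings_g", "Transportation CO2 savings (g)"),
        ("duration_min", "Duration (min)"),
        ("expenditure_g", "Telemedicine energy CO2 (g)"),
        ("net_g", "Net emissions savings per session (g)"),
        ("net_per_min_g", "Net emissions savings per minute (g)"),
    )
    rows = []
    for column, label in quantities:
        stats = summarize(frame[column])
        rows.append({"quantity": label, **stats.__dict__})
    return pd.DataFrame(rows, columns=["quantity", *STAT_COLUMNS])


def box_plot_by_region(frame: pd.DataFrame, path, value_column: str = "round_trip_miles") -> None:
    """Optional box plot of round-trip distance by region (whiskers at
    1.5 x IQR).  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [
        (region, frame.loc[frame["region"] == region, value_column].to_numpy())
        for region in sorted(frame["region"].dropna().unique())
    ]
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.boxplot([g[1] for g in groups], tick_labels=[g[0] for g in groups], whis=1.5)
    ax.set_ylabel(value_column)
    ax.set_xlabel("region")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
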