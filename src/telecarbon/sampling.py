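"""Stratification and proportional sampling.

Each eligible session is assigned to one of 40 strata — region (5) x
duration class (short: 5-30 min inclusive, long: >30 min) x day class
(weekday/weekend) x hour class (peak: 13:00-23:00 UTC, offpeak otherwise) —
and a proportional sample is drawn by largest-remainder (Hamilton)
apportionment followed by simple random sampling without replacement within
each stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .records import REGIONS, SessionRecord

DURATION_CLASSES = ("short", "long")
DAY_CLASSES = ("weekday", "weekend")
HOUR_CLASSES = ("peak", "offpeak")

#: Boundary between the short and long duration classes; 30.0 min is short.
SHORT_LONG_BOUNDARY_MIN = 30.0
#: Peak window in UTC hours, both ends inclusive.
PEAK_HOURS_UTC = (13, 23)


@dataclass(frozen=True, order=True)
class StratumKey:
    """One cell of the 5 x 2 x 2 x 2 sampling design."""

    region: str
    duration_class: str
    day_class: str
    hour_class: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise DomainError(f"unknown region {self.region!r}")
        if self.duration_class not in DURATION_CLASSES:
            raise DomainError(f"unknown duration class {self.duration_class!r}")
        if self.day_class not in DAY_CLASSES:
            raise DomainError(f"unknown day class {self.day_class!r}")
        if self.hour_class not in HOUR_CLASSES:
            raise DomainError(f"unknown hour class {self.hour_class!r}")

    @property
    def sort_index(self) -> tuple[int, int, int, int]:
        """Canonical total order used for deterministic tie-breaking."""
        return (
            REGIONS.index(self.region),
            DURATION_CLASSES.index(self.duration_class),
            DAY_CLASSES.index(self.day_class),
            HOUR_CLASSES.index(self.hour_class),
        )


def all_stratum_keys() -> list[StratumKey]:
    """The 40 possible keys in canonical order."""
    return [
        StratumKey(r, d, w, h)
        for r in REGIONS
        for d in DURATION_CLASSES
        for w in DAY_CLASSES
        for h in HOUR_CLASSES
    ]


@dataclass
class Allocation:
    """Per-stratum sample counts summing exactly to ``total``."""

    counts: dict[StratumKey, int]
    total: int


def assign_stratum(record: SessionRecord) -> StratumKey:
    """Deterministic stratum assignment for one eligible session."""
    duration_class = "short" if record.duration_min <= SHORT_LONG_BOUNDARY_MIN else "long"
    day_class = "weekend" if record.start_utc.dayofweek >= 5 else "weekday"
    lo, hi = PEAK_HOURS_UTC
    hour_class = "peak" if lo <= record.start_utc.hour <= hi else "offpeak"
    return StratumKey(record.region, duration_class, day_class, hour_class)


def assign_strata(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorised stratum assignment: appends the three class columns."""
    out = frame.copy()
    out["duration_class"] = np.where(
        out["duration_min"] <= SHORT_LONG_BOUNDARY_MIN, "short", "long"
    )
    out["day_class"] = np.where(out["start_utc"].dt.dayofweek >= 5, "weekend", "weekday")
    lo, hi = PEAK_HOURS_UTC
    hour = out["start_utc"].dt.hour
    out["hour_class"] = np.where((hour >= lo) & (hour <= hi), "peak", "offpeak")
    return out


def stratum_census(frame: pd.DataFrame) -> dict[StratumKey, int]:
    """Population counts per stratum (strata with zero sessions omitted)."""
    if "duration_class" not in frame.columns:
        frame = assign_strata(frame)
    grouped = frame.groupby(
        ["region", "duration_class", "day_class", "hour_class"], observed=True
    ).size()
    return {StratumKey(*key): int(n) for key, n in grouped.items()}


def allocate_proportional(
    population_counts: dict[StratumKey, int], sample_size: int
) -> Allocation:
    """Largest-remainder apportionment of ``sample_size`` across strata.

    Each stratum receives the floor of its proportional quota; the leftover
    units go to strata in order of descending fractional remainder, ties
    broken by the canonical stratum order.  A stratum is never allocated
    more than its population.
    """
    population = sum(population_counts.values())
    if sample_size > population:
        raise DomainError(
            f"sample_size {sample_size} exceeds population {population}"
        )
    if sample_size < 0:
        raise DomainError("sample_size must be non-negative")

    keys = sorted(population_counts, key=lambda k: k.sort_index)
    quotas = {k: sample_size * population_counts[k] / population for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    leftover = sample_size - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), k.sort_index))
    for k in by_remainder:
        if leftover == 0:
            break
        if counts[k] < population_counts[k]:
            counts[k] += 1
            leftover -= 1
    if leftover:  # only possible when quotas hit population caps
        for k in by_remainder:
            while leftover and counts[k] < population_counts[k]:
                counts[k] += 1
                leftover -= 1
    return Allocation(counts=counts, total=sample_size)


def draw_sample(frame: pd.DataFrame, allocation: Allocation, seed: int) -> pd.DataFrame:
    """Simple random sample without replacement within each stratum.

    Deterministic given ``seed``; strata are visited in canonical order so
    the draw does not depend on dictionary ordering.
    """
    if "duration_class" not in frame.columns:
        frame = assign_strata(frame)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A17]))
    groups = frame.groupby(["region", "duration_class", "day_class", "hour_class"], observed=True)
    index_by_key = {StratumKey(*key): idx for key, idx in groups.groups.items()}
    picked: list[np.ndarray] = []
    for key in sorted(allocation.counts, key=lambda k: k.sort_index):
        want = allocation.counts[key]
        if want == 0:
            continue
        idx = index_by_key.get(key)
        if idx is None or len(idx) < want:
            have = 0 if idx is None else len(idx)
            raise DomainError(
                f"allocation infeasible for stratum {key}: want {want}, have {have}"
            )
        picked.append(rng.choice(np.asarray(idx), size=want, replace=False))
    if not picked:
        return frame.iloc[0:0].copy()
    chosen = np.sort(np.concatenate(picked))
    return frame.loc[chosen].reset_index(drop=True)
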