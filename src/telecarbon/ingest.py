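"""Reading session tables and applying the inclusion/exclusion rules.

A session is retained iff it is a dyad (exactly 2 participants), lasts
between 5 and 120 minutes inclusive, starts inside the study window,
separates provider and patient by at most 400 geodesic miles, and carries a
region label.  Each excluded record is attributed to the FIRST failing rule
in the fixed order

    dyad -> duration-low -> duration-high -> window -> geodesic -> region

so exclusion reports are deterministic and their counts always sum to the
input size.  Filtering never raises on rule violations; it counts them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .records import REGIONS, SESSION_COLUMNS
from .travel import haversine_miles_arrays

#: Study window (inclusive, dates in UTC).
DEFAULT_DATE_WINDOW = (pd.Timestamp("2022-01-01", tz="UTC"), pd.Timestamp("2023-02-21", tz="UTC"))
#: Geodesic screening cutoff in one-way great-circle miles.
DEFAULT_MAX_GEODESIC_MILES = 400.0
#: Duration eligibility bounds in minutes, both inclusive.
DURATION_BOUNDS_MIN = (5.0, 120.0)

#: Exclusion rules in attribution order.
RULE_ORDER = (
    "not_dyad",
    "duration_below_min",
    "duration_above_max",
    "outside_window",
    "geodesic_too_far",
    "missing_region",
)


@dataclass
class FilterReport:
    """Auditable accounting of one filter pass."""

    n_input: int
    n_retained: int
    exclusions: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "exclusions": dict(self.exclusions),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class ReadResult:
    """Parsed session table plus an account of malformed rows."""

    frame: pd.DataFrame
    n_rows: int
    malformed: dict[str, int]
    malformed_rows: pd.DataFrame


def read_sessions(path) -> ReadResult:
    """Read a session CSV written with the documented header.

    Malformed rows (unparseable timestamp or numbers, out-of-range
    coordinates, non-positive duration, participant count below 1) are
    separated and counted, never silently dropped.  A missing region is NOT
    malformed — it is an exclusion handled by :func:`apply_filters`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"session file not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SESSION_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    reasons = pd.Series("", index=raw.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & (reasons == "")
        reasons[new] = reason

    ts = pd.to_datetime(raw["start_utc"], errors="coerce", utc=True, format="ISO8601")
    flag(ts.isna(), "bad_timestamp")
    numeric = {}
    for col in ("duration_min", "n_participants", "provider_lat", "provider_lon",
                "patient_lat", "patient_lon"):
        numeric[col] = pd.to_numeric(raw[col], errors="coerce")
        flag(numeric[col].isna(), f"bad_{col}")
    for prefix in ("provider", "patient"):
        flag(numeric[f"{prefix}_lat"].abs() > 90, f"{prefix}_lat_out_of_range")
        flag(numeric[f"{prefix}_lon"].abs() > 180, f"{prefix}_lon_out_of_range")
    flag(numeric["duration_min"] <= 0, "nonpositive_duration")
    flag(numeric["n_participants"] < 1, "participants_below_one")

    bad = reasons != ""
    frame = pd.DataFrame(
        {
            "session_id": raw.loc[~bad, "session_id"],
            "start_utc": ts[~bad],
            "duration_min": numeric["duration_min"][~bad],
            "n_participants": numeric["n_participants"][~bad].astype(int),
            "provider_lat": numeric["provider_lat"][~bad],
            "provider_lon": numeric["provider_lon"][~bad],
            "patient_lat": numeric["patient_lat"][~bad],
            "patient_lon": numeric["patient_lon"][~bad],
            "region": raw.loc[~bad, "region"].replace("", np.nan),
        }
    ).reset_index(drop=True)
    malformed_rows = raw[bad].assign(reason=reasons[bad]).reset_index(drop=True)
    counts = reasons[bad].value_counts().to_dict()
    return ReadResult(frame=frame, n_rows=len(raw), malformed=counts, malformed_rows=malformed_rows)


def apply_filters(
    frame: pd.DataFrame,
    date_window: tuple[pd.Timestamp, pd.Timestamp] = DEFAULT_DATE_WINDOW,
    max_geodesic_miles: float = DEFAULT_MAX_GEODESIC_MILES,
    duration_bounds: tuple[float, float] = DURATION_BOUNDS_MIN,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the eligibility rules; return (retained rows, report).

    Boundary semantics are inclusive: durations of exactly 5 and exactly 120
    minutes and a geodesic separation of exactly ``max_geodesic_miles`` are
    retained.  The window bound is inclusive of both endpoint dates.
    """
    lo, hi = duration_bounds
    start, end = (pd.Timestamp(t, tz="UTC") if pd.Timestamp(t).tzinfo is None else pd.Timestamp(t)
                  for t in date_window)
    end_exclusive = end.normalize() + pd.Timedelta(days=1)

    geodesic = haversine_miles_arrays(
        frame["provider_lat"], frame["provider_lon"], frame["patient_lat"], frame["patient_lon"]
    )
    region = frame["region"]
    fails = {
        "not_dyad": (frame["n_participants"] != 2).to_numpy(),
        "duration_below_min": (frame["duration_min"] < lo).to_numpy(),
        "duration_above_max": (frame["duration_min"] > hi).to_numpy(),
        "outside_window": ((frame["start_utc"] < start) | (frame["start_utc"] >= end_exclusive)).to_numpy(),
        "geodesic_too_far": geodesic > max_geodesic_miles,
        "missing_region": (region.isna() | ~region.isin(REGIONS)).to_numpy(),
    }

    excluded = np.zeros(len(frame), dtype=bool)
    exclusions: dict[str, int] = {}
    for rule in RULE_ORDER:
        hit = fails[rule] & ~excluded
        exclusions[rule] = int(hit.sum())
        excluded |= hit

    retained = frame[~excluded].reset_index(drop=True)
    report = FilterReport(n_input=len(frame), n_retained=len(retained), exclusions=exclusions)
    return retained, report
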