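"""Core record types and the canonical session-table schema.

A session population is carried through the pipeline as a pandas DataFrame
with the columns in :data:`SESSION_COLUMNS`; :class:`SessionRecord` is the
single-row view used by per-record operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DomainError

#: US census-style regions used for stratification, in canonical order
#: (descending share in the study population).
REGIONS = ("Northeast", "Southeast", "West", "Midwest", "Southwest")

#: Documented CSV header for session tables, in column order.
SESSION_COLUMNS = (
    "session_id",
    "start_utc",
    "duration_min",
    "n_participants",
    "provider_lat",
    "provider_lon",
    "patient_lat",
    "patient_lon",
    "region",
)

#: Timestamp wire format (ISO-8601, UTC, second resolution).
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%SZ"


@dataclass(frozen=True)
class GeoCoordinate:
    """A WGS-style latitude/longitude pair in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise DomainError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise DomainError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class SessionRecord:
    """One telemedicine session between a provider and a patient."""

    session_id: str
    start_utc: pd.Timestamp
    duration_min: float
    n_participants: int
    provider_loc: GeoCoordinate
    patient_loc: GeoCoordinate
    region: str | None

    @classmethod
    def from_row(cls, row: pd.Series) -> "SessionRecord":
        region = row["region"]
        if pd.isna(region) or region == "":
            region = None
        return cls(
            session_id=str(row["session_id"]),
            start_utc=pd.Timestamp(row["start_utc"]),
            duration_min=float(row["duration_min"]),
            n_participants=int(row["n_participants"]),
            provider_loc=GeoCoordinate(float(row["provider_lat"]), float(row["provider_lon"])),
            patient_loc=GeoCoordinate(float(row["patient_lat"]), float(row["patient_lon"])),
            region=region,
        )


def format_timestamps(ts: pd.Series) -> pd.Series:
    """Render tz-aware UTC timestamps in the documented wire format."""
    return ts.dt.strftime(TIMESTAMP_FORMAT)


def write_sessions_csv(frame: pd.DataFrame, path) -> None:
    """Write a session table using the documented header and timestamp format."""
    out = frame.loc[:, list(SESSION_COLUMNS)].copy()
    if pd.api.types.is_datetime64_any_dtype(out["start_utc"]):
        out["start_utc"] = format_timestamps(out["start_utc"])
    out.to_csv(path, index=False)
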