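"""Great-circle distance and per-session car-travel estimates.

Distances are computed on a sphere of radius 3958.8 miles (mean Earth
radius); the sub-0.5% departure from an ellipsoidal model is irrelevant at
the precision of the emissions analysis.  Road distance and travel time come
from a pluggable *router* — any object with a
``route(origin: GeoCoordinate, destination: GeoCoordinate) -> (miles, hours)``
method whose returned road miles are never below the geodesic separation of
the same points.  The default implementation is
:class:`telecarbon.synthetic.SyntheticRouter`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, RoutingError
from .records import GeoCoordinate, SessionRecord

#: Spherical Earth radius used throughout, in miles.
EARTH_RADIUS_MILES = 3958.8

#: Default fraction of round trips assumed to be by car (US adult commuting
#: mode share).
DEFAULT_CAR_SHARE = 0.848


def _check_latlon(lat: np.ndarray, lon: np.ndarray, label: str) -> None:
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise DomainError(f"{label} coordinates outside valid lat/lon ranges")


def haversine_miles_arrays(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Vectorised great-circle distance in miles between coordinate arrays."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    _check_latlon(lat1, lon1, "origin")
    _check_latlon(lat2, lon2, "destination")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return EARTH_RADIUS_MILES * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def haversine_miles(a: GeoCoordinate, b: GeoCoordinate) -> float:
    """Great-circle distance in miles between two points.

    Symmetric in its arguments and zero (to ~1e-9 miles) iff the points
    coincide.
    """
    return float(haversine_miles_arrays(a.lat, a.lon, b.lat, b.lon))


@dataclass(frozen=True)
class TravelEstimate:
    """Travel quantities for one avoided in-person visit.

    ``round_trip_miles`` is exactly twice the one-way routed distance;
    ``adjusted_round_trip_miles`` scales it by the car mode share so that
    non-car travel is not credited with tailpipe savings.
    """

    geodesic_miles: float
    oneway_road_miles: float
    round_trip_miles: float
    round_trip_hours: float
    adjusted_round_trip_miles: float


def estimate_travel(
    record: SessionRecord, router, car_share: float = DEFAULT_CAR_SHARE
) -> TravelEstimate:
    """Route one session's provider→patient trip and derive round-trip fields."""
    if not (0.0 < car_share <= 1.0):
        raise DomainError(f"car_share {car_share} outside (0, 1]")
    geodesic = haversine_miles(record.provider_loc, record.patient_loc)
    try:
        oneway_miles, oneway_hours = router.route(record.provider_loc, record.patient_loc)
    except DomainError:
        raise
    except Exception as exc:  # router failures are reported per-session
        raise RoutingError(record.session_id, str(exc)) from exc
    round_trip = 2.0 * oneway_miles
    return TravelEstimate(
        geodesic_miles=geodesic,
        oneway_road_miles=oneway_miles,
        round_trip_miles=round_trip,
        round_trip_hours=2.0 * oneway_hours,
        adjusted_round_trip_miles=round_trip * car_share,
    )


def add_travel_columns(
    frame: pd.DataFrame, router, car_share: float = DEFAULT_CAR_SHARE
) -> pd.DataFrame:
    """Append travel-estimate columns to a session table.

    Uses the router's vectorised ``route_many`` when available, else routes
    row by row.  Returns a new frame; the input is not mutated.
    """
    if not (0.0 < car_share <= 1.0):
        raise DomainError(f"car_share {car_share} outside (0, 1]")
    out = frame.copy()
    geodesic = haversine_miles_arrays(
        out["provider_lat"], out["provider_lon"], out["patient_lat"], out["patient_lon"]
    )
    if hasattr(router, "route_many"):
        miles, hours = router.route_many(
            out["provider_lat"].to_numpy(),
            out["provider_lon"].to_numpy(),
            out["patient_lat"].to_numpy(),
            out["patient_lon"].to_numpy(),
        )
    else:
        pairs = [
            router.route(GeoCoordinate(plat, plon), GeoCoordinate(qlat, qlon))
            for plat, plon, qlat, qlon in zip(
                out["provider_lat"], out["provider_lon"], out["patient_lat"], out["patient_lon"]
            )
        ]
        miles = np.array([p[0] for p in pairs])
        hours = np.array([p[1] for p in pairs])
    out["geodesic_miles"] = geodesic
    out["oneway_road_miles"] = miles
    out["round_trip_miles"] = 2.0 * miles
    out["round_trip_hours"] = 2.0 * hours
    out["adjusted_round_trip_miles"] = out["round_trip_miles"] * car_share
    return out
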