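"""Synthetic session populations and a deterministic routing oracle.

The proprietary platform data behind the analysis cannot be redistributed,
so this module generates populations with the same statistical structure:

* regional shares and a bimodal (short/long) duration mixture matching the
  study population's printed composition;
* per-region right-skewed one-way geodesic distances (lognormal, calibrated
  so the median of the 400-mile-truncated law equals the configured target);
* timestamps concentrated on weekdays and in the 13:00-23:00 UTC window;
* a small configurable fraction of records that violate the eligibility
  rules (too short/long, group call, too distant, missing region) so the
  filter stage has real work to do.

The :class:`SyntheticRouter` stands in for a live distance-matrix service:
road distance is the geodesic distance times a detour (circuity) factor
drawn deterministically per point pair from a normal truncated at 1.0, and
travel time is road distance over a fixed speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, DomainError
from .records import REGIONS, SESSION_COLUMNS, GeoCoordinate, write_sessions_csv
from .travel import EARTH_RADIUS_MILES, haversine_miles_arrays

__all__ = [
    "GeneratorConfig",
    "SyntheticRouter",
    "generate_sessions",
    "write_sessions",
    "destination_point",
]

_WEEKDAYS = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday")

#: Rough per-region (lat_min, lat_max, lon_min, lon_max) boxes for provider
#: placement.  Only pairwise distances matter downstream, not street realism.
_REGION_BOXES = {
    "Northeast": (39.0, 47.0, -80.0, -67.0),
    "Southeast": (25.5, 37.0, -92.0, -76.0),
    "West": (32.0, 48.5, -124.0, -103.0),
    "Midwest": (36.5, 48.5, -103.0, -81.0),
    "Southwest": (26.5, 37.0, -109.0, -93.5),
}

_VIOLATION_KINDS = ("short_call", "long_session", "group_session", "far", "missing_region")


def _default_region_shares() -> dict[str, float]:
    return {
        "Northeast": 0.3418,
        "Southeast": 0.2042,
        "West": 0.1899,
        "Midwest": 0.1726,
        "Southwest": 0.0915,
    }


def _default_distance_params() -> dict[str, tuple[float, float]]:
    # (log-median, log-sd) of one-way geodesic miles; medians are half the
    # study population's per-region round-trip medians, spreads back-solved
    # from the printed interquartile ratios of the lognormal family.
    return {
        "Northeast": (float(np.log(23.0)), 1.257),
        "Southeast": (float(np.log(31.5)), 1.658),
        "West": (float(np.log(22.0)), 1.454),
        "Midwest": (float(np.log(24.0)), 2.051),
        "Southwest": (float(np.log(24.5)), 1.546),
    }


def _default_weekday_shares() -> dict[str, float]:
    return {
        "Monday": 0.1724,
        "Tuesday": 0.2269,
        "Wednesday": 0.2222,
        "Thursday": 0.2134,
        "Friday": 0.1340,
        "Saturday": 0.01555,
        "Sunday": 0.01555,
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session population.

    Defaults encode the study population's composition: regional shares
    34.18 / 20.42 / 18.99 / 17.26 / 9.15 percent, a 44.06% short-duration
    share, weekday concentration with a sparse weekend, and per-region
    skewed distance laws with medians of 22-31.5 one-way miles.
    """

    n_sessions: int = 10_000
    region_shares: dict[str, float] = field(default_factory=_default_region_shares)
    duration_class_shares: dict[str, float] = field(
        default_factory=lambda: {"short": 0.4406, "long": 0.5594}
    )
    short_duration_mean: float = 18.0
    short_duration_sd: float = 7.0
    long_duration_mean: float = 45.0
    long_duration_sd: float = 20.0
    distance_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_distance_params
    )
    weekday_shares: dict[str, float] = field(default_factory=_default_weekday_shares)
    peak_hour_share: float = 0.75
    window_start: str = "2022-01-01"
    window_end: str = "2023-02-21"
    detour_factor_mean: float = 1.3
    detour_factor_sd: float = 0.1
    violation_fraction: float = 0.02
    max_valid_geodesic_miles: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_sessions, (int, np.integer)) or self.n_sessions < 0:
            raise ConfigurationError("n_sessions must be a non-negative integer")
        self._check_shares("region_shares", self.region_shares, set(REGIONS))
        self._check_shares(
            "duration_class_shares", self.duration_class_shares, {"short", "long"}
        )
        self._check_shares("weekday_shares", self.weekday_shares, set(_WEEKDAYS))
        if not (0.0 <= self.peak_hour_share <= 1.0):
            raise ConfigurationError("peak_hour_share must lie in [0, 1]")
        if set(self.distance_params) != set(REGIONS):
            raise ConfigurationError("distance_params must cover exactly the five regions")
        for region, (_, sigma) in self.distance_params.items():
            if sigma <= 0:
                raise ConfigurationError(
                    f"distance_params[{region!r}] log-sd must be strictly positive"
                )
        for name in ("short_duration_sd", "long_duration_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.detour_factor_mean < 1.0:
            raise ConfigurationError("detour_factor_mean must be >= 1")
        if self.detour_factor_sd < 0.0:
            raise ConfigurationError("detour_factor_sd must be >= 0")
        if not (0.0 <= self.violation_fraction < 1.0):
            raise ConfigurationError("violation_fraction must lie in [0, 1)")
        if self.max_valid_geodesic_miles <= 0:
            raise ConfigurationError("max_valid_geodesic_miles must be positive")
        if pd.Timestamp(self.window_end) < pd.Timestamp(self.window_start):
            raise ConfigurationError("window_end precedes window_start")

    @staticmethod
    def _check_shares(name: str, shares: dict[str, float], expected_keys: set[str]) -> None:
        if set(shares) != expected_keys:
            raise ConfigurationError(f"{name} keys must be exactly {sorted(expected_keys)}")
        values = np.array(list(shares.values()), dtype=float)
        if np.any(values < 0) or np.any(values > 1):
            raise ConfigurationError(f"{name} proportions must lie in [0, 1]")
        if abs(values.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"{name} must sum to 1 (got {values.sum():.12f})")


# ---------------------------------------------------------------------------
# deterministic per-pair hashing for the router


def _splitmix64(x: np.ndarray) -> np.ndarray:
    # standard splitmix64 finaliser; uint64 arithmetic wraps by construction
    with np.errstate(over="ignore"):
        x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
            0xFFFFFFFFFFFFFFFF
        )
        x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
            0xFFFFFFFFFFFFFFFF
        )
        return x ^ (x >> np.uint64(31))


def _pair_uniform(seed: int, lat1, lon1, lat2, lon2) -> np.ndarray:
    """A uniform(0,1) deviate that is a pure function of (seed, point pair)."""
    bits = [np.asarray(v, dtype=np.float64).view(np.uint64) for v in (lat1, lon1, lat2, lon2)]
    h = np.full_like(bits[0], np.uint64(seed & 0xFFFFFFFFFFFFFFFF))
    for b in bits:
        h = _splitmix64(h ^ b)
    u = (h >> np.uint64(11)).astype(np.float64) * (2.0**-53)
    return np.clip(u, 1e-12, 1.0 - 1e-12)


@dataclass
class SyntheticRouter:
    """Deterministic stand-in for a car-routing distance-matrix service.

    road miles = geodesic miles x detour factor, where the detour (circuity)
    factor is drawn from Normal(mean, sd) truncated below at 1.0 using a
    deviate derived by hashing (seed, origin, destination) — so repeated
    queries for the same pair always agree, with no stored state.
    """

    detour_factor_mean: float = 1.3
    detour_factor_sd: float = 0.1
    speed_mph: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detour_factor_mean < 1.0:
            raise ConfigurationError("detour_factor_mean must be >= 1")
        if self.detour_factor_sd < 0.0:
            raise ConfigurationError("detour_factor_sd must be >= 0")
        if self.speed_mph <= 0.0:
            raise ConfigurationError("speed_mph must be positive")

    def _detour(self, lat1, lon1, lat2, lon2) -> np.ndarray:
        if self.detour_factor_sd == 0.0:
            return np.full(np.broadcast(np.asarray(lat1)).shape or (1,), self.detour_factor_mean)
        u = _pair_uniform(self.seed, lat1, lon1, lat2, lon2)
        a = (1.0 - self.detour_factor_mean) / self.detour_factor_sd
        return stats.truncnorm.ppf(
            u, a, np.inf, loc=self.detour_factor_mean, scale=self.detour_factor_sd
        )

    def route_many(self, lat1, lon1, lat2, lon2) -> tuple[np.ndarray, np.ndarray]:
        geodesic = haversine_miles_arrays(lat1, lon1, lat2, lon2)
        detour = np.asarray(self._detour(lat1, lon1, lat2, lon2))
        miles = geodesic * np.maximum(detour, 1.0)
        return miles, miles / self.speed_mph

    def route(self, origin: GeoCoordinate, destination: GeoCoordinate) -> tuple[float, float]:
        miles, hours = self.route_many(
            np.array([origin.lat]), np.array([origin.lon]),
            np.array([destination.lat]), np.array([destination.lon]),
        )
        return float(miles[0]), float(hours[0])


# ---------------------------------------------------------------------------
# geometry helpers


def destination_point(lat, lon, bearing_deg, distance_miles) -> tuple[np.ndarray, np.ndarray]:
    """Destination reached from (lat, lon) along an initial bearing for the
    given great-circle distance, on the package's reference sphere."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_miles, dtype=float) / EARTH_RADIUS_MILES
    lat2 = np.arcsin(
        np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(theta)
    )
    lon2 = lon1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    lon2 = (lon2 + np.pi) % (2.0 * np.pi) - np.pi
    return np.degrees(lat2), np.degrees(lon2)


def _truncated_lognormal_location(log_median: float, sigma: float, cap: float) -> float:
    """Location mu such that the lognormal(mu, sigma) truncated above at
    ``cap`` has median exp(log_median)."""
    log_cap = float(np.log(cap))
    if log_median >= log_cap:
        raise ConfigurationError("distance median target must be below the truncation cap")

    def median_gap(mu: float) -> float:
        f_cap = stats.norm.cdf((log_cap - mu) / sigma)
        return mu + sigma * stats.norm.ppf(f_cap / 2.0) - log_median

    lo = log_median  # truncation can only pull the median down, so mu >= target
    hi = log_cap - 1e-9
    if median_gap(hi) <= 0:
        raise ConfigurationError(
            "distance spread too large to calibrate the truncated median"
        )
    return float(optimize.brentq(median_gap, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# generation


def generate_sessions(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a session table with the configured population structure.

    Returns exactly ``config.n_sessions`` rows with the documented columns.
    Two calls with the same config produce identical tables: every random
    component draws from its own stream spawned from the master seed in a
    fixed order, so adding a field later cannot perturb existing draws.
    """
    config.validate()
    n = int(config.n_sessions)
    columns = list(SESSION_COLUMNS)
    if n == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
        empty["start_utc"] = pd.Series(dtype="datetime64[ns, UTC]")
        empty["duration_min"] = pd.Series(dtype=float)
        empty["n_participants"] = pd.Series(dtype=int)
        for c in ("provider_lat", "provider_lon", "patient_lat", "patient_lon"):
            empty[c] = pd.Series(dtype=float)
        return empty.loc[:, columns]

    streams = np.random.SeedSequence(int(config.seed)).spawn(7)
    rng_region, rng_duration, rng_distance, rng_geometry, rng_time, rng_violation, _reserved = (
        np.random.default_rng(s) for s in streams
    )

    # --- region and duration class -------------------------------------
    region_idx = rng_region.choice(
        len(REGIONS), size=n, p=[config.region_shares[r] for r in REGIONS]
    )
    regions = np.array(REGIONS, dtype=object)[region_idx]
    is_short = rng_duration.random(n) < config.duration_class_shares["short"]

    # --- bimodal duration mixture on [5, 120] ---------------------------
    durations = np.empty(n)
    u = rng_duration.random(n)
    a_s = (5.0 - config.short_duration_mean) / config.short_duration_sd
    b_s = (30.0 - config.short_duration_mean) / config.short_duration_sd
    durations[is_short] = stats.truncnorm.ppf(
        u[is_short], a_s, b_s, loc=config.short_duration_mean, scale=config.short_duration_sd
    )
    a_l = (30.0 - config.long_duration_mean) / config.long_duration_sd
    b_l = (120.0 - config.long_duration_mean) / config.long_duration_sd
    durations[~is_short] = stats.truncnorm.ppf(
        u[~is_short], a_l, b_l, loc=config.long_duration_mean, scale=config.long_duration_sd
    )

    # --- one-way geodesic distances, truncated-lognormal per region -----
    distances = np.empty(n)
    u_dist = rng_distance.random(n)
    cap = config.max_valid_geodesic_miles
    for ridx, region in enumerate(REGIONS):
        mask = region_idx == ridx
        if not mask.any():
            continue
        log_median, sigma = config.distance_params[region]
        mu = _truncated_lognormal_location(log_median, sigma, cap)
        f_cap = stats.norm.cdf((np.log(cap) - mu) / sigma)
        distances[mask] = np.exp(mu + sigma * stats.norm.ppf(u_dist[mask] * f_cap))

    # --- coordinates: provider in a region box, patient at the sampled
    #     distance along a uniform bearing --------------------------------
    boxes = np.array([_REGION_BOXES[r] for r in REGIONS])
    lat_lo, lat_hi, lon_lo, lon_hi = (boxes[region_idx, k] for k in range(4))
    provider_lat = lat_lo + rng_geometry.random(n) * (lat_hi - lat_lo)
    provider_lon = lon_lo + rng_geometry.random(n) * (lon_hi - lon_lo)
    bearings = rng_geometry.random(n) * 360.0
    patient_lat, patient_lon = destination_point(provider_lat, provider_lon, bearings, distances)

    # --- timestamps ------------------------------------------------------
    dates = pd.date_range(config.window_start, config.window_end, freq="D", tz="UTC")
    dates_by_weekday = [dates[dates.dayofweek == d] for d in range(7)]
    if any(len(g) == 0 for g in dates_by_weekday):
        # short windows may miss a weekday entirely; renormalise over those present
        present = [d for d in range(7) if len(dates_by_weekday[d]) > 0]
        probs = np.array([config.weekday_shares[_WEEKDAYS[d]] for d in present])
        probs = probs / probs.sum()
        weekday_idx = np.array(present)[rng_time.choice(len(present), size=n, p=probs)]
    else:
        weekday_idx = rng_time.choice(
            7, size=n, p=[config.weekday_shares[d] for d in _WEEKDAYS]
        )
    base = np.empty(n, dtype="int64")
    for d in range(7):  # fixed visit order keeps the draw sequence stable
        mask = weekday_idx == d
        m = int(mask.sum())
        if m == 0:
            continue
        vals = dates_by_weekday[d].asi8
        base[mask] = vals[rng_time.integers(0, len(vals), size=m)]
    in_peak = rng_time.random(n) < config.peak_hour_share
    hours = np.where(
        in_peak, rng_time.integers(13, 24, size=n), rng_time.integers(0, 13, size=n)
    )
    seconds = hours * 3600 + rng_time.integers(0, 3600, size=n)
    start_utc = pd.to_datetime(base + seconds * 1_000_000_000, utc=True)

    n_participants = np.full(n, 2, dtype=int)

    # --- planted eligibility violations ---------------------------------
    n_viol = int(round(config.violation_fraction * n))
    if n_viol > 0:
        viol_idx = rng_violation.choice(n, size=n_viol, replace=False)
        kinds = rng_violation.integers(0, len(_VIOLATION_KINDS), size=n_viol)
        for i, kind_i in zip(viol_idx, kinds):
            kind = _VIOLATION_KINDS[kind_i]
            if kind == "short_call":
                durations[i] = 0.5 + rng_violation.random() * 4.0  # < 5 min
            elif kind == "long_session":
                durations[i] = 120.5 + rng_violation.random() * 119.0  # > 120 min
            elif kind == "group_session":
                n_participants[i] = int(rng_violation.integers(3, 6))
            elif kind == "far":
                far = cap + 1.0 + rng_violation.random() * cap
                patient_lat[i], patient_lon[i] = (
                    float(v)
                    for v in destination_point(
                        provider_lat[i], provider_lon[i], rng_violation.random() * 360.0, far
                    )
                )
            elif kind == "missing_region":
                regions[i] = np.nan

    frame = pd.DataFrame(
        {
            "session_id": [f"S{i:08d}" for i in range(n)],
            "start_utc": start_utc,
            "duration_min": np.round(durations, 2),
            "n_participants": n_participants,
            "provider_lat": np.round(provider_lat, 6),
            "provider_lon": np.round(provider_lon, 6),
            "patient_lat": np.round(patient_lat, 6),
            "patient_lon": np.round(patient_lon, 6),
            "region": regions,
        }
    )
    return frame.loc[:, columns]


def write_sessions(frame: pd.DataFrame, path) -> None:
    """Write a generated session table in the documented CSV format."""
    write_sessions_csv(frame, path)


def router_from_config(config: GeneratorConfig, speed_mph: float = 40.0) -> SyntheticRouter:
    """The routing oracle matched to a generator configuration."""
    return SyntheticRouter(
        detour_factor_mean=config.detour_factor_mean,
        detour_factor_sd=config.detour_factor_sd,
        speed_mph=speed_mph,
        seed=config.seed,
    )
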