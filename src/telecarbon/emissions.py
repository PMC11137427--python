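"""Per-session CO2 savings, videoconferencing expenditure, and net balance.

Two linear conversion chains, each driven by a constant in
:class:`EmissionFactors`:

* avoided-travel savings: round-trip car miles x 404 g CO2/mile (2022 US EPA
  average passenger-vehicle tailpipe rate at 22.0 mpg);
* videoconferencing expenditure:
  minutes x 0.036 GB/min x 0.015 kWh/GB x 4.33e-4 t CO2/kWh x 1e6 g/t,
  i.e. two-participant 720p video data volume, fixed-line transmission
  energy, and the US grid emission rate.

Net savings is their difference; it is negative only for (near-)zero-travel
sessions, whose energy cost exceeds the avoided trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .travel import TravelEstimate

GRAMS_PER_METRIC_TON = 1_000_000.0


@dataclass(frozen=True)
class EmissionFactors:
    """Every constant in the conversion chains, in one configurable record.

    Attributes
    ----------
    g_co2_per_mile : tailpipe grams CO2 per car mile.
    gb_per_min : data volume of a two-participant 720p video call, GB/minute.
    kwh_per_gb : fixed-line transmission energy, kWh/GB.
    t_co2_per_kwh : grid emission rate, metric tons CO2/kWh.
    car_share : fraction of round trips made by car, in (0, 1].
    """

    g_co2_per_mile: float = 404.0
    gb_per_min: float = 0.036
    kwh_per_gb: float = 0.015
    t_co2_per_kwh: float = 4.33e-4
    car_share: float = 0.848

    def __post_init__(self) -> None:
        for name in ("g_co2_per_mile", "gb_per_min", "kwh_per_gb", "t_co2_per_kwh"):
            if getattr(self, name) <= 0:
                raise DomainError(f"emission factor {name} must be strictly positive")
        if not (0.0 < self.car_share <= 1.0):
            raise DomainError(f"car_share {self.car_share} outside (0, 1]")

    @property
    def g_co2_per_min_video(self) -> float:
        """Collapsed expenditure chain: grams CO2 per session minute."""
        return self.gb_per_min * self.kwh_per_gb * self.t_co2_per_kwh * GRAMS_PER_METRIC_TON


@dataclass(frozen=True)
class EmissionsResult:
    """Per-session CO2 balance, all in grams."""

    savings_g: float
    expenditure_g: float
    net_g: float
    net_per_min_g: float


def travel_savings_g(round_trip_miles, factors: EmissionFactors = EmissionFactors()):
    """Avoided tailpipe CO2 in grams for a round trip of the given miles."""
    miles = np.asarray(round_trip_miles, dtype=float)
    if np.any(miles < 0):
        raise DomainError("round_trip_miles must be non-negative")
    out = miles * factors.g_co2_per_mile
    return float(out) if np.isscalar(round_trip_miles) else out


def session_expenditure_g(duration_min, factors: EmissionFactors = EmissionFactors()):
    """Videoconferencing CO2 in grams for a session of the given minutes."""
    minutes = np.asarray(duration_min, dtype=float)
    if np.any(minutes < 0):
        raise DomainError("duration_min must be non-negative")
    out = minutes * factors.g_co2_per_min_video
    return float(out) if np.isscalar(duration_min) else out


def net_session_emissions(
    travel: TravelEstimate,
    duration_min: float,
    factors: EmissionFactors = EmissionFactors(),
    apply_mode_adjustment: bool = False,
) -> EmissionsResult:
    """Compose savings and expenditure into a per-session balance.

    With ``apply_mode_adjustment`` the savings side uses the car-mode-share
    scaled miles instead of the raw round trip.
    """
    miles = travel.adjusted_round_trip_miles if apply_mode_adjustment else travel.round_trip_miles
    savings = travel_savings_g(miles, factors)
    expenditure = session_expenditure_g(duration_min, factors)
    net = savings - expenditure
    per_min = net / duration_min if duration_min > 0 else 0.0
    return EmissionsResult(savings, expenditure, net, per_min)


def add_emissions_columns(
    frame: pd.DataFrame,
    factors: EmissionFactors = EmissionFactors(),
    apply_mode_adjustment: bool = False,
) -> pd.DataFrame:
    """Append savings_g / expenditure_g / net_g / net_per_min_g to a session
    table that already carries travel columns."""
    out = frame.copy()
    col = "adjusted_round_trip_miles" if apply_mode_adjustment else "round_trip_miles"
    out["savings_g"] = travel_savings_g(out[col].to_numpy(), factors)
    out["expenditure_g"] = session_expenditure_g(out["duration_min"].to_numpy(), factors)
    out["net_g"] = out["savings_g"] - out["expenditure_g"]
    dur = out["duration_min"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        per_min = np.where(dur > 0, out["net_g"].to_numpy() / dur, 0.0)
    out["net_per_min_g"] = per_min
    return out
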