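"""The synthetic session generator and routing oracle."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telecarbon.errors import ConfigurationError, DomainError
from telecarbon.records import REGIONS, GeoCoordinate, write_sessions_csv
from telecarbon.synthetic import (
    GeneratorConfig,
    SyntheticRouter,
    destination_point,
    generate_sessions,
)
from telecarbon.travel import haversine_miles, haversine_miles_arrays

latitudes = st.floats(-85.0, 85.0, allow_nan=False)
longitudes = st.floats(-179.0, 179.0, allow_nan=False)


class TestGeneratorConfig:
    def test_defaults_are_valid(self):
        GeneratorConfig().validate()

    @pytest.mark.parametrize(
        ("field", "value", "fragment"),
        [
            ("n_sessions", -1, "n_sessions"),
            ("peak_hour_share", 1.5, "peak_hour_share"),
            ("detour_factor_mean", 0.9, "detour_factor_mean"),
            ("detour_factor_sd", -0.1, "detour_factor_sd"),
            ("violation_fraction", 1.0, "violation_fraction"),
            ("short_duration_sd", 0.0, "short_duration_sd"),
            ("region_shares", {"Northeast": 1.0}, "region_shares"),
            ("weekday_shares", {d: 1 / 7 + 0.01 for d in
              ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday")},
             "weekday_shares"),
        ],
    )
    def test_invalid_config_names_offending_field(self, field, value, fragment):
        with pytest.raises(ConfigurationError, match=fragment):
            GeneratorConfig(**{field: value})


class TestGenerateSessions:
    def test_zero_sessions_empty_table(self):
        frame = generate_sessions(GeneratorConfig(n_sessions=0))
        assert len(frame) == 0
        assert list(frame.columns) == [
            "session_id", "start_utc", "duration_min", "n_participants",
            "provider_lat", "provider_lon", "patient_lat", "patient_lon", "region",
        ]

    def test_exact_row_count(self, population_10k):
        assert len(population_10k) == 10_000

    def test_reproducibility_byte_identical(self):
        config = GeneratorConfig(n_sessions=2_000, seed=77)
        buffers = []
        for _ in range(2):
            frame = generate_sessions(GeneratorConfig(n_sessions=2_000, seed=77))
            buf = io.StringIO()
            write_sessions_csv(frame, buf)
            buffers.append(buf.getvalue())
        assert buffers[0] == buffers[1]
        assert config.seed == 77  # config not mutated by generation

    def test_region_shares_recovered(self, population_100k):
        targets = {"Northeast": 34.18, "Southeast": 20.42, "West": 18.99,
                   "Midwest": 17.26, "Southwest": 9.15}
        shares = population_100k["region"].value_counts(normalize=True) * 100.0
        for region, target_pct in targets.items():
            assert shares[region] == pytest.approx(target_pct, abs=0.5)

    def test_duration_split_recovered(self, retained_100k):
        short_share = (retained_100k["duration_min"] <= 30.0).mean()
        assert short_share == pytest.approx(0.4406, abs=0.01)

    def test_eligible_durations_in_support(self, retained_100k):
        assert retained_100k["duration_min"].between(5.0, 120.0).all()

    def test_regional_distance_medians_recovered(self, retained_100k):
        """Parameter recovery: the empirical median one-way geodesic distance
        per region is within 10% of the configured lognormal median."""
        config = GeneratorConfig()
        geodesic = haversine_miles_arrays(
            retained_100k["provider_lat"], retained_100k["provider_lon"],
            retained_100k["patient_lat"], retained_100k["patient_lon"],
        )
        medians = pd.Series(geodesic).groupby(retained_100k["region"].to_numpy()).median()
        for region in REGIONS:
            target = float(np.exp(config.distance_params[region][0]))
            assert medians[region] == pytest.approx(target, rel=0.10)

    def test_timestamps_respect_weekday_and_hour_shares(self, population_100k):
        config = GeneratorConfig()
        dow = population_100k["start_utc"].dt.dayofweek
        weekend_share = (dow >= 5).mean()
        assert weekend_share == pytest.approx(0.0311, abs=0.005)
        hour = population_100k["start_utc"].dt.hour
        peak_share = ((hour >= 13) & (hour <= 23)).mean()
        assert peak_share == pytest.approx(config.peak_hour_share, abs=0.01)
        within = population_100k["start_utc"].between(
            pd.Timestamp("2022-01-01", tz="UTC"), pd.Timestamp("2023-02-22", tz="UTC")
        )
        assert within.all()

    def test_planted_violation_fraction(self, population_10k):
        from telecarbon.ingest import apply_filters

        _, report = apply_filters(population_10k)
        planted = sum(report.exclusions.values())
        assert planted == pytest.approx(0.02 * len(population_10k), rel=0.25)


class TestSyntheticRouter:
    def test_same_point_routes_to_zero(self):
        router = SyntheticRouter(seed=3)
        p = GeoCoordinate(40.0, -100.0)
        assert router.route(p, p) == (0.0, 0.0)

    def test_degenerate_detour_distribution(self):
        router = SyntheticRouter(detour_factor_mean=1.3, detour_factor_sd=0.0, speed_mph=40.0, seed=0)
        lat2, lon2 = destination_point(40.0, -100.0, 90.0, 10.0)
        miles, hours = router.route(GeoCoordinate(40.0, -100.0), GeoCoordinate(float(lat2), float(lon2)))
        assert miles == pytest.approx(13.0, abs=1e-6)
        assert hours == pytest.approx(13.0 / 40.0, abs=1e-9)

    @given(lat1=latitudes, lon1=longitudes, lat2=latitudes, lon2=longitudes)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_road_never_below_geodesic(self, lat1, lon1, lat2, lon2):
        router = SyntheticRouter(seed=9)
        a, b = GeoCoordinate(lat1, lon1), GeoCoordinate(lat2, lon2)
        miles, hours = router.route(a, b)
        assert miles >= haversine_miles(a, b) - 1e-9
        assert hours == pytest.approx(miles / router.speed_mph, rel=1e-12)

    def test_deterministic_per_pair_and_seed(self):
        a, b = GeoCoordinate(40.0, -100.0), GeoCoordinate(41.0, -101.0)
        r1 = SyntheticRouter(seed=5)
        r2 = SyntheticRouter(seed=5)
        assert r1.route(a, b) == r2.route(a, b) == r1.route(a, b)
        r3 = SyntheticRouter(seed=6)
        assert r3.route(a, b) != r1.route(a, b)

    def test_invalid_coordinates_rejected(self):
        router = SyntheticRouter(seed=0)
        with pytest.raises(DomainError):
            router.route_many([95.0], [0.0], [0.0], [0.0])

    def test_invalid_router_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticRouter(detour_factor_mean=0.5)
        with pytest.raises(ConfigurationError):
            SyntheticRouter(speed_mph=0.0)


class TestDestinationPoint:
    @given(
        lat=latitudes, lon=longitudes,
        bearing=st.floats(0.0, 360.0, allow_nan=False),
        distance=st.floats(0.1, 400.0, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_round_trip_distance(self, lat, lon, bearing, distance):
        """Moving `distance` miles along any bearing lands exactly that
        geodesic distance away."""
        lat2, lon2 = destination_point(lat, lon, bearing, distance)
        got = haversine_miles(GeoCoordinate(lat, lon), GeoCoordinate(float(lat2), float(lon2)))
        assert got == pytest.approx(distance, rel=1e-9, abs=1e-9)
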