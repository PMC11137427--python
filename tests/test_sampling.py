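"""Stratum assignment, largest-remainder allocation, and sample drawing."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telecarbon.errors import DomainError
from telecarbon.records import GeoCoordinate, SessionRecord
from telecarbon.sampling import (
    StratumKey,
    all_stratum_keys,
    allocate_proportional,
    assign_strata,
    assign_stratum,
    draw_sample,
    stratum_census,
)


def _record(start: str, duration: float, region: str) -> SessionRecord:
    return SessionRecord(
        session_id="X",
        start_utc=pd.Timestamp(start),
        duration_min=duration,
        n_participants=2,
        provider_loc=GeoCoordinate(40.0, -100.0),
        patient_loc=GeoCoordinate(40.1, -100.1),
        region=region,
    )


class TestAssignStratum:
    def test_design_has_40_cells(self):
        keys = all_stratum_keys()
        assert len(keys) == len(set(keys)) == 40

    @pytest.mark.parametrize(
        ("start", "duration", "region", "expected"),
        [
            # 2022-06-04 is a Saturday
            ("2022-06-04T14:00:00Z", 20.0, "West", ("West", "short", "weekend", "peak")),
            # 2022-06-07 is a Tuesday
            ("2022-06-07T02:00:00Z", 45.0, "Northeast", ("Northeast", "long", "weekday", "offpeak")),
            ("2022-06-07T13:00:00Z", 30.0, "Midwest", ("Midwest", "short", "weekday", "peak")),
            ("2022-06-07T23:59:00Z", 30.01, "Midwest", ("Midwest", "long", "weekday", "peak")),
            ("2022-06-07T12:59:00Z", 30.0, "Midwest", ("Midwest", "short", "weekday", "offpeak")),
            ("2022-06-05T00:00:00Z", 5.0, "Southwest", ("Southwest", "short", "weekend", "offpeak")),
        ],
        ids=["weekend-peak", "weekday-offpeak", "boundary-30min-short",
             "boundary-just-over-30-long", "hour-just-before-peak", "sunday-midnight"],
    )
    def test_rule_application(self, start, duration, region, expected):
        key = assign_stratum(_record(start, duration, region))
        assert (key.region, key.duration_class, key.day_class, key.hour_class) == expected

    def test_vectorised_assignment_matches_per_record(self, population_10k):
        from telecarbon.ingest import apply_filters

        retained, _ = apply_filters(population_10k)
        sample = retained.head(200)
        frame = assign_strata(sample)
        for _, row in frame.iterrows():
            key = assign_stratum(SessionRecord.from_row(row))
            assert (row["duration_class"], row["day_class"], row["hour_class"]) == (
                key.duration_class, key.day_class, key.hour_class
            )


def _keys(n: int) -> list[StratumKey]:
    return all_stratum_keys()[:n]


class TestAllocateProportional:
    def test_symmetric_split(self):
        k1, k2 = _keys(2)
        alloc = allocate_proportional({k1: 50, k2: 50}, 10)
        assert alloc.counts == {k1: 5, k2: 5}

    def test_largest_remainder_tie_break_is_canonical(self):
        k1, k2, k3 = _keys(3)
        alloc = allocate_proportional({k1: 10, k2: 10, k3: 10}, 10)
        # equal remainders: the leftover unit goes to the first key in
        # canonical stratum order
        assert alloc.counts == {k1: 4, k2: 3, k3: 3}
        assert sum(alloc.counts.values()) == 10

    def test_single_stratum(self):
        (k1,) = _keys(1)
        assert allocate_proportional({k1: 100}, 7).counts == {k1: 7}

    def test_oversized_sample_rejected(self):
        (k1,) = _keys(1)
        with pytest.raises(DomainError):
            allocate_proportional({k1: 5}, 6)

    @given(
        sizes=st.lists(st.integers(1, 500), min_size=1, max_size=40),
        data=st.data(),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_exactness_and_share_distortion(self, sizes, data):
        keys = _keys(len(sizes))
        population = dict(zip(keys, sizes))
        total = sum(sizes)
        n = data.draw(st.integers(0, total))
        alloc = allocate_proportional(population, n)
        assert sum(alloc.counts.values()) == n
        for k in keys:
            assert 0 <= alloc.counts[k] <= population[k]
            if n > 0:
                quota = n * population[k] / total
                assert abs(alloc.counts[k] - quota) < 1.0  # floor/ceil of quota
                assert abs(alloc.counts[k] / n - population[k] / total) < 1.0 / n


@pytest.fixture(scope="module")
def stratified(retained_100k):
    return assign_strata(retained_100k)


class TestDrawSample:
    def test_census_case_returns_everything(self, stratified):
        small = stratified.head(500)
        census = stratum_census(small)
        alloc = allocate_proportional(census, 500)
        drawn = draw_sample(small, alloc, seed=1)
        assert len(drawn) == 500
        assert set(drawn["session_id"]) == set(small["session_id"])

    def test_deterministic_given_seed(self, stratified):
        census = stratum_census(stratified)
        alloc = allocate_proportional(census, 2_000)
        a = draw_sample(stratified, alloc, seed=11)
        b = draw_sample(stratified, alloc, seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = draw_sample(stratified, alloc, seed=12)
        assert set(a["session_id"]) != set(c["session_id"])

    def test_no_duplicates_and_subset(self, stratified):
        census = stratum_census(stratified)
        alloc = allocate_proportional(census, 2_000)
        drawn = draw_sample(stratified, alloc, seed=5)
        assert drawn["session_id"].is_unique
        assert drawn["session_id"].isin(stratified["session_id"]).all()

    def test_sampled_shares_match_population_shares(self, stratified):
        """Proportionality: every stratum's sampled share is within one
        sampling unit of its population share."""
        census = stratum_census(stratified)
        n = 10_000
        alloc = allocate_proportional(census, n)
        drawn = assign_strata(draw_sample(stratified, alloc, seed=2))
        got = stratum_census(drawn)
        total = sum(census.values())
        for key, pop in census.items():
            share_gap = abs(got.get(key, 0) / n - pop / total)
            assert share_gap < 1.0 / n + 1e-12

    def test_infeasible_allocation_names_stratum(self, stratified):
        census = stratum_census(stratified)
        key = next(iter(sorted(census, key=lambda k: k.sort_index)))
        bad = allocate_proportional(census, 100)
        bad.counts[key] = census[key] + 1
        with pytest.raises(DomainError, match=key.region):
            draw_sample(stratified, bad, seed=0)
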