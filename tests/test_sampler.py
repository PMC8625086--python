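"""Cumulative-weight interval sampling and pool-matched household assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rpgen.errors import DomainError, MatchError
from rpgen.harmonize import harmonize_housing, harmonize_persons
from rpgen.sampler import (
    build_intervals,
    draw_weighted,
    match_households,
    sample_persons,
    select_intervals,
)


class TestBuildIntervals:
    @pytest.mark.parametrize(
        "weights,expected",
        [([1, 1, 1, 1], [0.25, 0.5, 0.75, 1.0]),
         ([2, 1, 1], [0.5, 0.75, 1.0]),
         ([7.3], [1.0])],
    )
    def test_cumulative_normalization(self, weights, expected):
        iv = build_intervals(weights)
        np.testing.assert_allclose(iv.cumulative, expected, atol=1e-12)
        assert iv.cumulative[-1] == 1.0

    def test_interval_widths_proportional_to_weights(self):
        w = np.array([0.5, 3.0, 1.5, 5.0])
        iv = build_intervals(w)
        widths = np.diff(np.concatenate([[0.0], iv.cumulative]))
        np.testing.assert_allclose(widths, w / w.sum(), atol=1e-12)

    @pytest.mark.parametrize("weights", [[], [1, 0], [1, -2], [np.nan]])
    def test_invalid_weights_rejected(self, weights):
        with pytest.raises(DomainError):
            build_intervals(weights)


class TestSelection:
    def test_boundary_draw_selects_lower_indexed_record(self):
        iv = build_intervals([1, 1, 2])  # cumulative 0.25, 0.5, 1.0
        assert select_intervals(iv, [0.25]).tolist() == [0]
        assert select_intervals(iv, [0.5]).tolist() == [1]
        assert select_intervals(iv, [0.2500001]).tolist() == [1]

    def test_excluded_record_is_never_drawn(self):
        # A record absent from the intervals has zero measure by construction.
        iv = build_intervals([1.0], ids=np.array([7]))
        rng = np.random.default_rng(0)
        assert set(draw_weighted(iv, 1000, rng)) == {7}

    def test_heavy_record_frequency_matches_weight(self):
        # weights [1, 3]: P(id 2) = 0.75; binomial CI at n=1e5 is well
        # inside [0.74, 0.76].
        iv = build_intervals([1, 3], ids=np.array([1, 2]))
        rng = np.random.default_rng(1234)
        draws = draw_weighted(iv, 100_000, rng)
        freq = np.mean(draws == 2)
        assert 0.74 <= freq <= 0.76

    def test_equal_weights_uniform_by_chi_square(self):
        k, n = 10, 100_000
        iv = build_intervals(np.ones(k))
        rng = np.random.default_rng(99)
        draws = draw_weighted(iv, n, rng)
        counts = np.bincount(draws, minlength=k)
        _, p = stats.chisquare(counts)
        assert p > 0.001

    def test_frequency_convergence_for_arbitrary_weights(self):
        rng = np.random.default_rng(7)
        w = rng.lognormal(0, 1, size=25)
        iv = build_intervals(w)
        draws = draw_weighted(iv, 100_000, np.random.default_rng(8))
        freq = np.bincount(draws, minlength=25) / 100_000
        p = w / w.sum()
        bound = 3 * np.sqrt(p * (1 - p) / 100_000)
        assert np.all(np.abs(freq - p) < np.maximum(bound, 1e-3))

    def test_draw_requires_positive_n(self):
        with pytest.raises(DomainError):
            draw_weighted(build_intervals([1]), 0, np.random.default_rng(0))


class TestSamplePersons:
    def test_same_seed_identical_tables(self, small_surveys, house_type_recodes):
        persons, _, _ = small_surveys
        harm, _ = harmonize_persons(persons, house_type_recodes)
        a = sample_persons(harm.reset_index(drop=True), 200, np.random.default_rng(5))
        b = sample_persons(harm.reset_index(drop=True), 200, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_table_rejected(self):
        with pytest.raises(DomainError):
            sample_persons(pd.DataFrame({"weight": []}), 5, np.random.default_rng(0))


def _one_pool_tables(pool, weights, ids=None):
    n = len(weights)
    return pd.DataFrame({
        "pool": [pool] * n,
        "weight": weights,
        "housing_id": ids or [f"A{i}" for i in range(n)],
    })


class TestMatchHouseholds:
    def test_single_candidate_always_matched(self):
        persons = pd.DataFrame({"pool": [42] * 10})
        housing = _one_pool_tables(42, [3.0])
        energy = housing.rename(columns={"housing_id": "energy_id"})
        m = match_households(persons, housing, energy,
                             np.random.default_rng(0), np.random.default_rng(1))
        assert (m["housing_row"] == 0).all()
        assert (m["fallback_level"] == 0).all()

    def test_within_pool_weighted_frequency(self):
        # three pool-42 candidates with weights [1, 1, 2]: the heavy one
        # should be matched about half the time.
        persons = pd.DataFrame({"pool": [42] * 20_000})
        housing = _one_pool_tables(42, [1.0, 1.0, 2.0])
        energy = _one_pool_tables(42, [1.0]).rename(columns={"housing_id": "energy_id"})
        m = match_households(persons, housing, energy,
                             np.random.default_rng(3), np.random.default_rng(4))
        freq = np.mean(m["housing_row"] == 2)
        assert 0.47 <= freq <= 0.53

    def test_empty_pool_relaxes_income_first(self):
        # person pool 233 = (rural, South, multi, 2 adults no children,
        # middle income); candidates exist only at other income categories,
        # so one income relaxation suffices -> fallback_level 1.
        persons = pd.DataFrame({"pool": [233]})
        housing = _one_pool_tables(232, [1.0])  # same tuple, income cat 1
        energy = _one_pool_tables(233, [1.0]).rename(columns={"housing_id": "energy_id"})
        m = match_households(persons, housing, energy,
                             np.random.default_rng(0), np.random.default_rng(0))
        assert m.loc[0, "fallback_level_housing"] == 1
        assert m.loc[0, "fallback_level_energy"] == 0
        assert m.loc[0, "fallback_level"] == 1

    def test_house_type_relaxed_second_setting_third(self):
        persons = pd.DataFrame({"pool": [233]})
        # pool 221 = (rural, South, standalone, fam 2, inc 2): house type
        # differs -> needs level 2.
        housing_l2 = _one_pool_tables(221, [1.0])
        # pool 89 = (urban, South, multi, fam 2, inc 2): setting differs
        # -> needs level 3.
        housing_l3 = _one_pool_tables(89, [1.0])
        energy = _one_pool_tables(233, [1.0]).rename(columns={"housing_id": "energy_id"})
        m2 = match_households(persons, housing_l2, energy,
                              np.random.default_rng(0), np.random.default_rng(0))
        m3 = match_households(persons, housing_l3, energy,
                              np.random.default_rng(0), np.random.default_rng(0))
        assert m2.loc[0, "fallback_level_housing"] == 2
        assert m3.loc[0, "fallback_level_housing"] == 3

    def test_region_and_family_never_relaxed(self):
        persons = pd.DataFrame({"pool": [233]})
        # pool 305 would be out of range; use a different region instead:
        # (rural, West, multi, fam 2, inc 2) = encode(2,4,2,2,2).
        from rpgen.harmonize import encode_pool
        other_region = _one_pool_tables(encode_pool(2, 4, 2, 2, 2), [1.0])
        energy = _one_pool_tables(233, [1.0]).rename(columns={"housing_id": "energy_id"})
        with pytest.raises(MatchError, match="pool 233"):
            match_households(persons, other_region, energy,
                             np.random.default_rng(0), np.random.default_rng(0))

    def test_pool_consistency_without_fallback(self, covered_surveys,
                                               house_type_recodes):
        persons, housing, _ = covered_surveys
        ph, _ = harmonize_persons(persons, house_type_recodes)
        hh, _ = harmonize_housing(housing, house_type_recodes)
        sampled = sample_persons(ph.reset_index(drop=True), 500,
                                 np.random.default_rng(2))
        m = match_households(sampled, hh, hh.rename(columns={"housing_id": "energy_id"}),
                             np.random.default_rng(5), np.random.default_rng(6))
        zero = m["fallback_level"] == 0
        assert zero.all()
        matched_pools = hh.iloc[m["housing_row"]]["pool"].to_numpy()
        assert (matched_pools == sampled["pool"].to_numpy()).all()
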