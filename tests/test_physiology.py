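"""Physiology generation: conditioning, consistency, jitter, and caps."""

import numpy as np
import pytest
from scipy import stats

from rpgen.errors import DomainError
from rpgen.physiology import (
    HEIGHT_CAP_CM,
    WEIGHT_CAP_KG,
    Physiology,
    _with_factors,
    body_surface_area,
    derive,
    generate_physiology,
    generate_population_physiology,
    jitter_physiology,
    mean_height,
)


class TestBodySurfaceArea:
    def test_du_bois_closed_form(self):
        # 0.007184 * 180^0.725 * 80^0.425, evaluated independently
        assert body_surface_area(180, 80) == pytest.approx(1.9965, abs=2e-3)

    def test_power_law_scaling_in_weight(self):
        ratio = body_surface_area(170, 120) / body_surface_area(170, 60)
        assert ratio == pytest.approx(2**0.425, rel=1e-12)

    @pytest.mark.parametrize("h,w", [(0.0, 80), (180, 0.0), (-1, 70)])
    def test_nonpositive_inputs_rejected(self, h, w):
        with pytest.raises(DomainError):
            body_surface_area(h, w)


class TestGenerate:
    def test_determinism_given_identical_stream_state(self):
        a = generate_physiology(30, "M", "N", np.random.default_rng(42))
        b = generate_physiology(30, "M", "N", np.random.default_rng(42))
        assert a == b

    def test_adults_heavier_than_children_on_average(self):
        rng = np.random.default_rng(0)
        adults = [generate_physiology(30, "M", "N", rng).body_weight
                  for _ in range(1000)]
        rng = np.random.default_rng(0)
        kids = [generate_physiology(5, "M", "N", rng).body_weight
                for _ in range(1000)]
        assert np.mean(adults) > np.mean(kids)

    def test_weight_and_cardiac_output_positively_correlated(self):
        rng = np.random.default_rng(3)
        cohort = [generate_physiology(30, "M", "N", rng) for _ in range(1000)]
        w = [p.body_weight for p in cohort]
        co = [p.cardiac_output for p in cohort]
        rho, _ = stats.spearmanr(w, co)
        assert rho > 0

    def test_weight_and_breathing_rate_positively_correlated(self):
        rng = np.random.default_rng(4)
        cohort = [generate_physiology(40, "F", "N", rng) for _ in range(1000)]
        rho, _ = stats.spearmanr([p.body_weight for p in cohort],
                                 [p.breathing_rate for p in cohort])
        assert rho > 0

    def test_growth_curves_nondecreasing_through_age_18(self):
        for gender in ("M", "F"):
            heights = [mean_height(a, gender) for a in range(19)]
            assert all(b >= a for a, b in zip(heights, heights[1:]))

    def test_mean_weight_nondecreasing_through_age_18(self):
        from rpgen.physiology import mean_bmi
        for gender in ("M", "F"):
            weights = [mean_bmi(a, gender) * (mean_height(a, gender) / 100) ** 2
                       for a in range(19)]
            assert all(b >= a for a, b in zip(weights, weights[1:]))

    def test_age_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            generate_physiology(120, "M", "N", np.random.default_rng(0))


class TestInternalConsistency:
    def test_derived_quantities_recompute_exactly(self):
        rng = np.random.default_rng(11)
        for age in (2, 10, 35, 80):
            p = generate_physiology(age, "F", "M", rng)
            d = derive(p.height, p.body_weight, p.gender, p.age)
            assert d["body_surface_area"] == p.body_surface_area
            assert d["cardiac_output"] == p.cardiac_output
            assert d["breathing_rate"] == p.breathing_rate
            assert d["blood_volume"] == p.blood_volume
            assert d["compartment_volumes"] == p.compartment_volumes

    def test_compartment_volumes_positive_and_sum_below_body_volume(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            age = int(rng.integers(0, 100))
            p = generate_physiology(age, "M" if rng.random() < 0.5 else "F",
                                    "N", rng)
            vols = p.compartment_volumes
            assert all(v > 0 for v in vols.values())
            assert sum(vols.values()) < p.body_weight
            assert 0 < p.hematocrit < 1


class TestJitter:
    def _adult(self) -> Physiology:
        return generate_physiology(30, "M", "N", np.random.default_rng(1))

    def test_unit_factor_is_identity(self):
        p = self._adult()
        assert _with_factors(p, 1.0, 1.0) == p

    def test_weight_cap_applied_exactly(self):
        p = self._adult()
        # force a factor implying a weight above the cap
        factor = 163.0 / p.body_weight
        jittered = _with_factors(p, 1.0, factor)
        assert jittered.body_weight == WEIGHT_CAP_KG

    def test_height_cap_applied_exactly(self):
        p = self._adult()
        jittered = _with_factors(p, 230.0 / p.height, 1.0)
        assert jittered.height == HEIGHT_CAP_CM

    def test_derived_recomputed_after_jitter(self):
        p = self._adult()
        j = jitter_physiology(p, np.random.default_rng(5))
        d = derive(j.height, j.body_weight, j.gender, j.age)
        assert d["cardiac_output"] == j.cardiac_output
        assert d["body_surface_area"] == j.body_surface_area


class TestPopulationPhysiology:
    def test_caps_hold_over_10k_individuals(self):
        rng = np.random.default_rng(2024)
        ages = rng.integers(0, 100, size=10_000)
        genders = np.where(rng.random(10_000) < 0.5, "M", "F")
        eth = np.full(10_000, "N", dtype=object)
        df = generate_population_physiology(ages, genders, eth, seed=77)
        assert df["height_cm"].max() <= HEIGHT_CAP_CM
        assert df["body_weight_kg"].max() <= WEIGHT_CAP_KG
        assert (df["height_cm"] > 0).all()
        assert (df["body_weight_kg"] > 0).all()

    def test_matching_demographics_share_prejitter_values(self):
        # Pre-jitter draws are keyed on (age, gender, ethnicity): a cohort
        # of identical profiles differs only through jitter, so spread is
        # small relative to between-profile spread.
        n = 50
        df = generate_population_physiology(
            np.full(n, 30), np.full(n, "M", dtype=object),
            np.full(n, "N", dtype=object), seed=5, jitter_sigma=0.0,
        )
        assert df["height_cm"].nunique() == 1
        assert df["body_weight_kg"].nunique() == 1

    def test_reproducible_given_seed(self):
        ages = [5, 30, 70]
        g = np.array(["M", "F", "M"], dtype=object)
        e = np.array(["N", "O", "M"], dtype=object)
        a = generate_population_physiology(ages, g, e, seed=9)
        b = generate_population_physiology(ages, g, e, seed=9)
        assert a.equals(b)
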