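"""Synthetic-cohort IMR estimation against hand counts and the
direct-cohort oracle."""

import numpy as np
import pandas as pd
import pytest

from equimort import (
    AgeSegment,
    SyntheticCohortIMR,
    SyntheticConfig,
    cohort_imr_oracle,
    component_probability,
    estimate_imr,
    generate_births,
)
from equimort.errors import UndefinedEstimateError
from equimort.io import from_dhs_br

from conftest import make_births


class TestComponentProbability:
    def test_no_deaths_is_zero(self):
        births = make_births(10, age_months=24)
        assert component_probability(births, AgeSegment(0, 1)) == 0.0

    def test_hand_count_two_in_ten(self):
        births = make_births(10, age_months=24, death_ages={0: 0, 1: 0})
        assert component_probability(births, AgeSegment(0, 1)) == pytest.approx(0.2)

    def test_all_die_in_segment(self):
        births = make_births(5, age_months=24, death_ages={i: 0 for i in range(5)})
        assert component_probability(births, AgeSegment(0, 1)) == 1.0

    def test_earlier_deaths_leave_risk_set(self):
        # 4 children reach [1,3); the one who died at age 0 does not
        births = make_births(5, age_months=24, death_ages={0: 0, 1: 2})
        assert component_probability(births, AgeSegment(1, 3)) == pytest.approx(0.25)

    def test_partial_exposure_fraction(self):
        # ages 9 months: 3 of 6 months of [6,12) lived -> exposure 1/2 each
        births = make_births(4, age_months=9, death_ages={0: 7})
        q = component_probability(births, AgeSegment(6, 12))
        assert q == pytest.approx(1 / (4 * 0.5))

    def test_zero_denominator_is_flagged(self):
        births = make_births(3, age_months=0)
        with pytest.raises(UndefinedEstimateError, match="zero exposure"):
            component_probability(births, AgeSegment(6, 12))


class TestEstimateIMR:
    def test_all_alive_zero(self):
        res = estimate_imr(make_births(50, age_months=30))
        assert res.rate_per_1000 == 0.0

    def test_single_segment_product(self):
        births = make_births(10, age_months=24, death_ages={i: 0 for i in range(5)})
        res = estimate_imr(births)
        assert res.segment_probs[0] == pytest.approx(0.5)
        assert res.rate_per_1000 == pytest.approx(500.0)

    def test_death_at_twelve_months_counts_as_survived(self):
        births = make_births(10, age_months=30, death_ages={0: 12})
        assert estimate_imr(births).rate_per_1000 == 0.0
        assert cohort_imr_oracle(births) == 0.0

    def test_window_excludes_old_births(self):
        young = make_births(10, age_months=24, death_ages={0: 3})
        old = make_births(10, age_months=80, death_ages={0: 3})
        old["child_id"] += 100
        both = pd.concat([young, old], ignore_index=True)
        assert estimate_imr(both).rate_per_1000 == estimate_imr(young).rate_per_1000

    def test_weight_invariance(self):
        births = make_births(
            30, age_months=30, death_ages={0: 0, 1: 4}, weights=np.linspace(0.5, 2, 30)
        )
        r1 = estimate_imr(births).rate_per_1000
        births2 = births.assign(weight=births["weight"] * 37.5)
        assert estimate_imr(births2).rate_per_1000 == pytest.approx(r1, rel=1e-12)

    def test_adding_a_death_never_decreases(self):
        births = make_births(40, age_months=30, death_ages={0: 1})
        base = estimate_imr(births).rate_per_1000
        more = make_births(40, age_months=30, death_ages={0: 1, 1: 7})
        assert estimate_imr(more).rate_per_1000 >= base

    def test_bounds(self):
        births = make_births(8, age_months=30, death_ages={i: i for i in range(8)})
        assert 0 <= estimate_imr(births).rate_per_1000 <= 1000


class TestCohortOracle:
    def test_hand_count(self):
        births = make_births(100, age_months=20, death_ages={i: 2 for i in range(5)})
        assert cohort_imr_oracle(births) == pytest.approx(50.0)

    def test_requires_full_exposure(self):
        with pytest.raises(UndefinedEstimateError):
            cohort_imr_oracle(make_births(10, age_months=6))

    def test_agreement_with_component_method(self):
        """Under the generator's stationary hazards both estimators target
        the same q(1); at n=200,000 they agree within 3 combined SEs."""
        cfg = SyntheticConfig(n_births=200_000, target_q1=0.0467, seed=29)
        births = generate_births(cfg)
        est = estimate_imr(births).rate_per_1000
        oracle = cohort_imr_oracle(births)
        n_full = ((births["interview_cmc"] - births["dob_cmc"]) >= 12).sum()
        se = 1000 * np.sqrt(0.0467 * (1 - 0.0467) / n_full)
        assert est == pytest.approx(oracle, abs=3 * np.sqrt(2) * se)
        assert est == pytest.approx(46.7, abs=3 * se)


class TestBootstrapCI:
    def test_reproducible_and_covers_estimate(self):
        cfg = SyntheticConfig(n_births=20_000, n_clusters=100, target_q1=0.0467, seed=5)
        births = generate_births(cfg)
        model = SyntheticCohortIMR(births)
        r1 = model.fit(ci="bootstrap", n_boot=200, seed=7)
        r2 = model.fit(ci="bootstrap", n_boot=200, seed=7)
        assert r1.conf_int() == r2.conf_int()
        lo, hi = r1.conf_int()
        assert lo <= r1.rate_per_1000 <= hi
        assert r1.estimate.se > 0

    def test_missing_columns_rejected(self):
        births = make_births(10, age_months=20).drop(columns=["weight"])
        with pytest.raises(ValueError, match="weight"):
            SyntheticCohortIMR(births)


class TestDHSConverter:
    def test_variable_mapping(self):
        br = pd.DataFrame(
            {
                "b3": [1300, 1350],
                "b4": [1, 2],
                "b5": [1, 0],
                "b7": [np.nan, 3],
                "v001": [10, 11],
                "v005": [1_500_000, 800_000],
                "v008": [1367, 1367],
                "v025": [2, 1],
                "v106": [0, 2],
                "v190": [1, 5],
            }
        )
        out = from_dhs_br(br)
        assert list(out["sex"]) == ["male", "female"]
        assert list(out["alive"]) == [True, False]
        assert out["weight"].tolist() == [1.5, 0.8]
        assert list(out["residence"]) == ["rural", "urban"]
        assert list(out["education"]) == ["none", "secondary+"]
        assert out["age_at_death_months"].tolist() == [pd.NA, 3]

    def test_missing_variable_named(self):
        with pytest.raises(ValueError, match="v005"):
            from_dhs_br(pd.DataFrame({"b3": [1]}))
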