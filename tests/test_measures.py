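"""Inequality summary measures: published values, null coherence,
algebraic identities, CI closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from equimort import (
    InequalityAnalysis,
    aci,
    difference,
    measure_ci,
    paf,
    par,
    ratio,
    run_all,
)
from equimort.errors import UndefinedMeasureError, UnsupportedMeasureError
from equimort.measures import midpoint_ranks

from conftest import make_table

Z = stats.norm.ppf(0.975)


class TestPublishedValues:
    """Point estimates recomputed from the published disaggregated table."""

    def test_difference_education(self, yemen_tables):
        d = difference(yemen_tables["education"])
        assert d.estimate == pytest.approx(49.74 - 34.15, abs=1e-12)
        assert d.comparison_subgroup == "none"
        assert d.reference_subgroup == "secondary+"

    def test_difference_wealth(self, yemen_tables):
        assert difference(yemen_tables["wealth_quintile"]).estimate == pytest.approx(
            20.20, abs=1e-9
        )

    def test_ratio_wealth(self, yemen_tables):
        assert ratio(yemen_tables["wealth_quintile"]).estimate == pytest.approx(
            53.23 / 33.03
        )

    def test_ratio_residence(self, yemen_tables):
        assert ratio(yemen_tables["residence"]).estimate == pytest.approx(
            50.79 / 35.71
        )

    def test_paf_sex_reference_is_female(self, yemen_tables):
        r = paf(yemen_tables["sex"])
        assert r.reference_subgroup == "female"
        assert r.estimate == pytest.approx(100 * (45.02 - 46.73) / 46.73)

    def test_paf_wealth_reference_is_richest(self, yemen_tables):
        r = paf(yemen_tables["wealth_quintile"])
        assert r.reference_subgroup == "5"
        assert r.estimate == pytest.approx(100 * (33.03 - 46.73) / 46.73)

    def test_aci_wealth(self, yemen_tables):
        assert aci(yemen_tables["wealth_quintile"]).estimate == pytest.approx(
            -4.69, abs=0.01
        )

    def test_par_paf_share_sign(self, yemen_tables):
        t = yemen_tables["wealth_quintile"]
        assert np.sign(par(t).estimate) == np.sign(paf(t).estimate) == -1


class TestNullCoherence:
    def test_equal_subgroups_give_null_values(self):
        t = make_table([40.0] * 4, [100, 250, 25, 625], mu=40.0)
        assert difference(t).estimate == 0.0
        assert ratio(t).estimate == 1.0
        assert par(t).estimate == 0.0
        assert paf(t).estimate == 0.0
        assert aci(t).estimate == 0.0

    def test_paf_zero_when_reference_equals_mu(self):
        t = make_table([50.0, 46.0], [100, 100], mu=46.0, kind="binary")
        assert paf(t).estimate == 0.0


class TestMeasureDomains:
    def test_pairwise_measures_reject_unordered(self, yemen_tables):
        for fn in (difference, ratio):
            with pytest.raises(UnsupportedMeasureError):
                fn(yemen_tables["region"])

    def test_aci_rejects_binary(self, yemen_tables):
        with pytest.raises(UnsupportedMeasureError):
            aci(yemen_tables["residence"])

    def test_na_extreme_subgroup_undefined(self):
        t = make_table([None, 40.0, 30.0], [100, 100, 100], mu=35.0)
        with pytest.raises(UndefinedMeasureError):
            difference(t)
        with pytest.raises(UndefinedMeasureError):
            aci(t)
        # PAF still defined: reference is the lowest non-NA estimate
        assert paf(t).reference_subgroup == "s2"

    def test_zero_denominator_ratio(self):
        t = make_table([10.0, 0.0], [100, 100], mu=5.0, kind="binary")
        with pytest.raises(UndefinedMeasureError):
            ratio(t)

    def test_all_na_paf_undefined(self):
        t = make_table([None, None], [100, 100], mu=40.0, kind="binary")
        with pytest.raises(UndefinedMeasureError):
            paf(t)

    def test_paf_reference_is_lowest_even_if_not_most_advantaged(self):
        # middle subgroup has the lowest estimate; the rule follows the
        # estimates, not the nominal ordering
        t = make_table([50.0, 20.0, 30.0], [100, 100, 100], mu=33.0)
        assert paf(t).reference_subgroup == "s1"


class TestAlgebraicProperties:
    @given(
        est=st.lists(st.floats(0.1, 200), min_size=2, max_size=8),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_aci_equals_twice_weighted_covariance(self, est, seed):
        rng = np.random.default_rng(seed)
        pops = rng.integers(1, 100_000, len(est)).tolist()
        t = make_table(est, pops, mu=float(np.mean(est)))
        p, x = midpoint_ranks(pops)
        cov = float((p * np.array(est) * x).sum() - (p * np.array(est)).sum() * (p * x).sum())
        assert aci(t).estimate == pytest.approx(2 * cov, abs=1e-9)
        assert (p * x).sum() == pytest.approx(0.5, abs=1e-12)

    @given(
        est=st.lists(st.floats(0.1, 200), min_size=2, max_size=8),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_aci_antisymmetry_exact(self, est, seed):
        rng = np.random.default_rng(seed)
        pops = rng.integers(1, 100_000, len(est)).tolist()
        fwd = aci(make_table(est, pops, mu=50.0)).estimate
        rev = aci(make_table(est[::-1], pops[::-1], mu=50.0)).estimate
        assert rev == -fwd

    def test_scale_equivariance(self, yemen_tables):
        t = yemen_tables["wealth_quintile"]
        k = 3.7
        scaled = make_table(
            [r.estimate_per_1000 * k for r in t.ordered_rows()],
            [r.population for r in t.ordered_rows()],
            mu=t.national_average * k,
        )
        assert aci(scaled).estimate == pytest.approx(k * aci(t).estimate, rel=1e-9)
        assert difference(scaled).estimate == pytest.approx(
            k * difference(t).estimate, rel=1e-9
        )
        assert par(scaled).estimate == pytest.approx(k * par(t).estimate, rel=1e-9)
        assert ratio(scaled).estimate == pytest.approx(ratio(t).estimate, rel=1e-9)
        assert paf(scaled).estimate == pytest.approx(paf(t).estimate, rel=1e-9)

    def test_paf_bound_for_adverse_indicator(self, yemen_tables):
        for dim in ("wealth_quintile", "education", "residence", "sex"):
            value = paf(yemen_tables[dim]).estimate
            assert -100 < value <= 0


class TestConfidenceIntervals:
    def test_zero_se_degenerate(self):
        t = make_table(
            [10.0, 5.0], [100, 100], mu=7.5, kind="binary",
            cis=[(10.0, 10.0), (5.0, 5.0)],
        )
        lo, hi = measure_ci(t, "D")
        assert lo == hi == 5.0

    def test_difference_wald_closed_form(self):
        cis = [(10 - Z, 10 + Z), (5 - Z, 5 + Z)]  # SE = 1 each
        t = make_table([10.0, 5.0], [100, 100], mu=7.5, kind="binary", cis=cis)
        lo, hi = measure_ci(t, "D")
        assert lo == pytest.approx(5 - Z * np.sqrt(2))
        assert hi == pytest.approx(5 + Z * np.sqrt(2))

    def test_ratio_log_delta_positive(self, yemen_tables):
        lo, hi = measure_ci(yemen_tables["residence"], "R")
        r = ratio(yemen_tables["residence"]).estimate
        assert 0 < lo < r < hi

    def test_aci_parametric_sign_and_coverage(self, yemen_tables):
        lo, hi = measure_ci(yemen_tables["wealth_quintile"], "ACI", seed=12)
        assert lo < -4.68 < hi
        assert hi < 0  # concentration among the poor is significant

    def test_parametric_ci_reproducible(self, yemen_tables):
        a = measure_ci(yemen_tables["wealth_quintile"], "PAF", seed=3)
        b = measure_ci(yemen_tables["wealth_quintile"], "PAF", seed=3)
        assert a == b

    def test_no_ci_source_errors(self):
        t = make_table([10.0, 5.0], [100, 100], mu=7.5, kind="binary")
        with pytest.raises(UndefinedMeasureError):
            measure_ci(t, "D")


class TestRunAll:
    def test_table2_layout(self, yemen_tables):
        results, notes = run_all(yemen_tables, ci=None)
        cells = {(r.dimension, r.measure) for r in results}
        assert len(results) == 14
        assert ("wealth_quintile", "ACI") in cells
        assert ("education", "ACI") in cells
        assert ("residence", "ACI") not in cells
        assert ("sex", "ACI") not in cells
        assert not any(r.dimension == "region" for r in results)
        assert any("region" in n for n in notes)

    def test_all_equal_table_all_nulls(self):
        t = make_table([25.0] * 5, [10, 20, 30, 40, 50], mu=25.0)
        results, _ = run_all({"dim": t}, ci=None)
        by_measure = {r.measure: r.estimate for r in results}
        assert by_measure["D"] == 0.0
        assert by_measure["R"] == 1.0
        assert by_measure["PAF"] == 0.0
        assert by_measure["ACI"] == 0.0

    def test_model_results_interface(self, yemen_tables):
        res = InequalityAnalysis(yemen_tables).fit(ci=None)
        assert res[("wealth_quintile", "R")].estimate == pytest.approx(53.23 / 33.03)
        frame = res.to_frame()
        assert set(frame["measure"]) == {"ACI", "D", "PAF", "R"}
        text = res.summary()
        assert "wealth_quintile" in text and "ACI" in text
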