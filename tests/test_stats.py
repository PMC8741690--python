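"""Exact 2x2 inference, proportion intervals and rank tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from monodiab.stats import (
    BUILTIN_CRITERIA,
    ContingencyTable2x2,
    clopper_pearson,
    evaluate_criterion,
    fisher_exact,
    format_p,
    format_percent,
    ks_two_sample,
    mann_whitney,
    odds_ratio_exact,
    two_sample_proportion,
)
from monodiab.classify import MonogenicDiagnosis
from monodiab.triage import ChildRecord

from .oracles import (
    conditional_mle_oracle,
    exact_ci_oracle,
    fisher_oracle,
    ks_oracle,
    mann_whitney_oracle,
)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x, n, lo_pct, hi_pct",
        [
            (34, 1093, 2.2, 4.3),  # Turkish cohort minimum prevalence
            (20, 808, 1.5, 3.8),   # UK systematic study prevalence
        ],
    )
    def test_published_cohort_intervals_at_one_decimal(self, x, n, lo_pct, hi_pct):
        lo, hi = clopper_pearson(x, n, 0.95)
        assert round(100 * lo, 1) == lo_pct
        assert round(100 * hi, 1) == hi_pct

    def test_zero_successes_closed_form(self):
        lo, hi = clopper_pearson(0, 50, 0.95)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 50), rel=1e-10)

    def test_all_successes_upper_limit_is_one(self):
        lo, hi = clopper_pearson(50, 50, 0.95)
        assert hi == 1.0

    @pytest.mark.parametrize("x, n, conf", [(-1, 10, 0.95), (11, 10, 0.95), (5, 10, 1.0)])
    def test_domain_violations(self, x, n, conf):
        with pytest.raises(ValueError):
            clopper_pearson(x, n, conf)


class TestFisherExact:
    def test_symmetric_table_is_null(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_two_by_two_diagonal_enumeration(self):
        # support a in {0,1,2} with probabilities 1/6, 4/6, 1/6
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_recessive_fraction_contrast_vs_exact_oracle(self):
        # 14/34 vs 0/20 recessive causes
        p = fisher_exact([[14, 20], [0, 20]])
        assert p == pytest.approx(fisher_oracle(14, 20, 0, 20), abs=1e-12)
        assert 5e-4 < p < 1e-3

    def test_zero_margin_is_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    @given(
        st.tuples(
            st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
        ).filter(lambda t: sum(t) > 0 and min(t[0] + t[1], t[2] + t[3]) > 0
                 and min(t[0] + t[2], t[1] + t[3]) > 0)
    )
    def test_agrees_with_scipy_and_oracle_on_random_tables(self, cells):
        a, b, c, d = cells
        p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)
        assert p == pytest.approx(sps.fisher_exact([[a, b], [c, d]])[1], abs=1e-9)


class TestOddsRatioExact:
    def test_null_table(self):
        res = odds_ratio_exact([[10, 10], [10, 10]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_sample_odds_ratio_is_cross_product(self):
        res = odds_ratio_exact([[20, 10], [5, 40]])
        assert res.sample_odds_ratio == pytest.approx(16.0)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_conditional_mle_matches_oracle(self):
        res = odds_ratio_exact([[20, 10], [5, 40]])
        assert res.odds_ratio == pytest.approx(conditional_mle_oracle(20, 10, 5, 40), rel=1e-6)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="row or column"):
            odds_ratio_exact([[0, 5], [0, 7]])

    def test_single_zero_cell_gives_one_sided_interval(self):
        res = odds_ratio_exact([[0, 10], [5, 20]])
        assert res.odds_ratio == 0.0
        assert res.ci_low == 0.0
        assert res.ci_high < math.inf

    def test_ci_monotone_in_confidence_level(self):
        t = [[12, 5], [3, 14]]
        lo90, hi90 = odds_ratio_exact(t, 0.90).ci_low, odds_ratio_exact(t, 0.90).ci_high
        lo99, hi99 = odds_ratio_exact(t, 0.99).ci_low, odds_ratio_exact(t, 0.99).ci_high
        assert lo99 < lo90 and hi90 < hi99

    def test_ci_matches_grid_inversion_oracle_small_tables(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(0, 16, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            if 0 in t.row_margins or 0 in t.col_margins:
                continue
            res = odds_ratio_exact(t)
            lo, hi = exact_ci_oracle(int(a), int(b), int(c), int(d))
            assert res.ci_low == pytest.approx(lo, rel=1e-4, abs=1e-8)
            if math.isinf(hi):
                assert math.isinf(res.ci_high)
            else:
                assert res.ci_high == pytest.approx(hi, rel=1e-4)


class TestTwoSampleProportion:
    def test_identical_proportions(self):
        z, p = two_sample_proportion(10, 100, 10, 100)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_published_prevalence_comparison(self):
        # 34/1093 vs 20/808: pooled z-test lands near the printed p = 0.40
        _, p = two_sample_proportion(34, 1093, 20, 808)
        assert 0.40 < p < 0.42

    @given(
        st.integers(0, 30), st.integers(30, 60), st.integers(0, 30), st.integers(30, 60)
    )
    def test_swapping_samples_negates_z(self, x1, n1, x2, n2):
        pooled = (x1 + x2) / (n1 + n2)
        if pooled in (0.0, 1.0):
            return
        z1, p1 = two_sample_proportion(x1, n1, x2, n2)
        z2, p2 = two_sample_proportion(x2, n2, x1, n1)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_pooled_proportion_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            z, p = two_sample_proportion(0, 10, 0, 20)
        assert p == 1.0


class TestRankTests:
    def test_mann_whitney_identical_samples(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_mann_whitney_fully_separated(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6, 3)

    def test_ks_identical_and_disjoint(self):
        d, _ = ks_two_sample([1.0, 2.0], [1.0, 2.0])
        assert d == pytest.approx(0.0)
        d, _ = ks_two_sample([1.0, 2.0], [3.0, 4.0])
        assert d == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(2, 6))
    def test_exact_branches_match_enumeration_oracles(self, seed, nx, ny):
        r = np.random.default_rng(seed)
        # half the draws from a small integer lattice to force ties
        if seed % 2:
            x, y = r.integers(0, 4, nx).astype(float), r.integers(0, 4, ny).astype(float)
        else:
            x, y = r.normal(size=nx), r.normal(size=ny)
        if np.unique(np.concatenate([x, y])).size == 1:
            return
        _, p_mw = mann_whitney(x, y)
        _, p_mw_oracle = mann_whitney_oracle(x, y)
        assert p_mw == pytest.approx(p_mw_oracle, abs=1e-10)
        d, p_ks = ks_two_sample(x, y)
        d_oracle, p_ks_oracle = ks_oracle(x, y)
        assert d == pytest.approx(d_oracle, abs=1e-10)
        assert p_ks == pytest.approx(p_ks_oracle, abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [])


def _child(child_id, **kwargs):
    defaults = dict(
        age_at_diagnosis=10.0,
        antibody_status="negative",
        insulin_treated=True,
        clinically_diagnosed_t1d=True,
        parent_with_diabetes=False,
        hba1c=80.0,
        mody_probability=0.01,
        parental_consanguinity=False,
    )
    defaults.update(kwargs)
    return ChildRecord(child_id=child_id, **defaults)


class TestEvaluateCriterion:
    def _cohort_with_table(self, a, b, c, d, criterion="parent_with_diabetes"):
        """Cohort + diagnoses realising the 2x2 (a,b;c,d) for the criterion."""
        cohort, diagnoses, i = [], [], 0
        for count, is_case, present in ((a, True, True), (b, False, True),
                                        (c, True, False), (d, False, False)):
            for _ in range(count):
                i += 1
                cid = f"c{i}"
                cohort.append(_child(cid, parent_with_diabetes=present))
                if is_case:
                    diagnoses.append(MonogenicDiagnosis(cid, "WFS1", "autosomal_recessive"))
        return cohort, diagnoses

    def test_balanced_table_gives_null_odds_ratio(self):
        cohort, dx = self._cohort_with_table(10, 10, 10, 10)
        res = evaluate_criterion(cohort, dx, "parent_with_diabetes", "autosomal_recessive")
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (10, 10, 10, 10)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_perfect_separation_gives_infinite_or_one_sided_ci(self):
        cohort, dx = self._cohort_with_table(8, 0, 0, 25)
        res = evaluate_criterion(cohort, dx, "parent_with_diabetes", "autosomal_recessive")
        assert math.isinf(res.odds_ratio)
        assert math.isinf(res.ci_high)
        assert res.ci_low > 0

    def test_missing_values_excluded_pairwise(self):
        cohort, dx = self._cohort_with_table(5, 5, 5, 5)
        # align the HbA1c criterion with the parent-with-diabetes pattern,
        # then blank four children: they drop out of the table, counted
        for rec in cohort:
            rec.hba1c = 50.0 if rec.parent_with_diabetes else 80.0
        for rec in cohort[:4]:
            rec.hba1c = None
        res = evaluate_criterion(cohort, dx, "hba1c_le_58", "autosomal_recessive")
        assert res.n_excluded_missing == 4
        assert res.table.total == 16

    def test_unknown_criterion_lists_available(self):
        with pytest.raises(KeyError, match="non_insulin_treatment"):
            evaluate_criterion([], [], "nonexistent", "autosomal_dominant")

    def test_builtin_criteria_thresholds(self):
        rec = _child("x", hba1c=58.0, mody_probability=0.10)
        assert BUILTIN_CRITERIA["hba1c_le_58"](rec) is True  # boundary inclusive
        assert BUILTIN_CRITERIA["mody_probability_ge_10"](rec) is True
        rec2 = _child("y", hba1c=58.1, mody_probability=0.0999)
        assert BUILTIN_CRITERIA["hba1c_le_58"](rec2) is False
        assert BUILTIN_CRITERIA["mody_probability_ge_10"](rec2) is False


class TestReportFormatting:
    def test_percent_one_decimal(self):
        assert format_percent(0.0311) == "3.1%"

    @pytest.mark.parametrize("p, text", [(0.41, "0.41"), (0.0031, "0.003"), (7.6e-4, "8e-4")])
    def test_p_value_styles(self, p, text):
        assert format_p(p) == text
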