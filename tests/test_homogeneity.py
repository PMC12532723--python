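"""Homogeneity assessment: ANOVA identity, estimators, Bonferroni, max rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crmcert import (
    HomogeneityModel,
    HomogeneitySimSpec,
    StatisticalError,
    ValidationError,
    adjust_bonferroni,
    anova_oneway,
    assess_homogeneity,
    sbb,
    sbb_min,
    simulate_homogeneity,
)
from oracles import anova_twopass


def _table(groups, analyte="X"):
    rows = []
    for b, values in enumerate(groups, start=1):
        for r, v in enumerate(values, start=1):
            rows.append((analyte, b, r, v))
    return pd.DataFrame(rows, columns=["analyte", "bottle", "replicate", "value"])


class TestAnova:
    def test_hand_example(self, hand_homogeneity_table):
        d = anova_oneway(hand_homogeneity_table, "X")
        assert d.M_between == pytest.approx(1.0)
        assert d.M_within == pytest.approx(2.0)
        assert (d.df_between, d.df_within) == (1, 2)

    def test_zero_within_variance_is_an_error(self):
        with pytest.raises(StatisticalError, match="within-bottle"):
            anova_oneway(_table([[1.0, 1.0], [2.0, 2.0]]), "X")

    def test_single_bottle_is_an_error(self):
        with pytest.raises(StatisticalError, match="bottles"):
            anova_oneway(_table([[1.0, 2.0, 3.0]]), "X")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(-50, 50), min_size=2, max_size=4),
            min_size=2,
            max_size=6,
        )
    )
    def test_sum_of_squares_identity_and_oracle_agreement(self, groups):
        table = _table(groups)
        values = table["value"].to_numpy()
        ss_total = float(((values - values.mean()) ** 2).sum())
        try:
            d = anova_oneway(table, "X")
        except StatisticalError:
            return  # degenerate zero-within-variance draw
        scale = max(ss_total, 1.0)
        assert d.ss_between + d.ss_within == pytest.approx(ss_total, abs=1e-9 * scale)
        oracle = anova_twopass(groups)
        assert d.M_between == pytest.approx(oracle["M_between"], rel=1e-10, abs=1e-12)
        assert d.M_within == pytest.approx(oracle["M_within"], rel=1e-10, abs=1e-12)

    def test_unbalanced_effective_replicates_reduces_to_n_when_balanced(self):
        balanced = anova_oneway(_table([[1, 2, 3], [2, 3, 4]]), "X")
        assert balanced.n_eff == pytest.approx(3.0)
        unbalanced = anova_oneway(_table([[1, 2], [2, 3, 4], [0, 1, 2, 3]]), "X")
        assert 2.0 < unbalanced.n_eff < 4.0


class TestEstimators:
    @pytest.mark.parametrize(
        "M_b,M_w,n,mean,expected",
        [
            (0.0430, 0.0302, 3, 3.67, 0.0178),   # between-bottle SD visible
            (2.0364, 1.1036, 3, 12.7, 0.0439),
        ],
    )
    def test_sbb_relative_worked_examples(self, M_b, M_w, n, mean, expected):
        assert round(sbb(M_b, M_w, n) / mean, 4) == expected

    def test_sbb_boundary_and_not_applicable(self):
        assert sbb(2.0, 2.0, 3) == 0.0
        assert sbb(1.0, 2.0, 2) is None  # from the hand ANOVA example

    def test_sbb_requires_two_replicates(self):
        with pytest.raises(StatisticalError):
            sbb(2.0, 1.0, 1)

    @pytest.mark.parametrize(
        "M_w,n,N,mean,expected",
        [
            (4.7555, 3, 14, 71.2, 0.0091),
            (6.4807, 3, 14, 40.8, 0.0186),
        ],
    )
    def test_sbb_min_relative_worked_examples(self, M_w, n, N, mean, expected):
        assert round(sbb_min(M_w, n, N) / mean, 4) == expected

    def test_sbb_min_closed_form_unit_case(self):
        # sqrt(2/2) * (2/(2*1))^(1/4) = 1 exactly
        assert sbb_min(2.0, 2, 2) == pytest.approx(1.0)

    def test_sbb_min_preconditions(self):
        with pytest.raises(StatisticalError):
            sbb_min(1.0, 1, 14)
        with pytest.raises(StatisticalError):
            sbb_min(1.0, 3, 1)
        with pytest.raises(ValidationError):
            sbb_min(0.0, 3, 14)


class TestBonferroni:
    def test_cap_multiplier_and_zero(self):
        assert adjust_bonferroni([0.06], m=18)[0] == 1.0
        assert adjust_bonferroni([0.0], m=5)[0] == 0.0
        assert adjust_bonferroni([0.0139], m=24)[0] == pytest.approx(0.3336)

    def test_order_preserving_and_default_m(self):
        p = [0.01, 0.2, 0.005]
        adj = adjust_bonferroni(p)
        assert list(np.argsort(adj)) == list(np.argsort(p))
        assert adj[0] == pytest.approx(0.03)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            adjust_bonferroni([1.2])


class TestAssessment:
    def test_max_rule_when_model_inapplicable(self):
        # bottles barely differ: M_between < M_within -> u_bb_r = s_bb_min_r
        spec = HomogeneitySimSpec("X", 10.0, 0.0, 0.3, N=14, n=3, seed=12)
        table = simulate_homogeneity(spec)
        (res,) = assess_homogeneity(table)
        if not res.model_A_applicable:
            assert res.s_bb_r == 0.0
            assert res.u_bb_r == res.s_bb_min_r
        assert res.u_bb_r >= res.s_bb_min_r

    def test_single_analyte_adjusted_p_equals_p(self):
        spec = HomogeneitySimSpec("X", 10.0, 0.1, 0.3, N=5, n=3, seed=1)
        (res,) = assess_homogeneity(simulate_homogeneity(spec), m=1)
        assert res.P_adj == pytest.approx(res.P)

    def test_u_bb_r_is_scale_free(self):
        spec = HomogeneitySimSpec("X", 10.0, 0.2, 0.3, N=8, n=3, seed=3)
        table = simulate_homogeneity(spec)
        scaled = table.copy()
        scaled["value"] *= 37.5
        (a,) = assess_homogeneity(table)
        (b,) = assess_homogeneity(scaled)
        assert a.u_bb_r == pytest.approx(b.u_bb_r, rel=1e-12)
        assert a.s_bb_min_r == pytest.approx(b.s_bb_min_r, rel=1e-12)

    def test_study_mean_is_mean_of_bottle_means(self):
        table = _table([[1.0, 2.0], [2.0, 3.0, 4.0, 5.0]])
        (res,) = assess_homogeneity(table)
        assert res.mean == pytest.approx((1.5 + 3.5) / 2)

    def test_parameter_recovery_median_sbb_r(self):
        # N=14, n=3, sigma_bb/mu = 0.02, sigma_wb/mu = 0.03
        estimates = []
        for seed in range(500):
            spec = HomogeneitySimSpec("X", 100.0, 2.0, 3.0, N=14, n=3, seed=seed)
            (res,) = assess_homogeneity(simulate_homogeneity(spec))
            estimates.append(res.s_bb_r)
        med = float(np.median(estimates))
        assert abs(med - 0.02) <= 0.25 * 0.02

    def test_null_false_positive_rate(self):
        # true sigma_bb = 0: unadjusted ANOVA rejects at ~alpha
        rejections = 0
        runs = 1000
        for seed in range(runs):
            spec = HomogeneitySimSpec("X", 10.0, 0.0, 0.3, N=14, n=3, seed=seed)
            d = anova_oneway(simulate_homogeneity(spec), "X")
            rejections += d.P < 0.05
        assert abs(rejections / runs - 0.05) <= 0.02


class TestModelSurface:
    def test_fit_returns_frame_and_summary(self, pfhxa_like_spec):
        table = simulate_homogeneity(pfhxa_like_spec)
        res = HomogeneityModel(table).fit()
        df = res.to_frame()
        assert set(df.columns) >= {"analyte", "mean", "n", "N", "M_between", "M_within",
                                   "P", "P_adj", "s_bb_r", "s_bb_min_r", "u_bb_r"}
        assert "Homogeneity" in res.summary()
        assert len(res.bottle_means("PFHxA")) == 14

    def test_simulated_pfhxa_like_m_within_matches_design(self):
        # average within-bottle mean square ~ sigma_wb^2 = 0.893 ug^2/kg^2
        vals = []
        for seed in range(300):
            spec = HomogeneitySimSpec("PFHxA", 35.0, 0.425, 0.945, N=14, n=3, seed=seed)
            vals.append(anova_oneway(simulate_homogeneity(spec), "PFHxA").M_within)
        assert np.mean(vals) == pytest.approx(0.8936, rel=0.05)
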