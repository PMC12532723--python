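"""Synthetic-study generators: determinism, structure, variance recovery."""

import numpy as np
import pandas as pd
import pytest

from crmcert import (
    CharacterisationSimSpec,
    HomogeneitySimSpec,
    StabilitySimSpec,
    ValidationError,
    anova_oneway,
    simulate_batch,
    simulate_characterisation,
    simulate_homogeneity,
    simulate_stability,
)
from oracles import anova_twopass


class TestHomogeneitySim:
    def test_zero_variance_gives_constant_table(self):
        spec = HomogeneitySimSpec("X", mu=10.0, sigma_bb=0.0, sigma_wb=0.0, N=3, n=2, seed=1)
        table = simulate_homogeneity(spec)
        assert len(table) == 6
        assert (table["value"] == 10.0).all()

    def test_fixed_seed_is_bit_reproducible_distinct_seeds_differ(self, pfhxa_like_spec):
        a = simulate_homogeneity(pfhxa_like_spec)
        b = simulate_homogeneity(pfhxa_like_spec)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_homogeneity(
            HomogeneitySimSpec("PFHxA", 35.0, 0.425, 0.945, N=14, n=3, seed=8)
        )
        assert not np.allclose(a["value"], c["value"])

    def test_shape_and_filling_order(self, pfhxa_like_spec):
        table = simulate_homogeneity(pfhxa_like_spec)
        assert len(table) == 42
        assert list(table["bottle"].unique()) == list(range(1, 15))

    def test_mean_within_variance_recovers_sigma_wb_squared(self, pfhxa_like_spec):
        # Monte-Carlo: mean M_within -> sigma_wb^2, mean (M_b - M_w)/n -> sigma_bb^2
        m_w, m_b = [], []
        for seed in range(500):
            spec = HomogeneitySimSpec("PFHxA", 35.0, 0.425, 0.945, N=14, n=3, seed=seed)
            d = anova_oneway(simulate_homogeneity(spec), "PFHxA")
            m_w.append(d.M_within)
            m_b.append((d.M_between - d.M_within) / 3.0)
        assert np.mean(m_w) == pytest.approx(0.945**2, rel=0.05)  # ~0.893
        assert np.mean(m_b) == pytest.approx(0.425**2, rel=0.05)

    def test_null_batch_frequency_of_inapplicable_model(self):
        # with sigma_bb = 0, P(M_between < M_within) = P(F_{13,28} < 1) ~ 0.52
        hits = 0
        runs = 600
        for seed in range(runs):
            spec = HomogeneitySimSpec("X", 10.0, 0.0, 0.3, N=14, n=3, seed=seed)
            d = anova_oneway(simulate_homogeneity(spec), "X")
            hits += d.M_between < d.M_within
        assert 0.5 <= hits / runs <= 0.75

    @pytest.mark.parametrize(
        "kwargs,fragment",
        [
            (dict(mu=-1.0, sigma_bb=0.1, sigma_wb=0.1), "mu"),
            (dict(mu=1.0, sigma_bb=-0.1, sigma_wb=0.1), "sigma_bb"),
            (dict(mu=1.0, sigma_bb=0.1, sigma_wb=0.1, N=1), "N"),
            (dict(mu=1.0, sigma_bb=0.1, sigma_wb=0.1, n=1), "n"),
        ],
    )
    def test_invalid_spec_names_the_invariant(self, kwargs, fragment):
        with pytest.raises(ValidationError, match=fragment):
            HomogeneitySimSpec("X", **kwargs)


class TestStabilitySim:
    def test_zero_slope_near_zero_noise_is_flat(self):
        spec = StabilitySimSpec("X", y0=10.0, slopes={-20.0: 0.0}, times=(0, 6, 12),
                                units_per_point=1, sigma_meas=1e-12, seed=1)
        table = simulate_stability(spec)
        assert np.allclose(table["value"], 10.0)

    def test_ols_recovers_true_slope(self):
        spec = StabilitySimSpec("X", y0=10.0, slopes={60.0: -0.2},
                                times=(0, 2, 4, 6, 12), units_per_point=3,
                                sigma_meas=0.1, seed=3)
        table = simulate_stability(spec)
        from oracles import ols_normal_equations

        fit = ols_normal_equations(table["time_months"].tolist(), table["value"].tolist())
        assert abs(fit["b1"] - (-0.2)) <= 3 * fit["se_b1"]

    def test_grid_is_balanced(self):
        spec = StabilitySimSpec("X", 10.0, {-20.0: 0.0, 60.0: -0.1},
                                times=(0, 6, 12), units_per_point=2, sigma_meas=0.1, seed=4)
        table = simulate_stability(spec)
        counts = table.groupby(["temperature_C", "time_months"]).size()
        assert (counts == 2).all() and len(counts) == 6

    def test_empty_times_rejected(self):
        with pytest.raises(ValidationError, match="times"):
            StabilitySimSpec("X", 10.0, {-20.0: 0.0}, times=(), sigma_meas=0.1)

    def test_times_must_include_zero_and_increase(self):
        with pytest.raises(ValidationError, match="include 0"):
            StabilitySimSpec("X", 10.0, {-20.0: 0.0}, times=(1, 2), sigma_meas=0.1)
        with pytest.raises(ValidationError, match="increasing"):
            StabilitySimSpec("X", 10.0, {-20.0: 0.0}, times=(0, 2, 2), sigma_meas=0.1)


class TestCharacterisationSim:
    def test_layout_and_grand_mean(self):
        spec = CharacterisationSimSpec("X", mu=41.0, sigma_lab=0.56, sigma_unit=0.5,
                                       sigma_rep=1.0, W=3, U_n=10, R=3, seed=11)
        table = simulate_characterisation(spec)
        assert len(table) == 90
        assert table.groupby("workplace").size().tolist() == [30, 30, 30]
        total_sd = np.sqrt(0.56**2 + 0.5**2 + 1.0**2)
        assert abs(table["value"].mean() - 41.0) <= 3 * total_sd / np.sqrt(90) + 3 * 0.56 / np.sqrt(3)

    def test_all_zero_sds_give_mu_everywhere(self):
        spec = CharacterisationSimSpec("X", mu=7.0, sigma_lab=0.0, sigma_unit=0.0,
                                       sigma_rep=0.0, seed=2)
        assert (simulate_characterisation(spec)["value"] == 7.0).all()

    def test_single_workplace_rejected(self):
        with pytest.raises(ValidationError, match="W >= 2"):
            CharacterisationSimSpec("X", 1.0, 0.1, 0.1, 0.1, W=1)


def test_batch_output_is_order_independent():
    specs = [
        HomogeneitySimSpec("A", 10.0, 0.1, 0.2, N=4, n=2, seed=5),
        HomogeneitySimSpec("B", 20.0, 0.1, 0.2, N=4, n=2, seed=5),
    ]
    forward = simulate_batch(specs, "homogeneity")
    backward = simulate_batch(list(reversed(specs)), "homogeneity")
    key = ["analyte", "bottle", "replicate"]
    pd.testing.assert_frame_equal(
        forward.sort_values(key).reset_index(drop=True),
        backward.sort_values(key).reset_index(drop=True),
    )


def test_strict_positive_redraws_negative_values():
    spec = HomogeneitySimSpec("X", mu=0.5, sigma_bb=0.0, sigma_wb=0.4, N=10, n=3, seed=0)
    table = simulate_homogeneity(spec, strict_positive=True)
    assert (table["value"] > 0).all()
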