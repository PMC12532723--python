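"""Stability regression, shelf-life contribution, slope screening, PCM."""

import numpy as np
import pandas as pd
import pytest

from crmcert import (
    StabilityModel,
    StabilitySimSpec,
    StatisticalError,
    ValidationError,
    fit_degradation,
    pcm_check,
    screen_slopes,
    simulate_stability,
    u_stab_from_fit,
)
from oracles import ols_normal_equations


def _table(times, values, temp=-20.0, analyte="X"):
    return pd.DataFrame(
        {
            "analyte": analyte,
            "temperature_C": temp,
            "time_months": times,
            "unit": range(1, len(times) + 1),
            "value": values,
        }
    )


class TestFit:
    def test_noise_free_line_is_recovered_exactly(self):
        t = [0.0, 2.0, 4.0, 6.0, 12.0]
        y = [10.0 - 0.1 * ti for ti in t]
        f = fit_degradation(_table(t, y), "X", -20.0)
        assert f.b1 == pytest.approx(-0.1)
        assert f.b0 == pytest.approx(10.0)
        assert f.se_b1 == 0.0
        assert f.P_slope == 0.0
        # residuals vanish at every time point
        assert np.allclose([f.b0 + f.b1 * ti for ti in t], y)

    def test_constant_series_has_unit_p(self):
        f = fit_degradation(_table([0, 3, 6, 9], [5.0] * 4), "X", -20.0)
        assert f.b1 == 0.0
        assert f.P_slope == 1.0

    def test_simulated_slope_recovery_and_oracle_se(self):
        spec = StabilitySimSpec("X", 10.0, {60.0: -0.2}, times=(0, 2, 4, 6, 12),
                                units_per_point=3, sigma_meas=0.1, seed=3)
        table = simulate_stability(spec)
        f = fit_degradation(table, "X", 60.0)
        assert abs(f.b1 - (-0.2)) <= 3 * f.se_b1
        oracle = ols_normal_equations(table["time_months"].tolist(), table["value"].tolist())
        assert f.b1 == pytest.approx(oracle["b1"], rel=1e-9)
        assert f.se_b1 == pytest.approx(oracle["se_b1"], rel=1e-9)
        assert f.b0 == pytest.approx(oracle["b0"], rel=1e-9)

    def test_too_few_time_points_rejected(self):
        with pytest.raises(StatisticalError, match="time points"):
            fit_degradation(_table([0, 6], [10.0, 9.9]), "X", -20.0)

    def test_missing_series_rejected(self):
        with pytest.raises(StatisticalError, match="no data"):
            fit_degradation(_table([0, 3, 6], [1, 2, 3]), "X", 40.0)


class TestShelfLifeContribution:
    def test_direct_evaluation(self):
        f = fit_degradation(_table([0, 2, 4, 6, 12], [10, 9.9, 10.1, 10, 9.95]), "X", -20.0)
        f = u_stab_from_fit(f, t_sl=36.0, reference_value=41.096)
        assert f.u_stab == pytest.approx(f.se_b1 * 36.0)
        assert f.u_stab_r == pytest.approx(f.se_b1 * 36.0 / 41.096)

    def test_se_based_formula_value(self):
        # se = 0.05 ug/kg/month over 36 months against 41.096 ug/kg
        assert 0.05 * 36 / 41.096 == pytest.approx(0.0438, abs=5e-5)

    def test_doubling_horizon_doubles_contribution(self):
        f = fit_degradation(_table([0, 2, 4, 6], [10, 9.8, 10.1, 9.9]), "X", -20.0)
        a = u_stab_from_fit(f, 18.0, 10.0)
        b = u_stab_from_fit(f, 36.0, 10.0)
        assert b.u_stab_r == pytest.approx(2 * a.u_stab_r)

    def test_zero_se_gives_zero_contribution(self):
        f = fit_degradation(_table([0, 2, 4], [10.0, 9.8, 9.6]), "X", -20.0)
        assert f.se_b1 == 0.0
        assert u_stab_from_fit(f, 36.0, 10.0).u_stab_r == 0.0

    def test_invalid_horizon_or_reference(self):
        f = fit_degradation(_table([0, 2, 4], [10.0, 9.8, 9.7]), "X", -20.0)
        with pytest.raises(ValidationError):
            u_stab_from_fit(f, 0.0, 10.0)
        with pytest.raises(ValidationError):
            u_stab_from_fit(f, 36.0, -1.0)

    def test_relative_contribution_scale_invariant(self):
        t = [0, 2, 4, 6, 12]
        y = [10.0, 9.7, 10.2, 9.9, 10.1]
        f1 = u_stab_from_fit(fit_degradation(_table(t, y), "X", -20.0), 36.0, 10.0)
        f2 = u_stab_from_fit(
            fit_degradation(_table(t, [v * 8.0 for v in y]), "X", -20.0), 36.0, 80.0
        )
        assert f1.u_stab_r == pytest.approx(f2.u_stab_r, rel=1e-12)


class TestScreening:
    def test_counts_flags(self):
        from dataclasses import replace

        base = fit_degradation(
            _table([0, 2, 4, 6, 12], [10, 9.7, 10.2, 9.9, 10.1]), "X", -20.0
        )
        flags = screen_slopes(
            [replace(base, P_slope=p) for p in (0.03, 0.2, 0.04)], alpha=0.05
        )
        assert len(flags) == 2

    def test_null_slope_type_one_error_rate(self):
        hits = 0
        runs = 1000
        for seed in range(runs):
            spec = StabilitySimSpec("X", 10.0, {-20.0: 0.0}, times=(0, 2, 4, 6, 12),
                                    units_per_point=3, sigma_meas=0.1, seed=seed)
            f = fit_degradation(simulate_stability(spec), "X", -20.0)
            hits += f.P_slope < 0.05
        assert abs(hits / runs - 0.05) <= 0.02


class TestPcm:
    def test_identical_means_pass(self):
        ref = _table([0, 0, 0], [10.0, 10.2, 9.8])
        mon = _table([24, 24, 24], [10.0, 10.2, 9.8])
        assert pcm_check(ref, mon, "X", certificate_U=1.0).passed

    def test_large_shift_fails(self):
        ref = _table([0, 0, 0], [10.0, 10.1, 9.9])
        mon = _table([24, 24, 24], [16.0, 16.1, 15.9])
        chk = pcm_check(ref, mon, "X", certificate_U=1.0)
        assert not chk.passed
        assert abs(chk.monitoring_mean - chk.reference_mean) > 3 * chk.window

    def test_missing_analyte_is_an_error(self):
        ref = _table([0], [10.0])
        mon = _table([24], [10.0], analyte="Y")
        with pytest.raises(StatisticalError):
            pcm_check(ref, mon, "X", 1.0)

    def test_stable_analyte_pass_rate(self):
        # U covers 2 sd of the certified value; a stable analyte passes >= 95%
        passes = 0
        runs = 500
        rng = np.random.default_rng(42)
        for _ in range(runs):
            ref = _table([0] * 6, rng.normal(10.0, 0.2, 6).tolist())
            mon = _table([24] * 6, rng.normal(10.0, 0.2, 6).tolist())
            passes += pcm_check(ref, mon, "X", certificate_U=0.4).passed
        assert passes / runs >= 0.95


class TestModelSurface:
    def test_reference_temperature_feeds_budget_only(self):
        specs = StabilitySimSpec("X", 10.0, {-20.0: 0.0, 60.0: -0.3},
                                 times=(0, 2, 4, 6, 12), units_per_point=2,
                                 sigma_meas=0.05, seed=9)
        res = StabilityModel(simulate_stability(specs), reference_values={"X": 10.0}).fit()
        assert res.at("X", -20.0).u_stab_r is not None
        assert res.at("X", 60.0).u_stab_r is None
        assert set(res.u_stab_r()) == {"X"}
        assert "Stability" in res.summary()

    def test_missing_reference_temperature_rejected(self):
        spec = StabilitySimSpec("X", 10.0, {40.0: 0.0}, times=(0, 2, 4),
                                units_per_point=2, sigma_meas=0.05, seed=1)
        with pytest.raises(StatisticalError, match="-20"):
            StabilityModel(simulate_stability(spec), ref_temp=-20.0).fit()
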