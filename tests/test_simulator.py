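"""Forward grain-weight simulation, scenario comparison and evaluation."""

import numpy as np
import pandas as pd
import pytest

import thermodev as td
from thermodev.simulator import SimulationError


def constant_link(lam):
    """A link whose output is a constant λ regardless of A_N.20°C."""
    return td.AssimilationLink(slope=0.0, intercept=lam)


@pytest.fixture(scope="module")
def defaults(gen_config=None):
    cfg = td.GeneratorConfig()
    return cfg.dev_params, cfg.pn_params, cfg.r_params


class TestFitLink:
    def test_two_points_interpolated(self):
        link = td.fit_link([(1.0, 0.14), (1.4, 0.155)])
        assert link.predict(1.0) == pytest.approx(0.14, rel=1e-10)
        assert link.predict(1.4) == pytest.approx(0.155, rel=1e-10)
        assert link.r_squared == pytest.approx(1.0)
        assert link.valid_range == (1.0, 1.4)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0.9, 1.4, 8)
        y = 0.034 * x + 0.105 + 0.0005 * rng.standard_normal(8)
        link = td.fit_link(np.column_stack([x, y]))
        # closed-form OLS oracle
        b = np.polyfit(x, y, 1)
        assert link.slope == pytest.approx(b[0], rel=1e-10)
        assert link.intercept == pytest.approx(b[1], rel=1e-10)
        assert abs(link.slope - 0.034) < 0.005

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            td.fit_link([(1.0, 0.1), (1.0, 0.2)])


class TestBuildSeries:
    def test_constant_config(self):
        series = td.build_series({"days": 10, "t_day_C": 25, "t_night_C": 15})
        assert len(series) == 10
        assert all(s == series[0] for s in series)

    def test_default_length_100(self):
        series = td.build_series({"t_day_C": 20, "t_night_C": 15})
        assert len(series) == 100

    def test_per_day_arrays(self):
        series = td.build_series({"t_day_C": [20, 22, 24],
                                  "t_night_C": [15, 15, 16]})
        assert [s.t_day for s in series] == [20, 22, 24]

    def test_malformed_config_names_field(self):
        with pytest.raises(ValueError, match="t_night_C"):
            td.build_series({"t_day_C": 20})
        with pytest.raises(ValueError, match="photoperiod_h"):
            td.build_series({"t_day_C": [20, 21, 22],
                             "t_night_C": [15, 15, 15],
                             "photoperiod_h": [12, 12]})


class TestSimulateGrain:
    def test_constant_scenario_matches_logistic(self, defaults):
        """Under a constant 20/20 °C scenario with a constant-λ link, the
        simulated trajectory is the closed-form logistic: within 1 % at
        1 d steps, within 0.1 % with sub-stepping."""
        dev, pn, r = defaults
        lam = 0.145
        series = td.build_series({"days": 100, "t_day_C": 20, "t_night_C": 20})
        oracle = td.GrainGrowthParams(w0=1.65, t0=20.2, lam=lam,
                                      time_basis="developmental")
        for substeps, tol in ((1, 0.01), (10, 0.001)):
            res = td.simulate_grain(series, dev, pn, r, constant_link(lam),
                                    substeps=substeps)
            assert res.final_weight == pytest.approx(oracle.final_weight,
                                                     rel=tol)
            traj = res.records["weight_mg"].to_numpy()
            expected = td.weight_at(oracle, res.records["t_20C"].to_numpy())
            assert np.max(np.abs(traj - expected) / oracle.final_weight) < tol

    def test_monotone_and_starts_at_w0(self, defaults):
        dev, pn, r = defaults
        series = td.build_series({"days": 60, "t_day_C": 25, "t_night_C": 18})
        res = td.simulate_grain(series, dev, pn, r, td.default_link())
        w = res.records["weight_mg"].to_numpy()
        assert np.all(np.diff(w) >= 0)
        assert w[0] >= 1.65  # weight starts at W_0 and only grows

    def test_zero_photosynthesis_limit(self, defaults):
        """With a zero-amplitude P_N curve, λ comes from the intercept
        alone and the weight is still logistic in developmental time."""
        dev, pn, r = defaults
        tiny_pn = pn.scaled_to(1e-12, 20.0)
        tiny_r = r.scaled_to(1e-12, 20.0)
        link = td.AssimilationLink(slope=0.001, intercept=0.145)
        series = td.build_series({"days": 100, "t_day_C": 20, "t_night_C": 20})
        res = td.simulate_grain(series, dev, tiny_pn, tiny_r, link)
        oracle = td.GrainGrowthParams(w0=1.65, t0=20.2, lam=0.145,
                                      time_basis="developmental")
        assert res.final_weight == pytest.approx(oracle.final_weight, rel=0.01)

    def test_negative_lambda_names_day(self, defaults):
        dev, pn, r = defaults
        bad_link = td.AssimilationLink(slope=0.0, intercept=-0.1)
        series = td.build_series({"days": 5, "t_day_C": 20, "t_night_C": 20})
        with pytest.raises(SimulationError, match="day 0"):
            td.simulate_grain(series, dev, pn, r, bad_link)

    def test_halving_step_converges(self, defaults):
        dev, pn, r = defaults
        series = td.build_series({"days": 100, "t_day_C": 24, "t_night_C": 17})
        r1 = td.simulate_grain(series, dev, pn, r, td.default_link(), substeps=1)
        r2 = td.simulate_grain(series, dev, pn, r, td.default_link(), substeps=2)
        assert abs(r1.final_weight - r2.final_weight) / r2.final_weight < 0.005

    def test_night_warming_reduces_weight_more(self, defaults):
        """The core asymmetry: +5 °C at night lowers final grain weight
        more than +5 °C by day."""
        dev, pn, r = defaults
        link = td.default_link()
        def run(td_c, tn_c):
            series = td.build_series({"days": 100, "t_day_C": td_c,
                                      "t_night_C": tn_c})
            return td.simulate_grain(series, dev, pn, r, link)
        base, night, day = run(20, 15), run(20, 20), run(25, 15)
        red_night = td.compare_scenarios(base, night)
        red_day = td.compare_scenarios(base, day)
        assert red_night > red_day > 0


class TestCompareScenarios:
    def test_identical_scenarios_zero(self, defaults):
        dev, pn, r = defaults
        series = td.build_series({"days": 50, "t_day_C": 20, "t_night_C": 15})
        a = td.simulate_grain(series, dev, pn, r, td.default_link())
        b = td.simulate_grain(series, dev, pn, r, td.default_link())
        assert td.compare_scenarios(a, b) == 0.0

    def test_cooler_night_base_positive_reduction(self, defaults):
        dev, pn, r = defaults
        link = td.default_link()
        base = td.simulate_grain(
            td.build_series({"days": 100, "t_day_C": 20, "t_night_C": 15}),
            dev, pn, r, link)
        alt = td.simulate_grain(
            td.build_series({"days": 100, "t_day_C": 20, "t_night_C": 20}),
            dev, pn, r, link)
        red = td.compare_scenarios(base, alt)
        assert red > 0
        # antisymmetry relation: red(a,b)·W_a = −red(b,a)·W_b
        rev = td.compare_scenarios(alt, base)
        assert red * base.final_weight == pytest.approx(
            -rev * alt.final_weight, rel=1e-10)

    def test_parameter_mismatch_rejected(self, defaults):
        dev, pn, r = defaults
        series = td.build_series({"days": 20, "t_day_C": 20, "t_night_C": 15})
        a = td.simulate_grain(series, dev, pn, r, td.default_link())
        b = td.simulate_grain(series, dev, pn, r, constant_link(0.15))
        with pytest.raises(ValueError, match="different parameter"):
            td.compare_scenarios(a, b)


class TestEvaluateAgainstTable:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["study_id", "base_t_day",
                                           "base_t_night", "alt_t_day",
                                           "alt_t_night", "photoperiod_h",
                                           "observed_reduction_pct"])

    def test_self_consistency(self, defaults):
        """Feeding the model its own predictions back gives R² = 1 and
        zero bias."""
        dev, pn, r = defaults
        link = td.default_link()
        rows = [("s1", 20, 15, 20, 20, 12, 0.0), ("s2", 20, 15, 25, 15, 12, 0.0),
                ("s3", 22, 16, 25, 20, 12, 0.0)]
        first = td.evaluate_against_table(self.table(rows), dev, pn, r, link)
        preds = first["predictions"]["predicted_reduction_pct"].tolist()
        rows2 = [row[:-1] + (p,) for row, p in zip(rows, preds)]
        res = td.evaluate_against_table(self.table(rows2), dev, pn, r, link)
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert res["mean_bias_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_observation_perturbation_shifts_bias(self, defaults):
        dev, pn, r = defaults
        link = td.default_link()
        rows = [("s1", 20, 15, 20, 20, 12, 10.0), ("s2", 20, 15, 25, 15, 12, 8.0)]
        base = td.evaluate_against_table(self.table(rows), dev, pn, r, link)
        rows_up = [row[:-1] + (row[-1] * 1.1,) for row in rows]
        up = td.evaluate_against_table(self.table(rows_up), dev, pn, r, link)
        # mean((p − 1.1·o)/(1.1·o)) = (mean(p/o) − 1.1)/1.1, i.e. the bias
        # drops by ~10 points relative
        assert up["mean_bias_pct"] == pytest.approx(
            (base["mean_bias_pct"] + 100.0) / 1.1 - 100.0, rel=1e-9)

    def test_single_row_r2_undefined(self, defaults):
        dev, pn, r = defaults
        res = td.evaluate_against_table(
            self.table([("s1", 20, 15, 20, 20, 12, 12.0)]),
            dev, pn, r, td.default_link())
        assert res["r_squared"] is None
        assert np.isfinite(res["mean_bias_pct"])
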