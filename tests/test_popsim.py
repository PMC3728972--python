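"""Population simulator: logistic renewal, stochastic sampling, harvest."""

import numpy as np
import pytest
from scipy import stats

from declinewatch.params import (
    LIFE_HISTORIES,
    LifeHistoryParams,
    PressureScenario,
)
from declinewatch.popsim import (
    EnsembleAttritionError,
    harvest,
    sample_truncated_normal,
    simulate_ensemble,
    simulate_trajectory,
    step_population,
)


class TestLifeHistoryParams:
    @pytest.mark.parametrize("label,r,rcv,K,Kcv,nup", [
        ("slow", 0.1, 0.15, 1000, 0.01, 1300),
        ("medium", 0.2, 0.15, 1000, 0.01, 1600),
        ("fast", 0.3, 0.2, 1000, 0.01, 1900),
    ])
    def test_preset_parameter_block(self, label, r, rcv, K, Kcv, nup):
        lh = LIFE_HISTORIES[label]
        assert lh.r_mean == r and lh.r_cv == rcv
        assert lh.K_mean == K and lh.K_cv == Kcv and lh.N_upper == nup
        assert lh.r_sd == pytest.approx(rcv * r)
        assert lh.K_sd == pytest.approx(Kcv * K)
        # upper truncation sits ~3 SD above the mean (canonical rounded value)
        assert lh.r_upper == pytest.approx(lh.r_mean + 3 * lh.r_sd, rel=0.06)

    def test_start_far_from_K(self):
        assert LifeHistoryParams.preset("medium", start_at_K=False).N1 == 500

    def test_invalid_fields_rejected(self):
        with pytest.raises(ValueError):
            LifeHistoryParams("x", -0.1, 0.1, 0.2, 1000, 0.01, 1000, 1600)


class TestPressureScenario:
    @pytest.mark.parametrize("code,ptype,trend", [
        ("P1", "proportional", "constant"),
        ("P2", "proportional", "decreasing"),
        ("P3", "proportional", "increasing"),
        ("F1", "fixed", "constant"),
        ("F2", "fixed", "decreasing"),
        ("F3", "fixed", "increasing"),
    ])
    def test_code_mapping(self, code, ptype, trend):
        s = PressureScenario(code)
        assert s.pressure_type == ptype and s.trend == trend

    def test_intensity_levels_positive(self):
        for code in ("P1", "F1"):
            for level in ("low", "medium", "high"):
                s = PressureScenario(code, level)
                assert s.level0 > 0
                if s.pressure_type == "proportional":
                    assert 0 < s.level0 <= 1

    def test_trend_schedules(self):
        inc = PressureScenario("F3", base_level=10.0, ramp=2.0)
        assert inc.level_at(5) == 20.0
        dec = PressureScenario("F2", base_level=10.0, ramp=2.0)
        assert dec.level_at(10) == 0.0  # clamped at zero
        pinc = PressureScenario("P3", base_level=0.5, ramp=0.1)
        assert pinc.level_at(10) == 1.0  # clamped at one

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            PressureScenario("Q9")


class TestStepPopulation:
    def test_equilibrium_at_carrying_capacity(self):
        assert step_population(1000, 0.2, 1000) == 1000

    def test_extinction_is_absorbing(self):
        assert step_population(0, 0.3, 1000) == 0

    def test_logistic_growth_value(self):
        assert step_population(500, 0.2, 1000) == pytest.approx(550)

    def test_invalid_K(self):
        with pytest.raises(ValueError):
            step_population(100, 0.2, 0)

    def test_never_negative(self):
        assert step_population(2000, 1.5, 100) == 0.0


class TestTruncatedNormal:
    def test_degenerate_sd_returns_mean(self, rng):
        assert sample_truncated_normal(rng, 0.2, 0.0, 0, 0.3) == 0.2

    def test_degenerate_mean_outside_bounds(self, rng):
        with pytest.raises(ValueError):
            sample_truncated_normal(rng, 0.5, 0.0, 0, 0.3)

    def test_draws_respect_bounds(self, rng):
        draws = [sample_truncated_normal(rng, 0.2, 0.1, 0, 0.3) for _ in range(500)]
        assert all(0 <= x <= 0.3 for x in draws)

    def test_sample_mean_matches_analytic(self, rng):
        mean, sd, lo, hi = 0.2, 0.03, 0.0, 0.3
        draws = np.array(
            [sample_truncated_normal(rng, mean, sd, lo, hi) for _ in range(100_000)]
        )
        a, b = (lo - mean) / sd, (hi - mean) / sd
        expected = stats.truncnorm.mean(a, b, loc=mean, scale=sd)
        se = stats.truncnorm.std(a, b, loc=mean, scale=sd) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se


class TestHarvest:
    def test_proportional_thirty_percent(self):
        s = PressureScenario("P1", base_level=0.30)
        assert harvest(500, s, 0) == pytest.approx(350)

    def test_fixed_clamps_at_zero(self):
        s = PressureScenario("F1", base_level=50.0)
        assert harvest(10, s, 3) == 0.0

    def test_increasing_fixed_schedule(self):
        s = PressureScenario("F3", base_level=10.0, ramp=2.0)
        assert harvest(500, s, 5) == pytest.approx(480)


def _quiet(lh):
    return lh.with_(r_cv=0.0, K_cv=0.0)


class TestSimulateTrajectory:
    def test_equilibrium_stays_constant(self, medium):
        traj = simulate_trajectory(_quiet(medium), None, seed=0)
        assert np.allclose(traj.counts, 1000.0)

    def test_monotone_convergence_from_below(self, medium):
        lh = _quiet(medium).with_(N1=500.0)
        traj = simulate_trajectory(lh, None, total_years=60, seed=0)
        assert np.all(np.diff(traj.counts) >= -1e-9)
        assert traj.counts[-1] <= 1000.0 + 1e-9

    def test_overwhelming_pressure_drives_extinction(self, medium):
        scen = PressureScenario("P1", base_level=0.5)  # removal >> r_mean
        traj = simulate_trajectory(_quiet(medium), scen, seed=0)
        post = traj.counts[scen.onset_year:]
        assert np.all(np.diff(post[: max(len(post) - 1, 1)]) < 1e-9)
        assert traj.extinct

    def test_extinction_threshold_below_one(self, medium):
        scen = PressureScenario("P1", base_level=0.5)
        traj = simulate_trajectory(_quiet(medium), scen, seed=0)
        assert traj.counts[-1] < 1.0
        assert traj.extinct_year == len(traj.counts)

    def test_counts_never_negative(self, medium):
        scen = PressureScenario("F3", "high")
        for seed in range(5):
            traj = simulate_trajectory(medium, scen, seed=seed)
            assert np.all(traj.counts >= 0)

    def test_proportional_harvest_commutes_with_scale(self, medium):
        """Doubling N1 and K doubles every count under proportional harvest
        (zero stochasticity); fixed harvest breaks this."""
        scen = PressureScenario("P1", base_level=0.2)
        base = _quiet(medium)
        big = base.with_(N1=2000.0, K_mean=2000.0, N_upper=3200.0)
        t1 = simulate_trajectory(base, scen, total_years=120, seed=0)
        t2 = simulate_trajectory(big, scen, total_years=120, seed=0)
        m = min(len(t1.counts), len(t2.counts))
        assert np.allclose(2 * t1.counts[:m], t2.counts[:m], rtol=1e-9)

        scen_f = PressureScenario("F1", base_level=50.0)
        f1 = simulate_trajectory(base, scen_f, total_years=120, seed=0)
        f2 = simulate_trajectory(big, scen_f, total_years=120, seed=0)
        m = min(len(f1.counts), len(f2.counts))
        assert not np.allclose(2 * f1.counts[:m], f2.counts[:m], rtol=1e-3)


class TestSimulateEnsemble:
    def test_unpressured_full_length(self, medium):
        trajs = simulate_ensemble(medium, None, 10, 50, seed=1)
        assert len(trajs) == 10
        assert all(len(t.counts) == 100 for t in trajs)

    def test_survival_filter_contract(self, medium):
        scen = PressureScenario("F3", "high")
        trajs = simulate_ensemble(medium, scen, 30, 25, seed=1)
        assert all(len(t.counts) >= 25 for t in trajs)

    def test_deterministic_per_seed(self, medium, p1_low):
        a = simulate_ensemble(medium, p1_low, 5, 25, seed=42)
        b = simulate_ensemble(medium, p1_low, 5, 25, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.counts, y.counts)

    def test_unattainable_filter_reports_attrition(self, medium):
        scen = PressureScenario("P1", base_level=0.9)
        with pytest.raises(EnsembleAttritionError) as err:
            simulate_ensemble(medium, scen, 5, 100, seed=0,
                              attempt_cap_factor=3)
        assert err.value.attrition_rate > 0

    def test_unpressured_mean_tracks_carrying_capacity(self, medium):
        trajs = simulate_ensemble(medium, None, 40, 50, seed=7)
        mat = np.array([t.counts for t in trajs])
        mean, sd = mat.mean(axis=0), mat.std(axis=0)
        assert np.all(np.abs(mean - 1000.0) <= 3 * np.maximum(sd, 1.0))
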