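import math

import numpy as np
import pytest

from thermoload import (
    BOLTZMANN_EV_PER_K,
    CalibrationError,
    ConfigurationError,
    Individual,
    InvalidInputError,
    MicroclimateSeries,
    NoCrossoverError,
    RepairParams,
    StageSpec,
    TDTParams,
    calibrate_repair,
    damage_rate,
    draw_population,
    failure_time,
    net_damage_rate,
    permissive_boundary,
    repair_rate,
    simulate_individual,
    simulate_population,
    step_damage,
)

from .conftest import constant_series, make_series

REPAIR_OFF = RepairParams(shape="off")


class TestRepairRate:
    def test_reference_point(self):
        rep = RepairParams(shape="arrhenius", r_ref=1e-5, e_a=0.65, t_ref_c=31.0)
        assert repair_rate(rep, 31.0) == pytest.approx(1e-5, rel=1e-12)

    def test_arrhenius_closed_form(self):
        # independent evaluation of the Arrhenius exponential
        rep = RepairParams(shape="arrhenius", r_ref=1e-5, e_a=0.65, t_ref_c=31.0)
        expected = 1e-5 * math.exp(
            (0.65 / BOLTZMANN_EV_PER_K) * (1.0 / 304.15 - 1.0 / 314.15)
        )
        assert repair_rate(rep, 41.0) == pytest.approx(expected, rel=1e-12)
        assert repair_rate(rep, 41.0) == pytest.approx(2.203e-5, rel=1e-3)

    def test_off_is_zero(self):
        assert repair_rate(REPAIR_OFF, -10.0) == 0.0
        assert repair_rate(REPAIR_OFF, 80.0) == 0.0

    def test_gaussian_shape(self):
        rep = RepairParams(shape="gaussian", r_ref=2e-5, t_opt=31.0, sigma=5.0)
        assert repair_rate(rep, 31.0) == pytest.approx(2e-5)
        assert repair_rate(rep, 36.0) == pytest.approx(2e-5 * math.exp(-0.5))
        # symmetric around the peak
        assert repair_rate(rep, 26.0) == pytest.approx(repair_rate(rep, 36.0))

    def test_nonfinite_temperature_rejected(self):
        with pytest.raises(InvalidInputError):
            repair_rate(REPAIR_OFF, np.nan)

    def test_always_nonnegative(self):
        rep = RepairParams(shape="arrhenius", r_ref=1e-5, e_a=0.65, t_ref_c=31.0)
        temps = np.linspace(-20.0, 80.0, 101)
        assert np.all(repair_rate(rep, temps) >= 0.0)


class TestCalibrateRepair:
    def test_pollen_default_r_ref(self, pollen):
        rep = calibrate_repair(pollen, 31.0)
        # damage rate at 31 C is 10 ** ((31 - 46) / 3) = 1e-5
        assert rep.r_ref == pytest.approx(1e-5, rel=1e-12)
        assert rep.t_ref_c == 31.0

    def test_at_ctmax_gives_reference_rate(self, pollen):
        rep = calibrate_repair(pollen, pollen.ctmax)
        assert rep.r_ref == pytest.approx(1.0 / pollen.t_ref, rel=1e-12)

    def test_net_zero_at_crossover(self, pollen, pollen_repair):
        assert abs(net_damage_rate(pollen, pollen_repair, 31.0)) < 1e-12

    def test_gaussian_calibration(self, pollen):
        rep = calibrate_repair(pollen, 31.0, shape="gaussian", t_opt=33.0, sigma=4.0)
        assert repair_rate(rep, 31.0) == pytest.approx(damage_rate(pollen, 31.0), rel=1e-12)

    def test_off_shape_undefined(self, pollen):
        with pytest.raises(CalibrationError):
            calibrate_repair(pollen, 31.0, shape="off")


class TestNetDamageRate:
    def test_negative_in_permissive_range(self, pollen, pollen_repair):
        assert net_damage_rate(pollen, pollen_repair, 25.0) < 0.0

    def test_positive_and_dominant_in_stressful_range(self, pollen, pollen_repair):
        net40 = net_damage_rate(pollen, pollen_repair, 40.0)
        assert net40 > 0.0
        assert net40 > damage_rate(pollen, 31.0)

    def test_stressful_escalation_doubles_per_degree(self, pollen, pollen_repair):
        for temp in np.arange(33.0, 50.0, 1.0):
            ratio = net_damage_rate(pollen, pollen_repair, temp + 1.0) / net_damage_rate(
                pollen, pollen_repair, temp
            )
            assert ratio > 2.0


class TestPermissiveBoundary:
    def test_default_crossover_is_31(self, pollen, pollen_repair):
        assert permissive_boundary(pollen, pollen_repair, (0.0, 60.0)) == pytest.approx(
            31.0, abs=1e-5
        )

    def test_repair_off_has_no_crossover(self, pollen):
        with pytest.raises(NoCrossoverError):
            permissive_boundary(pollen, REPAIR_OFF, (0.0, 60.0))

    def test_recalibrated_crossover(self, pollen):
        rep = calibrate_repair(pollen, 35.0)
        assert permissive_boundary(pollen, rep, (0.0, 60.0)) == pytest.approx(35.0, abs=1e-5)


class TestStepDamage:
    def test_net_repair_below_crossover(self, pollen, pollen_repair):
        ind = Individual(stage="pollen", tdt=pollen, damage=0.5)
        out = step_damage(ind, pollen_repair, 25.0, dt=10.0)
        assert out.damage < 0.5

    def test_clamped_at_zero(self, pollen, pollen_repair):
        ind = Individual(stage="pollen", tdt=pollen, damage=0.0)
        out = step_damage(ind, pollen_repair, 25.0, dt=100.0)
        assert out.damage == 0.0

    def test_failure_is_absorbing(self, pollen, pollen_repair):
        ind = Individual(stage="pollen", tdt=pollen, damage=0.99)
        hot = step_damage(ind, pollen_repair, 50.0, dt=10.0)
        assert hot.failed and hot.damage == 1.0 and hot.p == 1.0
        cooled = step_damage(hot, pollen_repair, 20.0, dt=10000.0)
        assert cooled.failed and cooled.p == 1.0

    @pytest.mark.parametrize("dt", [0.0, -1.0])
    def test_invalid_dt(self, pollen, pollen_repair, dt):
        ind = Individual(stage="pollen", tdt=pollen)
        with pytest.raises(InvalidInputError):
            step_damage(ind, pollen_repair, 25.0, dt=dt)


class TestSimulateIndividual:
    def test_constant_temperature_matches_closed_form(self, pollen):
        # T = 43 C: closed-form failure time is 10 minutes
        series = constant_series(43.0, n_steps=150, step_minutes=0.1)
        traj = simulate_individual(pollen, REPAIR_OFF, series)
        first = np.argmax(traj.p[:, 0] >= 1.0)
        minutes = first * 0.1
        assert abs(minutes - 10.0) <= 0.1 + 1e-9

    @pytest.mark.parametrize("stage_tdt", [TDTParams(46, 3.0), TDTParams(52, 3.5), TDTParams(58, 4.5)])
    @pytest.mark.parametrize("offset", [-3.0, 0.0, 3.0])
    def test_constant_t_equivalence_all_stages(self, stage_tdt, offset):
        temp = stage_tdt.ctmax + offset
        t_fail = failure_time(stage_tdt, temp)
        step = t_fail / 50.0
        series = constant_series(temp, n_steps=80, step_minutes=step)
        traj = simulate_individual(stage_tdt, REPAIR_OFF, series)
        first = np.argmax(traj.p[:, 0] >= 1.0)
        assert traj.p[first, 0] == 1.0
        assert abs(first * step - t_fail) <= step + 1e-9

    def test_linear_accumulation_without_repair(self, pollen):
        series = constant_series(43.0, n_steps=60, step_minutes=0.1)
        traj = simulate_individual(pollen, REPAIR_OFF, series)
        expected = np.minimum(np.arange(60) * 0.1 / 10.0, 1.0)
        np.testing.assert_allclose(traj.damage[:, 0], expected, atol=1e-12)

    def test_benign_constant_stays_zero(self, pollen, pollen_repair):
        series = constant_series(20.0, n_steps=500)
        traj = simulate_individual(pollen, pollen_repair, series)
        assert np.all(traj.p == 0.0)

    def test_repair_recovery_strictly_decreasing(self, pollen, pollen_repair):
        # sustained permissive temperature repairs half damage away entirely
        series = constant_series(28.0, n_steps=2000, step_minutes=60.0)
        traj = simulate_individual(pollen, pollen_repair, series, d0=0.5)
        d = traj.damage[:, 0]
        positive = d > 0.0
        assert np.all(np.diff(d[positive]) < 0.0)
        assert d[-1] < 0.01

    def test_two_pulse_ratchet(self, pollen, pollen_repair):
        # hot pulse to D ~ 0.8, a permissive hour, then the same pulse again:
        # the second pulse kills sooner than a cold start would.
        step = 0.1
        pulse = np.full(37, 44.0)  # 3.7 min at 0.2154/min -> D ~ 0.797
        cool = np.full(600, 25.0)  # 60 permissive minutes
        temps = np.concatenate([pulse, cool, np.full(200, 44.0)])
        traj = simulate_individual(pollen, pollen_repair, make_series(temps, step))
        d_after_pulse1 = traj.damage[len(pulse), 0]
        assert 0.7 < d_after_pulse1 < 0.9
        pulse2_start = len(pulse) + len(cool)
        assert np.all(traj.p[: pulse2_start + 1, 0] < 1.0)
        first_fail = np.argmax(traj.p[:, 0] >= 1.0)
        minutes_into_pulse2 = (first_fail - pulse2_start) * step
        cold_start_time = failure_time(pollen, 44.0)  # ~ 4.64 min
        assert minutes_into_pulse2 < cold_start_time
        # two-pulse oracle: remaining damage / rate
        expected = (1.0 - traj.damage[pulse2_start, 0]) / damage_rate(pollen, 44.0)
        assert abs(minutes_into_pulse2 - expected) <= step + 1e-9

    def test_probability_bounds_and_absorption(self, pollen, pollen_repair):
        temps = np.concatenate([np.full(100, 48.0), np.full(500, 15.0)])
        traj = simulate_individual(pollen, pollen_repair, make_series(temps, 1.0))
        assert np.all((traj.p >= 0.0) & (traj.p <= 1.0))
        first = np.argmax(traj.p[:, 0] >= 1.0)
        assert np.all(traj.p[first:, 0] == 1.0)  # no post-failure repair

    def test_too_short_series_rejected(self, pollen):
        import pandas as pd

        with pytest.raises(InvalidInputError):
            MicroclimateSeries(
                times=pd.DatetimeIndex(["2024-01-01"]), temps={50.0: np.array([20.0])}
            )

    def test_invalid_dt(self, pollen):
        series = constant_series(20.0, n_steps=10)
        with pytest.raises(InvalidInputError):
            simulate_individual(pollen, REPAIR_OFF, series, dt=0.0)


def _stage(n=5, sd_ctmax=0.5, sd_z=0.15, **kw):
    return StageSpec(
        name=kw.pop("name", "pollen"),
        height_cm=kw.pop("height_cm", 50.0),
        tdt_mean=kw.pop("tdt_mean", TDTParams(46.0, 3.0)),
        sd_ctmax=sd_ctmax,
        sd_z=sd_z,
        n_individuals=n,
        **kw,
    )


class TestDrawPopulation:
    def test_exact_count(self):
        assert len(draw_population(_stage(n=100), seed=1)) == 100

    def test_degenerate_sds_yield_identical_individuals(self):
        pop = draw_population(_stage(n=10, sd_ctmax=0.0, sd_z=0.0), seed=3)
        assert all(ind.tdt == TDTParams(46.0, 3.0) for ind in pop)

    def test_seed_determinism(self):
        a = draw_population(_stage(n=50), seed=7)
        b = draw_population(_stage(n=50), seed=7)
        assert [i.tdt for i in a] == [i.tdt for i in b]

    def test_different_seeds_differ(self):
        a = draw_population(_stage(n=50), seed=7)
        b = draw_population(_stage(n=50), seed=8)
        assert [i.tdt for i in a] != [i.tdt for i in b]

    def test_z_truncated_at_half(self):
        pop = draw_population(_stage(n=500, sd_z=2.0), seed=0)
        assert all(ind.tdt.z >= 0.5 for ind in pop)


class TestSimulatePopulation:
    def test_zero_sds_match_single_individual(self, pollen, pollen_repair):
        series = constant_series(40.0, n_steps=300)
        stage = _stage(n=20, sd_ctmax=0.0, sd_z=0.0)
        pop_traj = simulate_population(stage, series, seed=1)
        ind_traj = simulate_individual(pollen, stage.resolve_repair(), series)
        np.testing.assert_allclose(pop_traj.mean_p, ind_traj.p[:, 0], atol=1e-12)

    def test_monotone_under_uniform_warming(self):
        temps = 25.0 + 12.0 * np.clip(np.sin(np.linspace(0, 6 * np.pi, 600)), 0, 1)
        series = make_series(temps, 10.0)
        stage = _stage(n=30)
        base = simulate_population(stage, series, seed=5)
        warm = simulate_population(stage, series.shifted(5.0), seed=5)
        assert warm.mean_p[-1] >= base.mean_p[-1]

    def test_benign_series_stays_zero(self):
        series = constant_series(25.0, n_steps=1000)
        traj = simulate_population(_stage(n=10), series, seed=2)
        assert np.all(traj.mean_p == 0.0)

    def test_missing_height_is_configuration_error(self):
        series = constant_series(40.0, n_steps=10, height=0.0)
        with pytest.raises(ConfigurationError, match="available heights"):
            simulate_population(_stage(height_cm=50.0), series, seed=0)

    def test_bitwise_seed_determinism(self):
        temps = np.linspace(20.0, 45.0, 400)
        series = make_series(temps, 5.0)
        a = simulate_population(_stage(n=25), series, seed=11)
        b = simulate_population(_stage(n=25), series, seed=11)
        assert np.array_equal(a.damage, b.damage)

    def test_probabilities_bounded(self):
        temps = 20.0 + 25.0 * np.abs(np.sin(np.linspace(0, 8 * np.pi, 500)))
        traj = simulate_population(_stage(n=40), make_series(temps, 10.0), seed=4)
        assert np.all((traj.p >= 0.0) & (traj.p <= 1.0))
        assert np.all((traj.mean_p >= 0.0) & (traj.mean_p <= 1.0))
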