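"""Integration behavior: events, conservation, convergence, long-term runs."""

import numpy as np
import pytest

from drinktwin import (
    DrinkEvent,
    MealEvent,
    SolverConfig,
    blood_volume,
    compile_schedule,
    peth_consumption_curve,
    simulate,
    simulate_days,
)
from drinktwin.model import (
    DEFAULT_CONSTANTS,
    I_BLOOD_CONC,
    I_CONC_ETOH_STOMACH,
    I_ETOH_POOL,
    I_MASS_ETOH_INTESTINES,
    I_TIME_ELAPSED,
    I_VOL_STOMACH,
)


class TestSimulate:
    def test_empty_schedule_is_stationary_except_clock(self, male, params):
        sched = compile_schedule([], [], 120)
        traj = simulate(sched, male, params, grid=np.linspace(0, 120, 13))
        ref = traj.states[0].copy()
        for i, t in enumerate(traj.times):
            expect = ref.copy()
            expect[I_TIME_ELAPSED] = t
            np.testing.assert_allclose(traj.states[i], expect, atol=1e-12)

    def test_water_empties_monotonically_after_drinking(self, male, params, library):
        scn = library["water_500ml"]
        traj = simulate(scn.schedule(), male, params)
        vol = traj.observables["yGastricVolume"]
        after = vol[traj.times >= 3.0]
        assert np.all(np.diff(after) <= 1e-12)
        assert after[-1] >= DEFAULT_CONSTANTS.ss_vol - 1e-12

    def test_tolerance_refinement_converges(self, male, params, beer_schedule):
        base = simulate(beer_schedule, male, params,
                        config=SolverConfig(rtol=1e-8, atol=1e-10))
        tight = simulate(beer_schedule, male, params,
                         config=SolverConfig(rtol=5e-9, atol=5e-11))
        rel = abs(base.peak_blood_conc - tight.peak_blood_conc) / tight.peak_blood_conc
        assert rel < 1e-3

    def test_coarse_grid_is_restriction_of_fine_grid(self, male, params, beer_schedule):
        fine = np.linspace(0, 480, 481)
        coarse = fine[::8]
        a = simulate(beer_schedule, male, params, grid=fine)
        b = simulate(beer_schedule, male, params, grid=coarse)
        np.testing.assert_allclose(a.states[::8], b.states, rtol=1e-12, atol=1e-14)

    def test_time_shift_equivariance(self, male, params):
        drinks = [DrinkEvent(0, 20, 1.0, 5.1, 133.0)]
        meals = [MealEvent(0.0, 700.0)]
        delta = 37.0
        grid = np.linspace(0, 480, 161)
        a = simulate(compile_schedule(drinks, meals, 480), male, params, grid=grid)
        shifted = compile_schedule(
            [DrinkEvent(delta, 20, 1.0, 5.1, 133.0)], [MealEvent(delta, 700.0)],
            480 + delta,
        )
        b = simulate(shifted, male, params, grid=grid + delta)
        # agreement is limited by the root-finding tolerance of the
        # digestion-reset event, not by the integration tolerance
        mask = np.ones(12, bool)
        mask[I_TIME_ELAPSED] = False  # clock counts from the (shifted) meal
        np.testing.assert_allclose(
            a.states[:, mask], b.states[:, mask], rtol=2e-4, atol=1e-6
        )
        np.testing.assert_allclose(
            a.states[:, I_TIME_ELAPSED], b.states[:, I_TIME_ELAPSED], rtol=1e-6, atol=1e-6
        )
        resets_a = [e.time for e in a.events if e.kind == "pool_reset"]
        resets_b = [e.time for e in b.events if e.kind == "pool_reset"]
        np.testing.assert_allclose(np.array(resets_a) + delta, resets_b, atol=1e-3)

    def test_ethanol_mass_balance_closed_drink_only(self, male, params, beer_schedule):
        """Consumed ethanol = stored + first-pass-eliminated + metabolized.

        No meal is involved, so no mass is ever discarded; the budget
        must close to well under 0.5% of the consumed dose.
        """
        traj = simulate(beer_schedule, male, params)
        y = traj.states
        vb = blood_volume(male)
        stored = (
            y[:, I_ETOH_POOL]
            + y[:, I_CONC_ETOH_STOMACH] * y[:, I_VOL_STOMACH]
            + y[:, I_MASS_ETOH_INTESTINES]
            + y[:, I_BLOOD_CONC] * vb
        )
        r4 = y[:, I_MASS_ETOH_INTESTINES] * params.k4
        blood = y[:, I_BLOOD_CONC]
        r5 = (params.Vmax_ADH * blood / (params.km_ADH + blood)
              + params.Vmax_CYP2E1 * blood / (params.km_CYP2E1 + blood))
        from scipy.integrate import cumulative_trapezoid

        eliminated = cumulative_trapezoid(
            r4 + r5 * DEFAULT_CONSTANTS.v_liver, traj.times, initial=0.0
        )
        consumed = traj.times / 20.0
        consumed = np.minimum(consumed, 1.0) * beer_schedule.total_ethanol_mg
        residual = np.abs(consumed - stored - eliminated)
        assert residual.max() <= 0.005 * beer_schedule.total_ethanol_mg

    def test_pool_reset_logs_discarded_encapsulated_ethanol(self, male, params, library):
        """Digestion completion zeroes the food pool and logs the loss.

        Once the liquid has left the stomach the pool exchange is gated
        off, so whatever ethanol is still encapsulated at that moment is
        removed from the system at the reset — this sizeable first-pass
        loss is the mechanism by which a meal blunts the BAC curve.
        """
        scn = library["spirit_140ml_meal700"]
        traj = simulate(scn.schedule(), male, params)
        resets = [e for e in traj.events if e.kind == "pool_reset"]
        assert len(resets) == 1
        discarded = resets[0].value
        consumed = scn.schedule().total_ethanol_mg
        assert 0 < discarded < consumed
        # pool state is exactly zero from the reset onward
        after = traj.times >= resets[0].time + 1e-9
        assert np.all(traj.states[after][:, I_ETOH_POOL] == 0.0)
        meals = [e for e in traj.events if e.kind == "meal"]
        assert meals and meals[0].value == 700.0

    def test_grid_outside_horizon_rejected(self, male, params, beer_schedule):
        with pytest.raises(ValueError, match="grid"):
            simulate(beer_schedule, male, params, grid=np.array([0.0, 500.0]))


class TestSimulateDays:
    def test_one_day_reduces_to_plain_simulation(self, female, params, library):
        scn = library["daily_wine_female"]
        days = simulate_days(scn.drinks, scn.meals, female, params, n_days=1)
        direct = simulate(scn.schedule(), female, params)
        np.testing.assert_allclose(
            days.final_day.states, direct.states, rtol=1e-12, atol=1e-14
        )
        assert days.peth_day_end[0] == pytest.approx(direct.states[-1, 10])

    def test_state_carries_over_and_peth_accumulates(self, female, params, library):
        scn = library["daily_wine_female"]
        days = simulate_days(scn.drinks, scn.meals, female, params, n_days=4)
        assert np.all(np.diff(days.peth_day_end) > 0)
        # far from steady state the daily increments still shrink
        assert np.all(np.diff(days.peth_day_end, 2) < 0)

    def test_rejects_nonpositive_day_count(self, female, params, library):
        scn = library["daily_wine_female"]
        with pytest.raises(ValueError, match="n_days"):
            simulate_days(scn.drinks, scn.meals, female, params, n_days=0)


class TestConsumptionCurve:
    def test_zero_dose_keeps_peth_at_basal_zero(self, male, params):
        out = peth_consumption_curve(male, params, grams_per_week=[0.0], n_days=2)
        assert out["peth_max"].iloc[0] == 0.0

    def test_doubling_dose_raises_steady_state_peth(self, male, params):
        out = peth_consumption_curve(
            male, params, grams_per_week=[60.0, 120.0, 240.0], n_days=8
        )
        ends = out["peth_day_end"].to_numpy()
        assert ends[1] > ends[0] and ends[2] > ends[1]

    def test_matches_simulate_days_for_same_pattern(self, male, params):
        grams = 224.0  # daily two-glass wine dose, in g/week
        out = peth_consumption_curve(male, params, grams_per_week=[grams], n_days=10)
        daily_volume = (grams / 7.0) / (13.5 * 7.891)
        days = simulate_days(
            [DrinkEvent(0, 20, daily_volume, 13.5)], [], male, params, n_days=10
        )
        assert out["peth_day_end"].iloc[0] == pytest.approx(
            days.peth_day_end[-1], rel=0.02
        )
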