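"""Unit tests of the pure model layer: rate laws, observables, defaults."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drinktwin import (
    Anthropometrics,
    ModelInputs,
    ModelParameters,
    ModelState,
    PARAMETER_NAMES,
    blood_volume,
    cohort_blood_volume,
    gastric_retention,
    initial_state,
    observables,
    reaction_rates,
    rhs,
)
from drinktwin.model import DEFAULT_CONSTANTS, STATE_NAMES


class TestBloodVolume:
    @pytest.mark.parametrize(
        "sex,height,weight,expected",
        [
            (0, 1.60, 60.0, 36.266856),  # female regression, direct evaluation
            (1, 1.80, 80.0, 53.190608),  # male regression, direct evaluation
        ],
    )
    def test_regression_values(self, sex, height, weight, expected):
        vb = blood_volume(Anthropometrics(sex, height, weight))
        assert vb == pytest.approx(expected, rel=1e-9)

    def test_male_exceeds_female_at_same_size(self):
        f = blood_volume(Anthropometrics(0, 1.80, 80.0))
        m = blood_volume(Anthropometrics(1, 1.80, 80.0))
        assert m > f > 0

    def test_non_binary_sex_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            Anthropometrics(2, 1.70, 70.0)

    def test_cohort_mean_is_between_members(self):
        f = Anthropometrics(0, 1.66, 60.0)
        m = Anthropometrics(1, 1.80, 80.0)
        mix = cohort_blood_volume([(f, 0.5), (m, 0.5)])
        assert blood_volume(f) < mix < blood_volume(m)
        with pytest.raises(ValueError, match="sum to 1"):
            cohort_blood_volume([(f, 0.5), (m, 0.6)])

    @given(h=st.floats(1.4, 2.1), w=st.floats(40, 150))
    @settings(max_examples=50, deadline=None)
    def test_positive_over_realistic_range(self, h, w):
        assert blood_volume(Anthropometrics(1, h, w)) > 0
        assert blood_volume(Anthropometrics(0, h, w)) > 0


class TestGastricRetention:
    def test_full_retention_at_meal_time(self):
        assert gastric_retention(0.0) == 1.0

    def test_characteristic_time(self):
        # (0.010·100)^1.86 = 1, so retention is exactly 1/e
        assert gastric_retention(100.0) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_late_tail(self):
        # direct evaluation of exp(-(3)^1.86)
        assert gastric_retention(300.0) == pytest.approx(4.4521765e-4, rel=1e-6)

    def test_negative_times_clamped(self):
        assert gastric_retention(-50.0) == 1.0

    @given(st.floats(0, 600), st.floats(0, 600))
    @settings(max_examples=100, deadline=None)
    def test_non_increasing(self, t1, t2):
        a, b = sorted((t1, t2))
        assert gastric_retention(a) >= gastric_retention(b)


class TestRhs:
    def test_rest_state_is_stationary_except_clock(self, params, male):
        y = initial_state(0.0, params).to_array()
        dy = rhs(0.0, y, ModelInputs(), params, male)
        clock = STATE_NAMES.index("time_elapsed")
        assert dy[clock] == 1.0
        dy[clock] = 0.0
        assert np.all(dy == 0.0)

    def test_liquid_emptying_rate_value(self, params, male):
        # Michaelis form in the excess volume, no caloric inhibition
        s = ModelState(vol_stomach=5.001, kcal_liquid=0.0)
        r = reaction_rates(0.0, s, ModelInputs(), params, male)
        assert r["r2"] == pytest.approx(0.60526464, rel=1e-6)

    def test_caloric_inhibition_is_exponential(self, params, male):
        s0 = ModelState(vol_stomach=5.001, kcal_liquid=0.0)
        s1 = ModelState(vol_stomach=5.001, kcal_liquid=params.kKcal)
        r0 = reaction_rates(0.0, s0, ModelInputs(), params, male)
        r1 = reaction_rates(0.0, s1, ModelInputs(), params, male)
        assert r1["r2"] / r0["r2"] == pytest.approx(math.exp(-1), rel=1e-12)

    def test_pool_fluxes_gated_without_food(self, params, male):
        s = ModelState(vol_stomach=2.0, kcal_solid=0.5, etoh_pool=5.0,
                       conc_etoh_stomach=100.0, max_kcal_solid=700.0, time_elapsed=10.0)
        r = reaction_rates(0.0, s, ModelInputs(), params, male)
        assert r["rPool_In"] == 0.0 and r["rPool_Out"] == 0.0
        fed = reaction_rates(
            0.0, s.replace(kcal_solid=500.0), ModelInputs(), params, male
        )
        assert fed["rPool_In"] > 0.0 and fed["rPool_Out"] > 0.0

    def test_nonpositive_volume_raises(self, params, male):
        y = initial_state(0.0, params).to_array()
        y[0] = -1e-6
        with pytest.raises(FloatingPointError, match="gastric volume"):
            rhs(0.0, y, ModelInputs(), params, male)

    def test_agrees_with_independent_rate_reimplementation(self, params, male):
        """Every printed rate law, re-evaluated from scratch, matches rhs."""
        rng = np.random.default_rng(7)
        c = DEFAULT_CONSTANTS
        vb = blood_volume(male)
        p = params
        for _ in range(100):
            y = rng.uniform(
                low=[0.01, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
                high=[8, 400, 900, 900, 400, 50, 2000, 3000, 60, 10, 50, 1e6],
            )
            u = ModelInputs(*rng.uniform(0, [0.2, 600, 40]))
            vol, kcal_l, maxk, kcal_s, te, pool, conc, mint, blood, ace, pe, peb = y
            r2 = p.Vmax * ((vol - 0.001) / (vol - 0.001 + p.km)) * math.exp(
                -max(0, kcal_l) / p.kKcal)
            x = 0.010 * max(0, te)
            rks = maxk * 1.88 * 0.010 * x**0.86 * math.exp(-(x**1.86))
            ksv = max(1.0, kcal_s) / 400.0
            if kcal_s <= 1 or vol < 0.002:
                rpi = rpo = 0.0
            else:
                rpi = max(0.0, conc - pool / ksv) * p.kPool_In
                rpo = pool * p.kPool_Out
            rdrink = (u.etoh_conc * 789.1 - conc) * u.vol_drink_per_time / vol * 10
            r5 = (p.Vmax_ADH * blood / (p.km_ADH + blood)
                  + p.Vmax_CYP2E1 * blood / (p.km_CYP2E1 + blood))
            expected = np.array([
                u.vol_drink_per_time * 10 - r2,
                u.vol_drink_per_time * u.kcal_liquid_per_vol - kcal_l * p.kKcal_clearance,
                0.0,
                -rks,
                1.0,
                rpi * vol - rpo,
                rdrink - rpi + rpo / vol,
                r2 * conc - mint * p.k3 - mint * p.k4,
                mint * p.k3 / vb - r5 * c.v_liver / vb,
                r5 - ace * p.k6,
                p.kPEth * blood - p.kPEth_bind * pe
                + max(0.0, p.kPEth_release * (peb - pe)) - p.kPEth_out * pe,
                p.kPEth_bind * pe - max(0.0, p.kPEth_release * (peb - pe)),
            ])
            got = rhs(0.0, y, u, p, male)
            np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-30)


class TestObservables:
    def test_breath_alcohol_intercept(self):
        obs = observables(ModelState())
        assert obs["yBrAC"] == pytest.approx(0.00367)
        assert obs["yEtOH"] == 0.0

    def test_acetate_unit_conversion(self):
        obs = observables(ModelState(plasma_acetate=10.2))
        assert obs["yAcetate"] == pytest.approx(1.0)

    def test_breath_alcohol_slope(self):
        obs = observables(ModelState(blood_conc=100.0))
        assert obs["yBrAC"] == pytest.approx(0.08767)

    def test_identity_outputs(self):
        s = ModelState(blood_conc=12.5, peth=44.0, vol_stomach=3.3)
        obs = observables(s)
        assert obs["yEtOH"] == 12.5
        assert obs["yPEth"] == 44.0
        assert obs["yGastricVolume"] == 3.3


class TestInitialState:
    def test_zero_basal_gives_fasted_rest(self, params):
        s = initial_state(0.0, params)
        assert s.peth == 0.0 and s.peth_bound == 0.0
        assert s.vol_stomach == pytest.approx(1.0e-3)
        assert all(
            getattr(s, n) == 0.0 for n in STATE_NAMES if n != "vol_stomach"
        )

    def test_bound_pool_quasi_equilibrium_value(self, params):
        s = initial_state(10.0, params)
        assert s.peth == 10.0
        assert s.peth_bound == pytest.approx(
            10.0 * (1.0 + params.kPEth_bind / params.kPEth_release), rel=1e-12
        )

    def test_bind_and_release_fluxes_cancel_at_start(self, params, male):
        for basal in (0.0, 3.5, 120.0):
            s = initial_state(basal, params)
            r = reaction_rates(0.0, s, ModelInputs(), params, male)
            assert r["rPEth_bound"] == pytest.approx(r["rPEth_release"], rel=1e-12, abs=1e-12)

    def test_negative_basal_rejected(self, params):
        with pytest.raises(ValueError, match="basal"):
            initial_state(-1.0, params)


class TestParameters:
    def test_defaults_inside_estimation_box(self, params):
        assert params.within_bounds()

    def test_array_round_trip(self, params):
        again = ModelParameters.from_array(params.to_array())
        assert again == params
        assert list(params.to_array()) == [getattr(params, n) for n in PARAMETER_NAMES]

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ModelParameters(Vmax=0.0)
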