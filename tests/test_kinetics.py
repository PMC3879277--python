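"""Five-level kinetics: conservation, limits, and propagator correctness."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from globlekin import (
    GlobleParameters,
    IrradiationSchedule,
    LevelState,
    acute_survival,
    class_probabilities,
    constant_rate_survival,
    evolve_schedule,
    evolve_trajectory,
    induction_rate,
    low_rate_limit_survival,
    survival_after_schedule,
    transition_rates,
)
from globlekin.kinetics import rate_matrix


class TestRates:
    def test_total_rate_is_log2_over_halflife(self, defaults):
        tr = transition_rates(defaults)
        assert tr.k_i == pytest.approx(np.log(2) / 0.5, rel=1e-12)
        assert tr.k_i == pytest.approx(1.38629, abs=1e-5)
        assert tr.k_c == pytest.approx(np.log(2) / 5.0, rel=1e-12)

    def test_rates_split_by_lethality(self, defaults):
        tr = transition_rates(defaults)
        assert tr.m_i == pytest.approx(defaults.eps_i * tr.k_i)
        assert tr.r_i + tr.m_i == pytest.approx(tr.k_i)
        lethal_only = GlobleParameters(eps_i=0.01, eps_c=1.0, hlt_i=0.5)
        tr2 = transition_rates(lethal_only)
        assert tr2.r_c == 0.0 and tr2.m_c == pytest.approx(tr2.k_c)

    @pytest.mark.parametrize("rate, expected", [(0.0, 0.0), (1.0, 0.01), (90.0, 0.9)])
    def test_induction_rate(self, defaults, rate, expected):
        assert induction_rate(rate, defaults) == pytest.approx(expected, rel=1e-12)

    def test_negative_dose_rate_rejected(self, defaults):
        with pytest.raises(ValueError):
            induction_rate(-1.0, defaults)


class TestEvolution:
    def test_zero_dose_schedule_leaves_state_unchanged(self, defaults):
        sched = IrradiationSchedule.from_segments([(2.0, 0.0)])
        end = evolve_schedule(sched, defaults, initial=LevelState.pristine())
        assert end.f0 == pytest.approx(1.0, abs=1e-14)

    def test_conservation_along_trajectory(self, defaults):
        sched = IrradiationSchedule.from_segments([(0.5, 10.0), (1.0, 0.0), (0.1, 50.0)])
        _, states = evolve_trajectory(sched, defaults, points_per_segment=30)
        sums = states.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) < 1e-8
        assert states.min() > -1e-10 and states.max() < 1 + 1e-10

    def test_lethal_levels_monotone_non_decreasing(self, defaults):
        sched = IrradiationSchedule.from_segments([(1.0, 8.0), (5.0, 0.0)])
        _, states = evolve_trajectory(sched, defaults, points_per_segment=40)
        assert np.all(np.diff(states[:, 3]) >= -1e-12)
        assert np.all(np.diff(states[:, 4]) >= -1e-12)

    def test_propagator_matches_adaptive_integrator(self, defaults):
        # independent route: solve the same linear system with solve_ivp
        dose, rate = 6.0, 2.0
        T = dose / rate
        A = rate_matrix(rate, defaults)
        sol = solve_ivp(
            lambda t, y: A @ y,
            (0.0, T),
            [1.0, 0.0, 0.0, 0.0, 0.0],
            method="Radau",
            rtol=1e-10,
            atol=1e-12,
        )
        end = evolve_schedule(IrradiationSchedule.constant_rate(dose, rate), defaults)
        assert np.allclose(end.as_array(), sol.y[:, -1], atol=1e-8)

    def test_high_rate_limit_reaches_poisson_occupations(self, defaults):
        # at extreme dose rate repair cannot act: (f0, fi, fc) are the
        # acute Poisson class probabilities
        dose = 5.0
        end = evolve_schedule(
            IrradiationSchedule.constant_rate(dose, 1e7), defaults
        )
        p0, p1, pm = class_probabilities(
            defaults.dsb_yield * dose / defaults.n_domains
        )
        assert end.f0 == pytest.approx(p0, abs=1e-6)
        assert end.fi == pytest.approx(p1, abs=1e-6)
        assert end.fc == pytest.approx(pm, abs=1e-6)

    def test_pulse_equals_high_rate_continuous(self, defaults):
        dose = 4.0
        pulsed = evolve_schedule(IrradiationSchedule.acute(dose), defaults)
        fast = evolve_schedule(
            IrradiationSchedule.constant_rate(dose, 1e9), defaults
        )
        assert np.allclose(pulsed.as_array(), fast.as_array(), atol=1e-8)

    def test_semigroup_segment_splitting(self, defaults):
        whole = evolve_schedule(
            IrradiationSchedule.from_segments([(2.0, 3.0)]), defaults
        )
        split = evolve_schedule(
            IrradiationSchedule.from_segments([(0.7, 3.0), (1.3, 3.0)]), defaults
        )
        assert np.allclose(whole.as_array(), split.as_array(), atol=1e-12)

    def test_invalid_initial_state_rejected(self, defaults):
        bad = LevelState(0.5, 0.1, 0.1, 0.1, 0.1)  # sums to 0.9
        with pytest.raises(ValueError, match="sum to 1"):
            evolve_schedule(IrradiationSchedule.acute(1.0), defaults, initial=bad)


class TestSurvival:
    def test_empty_schedule_full_survival(self, defaults):
        sched = IrradiationSchedule(elements=())
        assert survival_after_schedule(sched, defaults) == 1.0

    @pytest.mark.parametrize("dose", [1.0, 5.0, 10.0])
    def test_single_pulse_equals_static_survival(self, defaults, dose):
        s = survival_after_schedule(IrradiationSchedule.acute(dose), defaults)
        assert s == pytest.approx(acute_survival(dose, defaults), rel=1e-14)

    @pytest.mark.parametrize("dose", [1.0, 2.0, 4.0])
    def test_fast_delivery_approaches_acute(self, defaults, dose):
        s = constant_rate_survival(dose, 1e6, defaults)
        assert np.log(s) == pytest.approx(
            np.log(acute_survival(dose, defaults)), rel=1e-6
        )

    def test_zero_dose_survival_is_one(self, defaults):
        assert constant_rate_survival(0.0, 1.0, defaults) == 1.0

    def test_zero_rate_with_dose_rejected(self, defaults):
        with pytest.raises(ValueError, match="low"):
            IrradiationSchedule.constant_rate(5.0, 0.0)

    def test_survival_non_decreasing_with_protraction_on_all_fixtures(
        self, all_fixture_sets
    ):
        rates = np.array([90.0, 24.0, 8.4, 4.56, 0.96, 0.29, 0.06])
        for params in all_fixture_sets:
            for dose in (2.0, 6.0):
                s = np.array(
                    [constant_rate_survival(dose, r, params) for r in rates]
                )
                assert np.all(np.diff(s) >= -1e-12), params.name


class TestLowRateLimit:
    def test_zero_dose(self, defaults):
        assert low_rate_limit_survival(0.0, 0.01, defaults) == 1.0

    @pytest.mark.parametrize("dose", [1.0, 2.0, 5.0])
    def test_matches_kinetics_with_clustered_pathway_suppressed(self, defaults, dose):
        # oracle: the full five-level system with eps_c = 0 at a vanishing
        # dose rate reduces to the isolated-only closed form
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # eps_i > eps_c is deliberate here
            suppressed = defaults.with_updates(eps_c=0.0)
        s_reduced = low_rate_limit_survival(dose, 1e-3, defaults)
        s_full = constant_rate_survival(dose, 1e-3, suppressed)
        assert np.log(s_reduced) == pytest.approx(np.log(s_full), rel=1e-6)

    def test_first_order_coefficient_is_eps_i_yield(self, defaults):
        h = 1e-4
        slope = -np.log(low_rate_limit_survival(h, 0.01, defaults)) / h
        assert slope == pytest.approx(defaults.eps_i * defaults.dsb_yield, rel=1e-4)

    def test_second_order_coefficient_negative(self, defaults):
        # survival curves bend slightly upwards at very low dose rates
        h = 0.5
        g = lambda d: -np.log(low_rate_limit_survival(d, 0.01, defaults))
        c2 = (g(2 * h) - 2 * g(h)) / (2 * h**2)
        assert c2 < 0.0
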