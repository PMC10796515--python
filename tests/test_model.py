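"""Tumour-model dynamics: initial composition, dose transfers, smooth
integration accuracy, and the standard schedule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import gtvpredict as gp
from gtvpredict.model import MeasurementTimes

TINY = 1e-12


def params(lam=0.1, K=2.0, gamma=0.25, zeta=0.1, eta=0.05, phi0=0.2):
    return gp.ModelParams(lam=lam, K=K, gamma=gamma, zeta=zeta, eta=eta, phi0=phi0)


class TestInitialState:
    @pytest.mark.parametrize(
        "phi0, expected",
        [(0.2, (0.8, 0.2)), (1e-9, (1.0 - 1e-9, 1e-9)), (0.5, (0.5, 0.5))],
    )
    def test_composition(self, phi0, expected):
        st0 = gp.initial_state(phi0)
        assert (st0.L, st0.N) == pytest.approx(expected)
        assert st0.V == pytest.approx(1.0)

    @pytest.mark.parametrize("phi0", [0.0, 1.0, -0.3, 2.0])
    def test_domain(self, phi0):
        with pytest.raises(ValueError):
            gp.initial_state(phi0)


class TestApplyDose:
    def test_transfer(self):
        st0 = gp.TumourState(L=0.8, N=0.2)
        st1 = gp.apply_dose(st0, 0.25)
        assert (st1.L, st1.N) == pytest.approx((0.6, 0.4))

    def test_small_gamma_identity(self):
        st0 = gp.TumourState(L=0.7, N=0.1)
        st1 = gp.apply_dose(st0, 1e-14)
        assert (st1.L, st1.N) == pytest.approx((st0.L, st0.N), rel=1e-12)

    @given(
        L=st.floats(0.0, 10.0),
        N=st.floats(0.0, 10.0),
        gamma=st.floats(1e-6, 1 - 1e-6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_volume_conserved(self, L, N, gamma):
        st1 = gp.apply_dose(gp.TumourState(L=L, N=N), gamma)
        assert st1.L + st1.N == pytest.approx(L + N, rel=1e-14, abs=1e-14)
        assert st1.L >= 0 and st1.N >= 0

    @pytest.mark.parametrize("gamma", [0.0, 1.0, -0.5, 1.5])
    def test_domain(self, gamma):
        with pytest.raises(ValueError):
            gp.apply_dose(gp.TumourState(L=1.0, N=0.0), gamma)


class TestIntegrateSmooth:
    def test_logistic_closed_form(self):
        # with negligible necrosis the living compartment is pure logistic
        p = params(lam=0.1, K=2.0, gamma=0.5, zeta=TINY, eta=TINY, phi0=TINY)
        out = gp.integrate_smooth(gp.TumourState(L=1.0, N=0.0), p, 0.0, 7.0)
        exact = 2.0 / (1.0 + np.exp(-0.7))
        assert out.L == pytest.approx(exact, rel=1e-8)

    def test_necrotic_linear_decay(self):
        # with no living cells, N decays exponentially at rate zeta
        p = params(zeta=0.3, phi0=0.4)
        out = gp.integrate_smooth(gp.TumourState(L=0.0, N=0.4), p, 0.0, 10.0)
        assert out.N == pytest.approx(0.4 * np.exp(-3.0), rel=1e-10)
        assert out.L == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reference_integrator_agreement(self, seed, prior):
        """The exponential-integrator advance matches a tight-tolerance
        adaptive Runge-Kutta reference to 1e-8 relative."""
        theta = prior.sample(1, np.random.default_rng(seed))[0]
        p = gp.ModelParams.from_log(theta)
        y0 = [1.0 - p.phi0, p.phi0]

        def rhs(t, y):
            L, N = y
            return [
                p.lam * L * (1 - L / p.K) - p.eta * L,
                p.eta * L - p.zeta * N,
            ]

        sol = solve_ivp(
            rhs, (0.0, 14.0), y0, rtol=1e-12, atol=1e-14, dense_output=True,
            method="LSODA",
        )
        out = gp.integrate_smooth(gp.TumourState(*y0), p, 0.0, 14.0)
        ref_L, ref_N = sol.sol(14.0)
        assert out.L == pytest.approx(ref_L, rel=1e-8, abs=1e-12)
        assert out.N == pytest.approx(ref_N, rel=1e-8, abs=1e-12)

    def test_time_order(self):
        with pytest.raises(ValueError):
            gp.integrate_smooth(gp.TumourState(1.0, 0.0), params(), 5.0, 1.0)


class TestSimulate:
    def test_matches_stepwise_composition(self, standard):
        """simulate == alternating integrate_smooth / apply_dose by hand."""
        schedule, meas = standard
        p = params()
        traj = gp.simulate(p, schedule, meas.times)
        state = gp.initial_state(p.phi0)
        t = 0.0
        expected = {}
        events = sorted(
            set(schedule.dose_times.tolist()) | set(meas.times.tolist())
        )
        for te in events:
            state = gp.integrate_smooth(state, p, t, te)
            t = te
            if te in schedule.dose_times:
                state = gp.apply_dose(state, p.gamma)
            if te in meas.times:
                expected[te] = (state.L, state.N)
        for k, tk in enumerate(meas.times):
            assert traj.L[k] == pytest.approx(expected[tk][0], rel=1e-10)
            assert traj.N[k] == pytest.approx(expected[tk][1], rel=1e-10)

    def test_volume_continuous_across_doses(self, standard):
        """V just before a dose equals V at the dose instant (conservation)."""
        schedule, _ = standard
        p = params(gamma=0.6)
        eps = 1e-9
        t_dose = schedule.dose_times
        before = gp.simulate(p, schedule, t_dose - eps).V
        at = gp.simulate(p, schedule, t_dose).V
        np.testing.assert_allclose(at, before, rtol=1e-7)

    def test_dose_instant_reports_post_dose_state(self, standard):
        schedule, _ = standard
        p = params(gamma=0.5)
        t1 = schedule.dose_times[0]
        traj = gp.simulate(p, schedule, np.array([t1]))
        pre = gp.simulate(p, gp.DoseSchedule(dose_times=np.empty(0)), np.array([t1]))
        assert traj.L[0] == pytest.approx(0.5 * pre.L[0], rel=1e-10)

    def test_grid_splitting_invariance(self, standard, rng):
        schedule, meas = standard
        p = params(zeta=2.0, eta=1.5)
        extra = np.sort(rng.uniform(0.0, 56.0, size=17))
        grid = np.unique(np.concatenate([meas.times, extra]))
        coarse = gp.simulate(p, schedule, meas.times).V
        fine = gp.simulate(p, schedule, grid).V
        idx = np.searchsorted(grid, meas.times)
        np.testing.assert_allclose(fine[idx], coarse, rtol=1e-8)

    def test_gamma_limit_schedule_independence(self, standard):
        schedule, meas = standard
        p = params(gamma=1e-13)
        empty = gp.DoseSchedule(dose_times=np.empty(0))
        with_doses = gp.simulate(p, schedule, meas.times).V
        without = gp.simulate(p, empty, meas.times).V
        np.testing.assert_allclose(with_doses, without, rtol=1e-9)

    def test_single_dose_pure_transfer_keeps_v_constant(self):
        # no growth, necrosis or decay: dosing only moves volume internally
        p = params(lam=TINY, gamma=0.4, zeta=TINY, eta=TINY, phi0=0.3)
        sched = gp.DoseSchedule(dose_times=np.array([1.0]))
        traj = gp.simulate(p, sched, np.array([0.0, 0.5, 1.0, 2.0, 5.0]))
        np.testing.assert_allclose(traj.V, 1.0, rtol=1e-9)

    def test_nonnegative_compartments(self, prior):
        thetas = prior.sample(20, np.random.default_rng(3))
        schedule, meas = gp.standard_schedule()
        for theta in thetas:
            traj = gp.simulate(gp.ModelParams.from_log(theta), schedule, meas.times)
            assert np.all(traj.L >= 0) and np.all(traj.N >= 0)

    def test_negative_obs_time_rejected(self, standard):
        schedule, _ = standard
        with pytest.raises(ValueError):
            gp.simulate(params(), schedule, np.array([-1.0, 5.0]))


class TestStandardSchedule:
    def test_six_week_pattern(self):
        schedule, meas = gp.standard_schedule(start_day=14.0, weeks=6)
        assert schedule.n_doses == 30
        assert schedule.dose_times[0] == 14.0
        assert schedule.dose_times[-1] == 53.0
        assert meas.classification_times.size == 7
        np.testing.assert_array_equal(
            meas.classification_times, [14, 21, 28, 35, 42, 49, 53]
        )
        assert 0.0 in meas.times and 0.0 not in meas.classification_times

    def test_one_week_from_day_zero(self):
        schedule, meas = gp.standard_schedule(start_day=0.0, weeks=1)
        np.testing.assert_array_equal(schedule.dose_times, [0, 1, 2, 3, 4])
        np.testing.assert_array_equal(meas.classification_times, [0, 4])

    def test_weeks_domain(self):
        with pytest.raises(ValueError):
            gp.standard_schedule(weeks=0)


class TestModelParams:
    def test_log_round_trip(self):
        p = params()
        theta = p.to_log()
        np.testing.assert_allclose(
            gp.ModelParams.from_log(theta).to_log(), theta, rtol=0, atol=1e-13
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lam": -0.1},
            {"gamma": 1.2},
            {"phi0": 1.0},
            {"K": 0.0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            params(**kwargs)


def test_measurement_times_alignment():
    with pytest.raises(ValueError):
        MeasurementTimes(times=np.array([0.0, 1.0]), is_classification=np.array([True]))
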