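"""Deterministic/diffusion model representations and their invariants."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

import mrnakinetics as mk
from mrnakinetics.models import (
    _ode_solution_raw,
    em_ensemble,
    em_ensemble_qv,
    moment_solution,
)
from mrnakinetics.types import ExperimentParams, InsufficientDataError, InvalidParameterError, KineticParams

KP = KineticParams(0.2, 0.32, 0.01)
EP = ExperimentParams(m0=240, t0=0.96, scale=1.8, offset=6.5)


class TestOdeSolution:
    def test_initial_condition_and_pre_release(self):
        x1, x2 = mk.ode_solution(np.array([0.5, 0.96]), KP, EP)
        assert (x1[0], x2[0]) == (0.0, 0.0)
        assert (x1[1], x2[1]) == (240.0, 0.0)

    @pytest.mark.parametrize("th1,th3", [(0.2, 0.01), (0.11, 0.03), (1.5, 0.4)])
    def test_degradation_rate_swap_leaves_x2_unchanged(self, th1, th3):
        t = np.linspace(1, 30, 100)
        kp = KineticParams(th1, 0.32, th3)
        _, x2a = mk.ode_solution(t, kp, EP)
        _, x2b = mk.ode_solution(t, kp.swapped(), EP)
        assert np.array_equal(x2a, x2b)

    def test_against_numeric_integrator(self):
        """Closed form agrees with adaptive integration of the rate ODEs."""
        ep = ExperimentParams(m0=240, t0=0.0, scale=1.8, offset=6.5)

        def rhs(_t, x):
            return [-KP.theta1 * x[0], KP.theta2 * x[0] - KP.theta3 * x[1]]

        sol = solve_ivp(rhs, (0, 10), [240.0, 0.0], rtol=1e-11, atol=1e-12)
        x1, x2 = mk.ode_solution(10.0, KP, ep)
        assert x2 == pytest.approx(sol.y[1, -1], rel=1e-8)
        assert x1 == pytest.approx(sol.y[0, -1], rel=1e-8)

    def test_equal_rates_branch_is_the_limit(self):
        t = np.linspace(0.5, 30, 50)
        _, x_lim = _ode_solution_raw(t, 0.1, 0.3, 0.1, 200.0, 0.0)
        _, x_gen = _ode_solution_raw(t, 0.1, 0.3, 0.1 + 1e-6, 200.0, 0.0)
        assert np.max(np.abs(x_gen - x_lim) / x_lim) < 1e-4

    def test_scale_theta2_m0_product_invariance(self):
        """The noise-free signal depends on (scale, theta2, m0) only via
        their product."""
        t = np.linspace(1, 30, 60)
        base = (KP.theta2, EP.m0, EP.scale)
        variants = [
            (KP.theta2 * 4, EP.m0 / 4, EP.scale),
            (KP.theta2, EP.m0 / 3, EP.scale * 3),
        ]
        _, x2 = mk.ode_solution(t, KP, EP)
        ref = EP.scale * x2 + EP.offset
        for th2, m0, sc in variants:
            ep = ExperimentParams(m0=m0, t0=EP.t0, scale=sc, offset=EP.offset)
            _, x2v = mk.ode_solution(t, KineticParams(KP.theta1, th2, KP.theta3), ep)
            assert np.allclose(sc * x2v + EP.offset, ref, rtol=1e-12)


class TestEulerMaruyama:
    def test_origin_is_absorbing(self):
        ep = ExperimentParams(m0=0, t0=0.0, scale=1.0, offset=1.0)
        path = mk.em_simulate(KP, ep, dt=0.01, t_end=2.0, seed=0)
        assert np.all(path.x1 == 0) and np.all(path.x2 == 0)

    def test_invalid_step_raises(self):
        with pytest.raises(InvalidParameterError):
            mk.em_simulate(KP, EP, dt=0.0, t_end=10.0, seed=0)

    def test_determinism_and_nonnegativity(self):
        a = mk.em_simulate(KP, EP, dt=0.01, t_end=10.0, seed=5)
        b = mk.em_simulate(KP, EP, dt=0.01, t_end=10.0, seed=5)
        assert np.array_equal(a.x1, b.x1) and np.array_equal(a.x2, b.x2)
        assert np.all(a.x1 >= 0) and np.all(a.x2 >= 0)

    def test_ensemble_signal_mean_matches_moment_system(self):
        """Ensemble mean of scale*x2+offset tracks M01 at probe times."""
        probes = np.array([2.0, 5.0, 10.0, 20.0, 30.0])
        _, o2 = em_ensemble(KP, EP, n_paths=600, record_times=probes, seed=7)
        sig = EP.scale * o2 + EP.offset
        mom = moment_solution(np.concatenate([[EP.t0], probes]), KP, EP)
        m01 = mom.M01.to_numpy()[1:]
        se = sig.std(axis=0, ddof=1) / np.sqrt(sig.shape[0])
        assert np.all(np.abs(sig.mean(axis=0) - m01) < 3.0 * se)


class TestTransform:
    def test_fixed_points(self):
        path = mk.StatePath(np.array([0.96, 2.0]), np.array([240.0, 0.0]),
                            np.array([0.0, 0.0]), "deterministic")
        tp = mk.transform_path(path, EP)
        assert tp.z1[0] == 1.0 and tp.z2[0] == EP.offset
        assert tp.z1[1] == 0.0 and tp.z2[1] == EP.offset

    def test_round_trip(self):
        path = mk.em_simulate(KP, EP, dt=0.05, t_end=10.0, seed=2)
        back = mk.untransform_path(mk.transform_path(path, EP), EP)
        assert np.allclose(back.x1, path.x1, atol=1e-12)
        assert np.allclose(back.x2, path.x2, atol=1e-12)

    def test_requires_positive_m0(self):
        path = mk.em_simulate(KP, EP, dt=0.05, t_end=5.0, seed=2)
        with pytest.raises(InvalidParameterError):
            mk.transform_path(path, ExperimentParams(m0=0, t0=0, scale=1, offset=1))


class TestMoments:
    def test_initial_conditions(self):
        mom = moment_solution(np.array([EP.t0]), KP, EP)
        row = mom.iloc[0]
        assert row.M10 == 1.0 and row.M01 == EP.offset
        assert row.M20 == 1.0 and row.M02 == EP.offset**2 and row.M11 == EP.offset

    def test_first_moments_reproduce_ode_signal(self):
        grid = np.linspace(EP.t0, 30.0, 40)
        mom = moment_solution(grid, KP, EP)
        x1, x2 = mk.ode_solution(grid, KP, EP)
        assert np.allclose(mom.M10, x1 / EP.m0, atol=1e-7)
        assert np.allclose(mom.M01, EP.scale * x2 + EP.offset, atol=1e-5)

    def test_second_moments_dominate_squared_means(self):
        grid = np.linspace(EP.t0, 30.0, 40)
        mom = moment_solution(grid, KP, EP)
        assert np.all(mom.M20 >= mom.M10**2 - 1e-9)
        assert np.all(mom.M02 >= mom.M01**2 - 1e-9)

    def test_signal_variance_matches_em_ensemble(self):
        probes = np.array([5.0, 15.0, 30.0])
        _, o2 = em_ensemble(KP, EP, n_paths=800, record_times=probes, seed=13)
        sig = EP.scale * o2 + EP.offset
        mom = moment_solution(np.concatenate([[EP.t0], probes]), KP, EP)
        var_model = (mom.M02 - mom.M01**2).to_numpy()[1:]
        rng = np.random.default_rng(0)
        boot = np.array([
            sig[rng.integers(0, len(sig), len(sig))].var(axis=0, ddof=1)
            for _ in range(200)
        ])
        se = boot.std(axis=0, ddof=1)
        assert np.all(np.abs(sig.var(axis=0, ddof=1) - var_model) < 3.0 * se)


class TestQuadraticVariation:
    def test_basic_values(self):
        assert mk.quadratic_variation(np.array([3.0, 3.0, 3.0])) == 0.0
        assert mk.quadratic_variation(np.array([0.0, 1.0, 0.0])) == 2.0
        with pytest.raises(InsufficientDataError):
            mk.quadratic_variation(np.array([1.0]))

    def test_swapped_rates_separate_in_signal_variation(self):
        """Low mRNA- / high protein-degradation gives larger within-path
        variation of the signal than the swapped combination, although both
        share the same deterministic signal."""
        ep = ExperimentParams(m0=200, t0=0.0, scale=17.5, offset=8.9)
        q_low_th1 = em_ensemble_qv(KineticParams(0.03, 0.1, 0.11), ep, 100, seed=1)
        q_high_th1 = em_ensemble_qv(KineticParams(0.11, 0.1, 0.03), ep, 100, seed=2)
        res = stats.mannwhitneyu(q_low_th1, q_high_th1, alternative="greater")
        assert res.pvalue < 0.01

    def test_product_constrained_regimes_separate(self):
        """Three (m0, theta2, scale) combinations with the same product
        have distinguishable signal quadratic variation (the deterministic
        signal is identical for all three)."""
        combos = [(200.0, 0.1, 17.5), (200.0, 0.4, 4.375), (50.0, 0.4, 17.5)]
        qvs = []
        for i, (m0, th2, sc) in enumerate(combos):
            assert m0 * th2 * sc == pytest.approx(350.0)
            ep = ExperimentParams(m0=m0, t0=0.0, scale=sc, offset=8.9)
            qvs.append(em_ensemble_qv(KineticParams(0.11, th2, 0.03), ep, 100, seed=30 + i))
        assert stats.kruskal(*qvs).pvalue < 0.01
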