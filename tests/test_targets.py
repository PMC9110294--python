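"""Posterior target densities: values, symmetries and gradients."""

import numpy as np
import pytest
from scipy import stats

import mrnakinetics as mk
from mrnakinetics.priors import default_priors
from mrnakinetics.targets import (
    _prior_logpdf_sum,
    em_transition_logpdf,
    make_ode_target,
    make_sde_target,
    ode_log_posterior,
    sde_log_target,
)
from mrnakinetics.types import InvalidParameterError, ObservationSeries


def _random_ode_params(rng):
    return dict(
        theta1=rng.uniform(0.01, 1.0), theta2=rng.uniform(0.01, 1.0),
        theta3=rng.uniform(0.005, 0.5), m0=rng.uniform(50, 500),
        scale=rng.uniform(0.3, 10), offset=rng.uniform(1, 20),
        sigma=rng.uniform(0.01, 2), t0=rng.uniform(0.05, 5),
    )


class TestEmTransitionDensity:
    def test_matches_independent_normal_densities(self):
        """The one-step transition term is the product of two univariate
        normals with mean state+drift*dt and variance diffusion^2*dt."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            th = rng.uniform(0.01, 1.0, size=3)
            x = rng.uniform(1, 300, size=2)
            xn = x + rng.normal(0, 3, size=2)
            dt = rng.uniform(0.05, 0.5)
            v1 = th[0] * x[0] * dt
            v2 = (th[1] * x[0] + th[2] * x[1]) * dt
            ref = (
                stats.norm.logpdf(xn[0], x[0] - th[0] * x[0] * dt, np.sqrt(v1))
                + stats.norm.logpdf(xn[1], x[1] + (th[1] * x[0] - th[2] * x[1]) * dt, np.sqrt(v2))
            )
            assert em_transition_logpdf(xn, x, th, dt) == pytest.approx(ref, abs=1e-10)


class TestOdePosterior:
    def test_index_of_first_post_release_frame(self):
        grid = np.arange(181) / 6.0
        assert mk.first_index_at_or_after(grid, 0.96) == 6  # 7th frame, t=1.0
        assert grid[6] == pytest.approx(1.0)

    def test_pre_release_term_at_zero_residual(self):
        """A background frame observed exactly at the offset with sigma=1
        contributes -0.5*log(2*pi) to the log likelihood."""
        off = 4.0
        data = ObservationSeries(np.array([0.0, 1.0]), np.array([off, off]))
        params = dict(theta1=0.1, theta2=0.0, theta3=0.1, m0=10.0, scale=1.0,
                      offset=off, sigma=1.0, t0=0.9)
        lp = ode_log_posterior(data, params)
        priors = default_priors("ode")
        loglik = lp - _prior_logpdf_sum(priors, params)
        # theta2 = 0: the post-release signal also equals the offset
        assert loglik == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)), abs=1e-12)

    def test_swap_symmetry_at_random_points(self, fixture_noise_free):
        _, _, obs = fixture_noise_free
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = _random_ode_params(rng)
            q = dict(p, theta1=p["theta3"], theta3=p["theta1"])
            assert ode_log_posterior(obs, p) == pytest.approx(
                ode_log_posterior(obs, q), abs=1e-9
            )

    def test_t0_beyond_data_rejected(self, fixture_noise_free):
        _, _, obs = fixture_noise_free
        p = _random_ode_params(np.random.default_rng(0))
        p["t0"] = 31.0
        with pytest.raises(InvalidParameterError):
            ode_log_posterior(obs, p)

    def test_analytic_gradient_matches_finite_differences(self, fixture_noise_free):
        _, _, obs = fixture_noise_free
        target = make_ode_target(obs)
        rng = np.random.default_rng(7)
        for _ in range(20):
            u = target.from_natural(_random_ode_params(rng))
            lp_a, g_a = target.logp_grad(u)
            lp_f, g_f = target.logp_grad_fd(u)
            assert lp_a == pytest.approx(lp_f, rel=1e-9)
            assert np.allclose(g_a, g_f, rtol=1e-3, atol=1e-4 * np.abs(g_f).max())


class TestSdeTarget:
    def test_not_swap_symmetric(self, fixture_noise_free):
        _, _, obs = fixture_noise_free
        pars = dict(theta1=0.25, theta2=0.3, theta3=0.02, m0=200.0, scale=2.0)
        tgt = make_sde_target(obs, 0.96, noise_free=True)
        tau = tgt.tt - 0.96
        x1 = np.maximum(200 * np.exp(-0.25 * tau), 1e-2)
        lp = sde_log_target(obs, pars, x1, 0.96)
        swapped = dict(pars, theta1=pars["theta3"], theta3=pars["theta1"])
        lp_s = sde_log_target(obs, swapped, x1, 0.96)
        assert abs(lp - lp_s) > 1.0

    def test_noise_free_variant_excludes_sigma_and_offset(self, fixture_noise_free):
        _, ep, obs = fixture_noise_free
        tgt = make_sde_target(obs, 0.96, noise_free=True)
        assert tgt.param_names == ["theta1", "theta2", "theta3", "m0", "scale"]
        assert tgt.offset == obs.y[0] == ep.offset

    def test_transition_terms_match_independent_density(self, fixture_noise_free):
        """Differences of the joint target across latent paths equal the
        corresponding differences of independently computed transition
        densities (all other terms cancel)."""
        _, _, obs = fixture_noise_free
        t0 = 0.96
        tgt = make_sde_target(obs, t0, noise_free=True)
        pars = dict(theta1=0.2, theta2=0.32, theta3=0.01, m0=240.0, scale=1.8)
        tau = tgt.tt - t0
        rng = np.random.default_rng(4)
        x1a = np.maximum(240 * np.exp(-0.2 * tau), 1e-2)
        x1b = x1a * np.exp(0.1 * rng.standard_normal(len(x1a)))
        x2 = (tgt.yy - tgt.offset) / pars["scale"]
        theta = (pars["theta1"], pars["theta2"], pars["theta3"])

        def manual(x1):
            lp = em_transition_logpdf(
                (x1[0], x2[0]), (pars["m0"], 0.0), theta, tgt.dt0
            )
            for i in range(len(x1) - 1):
                lp += em_transition_logpdf(
                    (x1[i + 1], x2[i + 1]), (x1[i], x2[i]), theta, tgt.dts[i]
                )
            return lp

        d_impl = sde_log_target(obs, pars, x1b, t0) - sde_log_target(obs, pars, x1a, t0)
        d_manual = manual(x1b) - manual(x1a)
        assert d_impl == pytest.approx(d_manual, rel=1e-9)

    def test_point_mass_initial_state(self):
        """When a frame falls exactly on t0, the state there is (m0, 0) and
        the latent path starts at the following frame."""
        kp = mk.KineticParams(0.2, 0.32, 0.01)
        ep = mk.ExperimentParams(m0=240, t0=1.0, scale=1.8, offset=6.5)
        path = mk.gillespie_simulate(kp, ep, 30.0, seed=2)
        grid = np.arange(181) / 6.0
        obs = mk.observe(path, ep, grid, seed=3)
        tgt = make_sde_target(obs, 1.0, noise_free=True)
        assert tgt.j0 == mk.first_index_at_or_after(grid, 1.0) + 1
        assert tgt.dt0 == pytest.approx(1.0 / 6.0)
        pars = dict(theta1=0.2, theta2=0.32, theta3=0.01, m0=240.0, scale=1.8)
        x1 = np.maximum(240 * np.exp(-0.2 * (tgt.tt - 1.0)), 1e-2)
        z = tgt.pack(pars, x1)
        lp, grad = tgt.logp_grad(z)
        assert np.isfinite(lp) and np.all(np.isfinite(grad))

    @pytest.mark.parametrize("noise_free", [True, False])
    def test_analytic_gradient_matches_finite_differences(
        self, noise_free, fixture_noise_free, fixture_noisy
    ):
        _, _, obs = fixture_noise_free if noise_free else fixture_noisy
        t0 = 0.96
        tgt = make_sde_target(obs, t0, noise_free=noise_free)
        pars = dict(theta1=0.25, theta2=0.3, theta3=0.02, m0=200.0, scale=2.0)
        if not noise_free:
            pars.update(offset=6.4, sigma=0.05)
        tau = tgt.tt - t0
        rng = np.random.default_rng(11)
        x1 = np.maximum(200 * np.exp(-0.25 * tau), 1e-2)
        x1 = x1 * np.exp(0.03 * rng.standard_normal(len(x1)))
        if noise_free:
            z = tgt.pack(pars, x1)
        else:
            x2 = np.maximum((tgt.yy - 6.4) / 2.0, 0.1)
            z = tgt.pack(pars, x1, x2)
        lp, g = tgt.logp_grad(z)
        h = 1e-6
        idx = np.linspace(0, tgt.dim - 1, 30).astype(int)
        for i in idx:
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] -= h
            fd = (tgt.logp_grad(zp)[0] - tgt.logp_grad(zm)[0]) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_derived_products_equal_per_draw_products(self, fixture_noise_free):
        """Columns appended by the fit are exact per-draw products."""
        _, _, obs = fixture_noise_free
        cfg = mk.FitConfig(model="ode", n_chains=1, n_iter=60, warmup_frac=0.5,
                           seed=3, max_treedepth=4)
        draws = mk.fit(obs, cfg)
        df = draws.df
        assert np.allclose(df.theta2_m0_scale, df.theta2 * df.m0 * df.scale, rtol=1e-12)
        assert np.allclose(df.theta2_m0, df.theta2 * df.m0, rtol=1e-12)


class TestCompiledKernels:
    def test_agree_with_reference_implementation(self, fixture_noise_free):
        """The compiled gradients reproduce the pure-numpy reference at
        random interior points."""
        _, _, obs = fixture_noise_free
        sde = make_sde_target(obs, 0.96, noise_free=True)
        ode = make_ode_target(obs)
        assert sde._kernel_ok and ode._kernel_ok
        rng = np.random.default_rng(2)
        pars = dict(theta1=0.25, theta2=0.3, theta3=0.02, m0=200.0, scale=2.0)
        tau = sde.tt - 0.96
        x1 = np.maximum(200 * np.exp(-0.25 * tau), 1e-2)
        z0 = sde.pack(pars, x1)
        u0 = ode.from_natural(dict(pars, offset=6.4, sigma=0.05, t0=0.9))
        for _ in range(15):
            z = z0 + 0.2 * rng.standard_normal(len(z0))
            lp_k, g_k = sde.logp_grad(z)
            lp_p, g_p = sde.logp_grad_py(z)
            assert lp_k == pytest.approx(lp_p, rel=1e-10, abs=1e-8)
            assert np.allclose(g_k, g_p, rtol=1e-9, atol=1e-7)
            u = u0 + 0.2 * rng.standard_normal(8)
            lp_k, g_k = ode.logp_grad(u)
            lp_p, g_p = ode.logp_grad_py(u)
            assert lp_k == pytest.approx(lp_p, rel=1e-10, abs=1e-7)
            assert np.allclose(g_k, g_p, rtol=1e-9, atol=1e-7)


class TestEstimateT0:
    def test_mean_of_draws(self, fixture_noise_free):
        _, _, obs = fixture_noise_free
        cfg = mk.FitConfig(model="ode", n_chains=1, n_iter=40, warmup_frac=0.5,
                           seed=3, max_treedepth=4)
        draws = mk.fit(obs, cfg)
        assert mk.estimate_t0_from_ode(draws) == pytest.approx(draws.df.t0.mean())

    def test_requires_t0_column(self, fixture_noise_free):
        _, _, obs = fixture_noise_free
        cfg = mk.FitConfig(model="sde", noise="noise_free", n_chains=1, n_iter=40,
                           warmup_frac=0.5, seed=3, max_treedepth=4, t0_fixed=0.96)
        draws = mk.fit(obs, cfg)
        with pytest.raises(KeyError):
            mk.estimate_t0_from_ode(draws)
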