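"""Log posterior targets for the ODE and latent-path SDE models.

Two layers:

* public, natural-scale densities (`ode_log_posterior`, `sde_log_target`,
  `em_transition_logpdf`) used in tests and for direct inspection;
* unconstrained-scale target factories (`make_ode_target`,
  `make_sde_target`) that return ``logp_grad`` callables for the NUTS
  engine, with log/logit transforms and their Jacobians built in.

Both targets use analytic gradients (numba-compiled hot paths in
``_kernels``, pure-numpy reference implementations kept alongside); the
8-dim ODE target additionally exposes a batched finite-difference
gradient as an independent validation route.

Observation model: log y_k ~ N(log(scale*x2(t_k) + offset), sigma^2).
SDE transition model between observation times: one Euler-Maruyama step,
i.e. two independent normals with mean = state + drift*dt and variance =
(squared diffusion)*dt.  In the noise-free variant the observation
equation is exact, so the GFP path is the deterministic function
x2(t_k) = (y_k - offset)/scale of the data and only the mRNA path remains
latent; the change of variables from x2- to y-space contributes a
-log(scale) Jacobian per collapsed observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import BRANCH_TOL
from .priors import (
    FULL_PARAM_ORDER,
    Prior,
    TruncatedNormalPrior,
    UniformPrior,
    default_priors,
    transform_for,
)
from .types import InvalidParameterError, ObservationSeries, first_index_at_or_after

LOG_2PI = float(np.log(2.0 * np.pi))

#: initial transition shorter than this is treated as a point mass at (m0, 0)
POINT_MASS_DT = 1e-12


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

def _normal_logpdf(x, mean, var):
    return -0.5 * (LOG_2PI + np.log(var)) - (x - mean) ** 2 / (2.0 * var)


def em_transition_logpdf(x_next, x_curr, theta, dt: float) -> float:
    """Euler-Maruyama Gaussian transition log density of the Langevin model.

    Product of two independent univariate normals:
    x1' ~ N(x1 - th1*x1*dt, th1*x1*dt),
    x2' ~ N(x2 + (th2*x1 - th3*x2)*dt, (th2*x1 + th3*x2)*dt).
    """
    th1, th2, th3 = theta
    x1, x2 = x_curr
    v1 = th1 * x1 * dt
    v2 = (th2 * x1 + th3 * x2) * dt
    if v1 <= 0 or v2 <= 0:
        m = np.array([x1 - th1 * x1 * dt, x2 + (th2 * x1 - th3 * x2) * dt])
        return 0.0 if np.allclose(x_next, m) else -np.inf
    l1 = _normal_logpdf(x_next[0], x1 - th1 * x1 * dt, v1)
    l2 = _normal_logpdf(x_next[1], x2 + (th2 * x1 - th3 * x2) * dt, v2)
    return float(l1 + l2)


def _prior_logpdf_sum(priors: dict[str, Prior], values: dict[str, float]) -> float:
    total = 0.0
    for name, prior in priors.items():
        lp = prior.logpdf(values[name])
        total += float(lp)
    return total


# ---------------------------------------------------------------------------
# ODE model
# ---------------------------------------------------------------------------

def ode_signal(times, th1, th2, th3, m0, scale, offset, t0):
    """Noise-free model signal scale*x2(t)+offset; equals offset before t0.

    Vectorized over leading axes of the parameters (each may be an array
    broadcastable against ``times`` with a trailing time axis).
    """
    t = np.asarray(times, dtype=float)
    tau = np.maximum(t - t0, 0.0)
    diff = th3 - th1
    safe = np.where(np.abs(diff) < BRANCH_TOL, 1.0, diff)
    general = th2 * m0 / safe * (np.exp(-th1 * tau) - np.exp(-th3 * tau))
    limit = th2 * m0 * tau * np.exp(-0.5 * (th1 + th3) * tau)
    x2 = np.where(np.abs(diff) < BRANCH_TOL, limit, general)
    return np.where(t >= t0, scale * x2 + offset, offset)


def ode_log_posterior(
    data: ObservationSeries,
    params: dict[str, float],
    priors: dict[str, Prior] | None = None,
) -> float:
    """Log posterior density (up to the evidence) of the ODE model.

    ``params`` holds theta1..theta3, m0, scale, offset, sigma, t0 on the
    natural scale.  Observations at t_k >= t0 are lognormal around the
    closed-form signal, earlier ones around the offset alone.
    """
    if priors is None:
        priors = default_priors("ode")
    t0 = params["t0"]
    if t0 >= data.times[-1]:
        raise InvalidParameterError("t0 beyond the last observation: no signal")
    sigma = params["sigma"]
    if sigma <= 0:
        return -np.inf
    g = ode_signal(
        data.times, params["theta1"], params["theta2"], params["theta3"],
        params["m0"], params["scale"], params["offset"], t0,
    )
    if np.any(g <= 0):
        return -np.inf
    ll = float(np.sum(_normal_logpdf(np.log(data.y), np.log(g), sigma**2)))
    lp = _prior_logpdf_sum(priors, params)
    return ll + lp


def _safe_exp(u):
    return np.exp(np.clip(u, -700.0, 700.0))


def _default_prior_structure(priors: dict, param_names: list[str]) -> bool:
    """True when the priors match the compiled kernels' fixed layout:
    zero-truncated normals on the first four parameters, uniforms on the
    rest."""
    try:
        for n in param_names[:4]:
            p = priors[n]
            if not (isinstance(p, TruncatedNormalPrior) and p.lower == 0.0):
                return False
        for n in param_names[4:]:
            if not isinstance(priors[n], UniformPrior):
                return False
    except KeyError:
        return False
    return True


def _batch_ode_logp(u: np.ndarray, times, logy, priors) -> np.ndarray:
    """Vectorized unconstrained-scale ODE log target for rows of ``u``."""
    u = np.atleast_2d(u)
    th1 = _safe_exp(u[:, 0])
    th2 = _safe_exp(u[:, 1])
    th3 = _safe_exp(u[:, 2])
    m0 = _safe_exp(u[:, 3])
    tr_scale = transform_for(priors["scale"])
    tr_off = transform_for(priors["offset"])
    tr_sig = transform_for(priors["sigma"])
    tr_t0 = transform_for(priors["t0"])
    scale = tr_scale.forward(u[:, 4])
    offset = tr_off.forward(u[:, 5])
    sigma = tr_sig.forward(u[:, 6])
    t0 = tr_t0.forward(u[:, 7])

    g = ode_signal(
        times[None, :], th1[:, None], th2[:, None], th3[:, None],
        m0[:, None], scale[:, None], offset[:, None], t0[:, None],
    )
    r = logy[None, :] - np.log(g)
    ll = np.sum(
        -0.5 * LOG_2PI - np.log(sigma)[:, None] - r**2 / (2.0 * sigma[:, None] ** 2),
        axis=1,
    )
    # priors: truncated-normal kernels for the rates and m0 (normalizing
    # constants dropped); uniform priors are constant inside the support
    # enforced by the transforms
    pr = 0.0
    for name, val in (("theta1", th1), ("theta2", th2), ("theta3", th3), ("m0", m0)):
        p = priors[name]
        pr = pr - (val - p.mean) ** 2 / (2.0 * p.sd**2)
    jac = (
        u[:, 0] + u[:, 1] + u[:, 2] + u[:, 3]
        + tr_scale.log_jac(u[:, 4]) + tr_off.log_jac(u[:, 5])
        + tr_sig.log_jac(u[:, 6]) + tr_t0.log_jac(u[:, 7])
    )
    out = ll + pr + jac
    return np.where(np.isfinite(out), out, -np.inf)


@dataclass
class OdeTarget:
    """Unconstrained 8-dim ODE posterior with analytic gradients.

    ``logp_grad_fd`` provides an independent batched finite-difference
    gradient of the same density for validation.
    """

    data: ObservationSeries
    priors: dict[str, Prior]
    fd_step: float = 1e-5

    def __post_init__(self):
        self.param_names = list(FULL_PARAM_ORDER)
        self.dim = 8
        self._times = np.asarray(self.data.times, dtype=float)
        self._logy = np.log(np.asarray(self.data.y, dtype=float))
        self._transforms = [
            transform_for(self.priors[name]) for name in self.param_names
        ]
        self._kernel_ok = _default_prior_structure(self.priors, self.param_names)
        if self._kernel_ok:
            self._prior_mean = np.array(
                [self.priors[n].mean for n in self.param_names[:4]]
            )
            self._prior_sd = np.array(
                [self.priors[n].sd for n in self.param_names[:4]]
            )
            self._bounds = np.array(
                [[self.priors[n].lo, self.priors[n].hi] for n in self.param_names[4:]]
            )

    def logp(self, u: np.ndarray) -> float:
        return float(_batch_ode_logp(u, self._times, self._logy, self.priors)[0])

    def logp_grad(self, u: np.ndarray):
        if self._kernel_ok:
            from ._kernels import ode_logp_grad

            return ode_logp_grad(
                np.asarray(u, dtype=float), self._times, self._logy,
                self._prior_mean, self._prior_sd, self._bounds, BRANCH_TOL,
            )
        return self.logp_grad_py(u)

    def logp_grad_py(self, u: np.ndarray):
        """Pure-numpy reference implementation of :meth:`logp_grad`."""
        trs = self._transforms
        th1, th2, th3, m0 = (_safe_exp(u[i]) for i in range(4))
        scale = trs[4].forward(u[4])
        offset = trs[5].forward(u[5])
        sigma = trs[6].forward(u[6])
        t0 = trs[7].forward(u[7])
        t = self._times
        after = t >= t0
        tau = np.where(after, t - t0, 0.0)

        # signal and its parameter sensitivities
        if abs(th1 - th3) < BRANCH_TOL:
            thm = 0.5 * (th1 + th3)
            e = np.exp(-thm * tau)
            f = tau * e
            df_dth1 = df_dth3 = -0.5 * tau**2 * e
            df_dt0 = e * (thm * tau - 1.0)
        else:
            A = np.exp(-th1 * tau)
            B = np.exp(-th3 * tau)
            d = th3 - th1
            f = (A - B) / d
            df_dth1 = (-tau * A) / d + (A - B) / d**2
            df_dth3 = (tau * B) / d - (A - B) / d**2
            df_dt0 = (th1 * A - th3 * B) / d
        x2 = th2 * m0 * f
        g = np.where(after, scale * x2 + offset, offset)
        if np.any(g <= 0) or not np.isfinite(g).all():
            return -np.inf, np.zeros(self.dim)
        r = self._logy - np.log(g)
        s2 = sigma**2
        ll = float(np.sum(-0.5 * LOG_2PI - np.log(sigma) - r**2 / (2.0 * s2)))
        c = np.where(after, r / (s2 * g), 0.0)  # dll/dg, zero before t0
        am = scale * th2 * m0  # common factor of the x2 sensitivities
        g_nat = {
            "theta1": float(np.sum(c * am * df_dth1)),
            "theta2": float(np.sum(c * scale * m0 * f)),
            "theta3": float(np.sum(c * am * df_dth3)),
            "m0": float(np.sum(c * scale * th2 * f)),
            "scale": float(np.sum(c * x2)),
            "offset": float(np.sum(r / (s2 * g))),
            "sigma": float(np.sum(-1.0 / sigma + r**2 / sigma**3)),
            "t0": float(np.sum(c * am * df_dt0)),
        }
        # truncated-normal prior kernels for the rates and m0
        lp_prior = 0.0
        for name, val in (("theta1", th1), ("theta2", th2), ("theta3", th3), ("m0", m0)):
            p = self.priors[name]
            lp_prior += -(val - p.mean) ** 2 / (2.0 * p.sd**2)
            g_nat[name] += -(val - p.mean) / p.sd**2

        grad = np.empty(self.dim)
        jac = 0.0
        for i, name in enumerate(self.param_names):
            tr = trs[i]
            grad[i] = tr.dx_du(u[i]) * g_nat[name] + tr.dlog_jac_du(u[i])
            jac += float(tr.log_jac(u[i]))
        lp = ll + lp_prior + jac
        if not np.isfinite(lp):
            return -np.inf, np.zeros(self.dim)
        return lp, grad

    def logp_grad_fd(self, u: np.ndarray):
        """Batched central finite differences (independent check route)."""
        h = self.fd_step
        batch = np.tile(u, (2 * self.dim + 1, 1))
        for i in range(self.dim):
            batch[1 + i, i] += h
            batch[1 + self.dim + i, i] -= h
        lp = _batch_ode_logp(batch, self._times, self._logy, self.priors)
        grad = (lp[1:1 + self.dim] - lp[1 + self.dim:]) / (2.0 * h)
        return lp[0], grad

    def to_natural(self, u: np.ndarray) -> dict[str, np.ndarray]:
        """Map unconstrained draws (n, 8) to natural-scale columns."""
        u = np.atleast_2d(u)
        return {
            name: tr.forward(u[:, i])
            for i, (name, tr) in enumerate(zip(self.param_names, self._transforms))
        }

    def from_natural(self, values: dict[str, float]) -> np.ndarray:
        return np.array([
            tr.inverse(values[name])
            for name, tr in zip(self.param_names, self._transforms)
        ])


# ---------------------------------------------------------------------------
# SDE model (latent-path data augmentation)
# ---------------------------------------------------------------------------

def sde_log_target(
    data: ObservationSeries,
    params: dict[str, float],
    latent_x1: np.ndarray,
    t0_fixed: float,
    latent_x2: np.ndarray | None = None,
    priors: dict[str, Prior] | None = None,
) -> float:
    """Natural-scale joint log target of parameters and latent states.

    With ``latent_x2 = None`` this is the noise-free variant: sigma and
    offset are not sampled (offset is read from the first observation) and
    the GFP path is determined by the data and ``scale``.  Otherwise both
    state components are latent and lognormal observation terms with
    ``params['sigma']`` apply at every time point.
    """
    noise_free = latent_x2 is None
    if priors is None:
        priors = default_priors("sde_noise_free" if noise_free else "sde_with_noise")
    target = make_sde_target(
        data, t0_fixed, priors,
        noise_free=noise_free,
    )
    z = target.pack(params, latent_x1, latent_x2)
    lp, _ = target.logp_grad(z)
    # undo the log/logit reparameterization so the value refers to the
    # natural-scale density (drop transform Jacobians)
    return float(lp - target.jacobian_at(z))


class SdeTarget:
    """Unconstrained latent-path SDE posterior with analytic gradients.

    Parameter block: theta1..3, m0, scale (plus offset, sigma in the
    with-noise variant) on log/logit scales; latent block: log mRNA counts
    (and log GFP counts when with noise) at the observation times from the
    first frame at or after t0 onward.
    """

    def __init__(
        self,
        data: ObservationSeries,
        t0: float,
        priors: dict[str, Prior],
        noise_free: bool = True,
        offset_fixed: float | None = None,
    ):
        self.data = data
        self.t0 = float(t0)
        self.priors = priors
        self.noise_free = noise_free
        times = np.asarray(data.times, dtype=float)
        y = np.asarray(data.y, dtype=float)
        self.k_star = first_index_at_or_after(times, self.t0)
        # point-mass handling: when t_{k*} == t0 the state there is exactly
        # (m0, 0) and the first latent frame is the next one
        if times[self.k_star] - self.t0 <= POINT_MASS_DT:
            self.j0 = self.k_star + 1
        else:
            self.j0 = self.k_star
        if self.j0 >= len(times):
            raise InvalidParameterError("no observations after t0")
        self.tt = times[self.j0:]
        self.dt0 = float(self.tt[0] - self.t0)
        self.dts = np.diff(self.tt)
        self.n_lat = len(self.tt)
        self.yy = y[self.j0:]
        self.y_all = y
        self.times_all = times
        if noise_free:
            self.offset = float(y[0]) if offset_fixed is None else float(offset_fixed)
            if np.any(self.yy < self.offset):
                raise InvalidParameterError(
                    "noise-free variant requires y_k >= offset after t0"
                )
            if self.j0 > self.k_star and abs(y[self.k_star] - self.offset) > 1e-9 * self.offset:
                raise InvalidParameterError(
                    "t_{k*} == t0 requires a zero GFP count, i.e. y_{k*} == offset"
                )
            self.param_names = ["theta1", "theta2", "theta3", "m0", "scale"]
        else:
            self.offset = None
            self.param_names = [
                "theta1", "theta2", "theta3", "m0", "scale", "offset", "sigma",
            ]
        self.transforms = [transform_for(priors[p]) for p in self.param_names]
        self.n_par = len(self.param_names)
        self.dim = self.n_par + self.n_lat * (1 if noise_free else 2)
        self._kernel_ok = noise_free and _default_prior_structure(
            priors, self.param_names
        )
        if self._kernel_ok:
            self._prior_mean = np.array([priors[n].mean for n in self.param_names[:4]])
            self._prior_sd = np.array([priors[n].sd for n in self.param_names[:4]])

    # -- packing -----------------------------------------------------------
    def pack(self, params: dict[str, float], x1: np.ndarray,
             x2: np.ndarray | None = None) -> np.ndarray:
        u = [tr.inverse(params[name]) for name, tr in zip(self.param_names, self.transforms)]
        z = np.concatenate([u, np.log(np.asarray(x1, dtype=float))])
        if not self.noise_free:
            if x2 is None:
                raise ValueError("with-noise variant needs latent x2")
            z = np.concatenate([z, np.log(np.asarray(x2, dtype=float))])
        return z

    def unpack_params(self, z: np.ndarray) -> dict[str, np.ndarray]:
        z = np.atleast_2d(z)
        return {
            name: tr.forward(z[:, i])
            for i, (name, tr) in enumerate(zip(self.param_names, self.transforms))
        }

    def latent_x1(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(z)
        return np.exp(z[:, self.n_par:self.n_par + self.n_lat])

    def latent_x2(self, z: np.ndarray) -> np.ndarray | None:
        if self.noise_free:
            return None
        z = np.atleast_2d(z)
        return np.exp(z[:, self.n_par + self.n_lat:])

    def jacobian_at(self, z: np.ndarray) -> float:
        """Total log Jacobian of the reparameterization at ``z``."""
        jac = 0.0
        for i, tr in enumerate(self.transforms):
            jac += float(tr.log_jac(z[i]))
        jac += float(np.sum(z[self.n_par:]))
        return jac

    # -- density and gradient ---------------------------------------------
    def logp_grad(self, z: np.ndarray):
        if self.noise_free:
            return self._logp_grad_noise_free(z)
        return self._logp_grad_with_noise(z)

    def _param_grads_to_unconstrained(self, z, g_nat, grad, extra_jac_grad=None):
        for i, (name, tr) in enumerate(zip(self.param_names, self.transforms)):
            grad[i] = tr.dx_du(z[i]) * g_nat[name] + tr.dlog_jac_du(z[i])

    def _prior_terms(self, pars):
        """Log prior kernels and their natural-scale derivatives.

        Normalizing constants are dropped (they cancel in MCMC); uniform
        priors contribute nothing inside the support, which the transforms
        enforce.
        """
        lp = 0.0
        g = {}
        for name in self.param_names:
            prior = self.priors[name]
            x = pars[name]
            if isinstance(prior, TruncatedNormalPrior):
                lp += -((x - prior.mean) ** 2) / (2.0 * prior.sd**2)
                g[name] = -(x - prior.mean) / prior.sd**2
            else:
                g[name] = 0.0
        return lp, g

    def _logp_grad_noise_free(self, z):
        if self._kernel_ok:
            from ._kernels import sde_nf_logp_grad

            return sde_nf_logp_grad(
                np.asarray(z, dtype=float), self.yy, self.dts, self.dt0,
                self.offset, self._prior_mean, self._prior_sd,
                self.priors["scale"].lo, self.priors["scale"].hi,
            )
        with np.errstate(all="ignore"):
            lp, grad = self._logp_grad_noise_free_impl(z)
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros(self.dim)
        return lp, grad

    def logp_grad_py(self, z: np.ndarray):
        """Pure-numpy reference implementation (same density/gradient)."""
        with np.errstate(all="ignore"):
            if self.noise_free:
                lp, grad = self._logp_grad_noise_free_impl(z)
            else:
                lp, grad = self._logp_grad_with_noise_impl(z)
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros(self.dim)
        return lp, grad

    def _logp_grad_noise_free_impl(self, z):
        np_ = self.n_par
        th1, th2, th3 = _safe_exp(z[0]), _safe_exp(z[1]), _safe_exp(z[2])
        m0 = _safe_exp(z[3])
        sc = self.transforms[4].forward(z[4])
        v = z[np_:np_ + self.n_lat]
        x1 = _safe_exp(v)
        x2 = (self.yy - self.offset) / sc
        dt0, dts, n = self.dt0, self.dts, self.n_lat

        pars = {"theta1": th1, "theta2": th2, "theta3": th3, "m0": m0, "scale": sc}
        lp, gpri = self._prior_terms(pars)
        g = {k: gpri[k] for k in pars}
        g_x1 = np.zeros(n)

        # initial Euler-Maruyama step from (m0, 0) over dt0
        v1 = th1 * m0 * dt0
        v2 = th2 * m0 * dt0
        r1 = x1[0] - m0 * (1.0 - th1 * dt0)
        r2 = x2[0] - th2 * m0 * dt0
        lp += -0.5 * (2 * LOG_2PI + np.log(v1) + np.log(v2))
        lp += -(r1**2 / (2 * v1) + r2**2 / (2 * v2))
        a1 = r1**2 / (2 * v1**2) - 1.0 / (2 * v1)
        b1 = -r1 / v1
        a2 = r2**2 / (2 * v2**2) - 1.0 / (2 * v2)
        b2 = -r2 / v2
        g["theta1"] += a1 * m0 * dt0 + b1 * m0 * dt0
        g["m0"] += a1 * th1 * dt0 - b1 * (1.0 - th1 * dt0)
        g_x1[0] += b1
        g["theta2"] += a2 * m0 * dt0 - b2 * m0 * dt0
        g["m0"] += a2 * th2 * dt0 - b2 * th2 * dt0
        g["scale"] += b2 * (-x2[0] / sc)

        # transitions between observation frames
        x1c, x1n = x1[:-1], x1[1:]
        x2c, x2n = x2[:-1], x2[1:]
        v3 = th1 * x1c * dts
        r3 = x1n - x1c * (1.0 - th1 * dts)
        v4 = (th2 * x1c + th3 * x2c) * dts
        r4 = x2n - (x2c + (th2 * x1c - th3 * x2c) * dts)
        lp += float(np.sum(-0.5 * (2 * LOG_2PI + np.log(v3) + np.log(v4))
                           - r3**2 / (2 * v3) - r4**2 / (2 * v4)))
        a3 = r3**2 / (2 * v3**2) - 1.0 / (2 * v3)
        b3 = -r3 / v3
        a4 = r4**2 / (2 * v4**2) - 1.0 / (2 * v4)
        b4 = -r4 / v4
        g["theta1"] += float(np.sum(a3 * x1c * dts + b3 * x1c * dts))
        g["theta2"] += float(np.sum(a4 * x1c * dts - b4 * x1c * dts))
        g["theta3"] += float(np.sum(a4 * x2c * dts + b4 * x2c * dts))
        g_x1[:-1] += (a3 * th1 * dts - b3 * (1.0 - th1 * dts)
                      + a4 * th2 * dts - b4 * th2 * dts)
        g_x1[1:] += b3
        # scale enters through every x2 value: dx2/dscale = -x2/scale
        dx2c = -x2c / sc
        dx2n = -x2n / sc
        g["scale"] += float(np.sum(
            a4 * th3 * dts * dx2c + b4 * (dx2n - dx2c * (1.0 - th3 * dts))
        ))

        # observation-collapse Jacobian: one 1/scale factor per frame >= j0
        lp += -n * np.log(sc)
        g["scale"] += -n / sc

        grad = np.empty(self.dim)
        self._param_grads_to_unconstrained(z, g, grad)
        grad[np_:] = x1 * g_x1 + 1.0  # latent log Jacobian
        lp += self.jacobian_at(z)
        return float(lp), grad

    def _logp_grad_with_noise(self, z):
        with np.errstate(all="ignore"):
            lp, grad = self._logp_grad_with_noise_impl(z)
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros(self.dim)
        return lp, grad

    def _logp_grad_with_noise_impl(self, z):
        np_ = self.n_par
        th1, th2, th3 = _safe_exp(z[0]), _safe_exp(z[1]), _safe_exp(z[2])
        m0 = _safe_exp(z[3])
        sc = self.transforms[4].forward(z[4])
        off = self.transforms[5].forward(z[5])
        sig = self.transforms[6].forward(z[6])
        v = z[np_:np_ + self.n_lat]
        w = z[np_ + self.n_lat:]
        x1 = _safe_exp(v)
        x2 = _safe_exp(w)
        dt0, dts, n = self.dt0, self.dts, self.n_lat

        pars = {"theta1": th1, "theta2": th2, "theta3": th3, "m0": m0,
                "scale": sc, "offset": off, "sigma": sig}
        lp, gpri = self._prior_terms(pars)
        g = {k: gpri[k] for k in pars}
        g_x1 = np.zeros(n)
        g_x2 = np.zeros(n)

        # initial EM step from (m0, 0)
        v1 = th1 * m0 * dt0
        v2 = th2 * m0 * dt0
        r1 = x1[0] - m0 * (1.0 - th1 * dt0)
        r2 = x2[0] - th2 * m0 * dt0
        lp += -0.5 * (2 * LOG_2PI + np.log(v1) + np.log(v2))
        lp += -(r1**2 / (2 * v1) + r2**2 / (2 * v2))
        a1 = r1**2 / (2 * v1**2) - 1.0 / (2 * v1)
        b1 = -r1 / v1
        a2 = r2**2 / (2 * v2**2) - 1.0 / (2 * v2)
        b2 = -r2 / v2
        g["theta1"] += a1 * m0 * dt0 + b1 * m0 * dt0
        g["m0"] += a1 * th1 * dt0 - b1 * (1.0 - th1 * dt0)
        g_x1[0] += b1
        g["theta2"] += a2 * m0 * dt0 - b2 * m0 * dt0
        g["m0"] += a2 * th2 * dt0 - b2 * th2 * dt0
        g_x2[0] += b2

        # frame-to-frame EM transitions
        x1c, x1n = x1[:-1], x1[1:]
        x2c, x2n = x2[:-1], x2[1:]
        v3 = th1 * x1c * dts
        r3 = x1n - x1c * (1.0 - th1 * dts)
        v4 = (th2 * x1c + th3 * x2c) * dts
        r4 = x2n - (x2c + (th2 * x1c - th3 * x2c) * dts)
        lp += float(np.sum(-0.5 * (2 * LOG_2PI + np.log(v3) + np.log(v4))
                           - r3**2 / (2 * v3) - r4**2 / (2 * v4)))
        a3 = r3**2 / (2 * v3**2) - 1.0 / (2 * v3)
        b3 = -r3 / v3
        a4 = r4**2 / (2 * v4**2) - 1.0 / (2 * v4)
        b4 = -r4 / v4
        g["theta1"] += float(np.sum(a3 * x1c * dts + b3 * x1c * dts))
        g["theta2"] += float(np.sum(a4 * x1c * dts - b4 * x1c * dts))
        g["theta3"] += float(np.sum(a4 * x2c * dts + b4 * x2c * dts))
        g_x1[:-1] += (a3 * th1 * dts - b3 * (1.0 - th1 * dts)
                      + a4 * th2 * dts - b4 * th2 * dts)
        g_x1[1:] += b3
        g_x2[:-1] += a4 * th3 * dts - b4 * (1.0 - th3 * dts)
        g_x2[1:] += b4

        # lognormal observation terms at every frame
        x2_full = np.zeros(len(self.times_all))
        x2_full[self.j0:] = x2
        gg = sc * x2_full + off
        r_o = np.log(self.y_all) - np.log(gg)
        lp += float(np.sum(-0.5 * LOG_2PI - np.log(sig) - r_o**2 / (2 * sig**2)))
        coef = r_o / (sig**2 * gg)
        g_x2 += coef[self.j0:] * sc
        g["scale"] += float(np.sum(coef[self.j0:] * x2))
        g["offset"] += float(np.sum(coef))
        g["sigma"] += float(np.sum(-1.0 / sig + r_o**2 / sig**3))

        grad = np.empty(self.dim)
        self._param_grads_to_unconstrained(z, g, grad)
        grad[np_:np_ + n] = x1 * g_x1 + 1.0
        grad[np_ + n:] = x2 * g_x2 + 1.0
        lp += self.jacobian_at(z)
        return float(lp), grad


def make_sde_target(
    data: ObservationSeries,
    t0: float,
    priors: dict[str, Prior] | None = None,
    noise_free: bool = True,
    offset_fixed: float | None = None,
) -> SdeTarget:
    if priors is None:
        priors = default_priors("sde_noise_free" if noise_free else "sde_with_noise")
    return SdeTarget(data, t0, priors, noise_free=noise_free, offset_fixed=offset_fixed)


def make_ode_target(
    data: ObservationSeries,
    priors: dict[str, Prior] | None = None,
) -> OdeTarget:
    if priors is None:
        priors = default_priors("ode")
    return OdeTarget(data, priors)
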