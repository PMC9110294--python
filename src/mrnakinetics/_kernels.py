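"""Numba-compiled hot loops for the posterior gradients.

These mirror the pure-numpy implementations in :mod:`targets` operation by
operation (a unit test asserts agreement); they exist only because the
NUTS trajectories evaluate the gradients hundreds of times per iteration.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def _sigmoid(u):
    return 0.5 * (1.0 + np.tanh(0.5 * u))


@njit(cache=True)
def _clip_exp(u):
    if u > 700.0:
        u = 700.0
    elif u < -700.0:
        u = -700.0
    return np.exp(u)


@njit(cache=True)
def sde_nf_logp_grad(
    z,
    yy,            # observations from frame j0 on
    dts,           # frame gaps
    dt0,           # first-step length t_{j0} - t0
    offset,
    prior_mean,    # (4,) truncated-normal means: theta1..3, m0
    prior_sd,      # (4,) truncated-normal sds
    scale_lo,
    scale_hi,
):
    """Noise-free latent-path SDE log target and gradient.

    Layout of ``z``: [log th1, log th2, log th3, log m0, logit scale,
    log x1 at each frame].  Returns (logp, grad).
    """
    n_par = 5
    n = yy.shape[0]
    dim = n_par + n
    grad = np.zeros(dim)

    th1 = _clip_exp(z[0])
    th2 = _clip_exp(z[1])
    th3 = _clip_exp(z[2])
    m0 = _clip_exp(z[3])
    s = _sigmoid(z[4])
    if s <= 0.0 or s >= 1.0:  # saturated transform: boundary of the support
        return -np.inf, grad
    sc = scale_lo + (scale_hi - scale_lo) * s
    if sc <= 0.0 or th1 <= 0.0 or th2 <= 0.0 or th3 <= 0.0 or m0 <= 0.0:
        return -np.inf, grad

    x1 = np.empty(n)
    for i in range(n):
        x1[i] = _clip_exp(z[n_par + i])

    lp = 0.0
    g_th1 = 0.0
    g_th2 = 0.0
    g_th3 = 0.0
    g_m0 = 0.0
    g_sc = 0.0
    g_x1 = np.zeros(n)

    # priors (kernels)
    th = (th1, th2, th3, m0)
    gp = np.zeros(4)
    for i in range(4):
        lp += -((th[i] - prior_mean[i]) ** 2) / (2.0 * prior_sd[i] ** 2)
        gp[i] = -(th[i] - prior_mean[i]) / prior_sd[i] ** 2
    g_th1 += gp[0]
    g_th2 += gp[1]
    g_th3 += gp[2]
    g_m0 += gp[3]

    inv_sc = 1.0 / sc
    # x2 determined by the data given scale
    x2 = np.empty(n)
    for i in range(n):
        x2[i] = (yy[i] - offset) * inv_sc

    # initial EM step from (m0, 0)
    v1 = th1 * m0 * dt0
    v2 = th2 * m0 * dt0
    if v1 < 1e-150 or v2 < 1e-150:  # floor guards squared-variance underflow
        return -np.inf, grad
    r1 = x1[0] - m0 * (1.0 - th1 * dt0)
    r2 = x2[0] - th2 * m0 * dt0
    lp += -0.5 * (2.0 * LOG_2PI + np.log(v1) + np.log(v2))
    lp += -(r1 * r1 / (2.0 * v1) + r2 * r2 / (2.0 * v2))
    a1 = r1 * r1 / (2.0 * v1 * v1) - 1.0 / (2.0 * v1)
    b1 = -r1 / v1
    a2 = r2 * r2 / (2.0 * v2 * v2) - 1.0 / (2.0 * v2)
    b2 = -r2 / v2
    g_th1 += a1 * m0 * dt0 + b1 * m0 * dt0
    g_m0 += a1 * th1 * dt0 - b1 * (1.0 - th1 * dt0)
    g_x1[0] += b1
    g_th2 += a2 * m0 * dt0 - b2 * m0 * dt0
    g_m0 += a2 * th2 * dt0 - b2 * th2 * dt0
    g_sc += b2 * (-x2[0] * inv_sc)

    # frame transitions
    for i in range(n - 1):
        d = dts[i]
        v3 = th1 * x1[i] * d
        v4 = (th2 * x1[i] + th3 * x2[i]) * d
        if v3 < 1e-150 or v4 < 1e-150:
            return -np.inf, grad
        r3 = x1[i + 1] - x1[i] * (1.0 - th1 * d)
        r4 = x2[i + 1] - (x2[i] + (th2 * x1[i] - th3 * x2[i]) * d)
        lp += -0.5 * (2.0 * LOG_2PI + np.log(v3) + np.log(v4))
        lp += -(r3 * r3 / (2.0 * v3) + r4 * r4 / (2.0 * v4))
        a3 = r3 * r3 / (2.0 * v3 * v3) - 1.0 / (2.0 * v3)
        b3 = -r3 / v3
        a4 = r4 * r4 / (2.0 * v4 * v4) - 1.0 / (2.0 * v4)
        b4 = -r4 / v4
        g_th1 += (a3 + b3) * x1[i] * d
        g_th2 += (a4 - b4) * x1[i] * d
        g_th3 += (a4 + b4) * x2[i] * d
        g_x1[i] += (a3 * th1 * d - b3 * (1.0 - th1 * d)
                    + a4 * th2 * d - b4 * th2 * d)
        g_x1[i + 1] += b3
        dx2c = -x2[i] * inv_sc
        dx2n = -x2[i + 1] * inv_sc
        g_sc += a4 * th3 * d * dx2c + b4 * (dx2n - dx2c * (1.0 - th3 * d))

    # observation-collapse Jacobian
    lp += -n * np.log(sc)
    g_sc += -n * inv_sc

    # unconstrained-scale gradients and transform Jacobians
    grad[0] = th1 * g_th1 + 1.0
    grad[1] = th2 * g_th2 + 1.0
    grad[2] = th3 * g_th3 + 1.0
    grad[3] = m0 * g_m0 + 1.0
    dsc_du = (scale_hi - scale_lo) * s * (1.0 - s)
    grad[4] = dsc_du * g_sc + (1.0 - 2.0 * s)
    lp += z[0] + z[1] + z[2] + z[3]
    lp += np.log(scale_hi - scale_lo) + np.log(s) + np.log1p(-s)
    for i in range(n):
        grad[n_par + i] = x1[i] * g_x1[i] + 1.0
        lp += z[n_par + i]

    if not np.isfinite(lp):
        return -np.inf, np.zeros(dim)
    return lp, grad


@njit(cache=True)
def ode_logp_grad(
    u,
    times,
    logy,
    prior_mean,    # (4,)
    prior_sd,      # (4,)
    bounds,        # (4, 2) logit bounds for scale, offset, sigma, t0
    branch_tol,
):
    """ODE-model log posterior and gradient on the unconstrained scale.

    Layout of ``u``: [log th1, log th2, log th3, log m0, logit scale,
    logit offset, logit sigma, logit t0].
    """
    dim = 8
    grad = np.zeros(dim)
    K = times.shape[0]

    th1 = _clip_exp(u[0])
    th2 = _clip_exp(u[1])
    th3 = _clip_exp(u[2])
    m0 = _clip_exp(u[3])
    s = np.empty(4)
    x = np.empty(4)  # scale, offset, sigma, t0
    for j in range(4):
        s[j] = _sigmoid(u[4 + j])
        if s[j] <= 0.0 or s[j] >= 1.0:  # saturated transform
            return -np.inf, grad
        x[j] = bounds[j, 0] + (bounds[j, 1] - bounds[j, 0]) * s[j]
    scale, offset, sigma, t0 = x[0], x[1], x[2], x[3]
    if scale <= 0.0 or offset <= 0.0 or sigma <= 0.0 or th1 <= 0.0 or m0 <= 0.0:
        return -np.inf, grad

    lp = 0.0
    g_nat = np.zeros(8)  # th1, th2, th3, m0, scale, offset, sigma, t0
    s2 = sigma * sigma
    use_limit = abs(th1 - th3) < branch_tol
    d = th3 - th1
    thm = 0.5 * (th1 + th3)
    am = scale * th2 * m0

    for k in range(K):
        if times[k] >= t0:
            tau = times[k] - t0
            if use_limit:
                e = np.exp(-thm * tau)
                f = tau * e
                df1 = -0.5 * tau * tau * e
                df3 = df1
                dft0 = e * (thm * tau - 1.0)
            else:
                A = np.exp(-th1 * tau)
                B = np.exp(-th3 * tau)
                f = (A - B) / d
                df1 = (-tau * A) / d + (A - B) / (d * d)
                df3 = (tau * B) / d - (A - B) / (d * d)
                dft0 = (th1 * A - th3 * B) / d
            x2 = th2 * m0 * f
            g = scale * x2 + offset
            if g <= 0.0 or not np.isfinite(g):
                return -np.inf, np.zeros(dim)
            r = logy[k] - np.log(g)
            lp += -0.5 * LOG_2PI - np.log(sigma) - r * r / (2.0 * s2)
            c = r / (s2 * g)
            g_nat[0] += c * am * df1
            g_nat[1] += c * scale * m0 * f
            g_nat[2] += c * am * df3
            g_nat[3] += c * scale * th2 * f
            g_nat[4] += c * x2
            g_nat[5] += c
            g_nat[6] += -1.0 / sigma + r * r / (sigma * s2)
            g_nat[7] += c * am * dft0
        else:
            r = logy[k] - np.log(offset)
            lp += -0.5 * LOG_2PI - np.log(sigma) - r * r / (2.0 * s2)
            g_nat[5] += r / (s2 * offset)
            g_nat[6] += -1.0 / sigma + r * r / (sigma * s2)

    th = (th1, th2, th3, m0)
    for i in range(4):
        lp += -((th[i] - prior_mean[i]) ** 2) / (2.0 * prior_sd[i] ** 2)
        g_nat[i] += -(th[i] - prior_mean[i]) / prior_sd[i] ** 2

    for i in range(4):
        grad[i] = th[i] * g_nat[i] + 1.0
        lp += u[i]
    for j in range(4):
        w = bounds[j, 1] - bounds[j, 0]
        grad[4 + j] = w * s[j] * (1.0 - s[j]) * g_nat[4 + j] + (1.0 - 2.0 * s[j])
        lp += np.log(w) + np.log(s[j]) + np.log1p(-s[j])

    if not np.isfinite(lp):
        return -np.inf, np.zeros(dim)
    return lp, grad
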