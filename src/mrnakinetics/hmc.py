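"""A self-contained No-U-Turn sampler.

Implements dynamic Hamiltonian Monte Carlo on an unconstrained parameter
space: leapfrog integration with a diagonal mass matrix, the slice-variant
tree doubling of Hoffman & Gelman (2014, Algorithm 6), dual-averaging step
size adaptation targeting a given acceptance statistic, and Stan-style
windowed estimation of the diagonal metric during warmup.

The target is supplied as ``logp_grad(x) -> (logp, grad)``; constrained
parameters are expected to be transformed (log/logit) by the caller.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

#: energy error beyond which a trajectory is declared divergent
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsResult:
    draws: np.ndarray           # (n_draws, dim), post-warmup
    logp: np.ndarray            # (n_draws,)
    accept_stat: np.ndarray     # mean Metropolis acceptance per kept draw
    tree_depths: np.ndarray
    divergences: int
    step_size: float
    inv_metric: np.ndarray
    extras: dict = field(default_factory=dict)


class _DualAveraging:
    """Nesterov dual averaging of log(step size) (Hoffman & Gelman 2014)."""

    def __init__(self, eps0: float, delta: float, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.delta = delta
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.m = 0

    def update(self, accept_prob: float) -> float:
        self.m += 1
        w = 1.0 / (self.m + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.delta - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        eta = self.m ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    """Running mean/variance of warmup draws for the diagonal metric."""

    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # Stan's regularization toward unity keeps the metric sane early on
        w = self.n / (self.n + 5.0)
        return w * var + (1.0 - w) * 1e-3


def _leapfrog(logp_grad, x, p, grad, eps, inv_metric):
    p = p + 0.5 * eps * grad
    x = x + eps * inv_metric * p
    lp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _kinetic(p, inv_metric):
    # extreme momenta during warmup may overflow; inf energy is treated as
    # a divergence by the caller
    with np.errstate(over="ignore", invalid="ignore"):
        return 0.5 * float(np.dot(p, inv_metric * p))


def _find_reasonable_eps(logp_grad, x, lp, grad, inv_metric, rng):
    eps = 1.0
    p = rng.standard_normal(len(x)) / np.sqrt(inv_metric)
    h0 = lp - _kinetic(p, inv_metric)
    x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, grad, eps, inv_metric)
    h1 = lp1 - _kinetic(p1, inv_metric) if np.isfinite(lp1) else -np.inf
    log_ratio = h1 - h0
    direction = 1.0 if log_ratio > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, grad, eps, inv_metric)
        h1 = lp1 - _kinetic(p1, inv_metric) if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-10)


class _Tree:
    """Recursive tree construction for one NUTS transition."""

    def __init__(self, logp_grad, inv_metric, eps, log_u, h0, rng):
        self.logp_grad = logp_grad
        self.inv_metric = inv_metric
        self.eps = eps
        self.log_u = log_u
        self.h0 = h0
        self.rng = rng
        self.divergent = False
        self.sum_alpha = 0.0
        self.n_alpha = 0

    def build(self, x, p, grad, direction, depth):
        if depth == 0:
            x1, p1, lp1, grad1 = _leapfrog(
                self.logp_grad, x, p, grad, direction * self.eps, self.inv_metric
            )
            h1 = lp1 - _kinetic(p1, self.inv_metric) if np.isfinite(lp1) else -np.inf
            n_valid = int(self.log_u <= h1)
            diverged = (self.log_u - DIVERGENCE_THRESHOLD) > h1 or not np.isfinite(h1)
            if diverged:
                self.divergent = True
            self.sum_alpha += min(1.0, np.exp(min(h1 - self.h0, 0.0)))
            self.n_alpha += 1
            keep_going = not diverged
            return (x1, p1, grad1, lp1, x1, p1, grad1, lp1,
                    x1, lp1, n_valid, keep_going)
        # inner subtree
        (xm, pm, gm, lpm, xp, pp, gp, lpp,
         xc, lpc, n1, s1) = self.build(x, p, grad, direction, depth - 1)
        if not s1:
            return xm, pm, gm, lpm, xp, pp, gp, lpp, xc, lpc, n1, s1
        if direction == -1:
            (xm, pm, gm, lpm, _, _, _, _,
             xc2, lpc2, n2, s2) = self.build(xm, pm, gm, direction, depth - 1)
        else:
            (_, _, _, _, xp, pp, gp, lpp,
             xc2, lpc2, n2, s2) = self.build(xp, pp, gp, direction, depth - 1)
        if n1 + n2 > 0 and self.rng.uniform() < n2 / (n1 + n2):
            xc, lpc = xc2, lpc2
        s = s2 and self._no_uturn(xm, pm, xp, pp)
        return xm, pm, gm, lpm, xp, pp, gp, lpp, xc, lpc, n1 + n2, s

    def _no_uturn(self, xm, pm, xp, pp):
        dx = xp - xm
        return (np.dot(dx, self.inv_metric * pm) >= 0.0
                and np.dot(dx, self.inv_metric * pp) >= 0.0)


def _nuts_transition(logp_grad, x, lp, grad, eps, inv_metric, max_treedepth, rng):
    p0 = rng.standard_normal(len(x)) / np.sqrt(inv_metric)
    h0 = lp - _kinetic(p0, inv_metric)
    log_u = h0 + np.log(rng.uniform())
    tree = _Tree(logp_grad, inv_metric, eps, log_u, h0, rng)
    xm, pm, gm, lpm = x.copy(), p0.copy(), grad.copy(), lp
    xp, pp, gp, lpp = x.copy(), p0.copy(), grad.copy(), lp
    xc, lpc, gc = x, lp, grad
    n, s, depth = 1, True, 0
    while s and depth < max_treedepth:
        direction = -1 if rng.uniform() < 0.5 else 1
        if direction == -1:
            (xm, pm, gm, lpm, _, _, _, _,
             xc2, lpc2, n2, s2) = tree.build(xm, pm, gm, direction, depth)
        else:
            (_, _, _, _, xp, pp, gp, lpp,
             xc2, lpc2, n2, s2) = tree.build(xp, pp, gp, direction, depth)
        if s2 and n2 > 0 and rng.uniform() < min(1.0, n2 / n):
            xc, lpc = xc2, lpc2
            gc = None
        n += n2
        s = s2 and tree._no_uturn(xm, pm, xp, pp)
        depth += 1
    if gc is None:
        _, gc = logp_grad(xc)  # refresh gradient at the accepted point
    alpha = tree.sum_alpha / max(tree.n_alpha, 1)
    return xc, lpc, gc, depth, alpha, tree.divergent


def _warmup_windows(n_warmup: int):
    """Stan-style (initial fast, expanding slow, terminal fast) schedule.

    Returns the iteration indices at which the metric is re-estimated.
    The final window absorbs any remainder so the metric is never
    estimated from a handful of draws.
    """
    if n_warmup < 60:
        return []
    init_buf = max(int(0.15 * n_warmup), 10)
    term_buf = max(int(0.10 * n_warmup), 10)
    slow_end = n_warmup - term_buf
    ends, w, pos = [], 25, init_buf
    while pos < slow_end:
        end = pos + w
        if end + 2 * w > slow_end:
            end = slow_end
        ends.append(end)
        pos = end
        w *= 2
    return ends


def nuts_sample(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    seed,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    progress: bool = False,
) -> NutsResult:
    """Run one NUTS chain and return post-warmup draws.

    ``seed`` may be an int, SeedSequence or Generator; identical inputs
    produce bit-identical output.
    """
    rng = np.random.default_rng(seed)
    x = np.array(x0, dtype=float)
    dim = len(x)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")
    inv_metric = np.ones(dim)

    eps = _find_reasonable_eps(logp_grad, x, lp, grad, inv_metric, rng)
    da = _DualAveraging(eps, target_accept)
    metric_updates = _warmup_windows(n_warmup)
    welford = _Welford(dim)

    draws = np.empty((n_draws, dim))
    lps = np.empty(n_draws)
    accs = np.empty(n_draws)
    depths = np.empty(n_draws, dtype=int)
    divergences = 0

    total = n_warmup + n_draws
    for it in range(total):
        x, lp, grad, depth, alpha, div = _nuts_transition(
            logp_grad, x, lp, grad, eps, inv_metric, max_treedepth, rng
        )
        if it < n_warmup:
            eps = da.update(alpha)
            welford.add(x)
            if metric_updates and it + 1 == metric_updates[0]:
                metric_updates.pop(0)
                inv_metric = welford.variance()
                welford = _Welford(dim)
                eps = _find_reasonable_eps(logp_grad, x, lp, grad, inv_metric, rng)
                da = _DualAveraging(eps, target_accept)
            if it + 1 == n_warmup:
                eps = da.adapted
        else:
            i = it - n_warmup
            draws[i] = x
            lps[i] = lp
            accs[i] = alpha
            depths[i] = depth
            if div:
                divergences += 1
        if progress and (it + 1) % 200 == 0:
            print(f"  iter {it + 1}/{total} eps={eps:.3g}", file=sys.stderr)

    return NutsResult(
        draws=draws, logp=lps, accept_stat=accs, tree_depths=depths,
        divergences=divergences, step_size=float(eps), inv_metric=inv_metric,
    )
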