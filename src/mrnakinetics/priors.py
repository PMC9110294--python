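"""Prior distributions and their analytic summaries.

Two families cover every parameter: normals truncated from below (the
diffuse rate/copy-number priors) and uniforms on an interval (calibration
and noise parameters).  Each prior knows its log density and derivative on
the natural scale, the transform to an unconstrained sampling scale, and
its central 95% interval length (the identifiability baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TruncatedNormalPrior:
    """N(mean, sd^2) truncated from below at ``lower``."""

    mean: float
    sd: float
    lower: float = 0.0

    def _dist(self):
        a = (self.lower - self.mean) / self.sd
        return stats.truncnorm(a, np.inf, loc=self.mean, scale=self.sd)

    def logpdf(self, x):
        return self._dist().logpdf(x)

    def dlogpdf(self, x):
        """d/dx log p(x) on the support (the truncation constant drops)."""
        return -(np.asarray(x, dtype=float) - self.mean) / self.sd**2

    def rvs(self, rng: np.random.Generator, size=None):
        d = self._dist()
        return d.ppf(rng.uniform(size=size))

    def center_interval(self, level: float = 0.95) -> tuple[float, float]:
        d = self._dist()
        a = (1.0 - level) / 2.0
        return float(d.ppf(a)), float(d.ppf(1.0 - a))

    def center_interval_length(self, level: float = 0.95) -> float:
        lo, hi = self.center_interval(level)
        return hi - lo


@dataclass(frozen=True)
class UniformPrior:
    """Uniform on (lo, hi)."""

    lo: float
    hi: float

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x >= self.lo) & (x <= self.hi)
        return np.where(inside, -np.log(self.hi - self.lo), -np.inf)

    def dlogpdf(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def rvs(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.lo, self.hi, size=size)

    def center_interval(self, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        w = self.hi - self.lo
        return self.lo + a * w, self.hi - a * w

    def center_interval_length(self, level: float = 0.95) -> float:
        return level * (self.hi - self.lo)


Prior = TruncatedNormalPrior | UniformPrior

#: canonical parameter order of the full vector xi
FULL_PARAM_ORDER = (
    "theta1", "theta2", "theta3", "m0", "scale", "offset", "sigma", "t0",
)

#: derived product columns reported alongside the primitives
DERIVED_PRODUCTS = ("theta2_m0", "theta2_scale", "m0_scale", "theta2_m0_scale")


def default_priors(variant: str = "ode") -> dict[str, Prior]:
    """The study's diffuse priors, restricted to the sampled parameters.

    variant 'ode': all of theta1..3, m0, scale, offset, sigma, t0.
    variant 'sde_with_noise': no t0 (fixed beforehand from the ODE fit).
    variant 'sde_noise_free': additionally no sigma and no offset (the
    offset is read off the first, pre-release observation).
    """
    base: dict[str, Prior] = {
        "theta1": TruncatedNormalPrior(0.0, 5.0),
        "theta2": TruncatedNormalPrior(0.0, 5.0),
        "theta3": TruncatedNormalPrior(0.0, 5.0),
        "m0": TruncatedNormalPrior(300.0, 300.0),
        "scale": UniformPrior(0.0, 30.0),
    }
    if variant == "ode":
        base.update({
            "offset": UniformPrior(0.0, 30.0),
            "sigma": UniformPrior(0.001, 10.0),
            "t0": UniformPrior(0.0, 30.0),
        })
    elif variant == "sde_with_noise":
        base.update({
            "offset": UniformPrior(0.0, 30.0),
            "sigma": UniformPrior(0.001, 10.0),
        })
    elif variant == "sde_noise_free":
        pass
    else:
        raise ValueError(f"unknown prior variant {variant!r}")
    return base


# ---------------------------------------------------------------------------
# transforms between the natural and the unconstrained sampling scale
# ---------------------------------------------------------------------------

def _sigmoid(u):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(u, dtype=float)))


class LogTransform:
    """x = lower + exp(u) for half-line supports."""

    def __init__(self, lower: float = 0.0):
        self.lower = lower

    def forward(self, u):
        return self.lower + np.exp(u)

    def inverse(self, x):
        return np.log(np.asarray(x, dtype=float) - self.lower)

    def log_jac(self, u):
        return np.asarray(u, dtype=float)

    def dlog_jac_du(self, u):
        return np.ones_like(np.asarray(u, dtype=float))

    def dx_du(self, u):
        return np.exp(u)


class LogitTransform:
    """x = lo + (hi - lo) * sigmoid(u) for interval supports."""

    def __init__(self, lo: float, hi: float):
        self.lo, self.hi = lo, hi

    def forward(self, u):
        return self.lo + (self.hi - self.lo) * _sigmoid(u)

    def inverse(self, x):
        p = (np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo)
        return np.log(p) - np.log1p(-p)

    def log_jac(self, u):
        s = _sigmoid(u)
        return np.log(self.hi - self.lo) + np.log(s) + np.log1p(-s)

    def dlog_jac_du(self, u):
        return 1.0 - 2.0 * _sigmoid(u)

    def dx_du(self, u):
        s = _sigmoid(u)
        return (self.hi - self.lo) * s * (1.0 - s)


def transform_for(prior: Prior):
    if isinstance(prior, TruncatedNormalPrior):
        return LogTransform(prior.lower)
    return LogitTransform(prior.lo, prior.hi)


def prior_center_interval_length(
    prior: Prior, level: float = 0.95
) -> float:
    """Length of the central ``level`` interval of a prior (analytic)."""
    return prior.center_interval_length(level)


def product_prior_interval_length(
    priors: dict[str, Prior],
    factors: tuple[str, ...],
    level: float = 0.95,
    n: int = 1_000_000,
    seed: int = 20260101,
) -> float:
    """Central interval length of a product of independent prior draws.

    No closed form exists for products of truncated normals and uniforms,
    so this is seeded Monte Carlo with n >= 1e6 draws.
    """
    rng = np.random.default_rng(seed)
    prod = np.ones(n)
    for name in factors:
        prod *= priors[name].rvs(rng, size=n)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(prod, [a, 1.0 - a])
    return float(hi - lo)
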