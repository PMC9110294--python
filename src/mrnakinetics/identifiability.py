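"""Practical-identifiability metrics from posterior draws.

A parameter counts as practically identifiable when its 95% credible
interval — the percentile interval between the 2.5% and 97.5% posterior
quantiles — is narrow relative to the prior's central interval and covers
the truth across replicate synthetic trajectories.  The percentile
interval is used deliberately: under the bimodal posteriors of the ODE
model it yields one wide interval rather than two narrow ones, which is
the honest statement about identifiability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import PosteriorDraws
from .priors import DERIVED_PRODUCTS, Prior, product_prior_interval_length
from .priors import prior_center_interval_length  # re-exported module surface
from .types import InsufficientDataError


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Percentile credible interval with linear-interpolation quantiles."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise InsufficientDataError("credible_interval needs at least one draw")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a])
    return float(lo), float(hi)


def ess(chains: np.ndarray) -> float:
    """Effective sample size (classic autocorrelation-based estimator).

    ``chains`` has shape (n_chains, n_draws).  The mean-ESS variant matches
    the n_eff printed in the study's summary tables.  Constant chains are
    reported as perfectly efficient (ESS = total draw count).
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if np.ptp(chains) == 0.0:
        return float(chains.size)
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = float(np.asarray(
            az.ess(az.convert_to_dataset(chains), method="mean")["x"].values
        ).ravel()[0])
    if np.isnan(val):
        return float(chains.size)
    return val


def rhat(chains: np.ndarray) -> float:
    """Classic split-chain potential scale reduction factor.

    The non-rank-normalized variant is used because it is the one whose
    values the study's tables report (values far above 2 occur for the
    bimodal degradation rates, which the rank-normalized variant caps).
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] < 2:
        raise ValueError("rhat needs at least 2 chains")
    if np.ptp(chains) == 0.0:
        return 1.0
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = float(np.asarray(
            az.rhat(az.convert_to_dataset(chains), method="split")["x"].values
        ).ravel()[0])
    if np.isnan(val):
        return 1.0
    return val


@dataclass
class CISummary:
    """Per-parameter posterior summary mirroring the study's table layout."""

    parameter: str
    mean: float
    cv: float
    lo: float
    median: float
    hi: float
    length: float
    ess: float
    rhat: Optional[float]
    covers_true: Optional[bool] = None
    rescaled_length: Optional[float] = None
    true_value: Optional[float] = None


def _cv(x: np.ndarray) -> float:
    m = float(np.mean(x))
    if m == 0.0:
        return float("nan")
    return float(np.std(x, ddof=1) / m)


def summarize_fit(
    draws: PosteriorDraws,
    truth: Optional[dict[str, float]] = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Posterior summary table: one row per parameter and derived product.

    Columns follow the study's layout (mean, c.v., 2.5%/50%/97.5%
    quantiles, ESS, R-hat) plus CI length and, when the truth is known,
    coverage (boundary equality counts as covered) and the CI length
    rescaled by the true value.  Product summaries are computed from
    per-draw products, never from products of summaries.
    """
    rows = []
    for name in draws.columns:
        x = draws.df[name].to_numpy()
        lo, hi = credible_interval(x, level)
        med = float(np.quantile(x, 0.5))
        arr = draws.chain_array(name)
        row = CISummary(
            parameter=name,
            mean=float(np.mean(x)),
            cv=_cv(x),
            lo=lo,
            median=med,
            hi=hi,
            length=hi - lo,
            ess=ess(arr),
            rhat=rhat(arr) if draws.n_chains >= 2 else None,
        )
        if truth is not None and name in _with_products(truth):
            tv = _with_products(truth)[name]
            row.true_value = tv
            row.covers_true = bool(lo <= tv <= hi)
            row.rescaled_length = (hi - lo) / tv if tv != 0 else None
        rows.append(asdict(row))
    return pd.DataFrame(rows)


def _with_products(truth: dict[str, float]) -> dict[str, float]:
    out = dict(truth)
    if all(k in truth for k in ("theta2", "m0", "scale")):
        out.setdefault("theta2_m0", truth["theta2"] * truth["m0"])
        out.setdefault("theta2_scale", truth["theta2"] * truth["scale"])
        out.setdefault("m0_scale", truth["m0"] * truth["scale"])
        out.setdefault("theta2_m0_scale", truth["theta2"] * truth["m0"] * truth["scale"])
    return out


def prior_baseline_length(
    priors: dict[str, Prior], name: str, level: float = 0.95
) -> float:
    """Central prior interval length for a primitive or a derived product."""
    if name in priors:
        return prior_center_interval_length(priors[name], level)
    if name in DERIVED_PRODUCTS:
        factors = tuple(
            {"theta2_m0": ("theta2", "m0"),
             "theta2_scale": ("theta2", "scale"),
             "m0_scale": ("m0", "scale"),
             "theta2_m0_scale": ("theta2", "m0", "scale")}[name]
        )
        return product_prior_interval_length(priors, factors, level)
    raise KeyError(f"no prior known for {name!r}")


def aggregate_study(
    per_replicate: Sequence[pd.DataFrame],
    truth: dict[str, float],
    priors: dict[str, Prior],
    model: str,
    level: float = 0.95,
) -> pd.DataFrame:
    """Aggregate per-trajectory CI summaries into one row per parameter.

    Reports, across replicates: the median CI length, the c.v. of the CI
    lengths, the median of the truth-rescaled lengths, the count of CIs
    covering the truth, and the prior central-interval baseline.
    Aggregation is permutation invariant in the replicate order.
    """
    if len(per_replicate) < 2:
        raise InsufficientDataError("aggregation needs >= 2 replicates")
    names = list(per_replicate[0]["parameter"])
    for s in per_replicate[1:]:
        if list(s["parameter"]) != names:
            raise ValueError("replicates summarize different parameter sets")
    truth_full = _with_products(truth)
    rows = []
    for name in names:
        lengths = np.array([
            float(s.loc[s.parameter == name, "length"].iloc[0]) for s in per_replicate
        ])
        covers = sum(
            bool(s.loc[s.parameter == name, "covers_true"].iloc[0])
            for s in per_replicate
        )
        tv = truth_full.get(name)
        rows.append({
            "parameter": name,
            "model": model,
            "prior_interval_length": prior_baseline_length(priors, name, level)
            if (name in priors or name in DERIVED_PRODUCTS) else np.nan,
            "median_ci_length": float(np.median(lengths)),
            "cv_ci_length": _cv(lengths),
            "median_rescaled_length": float(np.median(lengths / tv))
            if tv not in (None, 0) else np.nan,
            "coverage_count": int(covers),
            "n_replicates": len(per_replicate),
        })
    return pd.DataFrame(rows)
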