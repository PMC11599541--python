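"""Convergence and model-fit diagnostics.

Convergence is assessed with the classic Gelman-Rubin potential scale
reduction factor (R-hat) computed from between- and within-chain variances;
convergence is conventionally declared when R-hat - 1 < 0.1.  Model fit is
assessed by a posterior-predictive check that compares, draw by draw, the
residual sum of squares of the observed data against that of a replicate
simulated from the likelihood at the same draw; the Bayesian p-value is the
fraction of draws where the replicated discrepancy is at least the observed
one (ties count as exceedance), with values near 0.5 indicating adequate fit
and values near 0 or 1 flagging mis-specification.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .draws import PosteriorDraws
from .model import HierarchicalModel

__all__ = [
    "gelman_rubin",
    "rhat_table",
    "PPCResult",
    "posterior_predictive_check",
]


def _classic_rhat(chains: np.ndarray) -> float:
    m, n = chains.shape
    if m < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    if n < 2:
        raise ValueError("Gelman-Rubin diagnostic requires >= 2 draws per chain")
    means = chains.mean(axis=1)
    W = float(np.mean(chains.var(axis=1, ddof=1)))
    B_over_n = float(np.var(means, ddof=1))  # = B / n
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def gelman_rubin(draws, parameter=None, *, split: bool = False) -> float:
    """Classic (non-split, non-rank-normalized) Gelman-Rubin R-hat.

    ``draws`` is a :class:`PosteriorDraws` (then ``parameter`` selects the
    parameter) or a (n_chains, n_draws) array.  With ``split=True`` each chain
    is split in half first (the split-R-hat variant).
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorDraws input")
        chains = draws.get(parameter)
    else:
        chains = np.atleast_2d(np.asarray(draws, dtype=float))
    if split:
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    return _classic_rhat(chains)


def rhat_table(draws: PosteriorDraws, *, split: bool = False) -> pd.DataFrame:
    """R-hat for every parameter, sorted worst-first."""
    rows = [
        {"parameter": n, "rhat": gelman_rubin(draws, n, split=split)}
        for n in draws.names
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("rhat", ascending=False)
        .reset_index(drop=True)
    )


@dataclass
class PPCResult:
    """Paired observed/replicated discrepancies and Bayesian p-values."""

    rss_observed: dict = field(default_factory=dict)  # tier -> (n_draws,)
    rss_replicated: dict = field(default_factory=dict)
    bayesian_p: dict = field(default_factory=dict)  # tier -> scalar, + "pooled"

    def pairs(self, tier: str = "pooled") -> np.ndarray:
        """(n_draws, 2) array of (RSS_obs, RSS_rep) for the 1:1 plot."""
        return np.column_stack([self.rss_observed[tier], self.rss_replicated[tier]])


def posterior_predictive_check(
    draws: PosteriorDraws,
    model: HierarchicalModel,
    *,
    seed: int = 0,
    max_draws: int | None = None,
) -> PPCResult:
    """Residual-sum-of-squares posterior-predictive check.

    For each retained draw, RSS_obs compares the observed responses with the
    fitted means at that draw, and RSS_rep compares one simulated replicate
    with the same means.  Discrepancies are computed per tier and pooled
    (the pooled value sums the tiers; responses are standardized so the
    Gaussian tiers are on comparable scales).  The Bayesian p-value is
    P(RSS_rep >= RSS_obs).
    """
    mat = draws.stacked_matrix()
    if mat.shape[0] == 0:
        raise ValueError("no retained draws")
    if max_draws is not None and mat.shape[0] > max_draws:
        idx = np.linspace(0, mat.shape[0] - 1, max_draws).astype(int)
        mat = mat[idx]
    if tuple(draws.names) != tuple(model.parameter_names()):
        raise ValueError("draws do not match the model's parameter set")

    rng = np.random.default_rng(seed)
    obs = model.observed()
    tiers = list(obs)
    n = mat.shape[0]
    rss_o = {t: np.empty(n) for t in tiers}
    rss_r = {t: np.empty(n) for t in tiers}
    for i in range(n):
        v = mat[i]
        means = model.fitted_means(v)
        rep = model.simulate_replicate(v, rng=rng)
        for t in tiers:
            d_obs = obs[t] - means[t]
            d_rep = rep[t] - means[t]
            rss_o[t][i] = d_obs @ d_obs
            rss_r[t][i] = d_rep @ d_rep

    res = PPCResult()
    pooled_o = np.zeros(n)
    pooled_r = np.zeros(n)
    for t in tiers:
        res.rss_observed[t] = rss_o[t]
        res.rss_replicated[t] = rss_r[t]
        res.bayesian_p[t] = float(np.mean(rss_r[t] >= rss_o[t]))
        pooled_o += rss_o[t]
        pooled_r += rss_r[t]
    res.rss_observed["pooled"] = pooled_o
    res.rss_replicated["pooled"] = pooled_r
    res.bayesian_p["pooled"] = float(np.mean(pooled_r >= pooled_o))
    return res
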