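"""Posterior sampling: chain schedules and the reference MCMC sampler.

The reference sampler is a Metropolis-within-Gibbs composite tailored to the
three-tier model:

* Gaussian-tier coefficient blocks and site effects have Gaussian full
  conditionals under the Normal priors and are drawn exactly (conjugate Gibbs
  steps);
* everything non-conjugate — herbivory-tier coefficients and site effects,
  all residual/site sds and the beta precision phi — is updated by adaptive
  random-walk Metropolis steps (log-scale walks for scale parameters, with
  the Jacobian), with proposal scales adapted toward a 0.44 acceptance rate
  during burn-in only, so all retained draws come from a fixed kernel.

Updates whose full conditionals factorize over disjoint observation groups
(the two genera, the three species, the sites) are proposed and
accepted/rejected jointly in vectorized form; this is what keeps the desk
schedule affordable on one CPU.

A generic componentwise adaptive random-walk kernel
(:func:`adaptive_rw_chain`) is exposed separately; it is the piece validated
against conjugate closed-form posteriors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import expit, gammaln

from .draws import PosteriorDraws
from .model import HierarchicalModel, ModelSpec, _beta_logpdf

__all__ = [
    "ChainSchedule",
    "PUBLICATION_SCHEDULE",
    "DESK_SCHEDULE",
    "retained_draw_count",
    "adaptive_rw_chain",
    "run_mcmc",
]


@dataclass(frozen=True)
class ChainSchedule:
    """MCMC chain schedule: chains, iterations, burn-in fraction, thinning."""

    n_chains: int = 3
    n_iterations: int = 400_000
    burn_in: float = 0.5
    thinning: int = 100
    seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.thinning < 1:
            raise ValueError("thinning interval must be >= 1")
        if not (0 <= self.burn_in < 1):
            raise ValueError("burn_in fraction must lie in [0, 1)")
        if self.seeds is not None and len(self.seeds) != self.n_chains:
            raise ValueError("one seed per chain required")

    @property
    def retained_per_chain(self) -> int:
        return math.floor(self.n_iterations * (1.0 - self.burn_in) / self.thinning)

    def chain_seeds(self, seed: int = 0) -> tuple[int, ...]:
        if self.seeds is not None:
            return tuple(self.seeds)
        state = np.random.SeedSequence(seed).generate_state(self.n_chains)
        return tuple(int(s % (2**31)) for s in state)


#: The publication-scale schedule: 3 x 400,000, half burn-in, thin 1/100.
PUBLICATION_SCHEDULE = ChainSchedule(3, 400_000, 0.5, 100)
#: Desk-scale schedule used throughout the test-suite experiments.
DESK_SCHEDULE = ChainSchedule(3, 20_000, 0.5, 10)


def retained_draw_count(schedule: ChainSchedule) -> int:
    """Total retained draws across chains for a schedule."""
    return schedule.n_chains * schedule.retained_per_chain


# ---------------------------------------------------------------------------
# generic componentwise adaptive random-walk Metropolis
# ---------------------------------------------------------------------------

def adaptive_rw_chain(
    logpdf,
    x0,
    n_iterations: int,
    seed: int = 0,
    *,
    burn_in: float = 0.5,
    thinning: int = 1,
    target_accept: float = 0.44,
    initial_scale: float = 1.0,
):
    """One chain of componentwise adaptive random-walk Metropolis.

    Proposal scales follow a Robbins-Monro recursion toward
    ``target_accept`` during burn-in and are frozen afterwards.  Returns
    ``(draws, info)`` where draws has shape (n_retained, n_dim).
    """
    rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    d = x.size
    scales = np.full(d, float(initial_scale))
    lp = float(logpdf(x))
    if not np.isfinite(lp):
        raise ValueError("log-density not finite at the initial point")

    n_retain = math.floor(n_iterations * (1.0 - burn_in) / thinning)
    n_burn = n_iterations - n_retain * thinning
    draws = np.empty((n_retain, d))
    acc_count = np.zeros(d)
    k = 0
    for t in range(1, n_iterations + 1):
        gamma = min(0.25, t ** -0.6)
        for j in range(d):
            prop = x.copy()
            prop[j] += scales[j] * rng.standard_normal()
            lp_prop = float(logpdf(prop))
            a = min(1.0, np.exp(min(0.0, lp_prop - lp)))
            if rng.uniform() < a:
                x, lp = prop, lp_prop
                acc_count[j] += 1
            if t <= n_burn:
                scales[j] *= math.exp(gamma * (a - target_accept))
        if t > n_burn and (t - n_burn) % thinning == 0:
            draws[k] = x
            k += 1
    info = {"scales": scales, "acceptance": acc_count / n_iterations,
            "n_burn": n_burn}
    return draws, info


# ---------------------------------------------------------------------------
# model-specific Metropolis-within-Gibbs
# ---------------------------------------------------------------------------

def _halfnormal_lp(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2  # constants cancel in MH ratios


class _ChainRunner:
    """One chain of the reference sampler over a bound HierarchicalModel."""

    def __init__(self, model: HierarchicalModel, rng: np.random.Generator):
        self.m = model
        self.rng = rng
        s = model.spec
        self.coef_sd = s.coef_prior_sd
        self.sd_scale = s.sd_prior_scale
        self.phi_shape = s.phi_prior_shape
        self.phi_rate = s.phi_prior_rate

        # precomputations
        self.XtX_soil = model.X_soil.T @ model.X_soil
        self.Xty_soil = {e: model.X_soil.T @ y for e, y in model.y_soil.items()}
        self.fol_pre = {}
        for r, t in model.fol.items():
            self.fol_pre[r] = {
                "XtX": t["X"].T @ t["X"],
                "Xt": t["X"].T.copy(),
            }
        if model.fol or model.herb is not None:
            self.site_counts = np.bincount(model.site_idx, minlength=model.n_sites)

        self.v = np.empty(model.n_params)
        self.herb_reps = 6
        self._init_state()
        self._init_scales()

    # -- initialization (overdispersed across chains via the chain rng) ----
    def _init_state(self):
        m, rng, v = self.m, self.rng, self.v
        for e, (bsl, isig) in m.soil_slices.items():
            v[bsl] = rng.normal(0.0, 1.0, bsl.stop - bsl.start)
            v[isig] = math.exp(rng.normal(0.0, 0.5))
        for r, (bsl, isig, itau, usl) in m.fol_slices.items():
            v[bsl] = rng.normal(0.0, 1.0, bsl.stop - bsl.start)
            v[isig] = math.exp(rng.normal(0.0, 0.5))
            v[itau] = math.exp(rng.normal(-1.0, 0.5))
            v[usl] = rng.normal(0.0, 0.1, usl.stop - usl.start)
        if m.herb_slices is not None:
            bsl, itau, usl, iphi = m.herb_slices
            # keep initial eta near the observed logit mean so the beta
            # likelihood is finite and informative from the start
            y = m.herb["y"]
            base = math.log(y.mean() / (1.0 - y.mean()))
            beta0 = rng.normal(0.0, 0.3, bsl.stop - bsl.start)
            beta0[: len(m.species)] += base
            v[bsl] = beta0
            v[itau] = math.exp(rng.normal(-1.0, 0.5))
            v[usl] = rng.normal(0.0, 0.1, usl.stop - usl.start)
            v[iphi] = math.exp(rng.normal(math.log(100.0), 0.7))
            self._refresh_herb_cache()

    def _init_scales(self):
        m = self.m
        self.sc_soil_sigma = {e: 0.3 for e in m.soil_slices}
        self.sc_fol = {r: {"sigma": 0.2, "tau": 0.4} for r in m.fol_slices}
        if m.herb_slices is not None:
            self.sc_herb_site = np.full(m.n_sites, 0.2)
            self.sc_herb_tau = 0.4
            self.sc_herb_phi = 0.2
            self._init_herb_blocks()

    def _init_herb_blocks(self):
        """Per-genus coefficient blocks for adaptive-Metropolis updates.

        Each genus's species intercepts and slopes only touch that genus's
        trees, so the two blocks have disjoint likelihood support and can be
        updated as joint multivariate random walks whose proposal covariance
        is the empirical posterior covariance accumulated during burn-in
        (Haario-style adaptive Metropolis, frozen after burn-in)."""
        m = self.m
        n_sp, n_pred = len(m.species), len(m.spec.herbivory_predictors)
        self.herb_blocks = []
        for gi, g in enumerate(m.genera):
            cols = [i for i, sp in enumerate(m.species) if m.genus_map[sp] == g]
            cols += [n_sp + gi * n_pred + k for k in range(n_pred)]
            cols = np.asarray(cols)
            d = len(cols)
            self.herb_blocks.append({
                "genus_index": gi,
                "cols": cols,
                "Xb": m.herb["X"][:, cols],
                "mask": (m.genus_idx == gi),
                "scale": 0.3,          # log proposal-magnitude multiplier
                "chol": np.eye(d) * 0.05,
                "welford_n": 0,
                "welford_mean": np.zeros(d),
                "welford_m2": np.zeros((d, d)),
            })

    def _update_block_covariance(self, blk):
        d = len(blk["cols"])
        if blk["welford_n"] > 4 * d:
            cov = blk["welford_m2"] / (blk["welford_n"] - 1)
            cov = (2.38**2 / d) * cov + 1e-9 * np.eye(d)
            try:
                blk["chol"] = cholesky(cov, lower=True)
            except np.linalg.LinAlgError:
                pass

    def _refresh_herb_cache(self):
        m, v = self.m, self.v
        bsl, itau, usl, iphi = m.herb_slices
        t = m.herb
        self.eta = t["X"] @ v[bsl] + v[usl][m.site_idx]
        mu = np.clip(expit(self.eta), 1e-12, 1.0 - 1e-12)
        self.ll_tree = _beta_logpdf(t["y"], t["ly"], t["l1y"], mu, v[iphi])

    # -- conjugate Gaussian draws ------------------------------------------
    def _draw_coef_block(self, XtX, Xty, sigma):
        p = XtX.shape[0]
        A = XtX / sigma**2 + np.eye(p) / self.coef_sd**2
        L = cholesky(A, lower=True)
        mean = solve_triangular(
            L.T, solve_triangular(L, Xty / sigma**2, lower=True), lower=False
        )
        z = self.rng.standard_normal(p)
        return mean + solve_triangular(L.T, z, lower=False)

    # -- scale-parameter random walks --------------------------------------
    def _rw_sigma(self, sigma, rss, n, scale):
        """MH step for a Gaussian residual sd on the log scale.

        Returns (new_sigma, acceptance_probability)."""
        prop = sigma * math.exp(scale * self.rng.standard_normal())
        dll = (
            -n * (math.log(prop) - math.log(sigma))
            - 0.5 * rss * (prop**-2 - sigma**-2)
        )
        dlp = _halfnormal_lp(prop, self.sd_scale) - _halfnormal_lp(sigma, self.sd_scale)
        djac = math.log(prop) - math.log(sigma)
        a = min(1.0, math.exp(min(0.0, dll + dlp + djac)))
        if self.rng.uniform() < a:
            return prop, a
        return sigma, a

    # -- per-iteration sweep ------------------------------------------------
    def sweep(self, t: int, adapt: bool):
        m, v, rng = self.m, self.v, self.rng
        gamma = min(0.25, t ** -0.6) if adapt else 0.0

        # soil tier
        for e, (bsl, isig) in m.soil_slices.items():
            v[bsl] = self._draw_coef_block(
                self.XtX_soil, self.Xty_soil[e], v[isig]
            )
            r = m.y_soil[e] - m.X_soil @ v[bsl]
            v[isig], a = self._rw_sigma(
                v[isig], float(r @ r), m.n_sites, self.sc_soil_sigma[e]
            )
            if adapt:
                self.sc_soil_sigma[e] *= math.exp(gamma * (a - 0.44))

        # foliage tiers
        for rname, (bsl, isig, itau, usl) in m.fol_slices.items():
            tier = m.fol[rname]
            pre = self.fol_pre[rname]
            u = v[usl]
            ytil = tier["y"] - u[m.site_idx]
            v[bsl] = self._draw_coef_block(
                pre["XtX"], pre["Xt"] @ ytil, v[isig]
            )
            resid = tier["y"] - tier["X"] @ v[bsl]
            # site effects: conjugate, vectorized over sites
            sums = np.bincount(m.site_idx, weights=resid, minlength=m.n_sites)
            prec = self.site_counts / v[isig] ** 2 + 1.0 / v[itau] ** 2
            mean = (sums / v[isig] ** 2) / prec
            v[usl] = mean + rng.standard_normal(m.n_sites) / np.sqrt(prec)
            u = v[usl]
            r_full = resid - u[m.site_idx]
            v[isig], a = self._rw_sigma(
                v[isig], float(r_full @ r_full), m.n_trees,
                self.sc_fol[rname]["sigma"],
            )
            if adapt:
                self.sc_fol[rname]["sigma"] *= math.exp(gamma * (a - 0.44))
            v[itau], a = self._rw_sigma(
                v[itau], float(u @ u), m.n_sites, self.sc_fol[rname]["tau"]
            )
            if adapt:
                self.sc_fol[rname]["tau"] *= math.exp(gamma * (a - 0.44))

        # herbivory tier: several cheap Metropolis sweeps per Gibbs cycle
        # (the non-conjugate tier mixes slowest; extra sweeps rebalance)
        if m.herb_slices is not None:
            for _ in range(self.herb_reps):
                self._sweep_herb(gamma, adapt)

    def _grouped_mh(self, group_idx, n_groups, step, dprior):
        """Vectorized MH over groups with disjoint observation support.

        ``step`` is the per-tree change in eta implied by the grouped
        proposals; acceptance is decided independently per group (the
        likelihood factorizes over trees and each tree belongs to exactly one
        group).  Returns ``(accept_mask, acceptance_probabilities)`` and
        updates the cached eta / per-tree log-likelihood for accepted groups.
        """
        m, v = self.m, self.v
        _, _, _, iphi = m.herb_slices
        t = m.herb
        eta_new = self.eta + step
        mu_new = np.clip(expit(eta_new), 1e-12, 1.0 - 1e-12)
        ll_new = _beta_logpdf(t["y"], t["ly"], t["l1y"], mu_new, v[iphi])
        dll = np.bincount(group_idx, weights=ll_new - self.ll_tree,
                          minlength=n_groups)
        log_a = np.minimum(0.0, dll + dprior)
        accept = np.log(self.rng.uniform(size=n_groups)) < log_a
        acc_tree = accept[group_idx]
        self.eta = np.where(acc_tree, eta_new, self.eta)
        self.ll_tree = np.where(acc_tree, ll_new, self.ll_tree)
        return accept, np.exp(log_a)

    def _sweep_herb(self, gamma, adapt):
        m, v, rng = self.m, self.v, self.rng
        bsl, itau, usl, iphi = m.herb_slices
        t = m.herb
        beta = v[bsl]

        # per-genus coefficient blocks: joint adaptive-Metropolis proposals.
        # The two blocks touch disjoint tree sets, so both are proposed and
        # accepted/rejected in one vectorized likelihood evaluation.
        n_gen = len(m.genera)
        step = np.zeros(m.n_trees)
        deltas, olds, dprior = [], [], np.zeros(n_gen)
        for gi, blk in enumerate(self.herb_blocks):
            z = rng.standard_normal(len(blk["cols"]))
            delta = blk["scale"] * (blk["chol"] @ z)
            old = beta[blk["cols"]]
            step += blk["Xb"] @ delta
            dprior[gi] = float(
                -np.sum((old + delta) ** 2 - old**2) / (2 * self.coef_sd**2)
            )
            deltas.append(delta)
            olds.append(old)
        accept, a = self._grouped_mh(m.genus_idx, n_gen, step, dprior)
        for gi, blk in enumerate(self.herb_blocks):
            if accept[gi]:
                beta[blk["cols"]] = olds[gi] + deltas[gi]
            if adapt:
                blk["scale"] *= math.exp(gamma * (a[gi] - 0.234))
                # accumulate posterior moments for the proposal covariance
                x = beta[blk["cols"]]
                blk["welford_n"] += 1
                dmean = x - blk["welford_mean"]
                blk["welford_mean"] += dmean / blk["welford_n"]
                blk["welford_m2"] += np.outer(dmean, x - blk["welford_mean"])
                if blk["welford_n"] % 200 == 0:
                    self._update_block_covariance(blk)

        # site effects (disjoint by site), prior N(0, tau)
        u = v[usl].copy()
        deltas = self.sc_herb_site * rng.standard_normal(m.n_sites)
        dprior = -((u + deltas) ** 2 - u**2) / (2 * v[itau] ** 2)
        accept, a = self._grouped_mh(m.site_idx, m.n_sites, deltas[m.site_idx],
                                     dprior)
        v[usl] = u + deltas * accept
        if adapt:
            self.sc_herb_site *= np.exp(gamma * (a - 0.44))

        # site sd
        u = v[usl]
        v[itau], a = self._rw_sigma(
            v[itau], float(u @ u), m.n_sites, self.sc_herb_tau
        )
        if adapt:
            self.sc_herb_tau *= math.exp(gamma * (a - 0.44))

        # beta precision phi (log-scale RW, Gamma prior)
        phi = v[iphi]
        prop = phi * math.exp(self.sc_herb_phi * rng.standard_normal())
        mu = np.clip(expit(self.eta), 1e-12, 1.0 - 1e-12)
        ll_new = _beta_logpdf(t["y"], t["ly"], t["l1y"], mu, prop)
        dll = float(np.sum(ll_new - self.ll_tree))
        dlp = (
            (self.phi_shape - 1.0) * (math.log(prop) - math.log(phi))
            - self.phi_rate * (prop - phi)
        )
        djac = math.log(prop) - math.log(phi)
        a = min(1.0, math.exp(min(0.0, dll + dlp + djac)))
        if rng.uniform() < a:
            v[iphi] = prop
            self.ll_tree = ll_new
        if adapt:
            self.sc_herb_phi *= math.exp(gamma * (a - 0.44))


def run_mcmc(
    model,
    data=None,
    schedule: ChainSchedule = DESK_SCHEDULE,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the joint posterior with the reference sampler.

    ``model`` may be a bound :class:`HierarchicalModel` or a
    :class:`ModelSpec` (then ``data`` must be the AnalysisData to bind).
    Fully reproducible: per-chain seeds derive from ``seed`` (or from
    ``schedule.seeds`` when given).
    """
    if isinstance(model, ModelSpec):
        model = HierarchicalModel(model, data)
    seeds = schedule.chain_seeds(seed)
    n_retain = schedule.retained_per_chain
    n_burn = schedule.n_iterations - n_retain * schedule.thinning
    values = np.empty((schedule.n_chains, n_retain, model.n_params))

    for c, chain_seed in enumerate(seeds):
        runner = _ChainRunner(model, np.random.default_rng(chain_seed))
        lp0 = model.log_posterior(runner.v)
        if not np.isfinite(lp0):
            raise RuntimeError(
                f"chain {c}: non-finite log-posterior at initialization "
                f"(lp={lp0}); check data and spec"
            )
        k = 0
        for t in range(1, schedule.n_iterations + 1):
            runner.sweep(t, adapt=(t <= n_burn))
            if t > n_burn and (t - n_burn) % schedule.thinning == 0:
                values[c, k] = runner.v
                k += 1
        assert k == n_retain

    return PosteriorDraws(
        values, model.parameter_names(), schedule=schedule, seeds=seeds,
        meta={"backend": "reference-mwg", "n_burn": n_burn},
    )
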