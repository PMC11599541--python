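# Methods

This note documents the model, the synthetic-data generator, the sampler,
and the numerical and design choices behind them. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The joint model

The model mirrors the assumed causal ordering of the study system —
climate/geology → soil → foliage → herbivory — as three likelihood tiers
sharing one acyclic predictor graph.

**Soil tier (site level).** Each of the five soil responses (N, P, K, Na and
the C:N ratio), depth-averaged per site and standardized across sites, is
Gaussian in reference-cell geology (basalt is the reference class; granite
and rhyolite get offsets) and standardized linear + quadratic climate (MAT,
MAT², MAP, MAP²). Quadratic terms are squares of the *standardized* linear
column, so their slopes live on a comparable scale. Because soil is measured
once per site, this tier carries no separate site random effect — its
residual absorbs site heterogeneity.

**Foliage tier (tree level).** Foliar total N and N digestibility
(standardized across trees) are Gaussian in species-specific intercepts
(three species), genus-specific slopes (two genera) over the five soil
elements, geology and the four climate terms, plus a site random effect
`Normal(0, tau)` and a residual. "Three intercepts and two slopes per
predictor" is the fixed shape of this tier and the next. Dry-matter
digestibility is carried in the data model but not modelled by default.

**Herbivory tier (tree level).** The response is the per-tree mean of the
leaf damage proportions (the natural estimator of a tree's expected damage;
a leaf-level response is a possible extension, but the tree level is the
default). It follows a beta distribution in the mean–precision
parameterization, `Beta(mu*phi, (1-mu)*phi)` with
`Var = mu(1-mu)/(1+phi)`, and `logit(mu)` is linear in the same
species/genus structure with foliar total N and N digestibility added as
predictors. Damage values are clamped into `(1e-6, 1 - 1e-6)` so the
likelihood is finite; observed damage in this kind of data never reaches the
boundaries, and values away from the boundary are preserved bit-exactly
(an alternative would be the Smithson–Verkuilen shrink-toward-1/2
transform, which perturbs every observation; the clamp perturbs none in
practice).

**Priors.** Vague on the standardized scale: `Normal(0, 10)` for every
intercept, slope and geology offset; `Half-Normal(5)` for residual and
site-effect sds; `Gamma(0.01, 0.01)` for the beta precision. Site effects
are hierarchical, `Normal(0, site_sd)`. These are declared package choices:
on standardized data they are far wider than any plausible effect, and the
prior is proper (the test suite integrates a reduced model's prior to 1 by
quadrature).

**Predictor sets.** The defaults above are the superset implied by the tier
wiring — every upstream variable feeds every downstream tier. All sets are
config-overridable (`ModelSpec`), and reduced models (fewer elements, no
foliage or herbivory tier) are first-class, which the fast calibration tests
exploit.

## The synthetic landscape generator

The generator is the package's substitute for field data: it produces
datasets with the same statistical structure and *known* coefficients.

* **Sites.** A latent elevation axis drives MAT downward (high = cool); a
  latent longitude axis drives MAP downward (west = dry). Both axes are
  stratified-uniform (one draw per equal-width bin), so the configured
  ranges — 14–26 °C and 1200–4000 mm/yr by default — are spanned at any
  site count; the axes are rank-correlated at 0.3 by default, giving crossed
  but not independent gradients. Geology classes are tiled across sites and
  shuffled, so every class always appears.
* **Species plan.** Defaults to 115 pioneer trees (*Alphitonia petriei*) and
  22 + 42 late-successional trees (*Flindersia brayleyana*,
  *F. pimenteliana*); the pioneer occupies every site, the late-successional
  species a random site subset with inclusion probabilities 0.48 and 0.60,
  approximating the uneven coverage of such species along gradients. Sample
  sizes and coverages are configuration, not constants.
* **Responses.** Soil is generated on an arbitrary unitless scale; foliar
  total N in natural % dry matter and digestibility as a fraction (clipped
  to [0, 1], with parameters chosen so clipping is rare); herbivory on the
  logit scale with leaf-level beta draws aggregated to tree means. The
  generator standardizes its covariates with the same code path the
  `prepare` step uses, so generated coefficients correspond exactly to
  fitted ones after an affine response rescaling; `truth_on_model_scale`
  performs that mapping exactly.
* **Default truth.** Signs follow the gradient structure the model is built
  to detect (basalt = nutrient-rich; precipitation raises soil N and P and
  lowers K and C:N; temperature raises K and lowers Na and C:N; foliar N
  higher on basalt; *Flindersia* climate-sensitive; herbivory rising with
  temperature and foliar N, falling with soil C:N for *Flindersia*), with
  one deliberately strong indirect chain MAP → soil C:N →
  herbivory(*Flindersia*), both edges near −0.8 standardized.
* **Identifiability calibration.** The herbivory tier regresses on five soil
  elements *and* the climate/geology terms that drive them. If the soil
  residual sd is small, each soil element is almost an exact linear
  combination of co-included predictors and no soil slope is identifiable at
  25 sites (the design matrix R² of soil C:N on the other predictors
  approaches 0.99). The default truth therefore uses soil residual sd 1.0
  against systematic magnitudes of 0.3–0.8, leaf-level beta precision
  phi = 40 with 20 leaves per tree (tree-mean precision ≈ 20·(1+phi) − 1),
  and a herbivory site sd of 0.15 logits — a landscape in which the planted
  effects are recoverable at the study's own sample sizes. This is a
  property of the simulated *design*, not of the inference.
* **What the generator does not emulate.** No spatial autocorrelation beyond
  the site effect, no temporal dynamics (each tree sampled once), no
  measurement error in covariates, no leaf-level damage zero-inflation, and
  tree-mean damage is only approximately beta (it is a mean of 20 beta
  draws). Passing tests therefore validate the inference machinery on data
  matching the model's assumptions plus this one benign aggregation
  mismatch; they do not certify behaviour under real-data pathologies.

## Sampling

The reference sampler is Metropolis-within-Gibbs, specialized to the tier
structure:

* Gaussian-tier coefficient blocks and site effects have Gaussian full
  conditionals under the Normal priors and are drawn exactly (Cholesky
  solves; site effects vectorized over sites).
* Residual/site sds and the beta precision use log-scale random-walk
  Metropolis with the Jacobian, scales adapted toward 0.44 acceptance.
* Herbivory coefficients are updated per genus as joint blocks: each genus's
  intercepts and slopes touch only that genus's trees, so the two blocks are
  proposed together and accepted/rejected independently in one vectorized
  likelihood evaluation. Proposals are Haario-style adaptive Metropolis —
  multivariate normal with covariance `2.38²/d` times the running empirical
  posterior covariance (Welford accumulation), scaled toward 0.234
  acceptance. Herbivory site effects are updated as a vectorized
  per-site random walk. The herbivory tier gets six such sweeps per Gibbs
  cycle; it is the slowest-mixing part and the sweeps are cheap.
* All adaptation stops at the end of burn-in, so retained draws come from a
  fixed kernel. Initialization is overdispersed across chains (coefficient
  draws ~ Normal(0,1), log-scale jitter on sds and phi), with the herbivory
  intercepts anchored at the observed mean logit so the likelihood is finite
  at the start; a non-finite initial posterior raises immediately.

Retention bookkeeping: with `n` iterations, burn-in fraction `b` and
thinning `t`, exactly `floor(n·(1−b)/t)` draws are kept per chain, counted
from the end — the publication schedule (3 × 400,000, b = 0.5, t = 100)
yields exactly 6,000 retained draws. The desk schedule (3 × 20,000, b = 0.5,
t = 10 → 3,000 draws) is the default for experiments and takes ~2 minutes
per fit on one CPU at the default problem size (200 parameters, 25 sites,
179 trees).

A generic componentwise adaptive random-walk kernel (`adaptive_rw_chain`) is
exposed separately; it is validated against closed-form conjugate posteriors
(Normal mean with known variance; beta-proportion), and the tier-specialized
sampler is cross-checked against it on reduced models.

## Diagnostics

* **R-hat**: the classic (non-split, non-rank-normalized) Gelman–Rubin
  potential scale reduction factor, `sqrt(((n−1)/n·W + B/n)/W)`; convergence
  is declared at R̂ − 1 < 0.1. A split variant is available (it additionally
  flags within-chain trends); the classic form is the default because the
  declared threshold refers to it.
* **Posterior-predictive check**: for each retained draw, the residual sum
  of squares of the observed responses about the fitted means is paired with
  the RSS of one likelihood replicate about the same means; the Bayesian
  p-value is `P(RSS_rep ≥ RSS_obs)` with ties counted as exceedance (so a
  degenerate fit with zero discrepancies gives p = 1, not NaN). Discrepancies
  are computed per tier and pooled; the pooled value sums tiers, which on
  standardized Gaussian responses weighs them comparably but lets the seven
  Gaussian tiers dominate the tiny-scale herbivory RSS — a herbivory-specific
  mis-specification is therefore read from the herbivory-tier p-value, and
  the mis-specification experiment injects a +6 logit offset into half the
  trees' damage (unpredictable from any model covariate) as its gross
  violation.

## Effect summaries

Posterior mean plus 89% *equal-tailed* interval (quantiles 0.055/0.945).
Equal-tailed is the default over highest-density intervals because it is
deterministic, has a trivial independent oracle, and is what interval-based
screening needs; "does not greatly overlap zero" is operationalized as the
interval excluding zero, with the level configurable. Indirect effects are
draw-wise products of standardized linear coefficients along tier-ordered
paths — never products of summarized means — and quadratic climate terms are
excluded from path products (a squared-term coefficient has no
sign-interpretable "effect per sd" to chain). The path graph retains an edge
per coefficient whose interval excludes zero, marks quadratic edges as
direct-only, and enumerates all abiotic → herbivory paths up to the full
3-edge cascade; genus consistency is enforced by construction (foliage and
herbivory nodes are genus-specific and never cross).

Coverage checks compare fitted intervals against `truth_on_model_scale`
output over intercepts, slopes and geology offsets only: scale parameters
are excluded because the tree-mean aggregation makes the model's precision a
derived quantity (≈ `k(1+phi_leaf) − 1`) rather than a generator parameter.

## Problem sizes used by the test suite

All experiment sizes are package choices balancing statistical resolution
against a laptop-class budget: unit and oracle tests run on a 6-site,
20-tree landscape; Monte-Carlo moment checks use 10⁴–10⁵ draws with 3-SE
tolerances; interval-coverage calibration runs 20 simulate-fit replicates of
the (conjugate, fast) soil-only model; and the end-to-end recovery and
diagnostics experiments run five full simulate-fit replicates at the default
landscape (25 sites / 179 trees / 3,580 leaves) under the desk schedule,
plus one mis-specified fit. The acceptance script repeats one well-specified
and one mis-specified cycle at the same sizes.

## Known limitations

* The sampler is specialized to this model family; it is a reference
  implementation, not a general PPL backend (external samplers can be
  plugged in by targeting `HierarchicalModel.log_posterior`).
* With the full predictor superset, site-level predictors are strongly
  collinear at 25 sites; posterior intervals honestly reflect that, and
  variable selection (which the original analysis handled separately) is
  out of scope.
* Bayesian p-values from an RSS discrepancy are not uniformly distributed
  under a well-specified model; with many parameters per tier they drift
  above 0.5 (replicate RSS tracks the residual-variance estimate, observed
  RSS the overfitted residuals). The calibration band used in testing
  ([0.25, 0.75] pooled) accounts for this.
* Damage exactly 0 or 1 cannot enter the beta likelihood; the clamp handles
  it, but data dominated by exact zeros would need a zero-inflated model.
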