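"""The joint hierarchical model: likelihoods, priors, and forward simulation.

Three tiers mirror the assumed causal cascade of the study system:

* **soil** — each soil element, standardized at the site level, is Gaussian in
  geology (reference-cell coding) and standardized linear+quadratic climate;
* **foliage** — each foliar response (standardized across trees) is Gaussian
  in species-specific intercepts, genus-specific slopes over soil, climate and
  geology, a site random effect, and a residual;
* **herbivory** — per-tree mean leaf damage follows a beta distribution in its
  mean/precision parameterization, Beta(mu*phi, (1-mu)*phi), with
  mu = logit^-1(species intercept + genus slopes + site effect) and
  Var = mu(1-mu)/(1+phi).

Priors are vague on the standardized scale: Normal(0, 10) on every intercept,
slope and geology offset; Half-Normal(5) on residual and site-effect sds;
Gamma(0.01, 0.01) on the beta precision phi.  Site effects are hierarchical,
Normal(0, site_sd).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .prepare import SOIL_ELEMENTS, AnalysisData

__all__ = [
    "ModelSpec",
    "ParameterVector",
    "HierarchicalModel",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "simulate_replicate",
    "truth_on_model_scale",
]

LOG_2PI = float(np.log(2.0 * np.pi))


def _default_foliage_predictors():
    return [f"soil_{e}" for e in SOIL_ELEMENTS] + [
        "mat", "mat2", "map", "map2", "geo_granite", "geo_rhyolite",
    ]


def _default_herbivory_predictors():
    return ["total_n", "n_digest"] + _default_foliage_predictors()


@dataclass
class ModelSpec:
    """Declarative specification of the joint model.

    Predictor lists name columns of the analysis frames: continuous predictors
    refer to their standardized ``z_`` versions, ``geo_<class>`` entries are
    reference-cell geology indicators (the reference class gets no offset).
    Genus-specific slopes and species-specific intercepts apply in the foliage
    and herbivory tiers; the soil tier is site-level with a single slope per
    predictor.
    """

    soil_elements: tuple = SOIL_ELEMENTS
    foliage_responses: tuple = ("total_n", "n_digest")
    include_herbivory: bool = True
    geology_classes: tuple = ("basalt", "granite", "rhyolite")
    soil_predictors: list = field(
        default_factory=lambda: ["geo_granite", "geo_rhyolite",
                                 "mat", "mat2", "map", "map2"]
    )
    foliage_predictors: list = field(default_factory=_default_foliage_predictors)
    herbivory_predictors: list = field(default_factory=_default_herbivory_predictors)
    # prior settings (standardized scale)
    coef_prior_sd: float = 10.0
    sd_prior_scale: float = 5.0
    phi_prior_shape: float = 0.01
    phi_prior_rate: float = 0.01

    @property
    def geology_reference(self) -> str:
        return self.geology_classes[0]

    def to_dict(self) -> dict:
        """JSON-serializable form of the model spec (round-trips via from_dict)."""
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, blob: dict) -> "ModelSpec":
        blob = dict(blob)
        for key in ("soil_elements", "foliage_responses", "geology_classes"):
            if key in blob:
                blob[key] = tuple(blob[key])
        return cls(**blob)

    def validate(self, data: AnalysisData) -> None:
        for sp in data.species:
            if sp not in data.genus_map:
                raise ValueError(f"species {sp!r} has no genus mapping")
        known = (
            {f"soil_{e}" for e in self.soil_elements}
            | {"mat", "mat2", "map", "map2", "total_n", "n_digest"}
            | {f"geo_{c}" for c in self.geology_classes[1:]}
        )
        active = [self.soil_predictors]
        if self.foliage_responses:
            active.append(self.foliage_predictors)
        if self.include_herbivory:
            active.append(self.herbivory_predictors)
        for plist in active:
            for p in plist:
                if p not in known:
                    raise ValueError(f"unknown predictor {p!r} in model spec")
        # the tier ordering climate/geology -> soil -> foliage -> herbivory is
        # acyclic by construction: soil predictors exclude soil and foliar
        # responses, foliage predictors exclude foliar responses
        for p in self.soil_predictors:
            if p.startswith("soil_") or p in ("total_n", "n_digest"):
                raise ValueError(f"soil tier cannot depend on {p!r} (cycle)")
        for p in self.foliage_predictors:
            if p in ("total_n", "n_digest"):
                raise ValueError(f"foliage tier cannot depend on {p!r} (cycle)")


class ParameterVector:
    """A flat named parameter vector for the joint model."""

    __slots__ = ("names", "values", "_index")

    def __init__(self, names, values):
        self.names = tuple(names)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values length does not match names")
        self._index = {n: i for i, n in enumerate(self.names)}

    @classmethod
    def from_dict(cls, names, mapping, default=None):
        vals = np.empty(len(names))
        for i, n in enumerate(names):
            if n in mapping:
                vals[i] = mapping[n]
            elif default is not None:
                vals[i] = default
            else:
                raise KeyError(f"missing parameter {n!r}")
        return cls(names, vals)

    def __getitem__(self, name):
        return self.values[self._index[name]]

    def __len__(self):
        return len(self.names)

    def as_dict(self):
        return dict(zip(self.names, self.values))

    def replace(self, **updates):
        vals = self.values.copy()
        for n, v in updates.items():
            vals[self._index[n]] = v
        return ParameterVector(self.names, vals)


def _beta_logpdf(y, ly, l1y, mu, phi):
    """Beta log-density in mean/precision form, elementwise (y logs cached)."""
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1.0) * ly + (b - 1.0) * l1y
    )


class HierarchicalModel:
    """A ModelSpec bound to data: evaluable log-densities and a simulator."""

    def __init__(self, spec: ModelSpec, data: AnalysisData):
        spec.validate(data)
        self.spec = spec
        self.data = data
        sf, tf = data.site_frame, data.tree_frame

        self.site_ids = list(sf["site_id"])
        self.n_sites = len(self.site_ids)
        self.n_trees = len(tf)
        self.species = list(data.species)
        self.genera = list(data.genera)
        self.genus_map = dict(data.genus_map)

        # --- soil tier design (site level) -------------------------------
        self.soil_cols = ["intercept"] + list(spec.soil_predictors)
        self.X_soil = np.column_stack(
            [np.ones(self.n_sites)]
            + [self._column(sf, p) for p in spec.soil_predictors]
        )
        self.y_soil = {
            e: sf[f"z_soil_{e}"].to_numpy(dtype=float) for e in spec.soil_elements
        }

        # --- tree-level structure ----------------------------------------
        site_index = {s: i for i, s in enumerate(self.site_ids)}
        self.site_idx = tf["site_id"].map(site_index).to_numpy()
        self.species_idx = tf["species"].map(
            {s: i for i, s in enumerate(self.species)}
        ).to_numpy()
        self.genus_idx = tf["genus"].map(
            {g: i for i, g in enumerate(self.genera)}
        ).to_numpy()

        def tier_design(predictors):
            cols = []
            names = [f"intercept[{sp}]" for sp in self.species]
            for i, sp in enumerate(self.species):
                cols.append((self.species_idx == i).astype(float))
            for g in self.genera:
                gmask = (tf["genus"] == g).to_numpy(dtype=float)
                for p in predictors:
                    cols.append(self._column(tf, p) * gmask)
                    names.append(f"slope[{g}][{p}]")
            return np.column_stack(cols), names

        self.fol = {}
        for r in spec.foliage_responses:
            X, coef_names = tier_design(spec.foliage_predictors)
            self.fol[r] = {
                "X": X, "coef_names": coef_names,
                "y": tf[f"z_{r}"].to_numpy(dtype=float),
            }

        self.herb = None
        if spec.include_herbivory:
            if "damage" not in tf.columns:
                raise ValueError("herbivory tier requested but no damage column")
            y = tf["damage"].to_numpy(dtype=float)
            if not ((y > 0) & (y < 1)).all():
                raise ValueError("tree damage must lie strictly in (0, 1)")
            X, coef_names = tier_design(spec.herbivory_predictors)
            self.herb = {
                "X": X, "coef_names": coef_names, "y": y,
                "ly": np.log(y), "l1y": np.log1p(-y),
            }

        self._build_layout()

    def _column(self, frame, p):
        if p.startswith("geo_"):
            return (frame["geology"] == p[4:]).to_numpy(dtype=float)
        return frame[f"z_{p}"].to_numpy(dtype=float)

    # -- parameter layout --------------------------------------------------
    def _build_layout(self):
        names: list[str] = []
        self.slices: dict[str, slice | dict] = {}

        def add(block_names):
            start = len(names)
            names.extend(block_names)
            return slice(start, len(names))

        self.soil_slices = {}
        for e in self.spec.soil_elements:
            beta = add([f"soil_{e}.{c}" for c in self.soil_cols])
            sig = add([f"soil_{e}.sigma"])
            self.soil_slices[e] = (beta, sig.start)
        self.fol_slices = {}
        for r in self.spec.foliage_responses:
            beta = add([f"{r}.{c}" for c in self.fol[r]["coef_names"]])
            sig = add([f"{r}.sigma"])
            tau = add([f"{r}.site_sd"])
            u = add([f"{r}.site[{s}]" for s in self.site_ids])
            self.fol_slices[r] = (beta, sig.start, tau.start, u)
        self.herb_slices = None
        if self.herb is not None:
            beta = add([f"herbivory.{c}" for c in self.herb["coef_names"]])
            tau = add(["herbivory.site_sd"])
            u = add([f"herbivory.site[{s}]" for s in self.site_ids])
            phi = add(["herbivory.phi"])
            self.herb_slices = (beta, tau.start, u, phi.start)
        self.names = tuple(names)
        self.n_params = len(names)

    def parameter_names(self):
        return self.names

    def _values(self, params) -> np.ndarray:
        if isinstance(params, ParameterVector):
            if params.names != self.names:
                return ParameterVector.from_dict(self.names, params.as_dict()).values
            return params.values
        if isinstance(params, dict):
            return ParameterVector.from_dict(self.names, params).values
        v = np.asarray(params, dtype=float)
        if v.shape != (self.n_params,):
            raise ValueError("parameter vector length mismatch")
        return v

    def parameter_vector(self, mapping, default=None) -> ParameterVector:
        return ParameterVector.from_dict(self.names, mapping, default=default)

    # -- densities ----------------------------------------------------------
    def _check_scales(self, v):
        for e, (b, isig) in self.soil_slices.items():
            if v[isig] <= 0:
                raise ValueError(f"non-positive residual sd for soil {e}")
        for r, (b, isig, itau, u) in self.fol_slices.items():
            if v[isig] <= 0 or v[itau] <= 0:
                raise ValueError(f"non-positive sd in foliage tier {r}")
        if self.herb_slices is not None:
            b, itau, u, iphi = self.herb_slices
            if v[itau] <= 0:
                raise ValueError("non-positive site sd in herbivory tier")
            if v[iphi] <= 0:
                raise ValueError("non-positive beta precision phi")

    def _scales_ok(self, v) -> bool:
        try:
            self._check_scales(v)
            return True
        except ValueError:
            return False

    def tier_log_likelihoods(self, params) -> dict[str, float]:
        """Per-tier log-likelihood contributions (they sum to the total)."""
        v = self._values(params)
        self._check_scales(v)
        out: dict[str, float] = {}
        for e, (bsl, isig) in self.soil_slices.items():
            mean = self.X_soil @ v[bsl]
            sig = v[isig]
            r = self.y_soil[e] - mean
            out[f"soil_{e}"] = float(
                -0.5 * np.sum(r * r) / sig**2
                - self.n_sites * (np.log(sig) + 0.5 * LOG_2PI)
            )
        for rname, (bsl, isig, itau, usl) in self.fol_slices.items():
            t = self.fol[rname]
            mean = t["X"] @ v[bsl] + v[usl][self.site_idx]
            sig = v[isig]
            r = t["y"] - mean
            out[rname] = float(
                -0.5 * np.sum(r * r) / sig**2
                - self.n_trees * (np.log(sig) + 0.5 * LOG_2PI)
            )
        if self.herb_slices is not None:
            bsl, itau, usl, iphi = self.herb_slices
            t = self.herb
            eta = t["X"] @ v[bsl] + v[usl][self.site_idx]
            mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
            out["herbivory"] = float(
                np.sum(_beta_logpdf(t["y"], t["ly"], t["l1y"], mu, v[iphi]))
            )
        return out

    def log_likelihood(self, params) -> float:
        return float(sum(self.tier_log_likelihoods(params).values()))

    def log_prior(self, params) -> float:
        v = self._values(params)
        self._check_scales(v)
        s = self.spec
        lp = 0.0

        def normal_lp(x, sd):
            x = np.atleast_1d(x)
            return float(
                -0.5 * np.sum(x * x) / sd**2 - x.size * (np.log(sd) + 0.5 * LOG_2PI)
            )

        def halfnormal_lp(x, scale):
            return float(
                0.5 * np.log(2.0 / np.pi) - np.log(scale)
                - 0.5 * (x / scale) ** 2
            )

        for e, (bsl, isig) in self.soil_slices.items():
            lp += normal_lp(v[bsl], s.coef_prior_sd)
            lp += halfnormal_lp(v[isig], s.sd_prior_scale)
        for r, (bsl, isig, itau, usl) in self.fol_slices.items():
            lp += normal_lp(v[bsl], s.coef_prior_sd)
            lp += halfnormal_lp(v[isig], s.sd_prior_scale)
            lp += halfnormal_lp(v[itau], s.sd_prior_scale)
            lp += normal_lp(v[usl], v[itau])  # hierarchical site effects
        if self.herb_slices is not None:
            bsl, itau, usl, iphi = self.herb_slices
            lp += normal_lp(v[bsl], s.coef_prior_sd)
            lp += halfnormal_lp(v[itau], s.sd_prior_scale)
            lp += normal_lp(v[usl], v[itau])
            a, b = s.phi_prior_shape, s.phi_prior_rate
            lp += float(
                a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(v[iphi])
                - b * v[iphi]
            )
        return lp

    def log_posterior(self, params) -> float:
        v = self._values(params)
        if not self._scales_ok(v):
            return -np.inf
        return self.log_prior(v) + self.log_likelihood(v)

    # -- forward simulation -------------------------------------------------
    def fitted_means(self, params) -> dict[str, np.ndarray]:
        """Expected responses at ``params`` (herbivory on the damage scale)."""
        v = self._values(params)
        out = {}
        for e, (bsl, isig) in self.soil_slices.items():
            out[f"soil_{e}"] = self.X_soil @ v[bsl]
        for r, (bsl, isig, itau, usl) in self.fol_slices.items():
            out[r] = self.fol[r]["X"] @ v[bsl] + v[usl][self.site_idx]
        if self.herb_slices is not None:
            bsl, itau, usl, iphi = self.herb_slices
            eta = self.herb["X"] @ v[bsl] + v[usl][self.site_idx]
            out["herbivory"] = expit(eta)
        return out

    def observed(self) -> dict[str, np.ndarray]:
        obs = {f"soil_{e}": self.y_soil[e] for e in self.spec.soil_elements}
        for r in self.spec.foliage_responses:
            obs[r] = self.fol[r]["y"]
        if self.herb is not None:
            obs["herbivory"] = self.herb["y"]
        return obs

    def simulate_replicate(self, params, rng=None, seed=None) -> dict[str, np.ndarray]:
        """Draw one replicate of every response from the likelihood at params."""
        if rng is None:
            rng = np.random.default_rng(seed)
        v = self._values(params)
        self._check_scales(v)
        means = self.fitted_means(v)
        rep = {}
        for e, (bsl, isig) in self.soil_slices.items():
            rep[f"soil_{e}"] = means[f"soil_{e}"] + v[isig] * rng.standard_normal(
                self.n_sites
            )
        for r, (bsl, isig, itau, usl) in self.fol_slices.items():
            rep[r] = means[r] + v[isig] * rng.standard_normal(self.n_trees)
        if self.herb_slices is not None:
            bsl, itau, usl, iphi = self.herb_slices
            mu = np.clip(means["herbivory"], 1e-12, 1.0 - 1e-12)
            phi = v[iphi]
            rep["herbivory"] = rng.beta(mu * phi, (1.0 - mu) * phi)
        return rep


# module-level functional wrappers -----------------------------------------

def _as_model(model, data=None, spec=None):
    if isinstance(model, HierarchicalModel):
        return model
    return HierarchicalModel(model if spec is None else spec, data)


def log_likelihood(params, data, spec: ModelSpec | None = None) -> float:
    return HierarchicalModel(spec or ModelSpec(), data).log_likelihood(params)


def log_prior(params, data, spec: ModelSpec | None = None) -> float:
    return HierarchicalModel(spec or ModelSpec(), data).log_prior(params)


def log_posterior(params, data, spec: ModelSpec | None = None) -> float:
    return HierarchicalModel(spec or ModelSpec(), data).log_posterior(params)


def simulate_replicate(params, data, spec: ModelSpec | None = None, seed=None):
    return HierarchicalModel(spec or ModelSpec(), data).simulate_replicate(
        params, seed=seed
    )


# ground-truth mapping -------------------------------------------------------

def truth_on_model_scale(truth, data: AnalysisData, spec: ModelSpec | None = None,
                         leaves_per_tree: int = 20) -> dict[str, float]:
    """Express generator ground truth on the fitted (standardized) scale.

    The model standardizes each response; standardization is affine, so the
    generating coefficients map exactly: slopes and sds divide by the realized
    response sd, intercepts recenter.  The herbivory tier is already on the
    model scale except for the beta precision: the model sees per-tree means
    of ``k`` leaves, whose effective precision is ``k * (1 + phi_leaf) - 1``.
    Only parameters present in the bound model's name set are returned.
    """
    spec = spec or ModelSpec()
    out: dict[str, float] = {}
    for e, c in truth.soil_coeffs.items():
        col = f"soil_{e}"
        if col not in data.site_scaler.sds:
            continue
        m, d = data.site_scaler.means[col], data.site_scaler.sds[col]
        out[f"soil_{e}.intercept"] = (c["intercept"] - m) / d
        for p in spec.soil_predictors:
            if p.startswith("geo_"):
                out[f"soil_{e}.{p}"] = c["geo"].get(p[4:], 0.0) / d
            else:
                out[f"soil_{e}.{p}"] = c.get(p, 0.0) / d
        out[f"soil_{e}.sigma"] = c["sigma"] / d
    for r, c in truth.foliage_coeffs.items():
        if r not in data.tree_scaler.sds:
            continue
        m, d = data.tree_scaler.means[r], data.tree_scaler.sds[r]
        for sp, a in c["intercepts"].items():
            out[f"{r}.intercept[{sp}]"] = (a - m) / d
        for g, slopes in c["slopes"].items():
            for p in spec.foliage_predictors:
                out[f"{r}.slope[{g}][{p}]"] = slopes.get(p, 0.0) / d
        out[f"{r}.sigma"] = c["sigma"] / d
        out[f"{r}.site_sd"] = c["site_sd"] / d
    hc = truth.herbivory_coeffs
    for sp, a in hc["intercepts"].items():
        out[f"herbivory.intercept[{sp}]"] = a
    for g, slopes in hc["slopes"].items():
        for p in spec.herbivory_predictors:
            out[f"herbivory.slope[{g}][{p}]"] = slopes.get(p, 0.0)
    out["herbivory.site_sd"] = hc["site_sd"]
    out["herbivory.phi"] = leaves_per_tree * (1.0 + hc["phi"]) - 1.0
    return out
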