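"""Synthetic landscape generator with known ground truth.

Emulates the statistical structure the analysis assumes: a network of sites
spanning crossed temperature/precipitation gradients over three geology
classes; depth-averaged soil chemistry driven by geology and linear+quadratic
climate; trees of three species in two genera (a widespread pioneer and two
late-successional congeners with restricted site coverage) whose foliar
chemistry follows genus-specific slopes and species-specific intercepts with
site random effects; and per-leaf herbivory damage drawn from a beta
distribution around a tree-level mean on the logit scale.

Every generator is deterministic for a fixed seed, and the ground-truth
parameters are returned alongside the tables so recovery of the coefficients
by the fitted model can be checked exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .measures import DAMAGE_EPS
from .prepare import (
    SOIL_ELEMENTS,
    standardize_tree_covariates,
)
from .measures import standardize

__all__ = [
    "LandscapeConfig",
    "TrueParameters",
    "SyntheticDataset",
    "default_true_parameters",
    "generate_sites",
    "generate_soil",
    "generate_trees",
    "generate_herbivory",
    "generate_dataset",
    "write_dataset",
    "inject_damage_offset",
]

DEFAULT_SPECIES_PLAN = (
    ("Alphitonia_petriei", "Alphitonia", 115),
    ("Flindersia_brayleyana", "Flindersia", 22),
    ("Flindersia_pimenteliana", "Flindersia", 42),
)

#: Fraction of sites each species occupies (pioneer everywhere; the two
#: late-successional congeners cover roughly half to two thirds of sites).
DEFAULT_SITE_COVERAGE = {
    "Alphitonia_petriei": 1.0,
    "Flindersia_brayleyana": 0.48,
    "Flindersia_pimenteliana": 0.60,
}


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of the synthetic study landscape."""

    n_sites: int = 25
    geology_classes: tuple[str, ...] = ("basalt", "granite", "rhyolite")
    mat_range: tuple[float, float] = (14.0, 26.0)  # deg C
    map_range: tuple[float, float] = (1200.0, 4000.0)  # mm / yr
    species_plan: tuple[tuple[str, str, int], ...] = DEFAULT_SPECIES_PLAN
    leaves_per_tree: int = 20
    site_coverage: dict = field(default_factory=lambda: dict(DEFAULT_SITE_COVERAGE))
    climate_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < len(self.geology_classes):
            raise ValueError(
                "n_sites must be at least the number of geology classes so every "
                "class is represented"
            )
        for name, rng in (("mat_range", self.mat_range), ("map_range", self.map_range)):
            if not rng[1] > rng[0]:
                raise ValueError(f"{name} must be a non-degenerate interval")
        if self.leaves_per_tree < 1:
            raise ValueError("leaves_per_tree must be >= 1")
        genus_of: dict[str, str] = {}
        for sp, genus, n in self.species_plan:
            if n < 1:
                raise ValueError(f"species {sp!r} must have n_trees >= 1")
            if genus_of.setdefault(sp, genus) != genus:
                raise ValueError(f"species {sp!r} maps to more than one genus")

    @property
    def species(self) -> list[str]:
        return [sp for sp, _, _ in self.species_plan]

    @property
    def genus_map(self) -> dict[str, str]:
        return {sp: g for sp, g, _ in self.species_plan}

    @property
    def genera(self) -> list[str]:
        out: dict[str, None] = {}
        for _, g, _ in self.species_plan:
            out.setdefault(g, None)
        return list(out)

    @property
    def n_trees(self) -> int:
        return sum(n for _, _, n in self.species_plan)


@dataclass
class TrueParameters:
    """Ground-truth generating coefficients, on the generation scale.

    ``soil_coeffs``: per element, ``{"intercept", "geo": {class: offset},
    "mat", "mat2", "map", "map2", "sigma"}`` — responses on an arbitrary
    unitless concentration scale, climate predictors standardized.

    ``foliage_coeffs``: per response, ``{"intercepts": {species: value},
    "slopes": {genus: {predictor: slope}}, "sigma", "site_sd"}`` — responses in
    natural units (% dry matter for total N, a fraction for N digestibility),
    predictors standardized; geology enters as ``geo_<class>`` offsets keyed as
    slopes so they can differ by genus.

    ``herbivory_coeffs``: ``{"intercepts": {species}, "slopes": {genus:
    {predictor}}, "phi", "site_sd"}`` on the logit scale; ``phi`` is the
    *leaf-level* beta precision.
    """

    soil_coeffs: dict
    foliage_coeffs: dict
    herbivory_coeffs: dict

    def validate(self, config: LandscapeConfig) -> None:
        offclasses = list(config.geology_classes[1:])
        for e, c in self.soil_coeffs.items():
            if c["sigma"] < 0:
                raise ValueError(f"soil sigma for {e} must be >= 0")
            for cls in offclasses:
                if cls not in c["geo"]:
                    raise ValueError(f"soil {e}: missing geology offset for {cls}")
            for k in ("intercept", "mat", "mat2", "map", "map2"):
                if k not in c:
                    raise ValueError(f"soil {e}: missing coefficient {k}")
        for tier_name, tier in (
            ("foliage", self.foliage_coeffs),
            ("herbivory", {"_": self.herbivory_coeffs}),
        ):
            for rname, c in tier.items():
                if c.get("sigma", 1.0) < 0 or c["site_sd"] < 0:
                    raise ValueError(f"{tier_name} {rname}: negative scale parameter")
                for sp in config.species:
                    if sp not in c["intercepts"]:
                        raise ValueError(
                            f"{tier_name} {rname}: missing intercept for {sp}"
                        )
                for g in config.genera:
                    if g not in c["slopes"]:
                        raise ValueError(f"{tier_name} {rname}: missing slopes for {g}")
        if self.herbivory_coeffs["phi"] <= 0:
            raise ValueError("beta precision phi must be strictly positive")


def _zero_slopes(predictors, genera) -> dict:
    return {g: {p: 0.0 for p in predictors} for g in genera}


def foliage_predictors(soil_elements=SOIL_ELEMENTS, geology=("granite", "rhyolite")):
    return (
        [f"soil_{e}" for e in soil_elements]
        + ["mat", "mat2", "map", "map2"]
        + [f"geo_{c}" for c in geology]
    )


def herbivory_predictors(soil_elements=SOIL_ELEMENTS, geology=("granite", "rhyolite")):
    return ["total_n", "n_digest"] + foliage_predictors(soil_elements, geology)


def default_true_parameters(config: LandscapeConfig | None = None) -> TrueParameters:
    """Default ground truth.

    The sign pattern follows the qualitative gradient structure the analysis
    is built to detect: basalt-derived soils are nutrient-rich (negative
    granite/rhyolite offsets for nutrients, positive for C:N); precipitation
    raises soil N and P and lowers K and C:N; temperature raises K and lowers
    Na and C:N.  Foliar total N is higher on basalt for both genera and
    climate-sensitive only in *Flindersia*; N digestibility responds to soil P
    (negative) and Na (positive) in *Flindersia* and is lower on basalt for
    *Alphitonia*.  Herbivory increases with temperature in both genera, with
    foliar N and on basalt for *Alphitonia*, and decreases with soil C:N for
    *Flindersia* — giving one deliberately strong indirect chain
    MAP → soil C:N → herbivory(Flindersia) with both edges near -0.8 on the
    standardized scale.  Magnitudes are chosen so effects are recoverable at
    the default sample sizes (25 sites, 179 trees).
    """
    config = config or LandscapeConfig()
    genera = config.genera
    fpred = foliage_predictors(geology=config.geology_classes[1:])
    hpred = herbivory_predictors(geology=config.geology_classes[1:])

    def geo_off(**by_class):
        return {c: by_class.get(c, by_class.get("default", 0.0))
                for c in config.geology_classes[1:]}

    # residual sds are sized against the systematic part so that soil
    # elements are climate-driven but not collinear with climate (and with
    # each other) at n_sites = 25 — the coefficients must stay identifiable
    soil = {
        "N": dict(intercept=0.5, geo=geo_off(granite=-0.6, rhyolite=-0.8, default=-0.6),
                  mat=0.0, mat2=0.0, map=0.6, map2=0.0, sigma=1.0),
        "P": dict(intercept=0.5, geo=geo_off(granite=-0.5, rhyolite=-0.7, default=-0.5),
                  mat=0.0, mat2=0.0, map=0.45, map2=0.0, sigma=1.0),
        "K": dict(intercept=0.4, geo=geo_off(granite=-0.5, rhyolite=-0.6, default=-0.5),
                  mat=0.5, mat2=0.0, map=-0.5, map2=0.0, sigma=1.0),
        "Na": dict(intercept=0.0, geo=geo_off(granite=-0.4, rhyolite=-0.4, default=-0.4),
                   mat=-0.5, mat2=0.0, map=0.0, map2=0.0, sigma=1.0),
        "CN": dict(intercept=-0.3, geo=geo_off(granite=0.5, rhyolite=0.6, default=0.5),
                   mat=-0.5, mat2=0.0, map=-0.8, map2=0.0, sigma=1.0),
    }

    fol_n = {
        "intercepts": {"Alphitonia_petriei": 2.1, "Flindersia_brayleyana": 1.4,
                       "Flindersia_pimenteliana": 1.7},
        "slopes": _zero_slopes(fpred, genera),
        "sigma": 0.35,
        "site_sd": 0.2,
    }
    n_dig = {
        "intercepts": {"Alphitonia_petriei": 0.45, "Flindersia_brayleyana": 0.55,
                       "Flindersia_pimenteliana": 0.62},
        "slopes": _zero_slopes(fpred, genera),
        "sigma": 0.05,
        "site_sd": 0.03,
    }
    herb = {
        "intercepts": {"Alphitonia_petriei": -3.6, "Flindersia_brayleyana": -3.0,
                       "Flindersia_pimenteliana": -3.8},
        "slopes": _zero_slopes(hpred, genera),
        "phi": 40.0,
        "site_sd": 0.15,
    }

    if set(genera) >= {"Alphitonia", "Flindersia"}:
        for g in ("Alphitonia", "Flindersia"):
            for c in config.geology_classes[1:]:
                fol_n["slopes"][g][f"geo_{c}"] = -0.35
        fol_n["slopes"]["Flindersia"]["mat"] = 0.35
        fol_n["slopes"]["Flindersia"]["map"] = -0.35

        n_dig["slopes"]["Flindersia"]["soil_P"] = -0.05
        n_dig["slopes"]["Flindersia"]["soil_Na"] = 0.05
        n_dig["slopes"]["Flindersia"]["mat"] = 0.04
        for c in config.geology_classes[1:]:
            n_dig["slopes"]["Alphitonia"][f"geo_{c}"] = 0.05

        for c in config.geology_classes[1:]:
            herb["slopes"]["Alphitonia"][f"geo_{c}"] = -0.5
        herb["slopes"]["Alphitonia"]["mat"] = 0.5
        herb["slopes"]["Alphitonia"]["total_n"] = 0.5
        herb["slopes"]["Flindersia"]["soil_CN"] = -0.8
        herb["slopes"]["Flindersia"]["mat"] = 0.4

    truth = TrueParameters(
        soil_coeffs=soil, foliage_coeffs={"total_n": fol_n, "n_digest": n_dig},
        herbivory_coeffs=herb,
    )
    truth.validate(config)
    return truth


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _stratified_unit(n: int, rng: np.random.Generator) -> np.ndarray:
    """n points stratified over (0, 1): one uniform draw per equal-width bin,
    in random bin order — guarantees near-full span coverage at any n."""
    return (rng.permutation(n) + rng.uniform(size=n)) / n


def generate_sites(config: LandscapeConfig) -> pd.DataFrame:
    """Generate the site table: climate gradients and geology classes.

    Mean annual temperature (MAT) decreases along a latent elevation axis and
    mean annual precipitation (MAP) along a latent longitude axis; the two
    axes are rank-correlated at ``config.climate_correlation``, giving the
    partial decorrelation of crossed gradients.  Every geology class appears
    at least once (classes are tiled over sites, then shuffled).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    elevation = _stratified_unit(n, rng)
    rho = float(np.clip(config.climate_correlation, -0.99, 0.99))
    latent = rho * (elevation - 0.5) + np.sqrt(1 - rho**2) * rng.normal(
        scale=0.3, size=n
    )
    # rank-map the correlated latent back onto a stratified grid so MAP also
    # spans its full range
    longitude = (np.argsort(np.argsort(latent)) + rng.uniform(size=n)) / n

    mat_lo, mat_hi = config.mat_range
    map_lo, map_hi = config.map_range
    mat = mat_hi - (mat_hi - mat_lo) * elevation  # high elevation = cool
    map_ = map_hi - (map_hi - map_lo) * longitude  # west = dry

    classes = np.array(config.geology_classes, dtype=object)
    geology = rng.permutation(np.resize(classes, n))

    return pd.DataFrame(
        {
            "site_id": [f"S{i + 1:02d}" for i in range(n)],
            "elevation_axis": elevation,
            "longitude_axis": longitude,
            "geology": geology,
            "mat": mat,
            "map": map_,
        }
    )


def _site_climate_design(sites: pd.DataFrame) -> pd.DataFrame:
    frame, _ = standardize(sites, ["mat", "map"], quadratic=("mat", "map"))
    return frame


def generate_soil(
    sites: pd.DataFrame, truth: TrueParameters, seed: int
) -> pd.DataFrame:
    """Generate per-site depth-averaged soil element concentrations.

    Each element is a Gaussian response to geology (reference = first class)
    and standardized linear+quadratic climate.
    """
    rng = np.random.default_rng(seed)
    frame = _site_climate_design(sites)
    out = pd.DataFrame({"site_id": frame["site_id"]})
    for e, c in truth.soil_coeffs.items():
        geo = np.array([c["geo"].get(g, 0.0) for g in frame["geology"]])
        mean = (
            c["intercept"]
            + geo
            + c["mat"] * frame["z_mat"].to_numpy()
            + c["mat2"] * frame["z_mat2"].to_numpy()
            + c["map"] * frame["z_map"].to_numpy()
            + c["map2"] * frame["z_map2"].to_numpy()
        )
        out[f"soil_{e}"] = mean + c["sigma"] * rng.standard_normal(len(frame))
    return out


def _linear_predictor(coeffs: dict, frame: pd.DataFrame) -> np.ndarray:
    """Species intercept + genus-specific slopes over standardized predictors."""
    eta = np.array([coeffs["intercepts"][sp] for sp in frame["species"]])
    genus = frame["genus"].to_numpy()
    for g, slopes in coeffs["slopes"].items():
        mask = genus == g
        if not mask.any():
            continue
        contrib = np.zeros(mask.sum())
        for pred, b in slopes.items():
            if b == 0.0:
                continue
            if pred.startswith("geo_"):
                x = (frame["geology"].to_numpy()[mask] == pred[4:]).astype(float)
            else:
                x = frame[f"z_{pred}"].to_numpy()[mask]
            contrib += b * x
        eta[mask] += contrib
    return eta


def generate_trees(
    sites: pd.DataFrame,
    soil: pd.DataFrame,
    truth: TrueParameters,
    species_plan=DEFAULT_SPECIES_PLAN,
    seed: int = 0,
    *,
    site_coverage: dict | None = None,
) -> pd.DataFrame:
    """Allocate trees to sites and generate their foliar chemistry.

    Late-successional species are restricted to a random subset of sites
    (per-species inclusion probability from ``site_coverage``); trees are then
    placed uniformly among included sites.  Foliar total N and N digestibility
    follow genus-slope / species-intercept Gaussian models with site random
    effects; digestibility is clipped into [0, 1].
    """
    rng = np.random.default_rng(seed)
    coverage = dict(DEFAULT_SITE_COVERAGE if site_coverage is None else site_coverage)
    site_ids = list(sites.sort_values("site_id")["site_id"])

    rows = []
    for sp, genus, n in species_plan:
        if genus is None:
            raise ValueError(f"species {sp!r} has no genus mapping")
        p = coverage.get(sp, 1.0)
        included = [s for s in site_ids if rng.uniform() < p]
        if not included:
            included = [site_ids[rng.integers(len(site_ids))]]
        placed = rng.choice(included, size=n)
        rows += [{"species": sp, "genus": genus, "site_id": s} for s in placed]
    trees = pd.DataFrame(rows)
    trees.insert(0, "tree_id", [f"T{i + 1:04d}" for i in range(len(trees))])

    frame, _ = standardize_tree_covariates(trees, sites, soil)
    site_index = {s: i for i, s in enumerate(site_ids)}
    sidx = frame["site_id"].map(site_index).to_numpy()

    for resp, coeffs in truth.foliage_coeffs.items():
        u = rng.normal(scale=coeffs["site_sd"], size=len(site_ids))
        mean = _linear_predictor(coeffs, frame) + u[sidx]
        values = mean + coeffs["sigma"] * rng.standard_normal(len(frame))
        if resp == "n_digest":
            values = np.clip(values, 0.0, 1.0)
        trees[resp] = values

    # dry-matter digestibility is carried in the data model but not modelled
    trees["dm_digest"] = np.clip(rng.normal(0.55, 0.08, size=len(trees)), 0.0, 1.0)
    return trees


def generate_herbivory(
    trees: pd.DataFrame,
    soil: pd.DataFrame,
    sites: pd.DataFrame,
    truth: TrueParameters,
    leaves_per_tree: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the leaf table: beta-distributed damage around tree means.

    Each tree's expected damage is inverse-logit of a genus-slope /
    species-intercept linear predictor (over standardized soil, climate and
    foliar chemistry) plus a site random effect; its leaves are i.i.d.
    Beta(mu*phi, (1-mu)*phi), clamped into the open unit interval.
    """
    c = truth.herbivory_coeffs
    if c["phi"] <= 0:
        raise ValueError("beta precision phi must be strictly positive")
    rng = np.random.default_rng(seed)

    frame, _ = standardize_tree_covariates(trees, sites, soil)
    frame, _ = standardize(frame, ["total_n", "n_digest"])
    site_ids = list(sites.sort_values("site_id")["site_id"])
    site_index = {s: i for i, s in enumerate(site_ids)}
    sidx = frame["site_id"].map(site_index).to_numpy()

    u = rng.normal(scale=c["site_sd"], size=len(site_ids))
    eta = _linear_predictor(c, frame) + u[sidx]
    mu = expit(eta)

    k = int(leaves_per_tree)
    a = np.repeat(mu * c["phi"], k)
    b = np.repeat((1.0 - mu) * c["phi"], k)
    damage = np.clip(rng.beta(a, b), DAMAGE_EPS, 1.0 - DAMAGE_EPS)

    tree_ids = np.repeat(trees["tree_id"].to_numpy(), k)
    leaf_no = np.tile(np.arange(1, k + 1), len(trees))
    return pd.DataFrame(
        {
            "leaf_id": [f"{t}_L{j:02d}" for t, j in zip(tree_ids, leaf_no)],
            "tree_id": tree_ids,
            "damage": damage,
        }
    )


@dataclass
class SyntheticDataset:
    """A complete synthetic dataset plus the truth that generated it."""

    sites: pd.DataFrame
    soil: pd.DataFrame
    trees: pd.DataFrame
    leaves: pd.DataFrame
    truth: TrueParameters
    config: LandscapeConfig
    seed: int

    def validate(self) -> None:
        site_ids = set(self.sites["site_id"])
        if not set(self.trees["site_id"]) <= site_ids:
            raise ValueError("tree references a non-existent site")
        if not set(self.leaves["tree_id"]) <= set(self.trees["tree_id"]):
            raise ValueError("leaf references a non-existent tree")
        d = self.leaves["damage"].to_numpy()
        if not ((d > 0) & (d < 1)).all():
            raise ValueError("leaf damage proportions must lie strictly in (0, 1)")
        for col in ("n_digest", "dm_digest"):
            v = self.trees[col].to_numpy()
            if not ((v >= 0) & (v <= 1)).all():
                raise ValueError(f"{col} must lie in [0, 1]")


def generate_dataset(
    config: LandscapeConfig | None = None, truth: TrueParameters | None = None
) -> SyntheticDataset:
    """Compose the four generators into a validated dataset.

    Component seeds are derived deterministically from ``config.seed`` so the
    whole dataset is reproducible from one integer.
    """
    config = config or LandscapeConfig()
    truth = truth or default_true_parameters(config)
    truth.validate(config)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    sites = generate_sites(config)
    soil = generate_soil(sites, truth, int(seeds[1]))
    trees = generate_trees(
        sites, soil, truth, config.species_plan, int(seeds[2]),
        site_coverage=config.site_coverage,
    )
    leaves = generate_herbivory(
        trees, soil, sites, truth, config.leaves_per_tree, int(seeds[3])
    )
    ds = SyntheticDataset(
        sites=sites, soil=soil, trees=trees, leaves=leaves, truth=truth,
        config=config, seed=config.seed,
    )
    ds.validate()
    return ds


def write_dataset(ds: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the four standard CSV files (plus the truth as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("sites", ds.sites), ("soil", ds.soil),
        ("trees", ds.trees), ("leaves", ds.leaves),
    ):
        paths[name] = out / f"{name}.csv"
        frame.to_csv(paths[name], index=False)
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "soil_coeffs": ds.truth.soil_coeffs,
                "foliage_coeffs": ds.truth.foliage_coeffs,
                "herbivory_coeffs": ds.truth.herbivory_coeffs,
                "config": {
                    **{k: v for k, v in asdict(ds.config).items()},
                },
            },
            fh, indent=1, default=list,
        )
    paths["truth"] = truth_path
    return paths


def inject_damage_offset(
    leaves: pd.DataFrame, trees: pd.DataFrame, *, offset: float = 6.0,
    fraction: float = 0.5, seed: int = 0,
) -> pd.DataFrame:
    """Mis-specification injection for model-checking experiments.

    Shifts the damage of all leaves of a random ``fraction`` of trees by
    ``offset`` on the logit scale — a tree-level mean distortion that no model
    covariate can explain, used to verify that the posterior-predictive check
    flags a broken herbivory tier.
    """
    rng = np.random.default_rng(seed)
    tree_ids = trees["tree_id"].to_numpy()
    chosen = set(tree_ids[rng.uniform(size=len(tree_ids)) < fraction])
    out = leaves.copy()
    mask = out["tree_id"].isin(chosen).to_numpy()
    shifted = expit(logit(out.loc[mask, "damage"].to_numpy()) + offset)
    out.loc[mask, "damage"] = np.clip(shifted, DAMAGE_EPS, 1.0 - DAMAGE_EPS)
    return out
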