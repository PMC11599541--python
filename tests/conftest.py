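"""Shared fixtures: tiny synthetic datasets and independent density oracles."""
from __future__ import annotations

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import settings
from scipy.special import expit

import herbscape as hs

# property tests assert universal invariants; run them reproducibly
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

TINY_PLAN = (
    ("Alphitonia_petriei", "Alphitonia", 8),
    ("Flindersia_brayleyana", "Flindersia", 5),
    ("Flindersia_pimenteliana", "Flindersia", 7),
)


@pytest.fixture(scope="session")
def tiny_config():
    return hs.LandscapeConfig(
        n_sites=6, species_plan=TINY_PLAN, leaves_per_tree=4,
        site_coverage={sp: 1.0 for sp, _, _ in TINY_PLAN}, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return hs.generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_data(tiny_dataset):
    ds = tiny_dataset
    return hs.build_analysis(ds.sites, ds.soil, ds.trees, ds.leaves, min_leaves=1)


@pytest.fixture(scope="session")
def tiny_model(tiny_data):
    return hs.HierarchicalModel(hs.ModelSpec(), tiny_data)


def random_params(model, seed=0):
    """A random valid parameter vector for a bound model."""
    rng = np.random.default_rng(seed)
    vals = {}
    for name in model.parameter_names():
        if name.endswith(".sigma") or name.endswith(".site_sd"):
            vals[name] = rng.uniform(0.5, 1.5)
        elif name.endswith(".phi"):
            vals[name] = rng.uniform(50.0, 150.0)
        elif ".site[" in name:
            vals[name] = rng.normal(0.0, 0.3)
        else:
            vals[name] = rng.normal(0.0, 0.3)
    return model.parameter_vector(vals)


def brute_log_likelihood(model, params) -> float:
    """Naive per-observation density summation, independent of the model's
    vectorized implementation: loops over rows and calls scipy.stats."""
    spec = model.spec
    sf = model.data.site_frame
    tf = model.data.tree_frame
    p = params.as_dict() if hasattr(params, "as_dict") else dict(params)

    def xval(row, pred):
        if pred.startswith("geo_"):
            return 1.0 if row["geology"] == pred[4:] else 0.0
        return float(row[f"z_{pred}"])

    total = 0.0
    for e in spec.soil_elements:
        sig = p[f"soil_{e}.sigma"]
        for _, row in sf.iterrows():
            mean = p[f"soil_{e}.intercept"] + sum(
                p[f"soil_{e}.{q}"] * xval(row, q) for q in spec.soil_predictors
            )
            total += st.norm.logpdf(row[f"z_soil_{e}"], mean, sig)
    for r in spec.foliage_responses:
        sig = p[f"{r}.sigma"]
        for _, row in tf.iterrows():
            mean = (
                p[f"{r}.intercept[{row['species']}]"]
                + sum(
                    p[f"{r}.slope[{row['genus']}][{q}]"] * xval(row, q)
                    for q in spec.foliage_predictors
                )
                + p[f"{r}.site[{row['site_id']}]"]
            )
            total += st.norm.logpdf(row[f"z_{r}"], mean, sig)
    if spec.include_herbivory:
        phi = p["herbivory.phi"]
        for _, row in tf.iterrows():
            eta = (
                p[f"herbivory.intercept[{row['species']}]"]
                + sum(
                    p[f"herbivory.slope[{row['genus']}][{q}]"] * xval(row, q)
                    for q in spec.herbivory_predictors
                )
                + p[f"herbivory.site[{row['site_id']}]"]
            )
            mu = expit(eta)
            total += st.beta.logpdf(row["damage"], mu * phi, (1 - mu) * phi)
    return float(total)


def brute_log_prior(model, params) -> float:
    """Independent prior evaluation via scipy.stats distributions."""
    spec = model.spec
    p = params.as_dict() if hasattr(params, "as_dict") else dict(params)
    total = 0.0
    site_sds = {}
    for name, val in p.items():
        if name.endswith(".site_sd"):
            site_sds[name.rsplit(".", 1)[0]] = val
    for name, val in p.items():
        if name.endswith(".sigma") or name.endswith(".site_sd"):
            total += st.halfnorm.logpdf(val, scale=spec.sd_prior_scale)
        elif name.endswith(".phi"):
            total += st.gamma.logpdf(
                val, spec.phi_prior_shape, scale=1.0 / spec.phi_prior_rate
            )
        elif ".site[" in name:
            tier = name.split(".", 1)[0]
            total += st.norm.logpdf(val, 0.0, site_sds[tier])
        else:
            total += st.norm.logpdf(val, 0.0, spec.coef_prior_sd)
    return float(total)
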