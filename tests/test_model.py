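"""Joint model densities against independent brute-force oracles."""
import numpy as np
import pytest
from scipy import integrate
import scipy.stats as st

import herbscape as hs
from herbscape.model import HierarchicalModel, ModelSpec

from conftest import brute_log_likelihood, brute_log_prior, random_params


class TestLogLikelihood:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_summation(self, tiny_model, seed):
        params = random_params(tiny_model, seed)
        assert tiny_model.log_likelihood(params) == pytest.approx(
            brute_log_likelihood(tiny_model, params), abs=1e-10, rel=1e-12
        )

    def test_uniform_beta_tier_contributes_zero(self, tiny_model):
        # mu = 1/2 and phi = 2 is Beta(1, 1): log-density 0 at any damage
        params = random_params(tiny_model, 3)
        zeroed = {
            n: 0.0 for n in tiny_model.parameter_names()
            if n.startswith("herbivory.") and not n.endswith(("phi",))
            and ".site_sd" not in n
        }
        pv = params.replace(**zeroed, **{"herbivory.phi": 2.0})
        tiers = tiny_model.tier_log_likelihoods(pv)
        assert tiers["herbivory"] == pytest.approx(0.0, abs=1e-10)

    def test_standard_normal_at_mode(self, tiny_config):
        # noiseless generation + exact truth on the model scale: residuals are
        # zero, so each soil observation contributes -log(2*pi)/2 at sd 1
        from test_synthetic import zeroed_truth

        truth = zeroed_truth()
        ds = hs.generate_dataset(tiny_config, truth=truth)
        data = hs.build_analysis(ds.sites, ds.soil, ds.trees, ds.leaves,
                                 min_leaves=1)
        spec = ModelSpec(foliage_responses=(), include_herbivory=False)
        model = HierarchicalModel(spec, data)
        tmap = hs.truth_on_model_scale(truth, data, spec)
        tmap = {k: v for k, v in tmap.items() if k in model.parameter_names()}
        for e in spec.soil_elements:
            tmap[f"soil_{e}.sigma"] = 1.0
        tiers = model.tier_log_likelihoods(model.parameter_vector(tmap))
        for e in spec.soil_elements:
            expected = -0.5 * np.log(2 * np.pi) * model.n_sites
            assert tiers[f"soil_{e}"] == pytest.approx(expected, abs=1e-8)

    def test_tier_factorization_and_row_permutation(self, tiny_model, tiny_data):
        params = random_params(tiny_model, 4)
        tiers = tiny_model.tier_log_likelihoods(params)
        assert sum(tiers.values()) == pytest.approx(
            tiny_model.log_likelihood(params), abs=1e-10
        )
        # permuting tree rows leaves the likelihood unchanged
        rng = np.random.default_rng(0)
        data2 = hs.AnalysisData(**{**tiny_data.__dict__})
        data2.tree_frame = tiny_data.tree_frame.sample(
            frac=1.0, random_state=rng
        ).reset_index(drop=True)
        model2 = HierarchicalModel(ModelSpec(), data2)
        pv2 = model2.parameter_vector(params.as_dict())
        assert model2.log_likelihood(pv2) == pytest.approx(
            tiny_model.log_likelihood(params), abs=1e-8
        )

    def test_domain_errors(self, tiny_model):
        params = random_params(tiny_model, 5)
        with pytest.raises(ValueError, match="sd|phi"):
            tiny_model.log_likelihood(params.replace(**{"soil_N.sigma": -1.0}))
        with pytest.raises(ValueError, match="phi"):
            tiny_model.log_likelihood(params.replace(**{"herbivory.phi": 0.0}))


class TestLogPrior:
    def test_matches_independent_scipy_evaluation(self, tiny_model):
        for seed in (0, 6):
            params = random_params(tiny_model, seed)
            assert tiny_model.log_prior(params) == pytest.approx(
                brute_log_prior(tiny_model, params), abs=1e-9
            )

    def test_zero_centered_terms_unimodal_at_zero(self, tiny_model):
        params = random_params(tiny_model, 7)
        name = "soil_N.map"
        lp0 = tiny_model.log_prior(params.replace(**{name: 0.5}))
        lp1 = tiny_model.log_prior(params.replace(**{name: 1.0}))
        assert lp1 < lp0

    def test_prior_is_proper_for_reduced_model(self, tiny_data):
        # one coefficient + one sd: the joint prior integrates to 1
        spec = ModelSpec(
            soil_elements=("N",), soil_predictors=[],
            foliage_responses=(), include_herbivory=False,
        )
        model = HierarchicalModel(spec, tiny_data)

        def density(sig, b):
            return np.exp(
                model.log_prior({"soil_N.intercept": b, "soil_N.sigma": sig})
            )

        total, err = integrate.dblquad(density, -80, 80, 0, 40)
        assert total == pytest.approx(1.0, abs=5e-3)


class TestLogPosterior:
    def test_is_prior_plus_likelihood(self, tiny_model):
        params = random_params(tiny_model, 8)
        assert tiny_model.log_posterior(params) == pytest.approx(
            tiny_model.log_prior(params) + tiny_model.log_likelihood(params),
            abs=1e-12, rel=1e-12,
        )

    def test_outside_support_is_minus_inf(self, tiny_model):
        params = random_params(tiny_model, 9)
        assert tiny_model.log_posterior(
            params.replace(**{"total_n.sigma": -0.5})
        ) == -np.inf

    def test_better_fit_at_equal_prior_scores_higher(self, tiny_model):
        # +c and -c have identical prior mass; the sign matching the data's
        # realized slope must fit better
        params = random_params(tiny_model, 10)
        y = tiny_model.y_soil["N"]
        x = tiny_model.X_soil[:, tiny_model.soil_cols.index("map")]
        sign = np.sign(np.cov(x, y)[0, 1])
        good = params.replace(**{"soil_N.map": sign * 0.5})
        bad = params.replace(**{"soil_N.map": -sign * 0.5})
        assert tiny_model.log_prior(good) == pytest.approx(
            tiny_model.log_prior(bad), abs=1e-10
        )
        assert tiny_model.log_posterior(good) > tiny_model.log_posterior(bad)


class TestSimulateReplicate:
    def test_degenerate_likelihood_returns_fitted_means(self, tiny_model):
        params = random_params(tiny_model, 11)
        small = {
            n: 1e-9 for n in tiny_model.parameter_names() if n.endswith(".sigma")
        }
        pv = params.replace(**small, **{"herbivory.phi": 1e9})
        rep = tiny_model.simulate_replicate(pv, seed=0)
        means = tiny_model.fitted_means(pv)
        for tier, values in rep.items():
            np.testing.assert_allclose(values, means[tier], atol=1e-4)

    def test_fixed_seed_identical(self, tiny_model):
        params = random_params(tiny_model, 12)
        a = tiny_model.simulate_replicate(params, seed=5)
        b = tiny_model.simulate_replicate(params, seed=5)
        for tier in a:
            np.testing.assert_array_equal(a[tier], b[tier])

    def test_replicate_mean_converges_to_fitted_means(self, tiny_model):
        params = random_params(tiny_model, 13)
        rng = np.random.default_rng(7)
        n_rep = 4000
        acc = None
        for _ in range(n_rep):
            rep = tiny_model.simulate_replicate(params, rng=rng)
            if acc is None:
                acc = {t: v.astype(float).copy() for t, v in rep.items()}
            else:
                for t in acc:
                    acc[t] += rep[t]
        means = tiny_model.fitted_means(params)
        sig = params["soil_N.sigma"]
        mc = acc["soil_N"] / n_rep
        se = sig / np.sqrt(n_rep)
        assert np.all(np.abs(mc - means["soil_N"]) < 3 * se + 1e-12)

    def test_beta_tier_variance_law(self, tiny_model):
        # Var(damage | mu, phi) = mu (1 - mu) / (1 + phi), by simulation
        params = random_params(tiny_model, 14).replace(
            **{"herbivory.phi": 30.0}
        )
        rng = np.random.default_rng(8)
        reps = np.stack(
            [tiny_model.simulate_replicate(params, rng=rng)["herbivory"]
             for _ in range(4000)]
        )
        mu = tiny_model.fitted_means(params)["herbivory"]
        expected = mu * (1 - mu) / (1 + 30.0)
        np.testing.assert_allclose(reps.var(axis=0, ddof=1), expected, rtol=0.25)


class TestSpecSerialization:
    def test_json_round_trip(self):
        import json

        spec = ModelSpec(soil_elements=("N", "P"), coef_prior_sd=5.0)
        blob = json.loads(json.dumps(spec.to_dict()))
        back = ModelSpec.from_dict(blob)
        assert back == spec


class TestSpecValidation:
    def test_cyclic_predictor_sets_rejected(self, tiny_data):
        with pytest.raises(ValueError, match="cycle"):
            HierarchicalModel(
                ModelSpec(soil_predictors=["mat", "soil_N"]), tiny_data
            )
        with pytest.raises(ValueError, match="cycle"):
            HierarchicalModel(
                ModelSpec(foliage_predictors=["total_n"]), tiny_data
            )

    def test_unknown_predictor_rejected(self, tiny_data):
        with pytest.raises(ValueError, match="unknown predictor"):
            HierarchicalModel(
                ModelSpec(herbivory_predictors=["leaf_toughness"]), tiny_data
            )
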