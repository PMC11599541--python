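"""Effect summaries, genus contrasts, indirect paths, and the path graph."""
import networkx as nx
import numpy as np
import pytest

import herbscape as hs
from herbscape.effects import (
    build_path_graph,
    coefficient_coverage,
    genus_contrast,
    indirect_effect,
    summarize,
    summary_table,
)
from herbscape.model import ModelSpec
from herbscape.sampler import ChainSchedule, run_mcmc


def draws_of(mapping):
    return hs.PosteriorDraws.from_dict(
        {k: np.atleast_2d(v) for k, v in mapping.items()}
    )


def brute_quantile(sorted_values, q):
    """Independent linear-interpolation quantile on sorted data."""
    n = len(sorted_values)
    h = (n - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return sorted_values[lo] + (h - lo) * (sorted_values[hi] - sorted_values[lo])


class TestSummarize:
    def test_constant_draws(self):
        d = draws_of({"a": np.full(100, 2.5), "b": np.zeros(100)})
        sa = summarize(d, "a")
        assert (sa.mean, sa.lower, sa.upper) == (2.5, 2.5, 2.5)
        assert sa.excludes_zero
        assert not summarize(d, "b").excludes_zero

    def test_interval_matches_brute_force_quantiles(self):
        grid = np.arange(1.0, 1001.0)
        s = summarize(draws_of({"g": grid}), "g", level=0.89)
        assert s.lower == pytest.approx(brute_quantile(grid, 0.055), rel=1e-12)
        assert s.upper == pytest.approx(brute_quantile(grid, 0.945), rel=1e-12)
        assert s.mean == pytest.approx(grid.mean())

    def test_symmetric_draws_do_not_exclude_zero(self):
        x = np.concatenate([np.linspace(-1, 1, 500)])
        assert not summarize(draws_of({"s": x}), "s").excludes_zero

    def test_hdi_option(self):
        rng = np.random.default_rng(9)
        x = rng.normal(1.0, 0.5, 4000)
        d = draws_of({"x": x})
        eti = summarize(d, "x", level=0.89)
        hdi = summarize(d, "x", level=0.89, interval="hdi")
        # symmetric posterior: both interval types nearly coincide
        assert hdi.lower == pytest.approx(eti.lower, abs=0.05)
        assert hdi.upper == pytest.approx(eti.upper, abs=0.05)
        # cross-check against the arviz implementation
        import arviz as az

        lo, hi = az.hdi(x, hdi_prob=0.89)
        assert hdi.lower == pytest.approx(lo, abs=0.02)
        assert hdi.upper == pytest.approx(hi, abs=0.02)
        with pytest.raises(ValueError, match="interval"):
            summarize(d, "x", interval="bogus")

    def test_unknown_parameter(self, tiny_model):
        with pytest.raises(KeyError):
            summarize(draws_of({"a": np.ones(5)}), "zzz")

    def test_table_has_one_row_per_parameter(self):
        d = draws_of({"a": np.ones(50), "b": np.linspace(-2, 2, 50)})
        t = summary_table(d)
        assert len(t) == 2 and set(t.parameter) == {"a", "b"}


class TestGenusContrast:
    def test_identical_and_constant_slopes(self):
        d = draws_of({
            "n_digest.slope[Alphitonia][soil_Na]": np.full(60, 0.2),
            "n_digest.slope[Flindersia][soil_Na]": np.full(60, 0.5),
            "n_digest.slope[Alphitonia][mat]": np.full(60, 0.3),
            "n_digest.slope[Flindersia][mat]": np.full(60, 0.3),
        })
        c = genus_contrast(d, "n_digest", "soil_Na")
        assert c.mean == pytest.approx(0.3) and c.excludes_zero
        same = genus_contrast(d, "n_digest", "mat")
        assert same.mean == 0.0 and not same.excludes_zero


class TestIndirectEffect:
    def test_constant_two_edge_product(self):
        d = draws_of({"soil_CN.map": np.full(80, 2.0),
                      "herbivory.slope[Flindersia][soil_CN]": np.full(80, 3.0)})
        pe = indirect_effect(
            d, ["soil_CN.map", "herbivory.slope[Flindersia][soil_CN]"]
        )
        assert pe.summary.mean == pytest.approx(6.0)

    def test_zero_coefficient_annihilates(self):
        d = draws_of({"a": np.zeros(50), "b": np.random.default_rng(0).normal(size=50)})
        pe = indirect_effect(d, ["a", "b"])
        assert np.all(pe.values == 0.0)
        assert not pe.summary.excludes_zero

    def test_independent_normal_product_mean(self):
        rng = np.random.default_rng(1)
        n = 6000
        d = draws_of({"a": rng.normal(2, 0.1, n), "b": rng.normal(3, 0.1, n)})
        pe = indirect_effect(d, ["a", "b"])
        se = pe.values.std(ddof=1) / np.sqrt(n)
        assert abs(pe.values.mean() - 6.0) < 3 * se

    def test_single_edge_equals_summarize(self):
        rng = np.random.default_rng(2)
        d = draws_of({"soil_N.map": rng.normal(0.4, 0.2, 500)})
        pe = indirect_effect(d, ["soil_N.map"])
        s = summarize(d, "soil_N.map")
        assert pe.summary.mean == s.mean
        assert pe.summary.lower == s.lower and pe.summary.upper == s.upper

    def test_product_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        vals = {k: rng.normal(size=200) for k in ("x", "y", "z")}
        pe = indirect_effect(draws_of(vals), ["x", "y", "z"])
        expected = np.array(
            [vals["x"][i] * vals["y"][i] * vals["z"][i] for i in range(200)]
        )
        np.testing.assert_allclose(pe.values, expected, atol=1e-10)

    def test_node_path_resolution(self):
        d = draws_of({"soil_CN.map": np.full(10, -0.5),
                      "herbivory.slope[Flindersia][soil_CN]": np.full(10, -0.8)})
        pe = indirect_effect(d, ["map", "soil_CN", "herbivory[Flindersia]"])
        assert pe.edge_parameters == (
            "soil_CN.map", "herbivory.slope[Flindersia][soil_CN]"
        )
        assert pe.summary.mean == pytest.approx(0.4)

    def test_invalid_paths_rejected(self):
        d = draws_of({"soil_CN.map": np.ones(5)})
        with pytest.raises(ValueError, match="tier ordering"):
            indirect_effect(d, ["soil_CN", "map"])
        with pytest.raises(ValueError, match="quadratic|tier"):
            indirect_effect(d, ["map2", "soil_CN", "herbivory[Flindersia]"])
        with pytest.raises(ValueError, match="genera"):
            indirect_effect(
                d, ["total_n[Alphitonia]", "herbivory[Flindersia]"]
            )


class TestPathGraph:
    def _null_draws(self, spec, seed=0, sd=1.0):
        rng = np.random.default_rng(seed)
        names = []
        for e in spec.soil_elements:
            names += [f"soil_{e}.{p}" for p in spec.soil_predictors]
        for r in spec.foliage_responses:
            for g in ("Alphitonia", "Flindersia"):
                names += [f"{r}.slope[{g}][{p}]" for p in spec.foliage_predictors]
        for g in ("Alphitonia", "Flindersia"):
            names += [f"herbivory.slope[{g}][{p}]" for p in spec.herbivory_predictors]
        return names, draws_of(
            {n: rng.normal(0, sd, (2, 400)) for n in names}
        )

    def test_null_draws_false_positive_rate(self):
        spec = ModelSpec()
        names, d = self._null_draws(spec, seed=11)
        g = build_path_graph(d, spec)
        n_candidates = len(names)
        # each zero-centered coefficient is retained w.p. ~0.11 at level 0.89
        p = 0.11
        bound = n_candidates * p + 3 * np.sqrt(n_candidates * p * (1 - p))
        assert g.number_of_edges() <= bound

    def test_graph_acyclic_and_signed(self):
        spec = ModelSpec()
        _, d = self._null_draws(spec, seed=12)
        g = build_path_graph(d, spec)
        assert nx.is_directed_acyclic_graph(g)
        for _, _, data in g.edges(data=True):
            assert data["sign"] in (-1, 1)
            assert np.sign(data["mean"]) == data["sign"]

    def test_planted_chain_retained_with_tight_draws(self):
        # a strong MAP -> soil C:N -> herbivory(Flindersia) chain in the draws
        # must appear as a 2-edge path whose product excludes zero
        spec = ModelSpec()
        names, d = self._null_draws(spec, seed=13, sd=0.01)
        rng = np.random.default_rng(14)
        mapping = {n: d.get(n) for n in names}
        mapping["soil_CN.map"] = rng.normal(-0.8, 0.05, (2, 400))
        mapping["herbivory.slope[Flindersia][soil_CN]"] = rng.normal(
            -0.8, 0.05, (2, 400)
        )
        d2 = hs.PosteriorDraws.from_dict(mapping)
        g = build_path_graph(d2, spec)
        paths = {p.nodes: p for p in g.graph["paths"]}
        key = ("map", "soil_CN", "herbivory[Flindersia]")
        assert key in paths
        assert paths[key].summary.excludes_zero
        assert paths[key].summary.mean > 0

    def test_quadratic_edges_never_in_paths(self):
        spec = ModelSpec()
        names, _ = self._null_draws(spec, seed=15)
        rng = np.random.default_rng(16)
        mapping = {n: rng.normal(0, 0.01, (2, 200)) for n in names}
        # strong quadratic edge into soil plus strong soil -> herbivory edge
        mapping["soil_K.mat2"] = rng.normal(1.0, 0.05, (2, 200))
        mapping["herbivory.slope[Alphitonia][soil_K]"] = rng.normal(
            1.0, 0.05, (2, 200)
        )
        d = hs.PosteriorDraws.from_dict(mapping)
        g = build_path_graph(d, spec)
        assert ("mat2", "soil_K") in g.edges  # direct quadratic edge retained
        for p in g.graph["paths"]:
            assert "mat2" not in p.nodes and "map2" not in p.nodes


class TestCoverageCalibration:
    def test_soil_tier_interval_coverage_across_replicates(self):
        # 20 simulate-fit replicates of the (conjugate, fast) soil tier:
        # 89% intervals should cover ~89% of true coefficients
        spec = ModelSpec(foliage_responses=(), include_herbivory=False)
        sched = ChainSchedule(2, 3000, 0.5, 5)
        covered = []
        for rep in range(20):
            ds = hs.generate_dataset(hs.LandscapeConfig(seed=300 + rep))
            data = hs.build_analysis(ds.sites, ds.soil, ds.trees, ds.leaves)
            model = hs.HierarchicalModel(spec, data)
            draws = run_mcmc(model, schedule=sched, seed=rep)
            truth = hs.truth_on_model_scale(ds.truth, data, spec)
            frac, table = coefficient_coverage(draws, truth)
            covered.append(table["covered"])
        pooled = np.concatenate(covered)
        assert 0.75 <= pooled.mean() <= 0.97
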