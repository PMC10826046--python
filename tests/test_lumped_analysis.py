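"""Lumped-model characterizations and the distribution analytics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fluxcomm.community_build import pool_models
from fluxcomm.flux_sampler import SamplerSettings, sample_fluxes
from fluxcomm.gem_core import apply_diet, solve_fba
from fluxcomm.lumped_analysis import (
    ensemble_to_array,
    flux_sum,
    iterative_biomass_optimization,
    optimal_community_growth,
    pathway_flux_summary,
    reaction_divergence,
)
from fluxcomm.synthetic_data import DietSpec, MicrobeSpec, make_toy_microbe

from conftest import linear_chain_model


def _pooled(spec_pairs, diet_caps):
    models = [make_toy_microbe(MicrobeSpec(name, **kw)) for name, kw in spec_pairs]
    pooled = pool_models(models)
    pooled.model = apply_diet(pooled.model, DietSpec("d", diet_caps), strict=False)
    return pooled


class TestIterativeOptimization:
    def test_pool_of_one_equals_plain_fba(self):
        pooled = _pooled([("solo", {})], {"glc": 10.0})
        res = iterative_biomass_optimization(pooled)
        assert res["BIOMASS__solo"].objective_value == pytest.approx(10.0)

    def test_independent_members_reproduce_mono_optima(self):
        pooled = _pooled(
            [("o1", {}), ("o2", {"carbon_sources": ("fru",), "uptake_cap": 4.0})],
            {"glc": 10.0, "fru": 4.0},
        )
        res = iterative_biomass_optimization(pooled)
        assert res["BIOMASS__o1"].objective_value == pytest.approx(10.0)
        assert res["BIOMASS__o2"].objective_value == pytest.approx(4.0)

    def test_starved_member_records_zero(self):
        pooled = _pooled(
            [("o1", {}), ("o2", {"carbon_sources": ("fru",)})], {"glc": 10.0}
        )
        res = iterative_biomass_optimization(pooled)
        assert res["BIOMASS__o2"].objective_value == pytest.approx(0.0)


class TestOptimalCommunityGrowth:
    def test_independent_substrates_min_of_optima(self):
        pooled = _pooled(
            [("o1", {}), ("o2", {"carbon_sources": ("fru",), "uptake_cap": 4.0})],
            {"glc": 10.0, "fru": 4.0},
        )
        out = optimal_community_growth(pooled)
        assert out.g_star == pytest.approx(4.0)
        for bio in pooled.model.biomass_ids:
            assert out.constrained_model.reaction(bio).lower_bound == pytest.approx(4.0)

    def test_shared_substrate_splits_evenly(self):
        pooled = _pooled([("s1", {}), ("s2", {})], {"glc": 10.0})
        assert optimal_community_growth(pooled).g_star == pytest.approx(5.0)

    def test_dead_member_forces_zero(self):
        pooled = _pooled(
            [("o1", {}), ("o2", {"carbon_sources": ("fru",)})], {"glc": 10.0}
        )
        assert optimal_community_growth(pooled).g_star == pytest.approx(0.0)

    def test_g_star_bounded_by_every_iterative_optimum(self):
        pooled = _pooled(
            [("s1", {}), ("s2", {}), ("o3", {"carbon_sources": ("fru",), "uptake_cap": 3.0})],
            {"glc": 10.0, "fru": 3.0},
        )
        g_star = optimal_community_growth(pooled).g_star
        for flux in iterative_biomass_optimization(pooled).values():
            assert g_star <= flux.objective_value + 1e-7

    def test_sampling_the_constrained_model_respects_g_star(self):
        pooled = _pooled([("s1", {}), ("s2", {})], {"glc": 10.0})
        out = optimal_community_growth(pooled)
        samples = sample_fluxes(
            out.constrained_model, SamplerSettings(n_samples=100, steps_per_point=20, seed=0)
        )
        for bio in pooled.model.biomass_ids:
            assert samples.column(bio).min() >= out.g_star - 1e-8


class TestPathwaySummary:
    def test_all_zero_fluxes_give_zero_medians(self):
        P = np.zeros((5, 3))
        Q = np.zeros((2, 3))
        table = pathway_flux_summary(P, Q, ["r1", "r2", "r3"], {"r1": "glycolysis"})
        assert (table.median_sampled == 0).all()
        assert (table.median_optimized == 0).all()
        assert set(table.subsystem) == {"glycolysis", "unassigned"}

    def test_uniform_sampling_vs_pinned_fba_pair(self):
        """1-dof uniform flux on [0,10] vs FBA at 10: normalized medians (0.5, 1.0)."""
        rng = np.random.default_rng(0)
        P = rng.uniform(0, 10, size=(20001, 1))
        Q = np.full((1, 1), 10.0)
        table = pathway_flux_summary(P, Q, ["r"], {"r": "s"})
        assert table.median_sampled[0] == pytest.approx(0.5, abs=0.02)
        assert table.median_optimized[0] == pytest.approx(1.0)

    def test_invariant_under_reaction_reordering(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(50, 4))
        Q = rng.normal(size=(8, 4))
        ids = ["a", "b", "c", "d"]
        subs = {"a": "s1", "b": "s1", "c": "s2", "d": "s2"}
        t1 = pathway_flux_summary(P, Q, ids, subs)
        perm = [2, 0, 3, 1]
        t2 = pathway_flux_summary(P[:, perm], Q[:, perm], [ids[i] for i in perm], subs)
        merged = t1.merge(t2, on="subsystem")
        assert np.allclose(merged.median_sampled_x, merged.median_sampled_y)

    def test_biomass_maximization_hides_submaximal_routes(self):
        """FBA pins the low-yield route at zero while sampling uses it: the
        optimization axis reads 0 and the sampling axis stays positive."""
        m = make_toy_microbe(MicrobeSpec("t", aerobic_yield=2.0, anaerobic_yield=1.0))
        m = apply_diet(m, DietSpec("aer", {"glc": 10.0, "o2": 1000.0}, aerobic=True))
        fba = solve_fba(m, "BIOMASS")
        assert abs(fba.values["FERM_glc"]) < 1e-9
        samples = sample_fluxes(m, SamplerSettings(n_samples=300, steps_per_point=30, seed=2))
        assert np.median(samples.column("FERM_glc")) > 0.1


class TestReactionDivergence:
    def test_identical_samples_have_zero_divergence(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(500, 2))
        table = reaction_divergence(P, P.copy(), ["r1", "r2"])
        assert (table.kl_sum < 1e-12).all()
        assert (table["class"] == "low").all()

    def test_two_gaussians_match_analytic_divergence(self):
        """N(0,1) vs N(1,1): D(P||Q) = D(Q||P) = 0.5, so kl_sum ~ 1.0."""
        rng = np.random.default_rng(3)
        P = rng.normal(0.0, 1.0, size=(5000, 1))
        Q = rng.normal(1.0, 1.0, size=(5000, 1))
        kl = reaction_divergence(P, Q, ["r"]).kl_sum[0]
        assert 0.8 <= kl <= 1.2

    def test_divergence_grows_with_separation(self):
        rng = np.random.default_rng(4)
        kls = []
        for mu in (0.5, 1.0, 2.0):
            P = rng.normal(0.0, 1.0, size=(4000, 1))
            Q = rng.normal(mu, 1.0, size=(4000, 1))
            kls.append(reaction_divergence(P, Q, ["r"]).kl_sum[0])
        assert kls[0] < kls[1] < kls[2]

    def test_point_masses_compared_without_blowup(self):
        P = np.full((100, 1), 2.0)
        Q = np.full((50, 1), 2.0)
        assert reaction_divergence(P, Q, ["r"]).kl_sum[0] == 0.0
        Q2 = np.full((50, 1), 5.0)
        table = reaction_divergence(P, Q2, ["r"])
        assert np.isfinite(table.kl_sum[0]) and table.kl_sum[0] > 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        P=arrays(np.float64, (30, 2), elements=st.floats(-50, 50)),
        Q=arrays(np.float64, (30, 2), elements=st.floats(-50, 50)),
    )
    def test_kl_estimates_are_nonnegative(self, P, Q):
        table = reaction_divergence(P, Q, ["r1", "r2"])
        assert (table.kl_forward >= 0).all()
        assert (table.kl_backward >= 0).all()


class TestFluxSum:
    def test_chain_intermediate_turns_over_at_throughput(self):
        m = linear_chain_model()
        flux = solve_fba(m, "BIOMASS")
        V = flux.as_array(m.reaction_ids)[None, :]
        table = flux_sum(V, m).set_index("metabolite")
        assert table.loc["x_c", "median_flux_sum"] == pytest.approx(10.0)

    def test_unused_metabolite_has_zero_flux_sum(self):
        from fluxcomm.gem_core import Metabolite

        m = linear_chain_model()
        m.metabolites.append(Metabolite("orphan_c", "c"))
        V = solve_fba(m, "BIOMASS").as_array(m.reaction_ids)[None, :]
        table = flux_sum(V, m).set_index("metabolite")
        assert table.loc["orphan_c", "median_flux_sum"] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10))
    def test_positively_homogeneous_of_degree_one(self, scale):
        m = linear_chain_model()
        rng = np.random.default_rng(0)
        V = rng.uniform(0, 5, size=(7, len(m.reactions)))
        base = flux_sum(V, m).median_flux_sum.to_numpy()
        scaled = flux_sum(scale * V, m).median_flux_sum.to_numpy()
        assert np.allclose(scaled, scale * base)


def test_ensemble_to_array_stacks_solutions():
    m = linear_chain_model()
    res = iterative_biomass_optimization(m)
    arr = ensemble_to_array(res, m.reaction_ids)
    assert arr.shape == (1, 3)
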