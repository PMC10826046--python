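"""Classifier semantics, protocol runs, regime maps, frequency tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxcomm.flux_sampler import FluxSampleSet, SamplerSettings
from fluxcomm.pairwise_interactions import (
    INTERACTION_TYPES,
    PairwiseSamplingResult,
    build_regime_map,
    classify_interaction,
    community_growth_ratio,
    pairwise_protocol_fba,
    pairwise_protocol_sampling,
    summarize_interaction_frequencies,
    unique_pairs,
)
from fluxcomm.synthetic_data import (
    MOTIFS,
    make_crossfeeding_pair,
    make_growth_neutral_crossfeeding_pair,
    motif_diet,
)

FAST_SAMPLER = SamplerSettings(n_samples=300, steps_per_point=50, seed=5)


def reference_classifier(ga_m, gb_m, ga_c, gb_c, delta):
    """Straight-line transcription of the verbal classification rules,
    kept independent of the implementation under test."""

    def label(mono, co):
        if mono <= 1e-6:
            return "+" if co > 1e-6 else "0"
        if co > (1 + delta) * mono:
            return "+"
        if co < (1 - delta) * mono:
            return "-"
        return "0"

    a, b = label(ga_m, ga_c), label(gb_m, gb_c)
    if a == "+" and b == "+":
        return "mutualism"
    if a == "-" and b == "-":
        return "competition"
    if a == "0" and b == "0":
        return "neutralism"
    if "+" in (a, b) and "-" in (a, b):
        return "parasitism"
    if "+" in (a, b):
        return "commensalism"
    return "amensalism"


class TestClassifier:
    def test_mutualism_when_both_grow_ten_percent_faster(self):
        assert classify_interaction(1, 1, 1.2, 1.2, 0.1).type == "mutualism"

    def test_within_band_is_neutralism(self):
        assert classify_interaction(1, 1, 1.05, 0.95, 0.1).type == "neutralism"

    def test_truth_table_multiplicities(self):
        """All 9 ordered faster/slower/unchanged pairs -> six types with
        multiplicities {1,1,1,2,2,2}."""
        co_values = {"faster": 1.2, "slower": 0.8, "unchanged": 1.0}
        counts = {}
        for ca in co_values.values():
            for cb in co_values.values():
                t = classify_interaction(1.0, 1.0, ca, cb, 0.1).type
                counts[t] = counts.get(t, 0) + 1
        assert counts == {
            "mutualism": 1,
            "competition": 1,
            "neutralism": 1,
            "parasitism": 2,
            "commensalism": 2,
            "amensalism": 2,
        }

    def test_orientation_marks_the_asymmetric_partner(self):
        assert classify_interaction(1, 1, 1.5, 1.0, 0.1).orientation == "a"
        assert classify_interaction(1, 1, 1.0, 0.5, 0.1).orientation == "b"
        assert classify_interaction(1, 1, 0.5, 1.5, 0.1).orientation == "b"

    def test_negative_growth_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            classify_interaction(-1, 1, 1, 1)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        g=st.tuples(*(st.floats(0, 100) for _ in range(4))),
        delta=st.floats(0.01, 0.5),
    )
    def test_total_and_matches_independent_transcription(self, g, delta):
        call = classify_interaction(*g, delta)
        assert call.type in INTERACTION_TYPES
        assert call.type == reference_classifier(*g, delta)


class TestProtocolFba:
    @pytest.mark.parametrize("motif", MOTIFS)
    def test_recovers_engineered_motifs(self, motif):
        a, b, expected = make_crossfeeding_pair(motif)
        call = pairwise_protocol_fba(a, b, motif_diet(motif))
        assert call.type == expected

    def test_nongrowing_partner_reads_as_neutralism(self):
        """B cannot grow in either setting and A is unchanged: the zero-growth
        convention labels B unchanged, so the pair is neutral."""
        from fluxcomm.synthetic_data import MicrobeSpec, make_toy_microbe, DietSpec

        a = make_toy_microbe(MicrobeSpec("A", carbon_sources=("glc",)))
        b = make_toy_microbe(MicrobeSpec("B", carbon_sources=("fru",)))
        call = pairwise_protocol_fba(a, b, DietSpec("glc_only", {"glc": 10.0}))
        assert call.growth_b_mono == pytest.approx(0.0)
        assert call.type == "neutralism"


class TestProtocolSampling:
    def test_growth_envelope_and_basal_bound(self):
        a, b, diet = make_growth_neutral_crossfeeding_pair()
        res = pairwise_protocol_sampling(a, b, diet, FAST_SAMPLER, basal_fraction=0.1)
        assert not res.infeasible
        assert res.growth_a_co.min() >= 0.1 * res.growth_a_mono_fba - 1e-9
        assert res.growth_b_co.min() >= 0.1 * res.growth_b_mono_fba - 1e-9
        assert res.growth_a_co.max() <= res.growth_a_co_fba + 1e-7
        ratios = community_growth_ratio(res)
        assert ratios.min() >= 10.0 - 1e-6
        assert ratios.max() <= 100.0 + 1e-6

    def test_relaxed_basal_lets_growth_fall_below_the_floor(self):
        """Without the basal rule, sampled growths drop below 10% of the mono
        FBA optimum, so the ratio envelope is no longer bounded at 10%."""
        a, b, diet = make_growth_neutral_crossfeeding_pair()
        res = pairwise_protocol_sampling(a, b, diet, FAST_SAMPLER, basal_fraction=0.0)
        assert res.growth_a_co.min() < 0.1 * res.growth_a_mono_fba
        assert res.growth_b_co.min() < 0.1 * res.growth_b_mono_fba

    def test_disjoint_pair_concentrates_on_neutralism(self):
        a, b, _ = make_crossfeeding_pair("neutralism")
        res = pairwise_protocol_sampling(
            a, b, motif_diet("neutralism"), FAST_SAMPLER
        )
        assert res.call_distribution()["neutralism"] > 0.5
        assert res.modal_call() == "neutralism"

    def test_call_distribution_sums_to_one(self):
        a, b, _ = make_crossfeeding_pair("competition")
        res = pairwise_protocol_sampling(a, b, motif_diet("competition"), FAST_SAMPLER)
        assert sum(res.call_distribution().values()) == pytest.approx(1.0)


def _synthetic_result(ga, gb, calls):
    samples = np.column_stack([ga, gb])
    sset = FluxSampleSet(samples, ["BIO_A", "BIO_B"])
    res = PairwiseSamplingResult(
        mono_a=None,
        mono_b=None,
        co=sset,
        biomass_a="BIO_A",
        biomass_b="BIO_B",
        growth_a_mono_fba=1.0,
        growth_b_mono_fba=1.0,
        growth_a_co_fba=1.0,
        growth_b_co_fba=1.0,
        basal_fraction=0.1,
        delta=0.1,
        reference="quantile",
    )
    res.calls = [
        classify_interaction(1.0, 1.0, {"f": 1.5, "u": 1.0}[a], {"f": 1.5, "u": 1.0}[b], 0.1)
        for a, b in calls
    ]
    return res


class TestRegimeMap:
    def test_constant_calls_give_constant_map(self):
        rng = np.random.default_rng(0)
        ga, gb = rng.uniform(1, 2, 100), rng.uniform(1, 2, 100)
        res = _synthetic_result(ga, gb, [("f", "f")] * 100)
        rmap = build_regime_map(res, n_bins=4)
        occupied = rmap.cells[rmap.cells.support > 0]
        assert set(occupied["type"]) == {"mutualism"}

    def test_engineered_block_pattern_recovered(self):
        """Calls switch at the growth median of organism A: a 2x2 map splits
        into mutualism rows above and commensalism rows below."""
        ga = np.concatenate([np.linspace(0, 0.9, 50), np.linspace(1.1, 2, 50)])
        gb = np.tile(np.linspace(0, 2, 50), 2)
        calls = [("u", "f")] * 50 + [("f", "f")] * 50
        res = _synthetic_result(ga, gb, calls)
        rmap = build_regime_map(res, n_bins=2)
        assert rmap.cell_type(0, 0) == "commensalism"
        assert rmap.cell_type(0, 1) == "commensalism"
        assert rmap.cell_type(1, 0) == "mutualism"
        assert rmap.cell_type(1, 1) == "mutualism"

    def test_supports_sum_to_sample_count(self):
        rng = np.random.default_rng(1)
        ga, gb = rng.uniform(0, 1, 123), rng.uniform(0, 1, 123)
        res = _synthetic_result(ga, gb, [("f", "f")] * 123)
        rmap = build_regime_map(res, n_bins=5)
        assert rmap.cells.support.sum() == 123

    def test_bad_bin_count_rejected(self):
        res = _synthetic_result(np.ones(10), np.ones(10), [("f", "f")] * 10)
        with pytest.raises(ValueError, match="n_bins"):
            build_regime_map(res, n_bins=0)


class TestFrequencies:
    def test_single_call_is_one_hundred_percent(self):
        call = classify_interaction(1, 1, 1.5, 1.5, 0.1)
        table = summarize_interaction_frequencies([call])
        assert table.loc[0, "mutualism"] == pytest.approx(100.0)

    def test_uniform_cohort_of_six_motifs(self):
        calls = [
            pairwise_protocol_fba(*make_crossfeeding_pair(m)[:2], motif_diet(m))
            for m in MOTIFS
        ]
        table = summarize_interaction_frequencies(calls)
        for t in INTERACTION_TYPES:
            assert table.loc[0, t] == pytest.approx(100.0 / 6.0)

    def test_aggregates_partition_the_total(self):
        calls = ["competition", "mutualism", "amensalism", "neutralism"]
        table = summarize_interaction_frequencies(calls)
        assert table.loc[0, "antagonistic"] + table.loc[0, "cooperative_or_neutral"] == pytest.approx(100.0)

    def test_grouping_by_condition(self):
        table = summarize_interaction_frequencies(
            ["mutualism", "competition"], conditions=["aerobic", "anaerobic"]
        )
        assert len(table) == 2
        assert set(table.condition) == {"aerobic", "anaerobic"}


def test_unique_pairs_counts_combinations():
    assert len(unique_pairs(range(5))) == 10
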