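"""Pairwise co-culture protocol, interaction classification, regime maps.

The seven-step protocol: join two models through a lumen, apply the diet,
measure each organism's mono-culture growth with the partner shut off, then
measure co-culture growth with both active (two separate biomass LPs in FBA
mode; uniform polytope samples in sampling mode, with each biomass bounded
below at a basal fraction of its mono-culture FBA optimum).  An organism is
*faster* in co-culture when its growth exceeds (1+delta) times its reference,
*slower* below (1-delta) times it, otherwise *unchanged*; the ordered label
pair maps onto the six classic ecological motifs.

Sampling mode classifies every co-culture sample.  The default reference for
a sample is the quantile-matched mono-culture growth (the co-culture sample at
rank r is compared against the mono distribution at the same quantile), which
makes an uncoupled pair read as neutral instead of as symmetric noise;
``reference`` may also be "median" or "fba".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_build import CommunityModel, join_compartmentalized, shut_off
from .flux_sampler import FluxSampleSet, SamplerSettings, constrain_basal_growth, sample_fluxes
from .gem_core import FbaSettings, MetabolicModel, apply_diet, solve_fba
from ._lp import InfeasibleError, LPError

__all__ = [
    "INTERACTION_TYPES",
    "InteractionCall",
    "RegimeMap",
    "PairwiseSamplingResult",
    "classify_interaction",
    "pairwise_protocol_fba",
    "pairwise_protocol_sampling",
    "build_regime_map",
    "community_growth_ratio",
    "summarize_interaction_frequencies",
    "unique_pairs",
]

#: fixed order used for deterministic modal tie-breaks
INTERACTION_TYPES = (
    "mutualism",
    "commensalism",
    "neutralism",
    "amensalism",
    "parasitism",
    "competition",
)

#: growth below this is treated as zero (h^-1)
ZERO_GROWTH_FLOOR = 1e-6

_PAIR_TO_TYPE = {
    ("faster", "faster"): "mutualism",
    ("slower", "slower"): "competition",
    ("unchanged", "unchanged"): "neutralism",
    ("faster", "unchanged"): "commensalism",
    ("unchanged", "faster"): "commensalism",
    ("slower", "unchanged"): "amensalism",
    ("unchanged", "slower"): "amensalism",
    ("faster", "slower"): "parasitism",
    ("slower", "faster"): "parasitism",
}


@dataclass
class InteractionCall:
    type: str
    growth_a_mono: float
    growth_b_mono: float
    growth_a_co: float
    growth_b_co: float
    threshold: float = 0.10
    orientation: str | None = None  # which organism benefits/suffers

    def as_dict(self) -> dict:
        return {
            "type": self.type,
            "growth_a_mono": self.growth_a_mono,
            "growth_b_mono": self.growth_b_mono,
            "growth_a_co": self.growth_a_co,
            "growth_b_co": self.growth_b_co,
            "threshold": self.threshold,
            "orientation": self.orientation,
        }


def _growth_label(mono: float, co: float, delta: float) -> str:
    if mono <= ZERO_GROWTH_FLOOR:
        # relative change undefined at zero: faster needs an absolute floor
        return "faster" if co > ZERO_GROWTH_FLOOR else "unchanged"
    if co > (1.0 + delta) * mono:
        return "faster"
    if co < (1.0 - delta) * mono:
        return "slower"
    return "unchanged"


def classify_interaction(
    growth_a_mono: float,
    growth_b_mono: float,
    growth_a_co: float,
    growth_b_co: float,
    delta: float = 0.10,
) -> InteractionCall:
    """Map the four growth rates onto one of the six interaction motifs."""
    growths = (growth_a_mono, growth_b_mono, growth_a_co, growth_b_co)
    if any(g < 0 for g in growths):
        raise ValueError(f"growth rates must be nonnegative, got {growths}")
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie in (0, 1)")
    la = _growth_label(growth_a_mono, growth_a_co, delta)
    lb = _growth_label(growth_b_mono, growth_b_co, delta)
    itype = _PAIR_TO_TYPE[(la, lb)]
    orientation = None
    if itype == "commensalism":
        orientation = "a" if la == "faster" else "b"
    elif itype == "amensalism":
        orientation = "a" if la == "slower" else "b"
    elif itype == "parasitism":
        orientation = "a" if la == "faster" else "b"  # the parasite
    return InteractionCall(
        type=itype,
        growth_a_mono=growth_a_mono,
        growth_b_mono=growth_b_mono,
        growth_a_co=growth_a_co,
        growth_b_co=growth_b_co,
        threshold=delta,
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# protocol runners
# ---------------------------------------------------------------------------

def _step(step_no: int, what):
    try:
        return what()
    except LPError as err:
        raise type(err)(f"protocol step {step_no}: {err}") from err


def _joined_with_diet(model_a, model_b, diet) -> CommunityModel:
    community = join_compartmentalized(model_a, model_b)
    community.model = apply_diet(community.model, diet)
    return community


def pairwise_protocol_fba(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    diet,
    settings: FbaSettings | None = None,
    delta: float = 0.10,
) -> InteractionCall:
    """Steps 1-7 with FBA: join, diet, two mono-cultures, co-culture, classify."""
    community = _step(2, lambda: _joined_with_diet(model_a, model_b, diet))
    tag_a, tag_b = community.organisms
    bio_a, bio_b = community.biomass_of(tag_a), community.biomass_of(tag_b)

    mono_a_model = shut_off(community, tag_b).model
    g_a_mono = _step(4, lambda: solve_fba(mono_a_model, bio_a, settings)).objective_value
    mono_b_model = shut_off(community, tag_a).model
    g_b_mono = _step(5, lambda: solve_fba(mono_b_model, bio_b, settings)).objective_value
    # step 6: both active; each biomass optimized separately, growth read from
    # its own LP (the partner's growth in that LP is not used)
    g_a_co = _step(6, lambda: solve_fba(community.model, bio_a, settings)).objective_value
    g_b_co = _step(6, lambda: solve_fba(community.model, bio_b, settings)).objective_value
    return classify_interaction(
        max(g_a_mono, 0.0), max(g_b_mono, 0.0), max(g_a_co, 0.0), max(g_b_co, 0.0), delta
    )


@dataclass
class PairwiseSamplingResult:
    mono_a: FluxSampleSet | None
    mono_b: FluxSampleSet | None
    co: FluxSampleSet | None
    biomass_a: str
    biomass_b: str
    growth_a_mono_fba: float
    growth_b_mono_fba: float
    growth_a_co_fba: float
    growth_b_co_fba: float
    basal_fraction: float
    delta: float
    reference: str
    calls: list[InteractionCall] = field(default_factory=list)
    infeasible: bool = False

    @property
    def growth_a_co(self) -> np.ndarray:
        return self.co.column(self.biomass_a)

    @property
    def growth_b_co(self) -> np.ndarray:
        return self.co.column(self.biomass_b)

    def call_distribution(self, per_sample: bool = True) -> dict[str, float]:
        """Fraction of each interaction type among the per-sample calls."""
        if not self.calls:
            return {}
        counts = {t: 0 for t in INTERACTION_TYPES}
        for call in self.calls:
            counts[call.type] += 1
        n = len(self.calls)
        return {t: counts[t] / n for t in INTERACTION_TYPES}

    def modal_call(self) -> str:
        dist = self.call_distribution()
        best = max(dist.values())
        for t in INTERACTION_TYPES:  # fixed order breaks ties deterministically
            if dist[t] == best:
                return t
        raise RuntimeError("empty call distribution")


def _reference_growths(
    mono_growths: np.ndarray, co_growths: np.ndarray, reference: str, fba_opt: float
) -> np.ndarray:
    if reference == "fba":
        return np.full_like(co_growths, fba_opt)
    if reference == "median":
        return np.full_like(co_growths, float(np.median(mono_growths)))
    if reference == "quantile":
        ranks = np.argsort(np.argsort(co_growths, kind="stable"), kind="stable")
        q = (ranks + 0.5) / len(co_growths)
        return np.quantile(mono_growths, q)
    raise ValueError(f"unknown reference {reference!r}")


def pairwise_protocol_sampling(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    diet,
    sampler_settings: SamplerSettings | None = None,
    basal_fraction: float = 0.10,
    delta: float = 0.10,
    reference: str = "quantile",
    fba_settings: FbaSettings | None = None,
) -> PairwiseSamplingResult:
    """Steps 4-6 with flux sampling plus the basal growth rule.

    Mono-cultures are sampled with the partner shut off; the co-culture is
    sampled with each biomass bounded below by ``basal_fraction`` times its
    mono FBA optimum.  Every co-culture sample is classified, yielding a
    distribution over the six motifs.
    """
    sampler_settings = sampler_settings or SamplerSettings()
    community = _joined_with_diet(model_a, model_b, diet)
    tag_a, tag_b = community.organisms
    bio_a, bio_b = community.biomass_of(tag_a), community.biomass_of(tag_b)

    def sub_settings(offset: int) -> SamplerSettings:
        return SamplerSettings(
            n_samples=sampler_settings.n_samples,
            steps_per_point=sampler_settings.steps_per_point,
            seed=(sampler_settings.seed + offset) % 2**31,
            steady_state_tolerance=sampler_settings.steady_state_tolerance,
            warmup=sampler_settings.warmup,
        )

    mono_a_model = shut_off(community, tag_b).model
    mono_b_model = shut_off(community, tag_a).model
    g_a_fba = solve_fba(mono_a_model, bio_a, fba_settings).objective_value
    g_b_fba = solve_fba(mono_b_model, bio_b, fba_settings).objective_value
    g_a_co_fba = solve_fba(community.model, bio_a, fba_settings).objective_value
    g_b_co_fba = solve_fba(community.model, bio_b, fba_settings).objective_value

    mono_a_model = constrain_basal_growth(mono_a_model, bio_a, basal_fraction, fba_settings)
    mono_b_model = constrain_basal_growth(mono_b_model, bio_b, basal_fraction, fba_settings)
    co_model = community.model.copy()
    for bio, g in ((bio_a, g_a_fba), (bio_b, g_b_fba)):
        if g > 1e-9:
            co_model.reaction(bio).lower_bound = basal_fraction * g

    result = PairwiseSamplingResult(
        mono_a=None,
        mono_b=None,
        co=None,
        biomass_a=bio_a,
        biomass_b=bio_b,
        growth_a_mono_fba=g_a_fba,
        growth_b_mono_fba=g_b_fba,
        growth_a_co_fba=g_a_co_fba,
        growth_b_co_fba=g_b_co_fba,
        basal_fraction=basal_fraction,
        delta=delta,
        reference=reference,
    )
    try:
        result.mono_a = sample_fluxes(mono_a_model, sub_settings(0))
        result.mono_b = sample_fluxes(mono_b_model, sub_settings(1))
        result.co = sample_fluxes(co_model, sub_settings(2))
    except InfeasibleError:
        result.infeasible = True  # jointly infeasible basal bounds: recorded, not raised
        return result

    ga_mono = result.mono_a.column(bio_a)
    gb_mono = result.mono_b.column(bio_b)
    ga_co = result.co.column(bio_a)
    gb_co = result.co.column(bio_b)
    ref_a = _reference_growths(ga_mono, ga_co, reference, g_a_fba)
    ref_b = _reference_growths(gb_mono, gb_co, reference, g_b_fba)
    result.calls = [
        classify_interaction(
            max(ra, 0.0), max(rb, 0.0), max(ga, 0.0), max(gb, 0.0), delta
        )
        for ra, rb, ga, gb in zip(ref_a, ref_b, ga_co, gb_co)
    ]
    return result


# ---------------------------------------------------------------------------
# downstream analytics
# ---------------------------------------------------------------------------

@dataclass
class RegimeMap:
    bins_a: np.ndarray
    bins_b: np.ndarray
    cells: pd.DataFrame  # columns: bin_a, bin_b, type, support
    condition: str = ""

    def cell_type(self, i: int, j: int) -> str | None:
        m = self.cells[(self.cells.bin_a == i) & (self.cells.bin_b == j)]
        return None if m.empty else m["type"].iloc[0]


def build_regime_map(
    result: PairwiseSamplingResult, n_bins: int = 20, condition: str = ""
) -> RegimeMap:
    """Quantile-bin both organisms' sampled co-culture growths; each cell's
    label is the modal per-sample interaction call among its samples."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if result.co is None or not result.calls:
        raise ValueError("regime map needs a sampled, classified co-culture")
    ga = result.growth_a_co
    gb = result.growth_b_co
    qs = np.linspace(0, 1, n_bins + 1)
    bins_a = np.unique(np.quantile(ga, qs))
    bins_b = np.unique(np.quantile(gb, qs))
    ia = np.clip(np.searchsorted(bins_a, ga, side="right") - 1, 0, len(bins_a) - 2)
    ib = np.clip(np.searchsorted(bins_b, gb, side="right") - 1, 0, len(bins_b) - 2)
    records = []
    types = np.array([c.type for c in result.calls])
    for i in range(len(bins_a) - 1):
        for j in range(len(bins_b) - 1):
            mask = (ia == i) & (ib == j)
            support = int(mask.sum())
            if support == 0:
                records.append({"bin_a": i, "bin_b": j, "type": None, "support": 0})
                continue
            cell_types = types[mask]
            counts = {t: int((cell_types == t).sum()) for t in INTERACTION_TYPES}
            best = max(counts.values())
            modal = next(t for t in INTERACTION_TYPES if counts[t] == best)
            records.append({"bin_a": i, "bin_b": j, "type": modal, "support": support})
    return RegimeMap(
        bins_a=bins_a, bins_b=bins_b, cells=pd.DataFrame(records), condition=condition
    )


def community_growth_ratio(result: PairwiseSamplingResult) -> np.ndarray:
    """Per-sample summed co-culture growth as % of the FBA co-culture sum."""
    denom = result.growth_a_co_fba + result.growth_b_co_fba
    if denom <= 0:
        return np.full(result.co.n_samples if result.co is not None else 0, np.nan)
    return 100.0 * (result.growth_a_co + result.growth_b_co) / denom


def summarize_interaction_frequencies(
    calls, conditions=None
) -> pd.DataFrame:
    """Percentage of each interaction type per condition, plus the derived
    antagonistic / cooperative-or-net-neutral / symmetrical aggregates.

    ``calls`` may contain :class:`InteractionCall`s, type strings, or
    type->weight distributions (sampling mode).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no calls to summarize")
    if conditions is None:
        conditions = ["all"] * len(calls)
    weights: dict[str, dict[str, float]] = {}
    for call, cond in zip(calls, conditions):
        w = weights.setdefault(cond, {t: 0.0 for t in INTERACTION_TYPES})
        if isinstance(call, InteractionCall):
            w[call.type] += 1.0
        elif isinstance(call, str):
            w[call] += 1.0
        else:  # distribution
            for t, frac in call.items():
                w[t] += frac
    rows = []
    for cond, w in weights.items():
        total = sum(w.values())
        pct = {t: 100.0 * w[t] / total for t in INTERACTION_TYPES}
        pct["condition"] = cond
        pct["antagonistic"] = pct["competition"] + pct["amensalism"] + pct["parasitism"]
        pct["cooperative_or_neutral"] = (
            pct["commensalism"] + pct["neutralism"] + pct["mutualism"]
        )
        pct["symmetrical"] = pct["mutualism"] + pct["neutralism"] + pct["competition"]
        rows.append(pct)
    cols = ["condition", *INTERACTION_TYPES, "antagonistic", "cooperative_or_neutral", "symmetrical"]
    return pd.DataFrame(rows)[cols]


def unique_pairs(items) -> list[tuple]:
    """All unordered pairs of distinct items (75 models -> 2775 pairs)."""
    return list(itertools.combinations(list(items), 2))
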