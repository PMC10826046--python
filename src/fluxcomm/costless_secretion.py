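"""Quasi-dynamic costless-secretion loop with all/most/any secretion thresholds.

Organisms are simulated as separate models sharing an extracellular media
state.  Each iteration grows every organism under the current media (FBA, an
alternate-optima ensemble, or uniform flux sampling), reads secreted
metabolites off the exchange fluxes, adds them to the media, and repeats until
the media stabilizes.  Secretions read from optimal FBA solutions are
"costless" by construction: the organism grows at its optimum while exporting
them.

With sampling (or an FBA ensemble), a metabolite counts as secreted when the
fraction of flux distributions exporting it meets the cutoff: *any* (> 0),
*most* (> 0.5, so 750/1000 qualifies and 500/1000 does not), or *all* (every
distribution).  Looser cutoffs admit supersets of media at every iteration.

Converged runs are labeled with the N/C/M-#-a/b convention: N (no used media
metabolite comes from a partner), C (unidirectional cross-feeding), M
(reciprocal exchange); the digit counts supplied carbon sources; ``b`` marks
competition (both organisms consume a common capped metabolite), ``a`` its
absence.  Runs where no organism ever grows form the distinguished
``no-growth`` category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lp import InfeasibleError
from .flux_sampler import SamplerSettings, sample_fluxes
from .gem_core import (
    DEFAULT_BOUND,
    FbaSettings,
    MetabolicModel,
    enumerate_optimal_solutions,
    solve_fba,
)

__all__ = [
    "MediaState",
    "GrowthResult",
    "IterationRecord",
    "CostlessRecord",
    "init_minimal_media",
    "detect_secretions",
    "run_costless",
    "label_costless_interaction",
    "costless_design_cases",
    "CARBON_SOURCE_CAP",
]

#: growth-limiting carbon sources are capped at 10 mmol gDW^-1 h^-1
CARBON_SOURCE_CAP = 10.0
#: exchange flux below this magnitude is LP noise, not secretion/uptake
SECRETION_FLOOR = 1e-6
GROWTH_FLOOR = 1e-6

THRESHOLD_MODES = ("fba", "all", "most", "any")


@dataclass
class MediaState:
    """Available exchange metabolites with uptake caps and their provenance."""

    caps: dict[str, float]
    provenance: dict[str, dict] = field(default_factory=dict)

    @property
    def available(self) -> set[str]:
        return set(self.caps)

    def copy(self) -> "MediaState":
        return MediaState(caps=dict(self.caps), provenance={k: dict(v) for k, v in self.provenance.items()})


@dataclass
class GrowthResult:
    organism: str
    feasible: bool
    growth_max: float
    growth_median: float
    #: rows = solutions/samples, columns = exchanged base metabolites
    exchange_fluxes: pd.DataFrame | None

    @property
    def grew(self) -> bool:
        return self.feasible and self.growth_max > GROWTH_FLOOR


@dataclass
class IterationRecord:
    iteration: int
    media: MediaState
    growth: dict[str, GrowthResult]
    secreted: dict[str, set[str]]


@dataclass
class CostlessRecord:
    iterations: list[IterationRecord]
    threshold_mode: str
    converged_at: int
    converged: bool
    carbon_sources: list[str]
    organisms: list[str]

    @property
    def final_media(self) -> MediaState:
        return self.iterations[-1].media

    def secreted_union(self) -> set[str]:
        out: set[str] = set()
        for it in self.iterations:
            for s in it.secreted.values():
                out |= s
        return out


def _apply_media(model: MetabolicModel, caps: dict[str, float]) -> MetabolicModel:
    """Media application for separate models: exchanges absent from the media
    are closed for uptake; an organism simply lacking an exchange for a media
    metabolite ignores it (unlike :func:`gem_core.apply_diet`, which errors)."""
    out = model.copy()
    for base, rid in out.exchanges_by_base().items():
        out.reaction(rid).lower_bound = -float(caps.get(base, 0.0))
    return out


def init_minimal_media(
    models: list[MetabolicModel],
    media,
    carbon_sources: list[str],
    aerobic: bool,
) -> tuple[list[MetabolicModel], MediaState]:
    """Close all uptakes except the media, the capped carbon sources, and O2."""
    available_bases = set()
    for m in models:
        available_bases |= set(m.exchanges_by_base())
    unknown = [c for c in carbon_sources if c not in available_bases]
    if unknown:
        raise KeyError(f"carbon sources with no exchange reaction in any model: {unknown}")
    caps = dict(getattr(media, "uptake_caps", media) or {})
    for c in carbon_sources:
        caps[c] = CARBON_SOURCE_CAP
    caps["o2"] = DEFAULT_BOUND if aerobic else 0.0
    state = MediaState(caps=caps)
    return [_apply_media(m, caps) for m in models], state


def _exchange_flux_frame(model: MetabolicModel, rows: np.ndarray) -> pd.DataFrame:
    by_base = model.exchanges_by_base()
    ids = model.reaction_ids
    cols = {base: rows[:, ids.index(rid)] for base, rid in by_base.items()}
    return pd.DataFrame(cols)


def detect_secretions(
    result: GrowthResult, mode: str, eps: float = SECRETION_FLOOR
) -> set[str]:
    """Metabolites secreted under the given threshold mode.

    FBA mode: exported (flux > eps) in the solution.  Thresholded modes:
    the fraction of rows exporting must be > 0 (any), > 0.5 (most), or
    1.0 (all).
    """
    if mode not in THRESHOLD_MODES:
        raise ValueError(f"unknown threshold mode {mode!r}; expected {THRESHOLD_MODES}")
    if not result.feasible or result.exchange_fluxes is None:
        return set()
    frac = (result.exchange_fluxes > eps).mean(axis=0)
    if mode == "fba":
        return set(frac.index[frac > 0])
    if mode == "any":
        return set(frac.index[frac > 0])
    if mode == "most":
        return set(frac.index[frac > 0.5])
    return set(frac.index[frac >= 1.0])  # all


def _uptakes(result: GrowthResult, mode: str, eps: float = SECRETION_FLOOR) -> set[str]:
    """Metabolites consumed, thresholded symmetrically to secretion."""
    if not result.feasible or result.exchange_fluxes is None:
        return set()
    frac = (result.exchange_fluxes < -eps).mean(axis=0)
    if mode in ("fba", "any"):
        return set(frac.index[frac > 0])
    if mode == "most":
        return set(frac.index[frac > 0.5])
    return set(frac.index[frac >= 1.0])


def _grow_one(
    model: MetabolicModel,
    caps: dict[str, float],
    mode: str,
    engine: str,
    sampler_settings: SamplerSettings | None,
    seed: int,
    ensemble_size: int,
    fba_settings: FbaSettings | None,
) -> GrowthResult:
    constrained = _apply_media(model, caps)
    bio = constrained.biomass_ids[0]
    try:
        if mode == "fba" or engine == "fba-ensemble":
            n_sol = 1 if mode == "fba" else ensemble_size
            if n_sol == 1:
                fluxes = [solve_fba(constrained, bio, fba_settings)]
            else:
                fluxes = enumerate_optimal_solutions(constrained, bio, n_sol, fba_settings)
            rows = np.vstack([f.as_array(constrained.reaction_ids) for f in fluxes])
        else:
            base = sampler_settings or SamplerSettings()
            settings = SamplerSettings(
                n_samples=base.n_samples,
                steps_per_point=base.steps_per_point,
                seed=seed % 2**31,
                steady_state_tolerance=base.steady_state_tolerance,
                warmup=base.warmup,
            )
            rows = sample_fluxes(constrained, settings).samples
    except InfeasibleError:
        return GrowthResult(model.id, False, 0.0, 0.0, None)
    growth = rows[:, constrained.reaction_ids.index(bio)]
    return GrowthResult(
        organism=model.id,
        feasible=True,
        growth_max=float(growth.max()),
        growth_median=float(np.median(growth)),
        exchange_fluxes=_exchange_flux_frame(constrained, rows),
    )


def run_costless(
    models: list[MetabolicModel],
    media,
    carbon_sources: list[str],
    aerobic: bool = False,
    mode: str = "fba",
    sampler_settings: SamplerSettings | None = None,
    max_iterations: int = 25,
    added_uptake_cap: float | None = None,
    engine: str = "sampling",
    ensemble_size: int = 5,
    fba_settings: FbaSettings | None = None,
) -> CostlessRecord:
    """Iterate grow -> detect secretions -> expand media until stable.

    Newly secreted metabolites enter the media with unbounded uptake unless
    ``added_uptake_cap`` is given.  Between iterations the sampler is re-seeded
    as ``seed + iteration`` so records are reproducible end to end.  Exceeding
    ``max_iterations`` flags the record unconverged instead of raising.
    """
    if mode not in THRESHOLD_MODES:
        raise ValueError(f"unknown threshold mode {mode!r}")
    _, state = init_minimal_media(models, media, carbon_sources, aerobic)
    base_seed = (sampler_settings.seed if sampler_settings else 0)
    iterations: list[IterationRecord] = []
    converged = False
    converged_at = max_iterations
    for it in range(1, max_iterations + 1):
        growth: dict[str, GrowthResult] = {}
        secreted: dict[str, set[str]] = {}
        for m in models:
            res = _grow_one(
                m,
                state.caps,
                mode,
                engine,
                sampler_settings,
                base_seed + it,
                ensemble_size,
                fba_settings,
            )
            growth[m.id] = res
            secreted[m.id] = detect_secretions(res, mode)
        iterations.append(
            IterationRecord(iteration=it, media=state.copy(), growth=growth, secreted=secreted)
        )
        new_mets = set().union(*secreted.values()) - state.available
        if not new_mets:
            converged = True
            converged_at = it
            break
        for met in sorted(new_mets):
            state.caps[met] = (
                added_uptake_cap if added_uptake_cap is not None else DEFAULT_BOUND
            )
            source = next(org for org, s in secreted.items() if met in s)
            state.provenance[met] = {"iteration": it, "organism": source}
    return CostlessRecord(
        iterations=iterations,
        threshold_mode=mode,
        converged_at=converged_at,
        converged=converged,
        carbon_sources=list(carbon_sources),
        organisms=[m.id for m in models],
    )


def label_costless_interaction(
    record: CostlessRecord, n_carbon_sources: int | None = None
) -> str:
    """N/C/M-#-a/b code for a (usually pairwise) costless record."""
    n_c = n_carbon_sources if n_carbon_sources is not None else len(record.carbon_sources)
    if not any(g.grew for it in record.iterations for g in it.growth.values()):
        return "no-growth"
    final = record.iterations[-1]
    mode = record.threshold_mode
    uptakes = {org: _uptakes(res, mode) for org, res in final.growth.items()}
    secreted_by: dict[str, set[str]] = {org: set() for org in record.organisms}
    for it in record.iterations:
        for org, s in it.secreted.items():
            secreted_by[org] |= s
    # directed cross-feeding edges: i secreted a metabolite j consumed
    edges = set()
    for i in record.organisms:
        for j in record.organisms:
            if i != j and secreted_by[i] & uptakes[j]:
                edges.add((i, j))
    reciprocal = any((j, i) in edges for (i, j) in edges)
    letter = "M" if reciprocal else ("C" if edges else "N")
    # competition: both organisms draw on a common *capped* metabolite
    initial_caps = record.iterations[0].media.caps
    capped = {m for m, c in initial_caps.items() if 0.0 < c < DEFAULT_BOUND}
    shared = set.intersection(*(uptakes[o] for o in record.organisms)) if uptakes else set()
    suffix = "b" if shared & capped else "a"
    return f"{letter}{n_c}{suffix}"


def costless_design_cases(
    organisms: list, carbon_sources: list, aerobic_states=(True, False)
) -> list[tuple]:
    """Full costless design: every organism pair x aerobic state x carbon source
    (3 organisms x 2 states x 108 sources -> 648 cases)."""
    import itertools

    pairs = list(itertools.combinations(list(organisms), 2))
    return [
        (pair, state, source)
        for pair in pairs
        for state in aerobic_states
        for source in carbon_sources
    ]
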