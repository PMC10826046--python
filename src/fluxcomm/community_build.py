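"""Static community topologies: the compartmentalized join and the pooled model.

``join_compartmentalized`` merges two organism models through a shared *lumen*
compartment: each organism's exchange reaction becomes a bidirectional
transport between its own extracellular species and the lumen species, and one
community-level exchange per lumen species connects the lumen to the
environment.  Diets applied afterwards constrain only the community exchanges;
the inter-organism lumen transports are left unbounded so the microbes can
secrete and absorb metabolites freely.

``pool_models`` builds the lumped ("mixed-bag") supra-organism: a
single-compartment union of all reactions in which duplicated stoichiometries
are consolidated to one copy (bounds merged by interval hull) while each input
model's biomass reaction is kept — one growth readout per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gem_core import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = ["CommunityModel", "join_compartmentalized", "shut_off", "pool_models", "TAG_DELIMITER"]

TAG_DELIMITER = "__"
LUMEN = "u"


@dataclass
class CommunityModel:
    model: MetabolicModel
    organisms: list[str]
    lumen_compartment: str | None
    id_map: dict[str, dict[str, str]] = field(default_factory=dict)

    def biomass_of(self, organism: str) -> str:
        for rid in self.model.biomass_ids:
            rxn = self.model.reaction(rid)
            if rxn.organism_tag == organism:
                return rid
        raise KeyError(f"no biomass reaction for organism {organism!r}")

    def reactions_of(self, organism: str) -> list[str]:
        return [r.id for r in self.model.reactions if r.organism_tag == organism]

    def original_id(self, tagged_id: str) -> tuple[str, str]:
        """Inverse of the per-organism id map: tagged id -> (organism, original)."""
        for org, mapping in self.id_map.items():
            for orig, tagged in mapping.items():
                if tagged == tagged_id:
                    return org, orig
        raise KeyError(f"{tagged_id!r} not found in any organism id map")

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            model=self.model.copy(),
            organisms=list(self.organisms),
            lumen_compartment=self.lumen_compartment,
            id_map={org: dict(m) for org, m in self.id_map.items()},
        )


def _tagged(identifier: str, tag: str) -> str:
    return f"{identifier}{TAG_DELIMITER}{tag}"


def join_compartmentalized(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    tags: tuple[str, str] | None = None,
) -> CommunityModel:
    """Join two organism models through a shared lumen compartment."""
    if tags is None:
        if model_a.id == model_b.id:  # clonal pairing: auto-suffix copy indices
            tags = (f"{model_a.id}_1", f"{model_a.id}_2")
        else:
            tags = (model_a.id, model_b.id)
    if tags[0] == tags[1]:
        raise ValueError(f"organism tags must be distinct, got {tags!r}")

    metabolites: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []
    biomass_ids: list[str] = []
    exchange_ids: set[str] = set()
    id_map: dict[str, dict[str, str]] = {}
    lumen_bases: dict[str, str] = {}  # base name -> lumen metabolite id

    for model, tag in zip((model_a, model_b), tags):
        model.validate()
        id_map[tag] = {}
        for met in model.metabolites:
            tid = _tagged(met.id, tag)
            if tid in metabolites:
                raise ValueError(f"metabolite id collision after tagging: {tid!r}")
            metabolites[tid] = Metabolite(
                tid, met.compartment, met.name, dict(met.annotation)
            )
        for rxn in model.reactions:
            tid = _tagged(rxn.id, tag)
            id_map[tag][rxn.id] = tid
            if rxn.id in model.exchange_ids:
                met_id = next(iter(rxn.stoichiometry))
                base = model.metabolite(met_id).base_id
                lumen_id = lumen_bases.setdefault(base, f"{base}_{LUMEN}")
                if lumen_id not in metabolites:
                    metabolites[lumen_id] = Metabolite(lumen_id, LUMEN, name=base)
                # export-positive transport: organism species -> lumen species
                reactions.append(
                    Reaction(
                        tid,
                        {_tagged(met_id, tag): -1.0, lumen_id: 1.0},
                        -DEFAULT_BOUND,
                        DEFAULT_BOUND,
                        subsystem="lumen transport",
                        organism_tag=tag,
                    )
                )
            else:
                reactions.append(
                    Reaction(
                        tid,
                        {_tagged(m, tag): c for m, c in rxn.stoichiometry.items()},
                        rxn.lower_bound,
                        rxn.upper_bound,
                        subsystem=rxn.subsystem,
                        organism_tag=tag,
                    )
                )
            if rxn.id in model.biomass_ids:
                biomass_ids.append(tid)

    for base, lumen_id in sorted(lumen_bases.items()):
        rid = f"EX_{lumen_id}"
        reactions.append(
            Reaction(
                rid,
                {lumen_id: -1.0},
                -DEFAULT_BOUND,
                DEFAULT_BOUND,
                subsystem="exchange",
                organism_tag=None,
            )
        )
        exchange_ids.add(rid)

    joined = MetabolicModel(
        id=f"{tags[0]}|{tags[1]}",
        metabolites=list(metabolites.values()),
        reactions=reactions,
        biomass_ids=biomass_ids,
        exchange_ids=exchange_ids,
        annotation={"construction": "join_compartmentalized"},
    )
    joined.validate()
    return CommunityModel(
        model=joined,
        organisms=list(tags),
        lumen_compartment=LUMEN,
        id_map=id_map,
    )


def shut_off(community: CommunityModel, organism: str) -> CommunityModel:
    """Inactivate one organism: all its reactions (biomass included) get lb=ub=0."""
    if organism not in community.organisms:
        raise KeyError(
            f"unknown organism {organism!r}; present: {community.organisms}"
        )
    out = community.copy()
    for rxn in out.model.reactions:
        if rxn.organism_tag == organism:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def _canonical_stoichiometry(rxn: Reaction) -> tuple:
    return tuple(sorted((m, round(c, 12)) for m, c in rxn.stoichiometry.items()))


def pool_models(
    models: list[MetabolicModel], tags: list[str] | None = None
) -> CommunityModel:
    """Pool organism models into one supra-organism (lumped) model."""
    if not models:
        raise ValueError("pool_models needs at least one model")
    if tags is None:
        tags = []
        seen: dict[str, int] = {}
        for m in models:
            k = seen.get(m.id, 0)
            tags.append(m.id if k == 0 else f"{m.id}_{k + 1}")
            seen[m.id] = k + 1
    if len(set(tags)) != len(tags):
        raise ValueError("organism tags must be distinct")

    metabolites: dict[str, Metabolite] = {}
    reactions: dict[str, Reaction] = {}
    by_stoich: dict[tuple, str] = {}
    biomass_ids: list[str] = []
    exchange_ids: set[str] = set()
    id_map: dict[str, dict[str, str]] = {}

    for model, tag in zip(models, tags):
        model.validate()
        id_map[tag] = {}
        for met in model.metabolites:
            if met.id not in metabolites:
                metabolites[met.id] = Metabolite(
                    met.id, met.compartment, met.name, dict(met.annotation)
                )
        for rxn in model.reactions:
            if rxn.id in model.biomass_ids:
                # biomass reactions are never consolidated: one per species
                tid = _tagged(rxn.id, tag)
                reactions[tid] = Reaction(
                    tid,
                    dict(rxn.stoichiometry),
                    rxn.lower_bound,
                    rxn.upper_bound,
                    subsystem=rxn.subsystem,
                    organism_tag=tag,
                )
                biomass_ids.append(tid)
                id_map[tag][rxn.id] = tid
                continue
            key = _canonical_stoichiometry(rxn)
            if key in by_stoich:
                rep = reactions[by_stoich[key]]
                rep.lower_bound = min(rep.lower_bound, rxn.lower_bound)
                rep.upper_bound = max(rep.upper_bound, rxn.upper_bound)
                rep.organism_tag = None  # shared by construction
                id_map[tag][rxn.id] = rep.id
            else:
                rid = rxn.id if rxn.id not in reactions else _tagged(rxn.id, tag)
                reactions[rid] = Reaction(
                    rid,
                    dict(rxn.stoichiometry),
                    rxn.lower_bound,
                    rxn.upper_bound,
                    subsystem=rxn.subsystem,
                    organism_tag=tag,
                )
                by_stoich[key] = rid
                id_map[tag][rxn.id] = rid
                if rxn.id in model.exchange_ids:
                    exchange_ids.add(rid)

    pooled = MetabolicModel(
        id="pooled:" + "+".join(tags),
        metabolites=list(metabolites.values()),
        reactions=list(reactions.values()),
        biomass_ids=biomass_ids,
        exchange_ids=exchange_ids,
        annotation={"construction": "pool_models"},
    )
    pooled.validate()
    return CommunityModel(
        model=pooled, organisms=list(tags), lumen_compartment=None, id_map=id_map
    )
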