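"""Toy microbe generators with engineered ground-truth interactions.

Every generator builds a small (10–30 reaction) microbe-like network that is
carbon-balanced by construction against a declared per-metabolite carbon mass:
a capped carbon uptake, a fermentative route (secreting byproducts), a
higher-yield respiratory route (consuming oxygen), and a single biomass drain.
Growth-associated maintenance is omitted so the toys stay hand-solvable; an
optional *non-growth-associated* maintenance flux (a forced substrate burn,
the ATPM analog in real reconstructions) is available because it is the
mechanism by which an active partner consumes shared resources and therefore
the only way a two-LP co-culture protocol can produce negative interactions.

Interaction-motif recipes (all evaluated anaerobically, shared lumen, diet
listed by :func:`motif_diet`):

* ``neutralism``    — disjoint substrates (A: glucose, B: fructose).
* ``competition``   — both on glucose, each with a forced maintenance burn of
  the shared pool, so either partner's presence taxes the other.
* ``mutualism``     — each organism's fermentation secretes a vitamin the
  partner needs for a double-yield boosted route (reciprocal cross-feeding).
* ``commensalism``  — A ferments glucose to acetate; B grows on fructose and
  additionally on A's acetate.
* ``amensalism``    — B grows on fructose but burns shared glucose for
  maintenance, taxing A; A does nothing for or against B.
* ``parasitism``    — B grows only on A's acetate (benefits) while burning
  shared glucose for maintenance (harms A).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .gem_core import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = [
    "MicrobeSpec",
    "DietSpec",
    "SpecificationError",
    "metabolite_carbon_mass",
    "make_toy_microbe",
    "make_crossfeeding_pair",
    "make_growth_neutral_crossfeeding_pair",
    "make_acetate_rescue_pair",
    "make_community",
    "make_diet",
    "motif_diet",
    "MOTIFS",
]

MOTIFS = (
    "mutualism",
    "commensalism",
    "parasitism",
    "amensalism",
    "competition",
    "neutralism",
)


class SpecificationError(ValueError):
    """A microbe/diet spec references undefined metabolites or is inconsistent."""


#: declared carbon mass per extracellular metabolite; the elemental-consistency
#: invariant is checked against this vector (cofactors/minerals carry 0 carbon)
_CARBON_MASS = {
    "glc": 6.0,
    "fru": 6.0,
    "ac": 2.0,
    "fiber": 24.0,  # polymer worth 4 hexose units
    "co2": 1.0,
    "o2": 0.0,
    "nh4": 0.0,
}
_PATTERNS = [
    (re.compile(r"^src\d+$"), 6.0),
    (re.compile(r"^byp\d+$"), 2.0),
    (re.compile(r"^vit[A-Za-z0-9]*$"), 0.0),
]


def metabolite_carbon_mass(base_id: str) -> float:
    if base_id in _CARBON_MASS:
        return _CARBON_MASS[base_id]
    for pat, mass in _PATTERNS:
        if pat.match(base_id):
            return mass
    raise SpecificationError(f"undefined metabolite id {base_id!r}")


@dataclass(frozen=True)
class MicrobeSpec:
    """Blueprint of one toy microbe.

    ``secretes`` entries are ``(metabolite, route)`` or
    ``(metabolite, route, coefficient)`` with route in {"ferm", "resp"};
    byproducts are produced obligately by that route.  ``boost`` optionally
    grants a higher-yield route on the first carbon source that consumes one
    unit of a partner-supplied cofactor per substrate.  ``maintenance`` forces
    a fixed substrate burn (carbon units per hour) on ``maintenance_substrate``.
    """

    name: str
    carbon_sources: tuple[str, ...] = ("glc",)
    secretes: tuple[tuple, ...] = ()
    requires: tuple[str, ...] = ()
    aerobic_yield: float = 2.0
    anaerobic_yield: float = 1.0
    uptake_cap: float = 10.0
    boost: tuple[str, float] | None = None  # (cofactor metabolite, boosted yield)
    maintenance: float = 0.0
    maintenance_substrate: str | None = None

    def validate(self) -> None:
        if not (self.aerobic_yield >= self.anaerobic_yield > 0):
            raise SpecificationError(
                f"{self.name}: need aerobic_yield >= anaerobic_yield > 0"
            )
        if self.uptake_cap <= 0:
            raise SpecificationError(f"{self.name}: uptake_cap must be positive")
        secreted = {entry[0] for entry in self.secretes}
        if secreted & set(self.requires):
            raise SpecificationError(
                f"{self.name}: secreted and required metabolites overlap"
            )
        for met in (
            list(self.carbon_sources)
            + list(secreted)
            + list(self.requires)
            + ([self.maintenance_substrate] if self.maintenance_substrate else [])
            + ([self.boost[0]] if self.boost else [])
        ):
            metabolite_carbon_mass(met)
        if self.maintenance < 0:
            raise SpecificationError(f"{self.name}: maintenance must be >= 0")
        if self.maintenance > 0 and self.maintenance_substrate is None:
            raise SpecificationError(
                f"{self.name}: maintenance requires a maintenance_substrate"
            )


@dataclass(frozen=True)
class DietSpec:
    """Exchange uptake capacities (mmol gDW^-1 h^-1) keyed by base metabolite."""

    name: str
    uptake_caps: dict[str, float] = field(default_factory=dict)
    aerobic: bool = False

    def __post_init__(self) -> None:
        for met, cap in self.uptake_caps.items():
            metabolite_carbon_mass(met)
            if cap < 0:
                raise SpecificationError(f"diet {self.name}: negative cap for {met}")
        if not self.aerobic and self.uptake_caps.get("o2", 0.0) != 0.0:
            raise SpecificationError(
                f"diet {self.name}: oxygen cap must be 0 when anaerobic"
            )


# ---------------------------------------------------------------------------
# single-microbe builder
# ---------------------------------------------------------------------------

def _route(
    rid: str,
    substrate: str,
    yield_: float,
    byproducts: list[tuple[str, float]],
    oxygen: float,
    subsystem: str,
    prec_id: str = "prec_c",
) -> Reaction:
    """Mass-balanced conversion: substrate (+O2) -> prec + byproducts + CO2."""
    m_s = metabolite_carbon_mass(substrate)
    carbon_out = yield_ + sum(
        coef * metabolite_carbon_mass(met) for met, coef in byproducts
    )
    n_co2 = m_s - carbon_out
    if n_co2 < -1e-12:
        raise SpecificationError(
            f"route {rid}: products carry more carbon ({carbon_out}) than "
            f"substrate {substrate} ({m_s})"
        )
    stoich: dict[str, float] = {f"{substrate}_e": -1.0, prec_id: yield_}
    if oxygen > 0:
        stoich["o2_e"] = -oxygen
    for met, coef in byproducts:
        stoich[f"{met}_e"] = stoich.get(f"{met}_e", 0.0) + coef
    if n_co2 > 1e-12:
        stoich["co2_e"] = stoich.get("co2_e", 0.0) + n_co2
    return Reaction(rid, stoich, 0.0, DEFAULT_BOUND, subsystem=subsystem)


def make_toy_microbe(spec: MicrobeSpec) -> MetabolicModel:
    """Deterministically build the mass-balanced toy model for ``spec``.

    Growth equals (route yield) x (substrate consumption); with the default
    1:1 biomass drain on the precursor, an uptake cap of 10 and yields 2/1
    give FBA growth 20 with oxygen and 10 without.
    """
    spec.validate()
    mets: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []
    exchange_ids: set[str] = set()
    # the biomass precursor is organism-specific: each species has its own
    # biomass composition, so pooling must not merge precursor pools
    prec_id = f"prec_{spec.name}_c"

    def ensure_met(base: str, compartment: str) -> str:
        mid = f"{base}_{compartment}"
        if mid not in mets:
            mets[mid] = Metabolite(
                mid,
                compartment,
                name=base,
                annotation={"carbon_mass": metabolite_carbon_mass(base)}
                if compartment == "e"
                else {},
            )
        return mid

    def ensure_exchange(base: str, cap: float) -> None:
        mid = ensure_met(base, "e")
        rid = f"EX_{mid}"
        if rid not in {r.id for r in reactions}:
            reactions.append(
                Reaction(rid, {mid: -1.0}, -cap, DEFAULT_BOUND, subsystem="exchange")
            )
            exchange_ids.add(rid)

    mets[prec_id] = Metabolite(prec_id, "c", name="biomass precursor")
    ferm_byproducts = [
        (e[0], float(e[2]) if len(e) > 2 else 1.0) for e in spec.secretes if e[1] == "ferm"
    ]
    resp_byproducts = [
        (e[0], float(e[2]) if len(e) > 2 else 1.0) for e in spec.secretes if e[1] == "resp"
    ]

    carbon_sources = list(spec.carbon_sources)
    if "fiber" in carbon_sources:
        # the polymer is degraded extracellularly to hexose, then consumed
        ensure_exchange("fiber", spec.uptake_cap)
        ensure_met("glc", "e")
        reactions.append(
            Reaction(
                "DEGR_fiber",
                {"fiber_e": -1.0, "glc_e": 4.0},
                0.0,
                DEFAULT_BOUND,
                subsystem="degradation",
            )
        )
        carbon_sources = [s for s in carbon_sources if s != "fiber"]
        if "glc" not in carbon_sources:
            carbon_sources.append("glc")
            # no direct glc supply: the exchange stays but the diet decides caps
            ensure_exchange("glc", 0.0)

    for src in carbon_sources:
        ensure_exchange(src, spec.uptake_cap)
        reactions.append(
            _route(
                f"FERM_{src}",
                src,
                spec.anaerobic_yield,
                ferm_byproducts,
                oxygen=0.0,
                subsystem="fermentation",
                prec_id=prec_id,
            )
        )
        reactions.append(
            _route(
                f"RESP_{src}",
                src,
                spec.aerobic_yield,
                resp_byproducts,
                oxygen=metabolite_carbon_mass(src),
                subsystem="respiration",
                prec_id=prec_id,
            )
        )
    if spec.boost is not None:
        cofactor, boosted_yield = spec.boost
        src = carbon_sources[0]
        ensure_exchange(cofactor, 0.0)
        rxn = _route(
            f"BOOST_{src}",
            src,
            boosted_yield,
            [],
            oxygen=0.0,
            subsystem="boosted",
            prec_id=prec_id,
        )
        rxn.stoichiometry[f"{cofactor}_e"] = -1.0
        reactions.append(rxn)

    for entry in spec.secretes:
        ensure_exchange(entry[0], 0.0)
    ensure_exchange("co2", 0.0)
    ensure_exchange("o2", DEFAULT_BOUND)

    biomass_stoich: dict[str, float] = {prec_id: -1.0}
    for req in spec.requires:
        ensure_exchange(req, DEFAULT_BOUND)
        biomass_stoich[f"{req}_e"] = -1.0
    reactions.append(
        Reaction("BIOMASS", biomass_stoich, 0.0, DEFAULT_BOUND, subsystem="biomass")
    )

    if spec.maintenance > 0:
        sub = spec.maintenance_substrate
        ensure_exchange(sub, DEFAULT_BOUND if sub not in spec.carbon_sources else spec.uptake_cap)
        m_s = metabolite_carbon_mass(sub)
        reactions.append(
            Reaction(
                "MAINT",
                {f"{sub}_e": -1.0, "co2_e": m_s},
                spec.maintenance,
                spec.maintenance,
                subsystem="maintenance",
            )
        )

    model = MetabolicModel(
        id=spec.name,
        metabolites=list(mets.values()),
        reactions=reactions,
        biomass_ids=["BIOMASS"],
        exchange_ids=exchange_ids,
        annotation={"generator": "make_toy_microbe"},
    )
    model.validate()
    check_carbon_balance(model)
    return model


def check_carbon_balance(model: MetabolicModel) -> None:
    """Every non-exchange, non-biomass reaction conserves declared carbon."""
    for rxn in model.reactions:
        if rxn.id in model.exchange_ids or rxn.id in model.biomass_ids:
            continue
        total = 0.0
        for met_id, coef in rxn.stoichiometry.items():
            met = model.metabolite(met_id)
            if met.compartment == "e":
                total += coef * metabolite_carbon_mass(met.base_id)
            elif met.base_id.startswith("prec"):
                total += coef * 1.0  # precursor carries one carbon unit
        if abs(total) > 1e-9:
            raise SpecificationError(
                f"reaction {rxn.id!r} breaks carbon balance by {total}"
            )


# ---------------------------------------------------------------------------
# engineered pairs
# ---------------------------------------------------------------------------

def make_crossfeeding_pair(motif: str):
    """Two toy microbes whose compartmentalized FBA protocol yields ``motif``.

    Returns ``(model_a, model_b, expected_motif)``; pair the result with
    :func:`motif_diet` for the matching environment.
    """
    if motif not in MOTIFS:
        raise SpecificationError(
            f"unknown motif {motif!r}; expected one of {sorted(MOTIFS)}"
        )
    if motif == "neutralism":
        a = MicrobeSpec("A_neutral", carbon_sources=("glc",))
        b = MicrobeSpec("B_neutral", carbon_sources=("fru",))
    elif motif == "competition":
        a = MicrobeSpec(
            "A_compete", carbon_sources=("glc",),
            maintenance=2.0, maintenance_substrate="glc",
        )
        b = MicrobeSpec(
            "B_compete", carbon_sources=("glc",),
            maintenance=2.0, maintenance_substrate="glc",
        )
    elif motif == "mutualism":
        a = MicrobeSpec(
            "A_mutual", carbon_sources=("glc",),
            secretes=(("vitA", "ferm"),), boost=("vitB", 2.0),
        )
        b = MicrobeSpec(
            "B_mutual", carbon_sources=("fru",),
            secretes=(("vitB", "ferm"),), boost=("vitA", 2.0),
        )
    elif motif == "commensalism":
        a = MicrobeSpec("A_commensal", carbon_sources=("glc",), secretes=(("ac", "ferm", 2.0),))
        b = MicrobeSpec("B_commensal", carbon_sources=("fru", "ac"))
    elif motif == "amensalism":
        a = MicrobeSpec("A_amensal", carbon_sources=("glc",))
        b = MicrobeSpec(
            "B_amensal", carbon_sources=("fru",),
            maintenance=2.0, maintenance_substrate="glc",
        )
    else:  # parasitism
        a = MicrobeSpec("A_host", carbon_sources=("glc",), secretes=(("ac", "ferm", 2.0),))
        b = MicrobeSpec(
            "B_parasite", carbon_sources=("ac",),
            maintenance=2.0, maintenance_substrate="glc",
        )
    return make_toy_microbe(a), make_toy_microbe(b), motif


def motif_diet(motif: str) -> DietSpec:
    """Anaerobic environment matching :func:`make_crossfeeding_pair`."""
    if motif not in MOTIFS:
        raise SpecificationError(f"unknown motif {motif!r}")
    caps = {
        "neutralism": {"glc": 10.0, "fru": 10.0},
        "competition": {"glc": 10.0},
        "mutualism": {"glc": 10.0, "fru": 10.0},
        "commensalism": {"glc": 10.0, "fru": 5.0},
        "amensalism": {"glc": 10.0, "fru": 10.0},
        "parasitism": {"glc": 10.0},
    }[motif]
    return DietSpec(name=f"diet_{motif}", uptake_caps=caps, aerobic=False)


def make_growth_neutral_crossfeeding_pair():
    """Cross-feeding pair whose co-culture FBA optima equal the mono optima.

    A ferments glucose and obligately secretes acetate; B can burn its own
    fructose or A's acetate but is capped by its nitrogen supply, so the
    acetate exchange is real in the flux sense yet growth-neutral.  Under a
    basal bound of 10% of the mono FBA optimum the summed sampled growth is
    therefore bracketed by exactly 10% and 100% of the FBA co-culture sum.
    Returns ``(model_a, model_b, diet)``.
    """
    a = make_toy_microbe(
        MicrobeSpec("A_donor", carbon_sources=("glc",), secretes=(("ac", "ferm", 2.0),))
    )
    b = make_toy_microbe(
        MicrobeSpec("B_capped", carbon_sources=("fru", "ac"), requires=("nh4",))
    )
    diet = DietSpec(
        name="neutral_crossfeed",
        uptake_caps={"glc": 10.0, "fru": 10.0, "nh4": 5.0},
        aerobic=False,
    )
    return a, b, diet


def make_acetate_rescue_pair():
    """Costless-secretion fixture: A ferments glucose to acetate; B grows only
    on acetate.  Returns ``(model_a, model_b)``; feed glucose as the sole
    carbon source."""
    a = make_toy_microbe(
        MicrobeSpec("A_fermenter", carbon_sources=("glc",), secretes=(("ac", "ferm", 2.0),))
    )
    b = make_toy_microbe(MicrobeSpec("B_acetotroph", carbon_sources=("ac",)))
    return a, b


# ---------------------------------------------------------------------------
# communities and diets
# ---------------------------------------------------------------------------

def make_community(
    n: int, crossfeed_density: float = 0.0, seed: int = 0
) -> list[MetabolicModel]:
    """``n`` toy microbes with randomly wired byproduct->requirement edges.

    Microbe ``i`` grows on ``src{i}`` and secretes cofactor ``vit{i}`` during
    fermentation; with probability ``crossfeed_density`` microbe ``j``
    additionally *requires* ``vit{i}`` for biomass (a directed cross-feeding
    edge).  Pure function of ``(n, crossfeed_density, seed)``.
    """
    if n < 1:
        raise SpecificationError("n must be >= 1")
    if not (0.0 <= crossfeed_density <= 1.0):
        raise SpecificationError("crossfeed_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    requires: dict[int, list[str]] = {j: [] for j in range(n)}
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < crossfeed_density:
                requires[j].append(f"vit{i}")
    models = []
    for i in range(n):
        spec = MicrobeSpec(
            name=f"microbe{i}",
            carbon_sources=(f"src{i}",),
            secretes=((f"vit{i}", "ferm"),),
            requires=tuple(sorted(requires[i])),
        )
        models.append(make_toy_microbe(spec))
    return models


def make_diet(kind: str, aerobic: bool = False) -> DietSpec:
    """Diet analogs: ``sugar-like`` (Western analog) feeds a monosaccharide
    directly; ``fiber-like`` supplies only a polymer that must be degraded."""
    if kind == "sugar-like":
        caps = {"glc": 10.0}
    elif kind == "fiber-like":
        caps = {"fiber": 2.5, "glc": 0.0}
    else:
        raise SpecificationError(f"unknown diet kind {kind!r}")
    caps["o2"] = DEFAULT_BOUND if aerobic else 0.0
    return DietSpec(name=kind, uptake_caps=caps, aerobic=aerobic)
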