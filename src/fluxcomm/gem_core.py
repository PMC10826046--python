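"""Constraint-based model substrate: data structures, I/O, FBA, FVA, alternate optima.

A :class:`MetabolicModel` is a stoichiometric network ``S`` with flux bounds
``lb <= v <= ub``, a registry of biomass (growth drain) reactions — one per
organism present — and a registry of exchange reactions.  Exchange reactions
touch exactly one metabolite and are written **export-positive**: an uptake
capacity ``c`` means ``lower_bound = -c``.  This matches the dominant
SBML/AGORA convention and is applied uniformly across the package.

FBA is the LP ``max v_obj  s.t.  S v = 0, lb <= v <= ub``.  Alternate optimal
solutions with distinct activity patterns are enumerated with integer cuts on
the binary pattern ``|v_j| > activity_threshold`` (a MILP per new solution),
mirroring the classic enumerateOptimalSolutions procedure.
"""

from __future__ import annotations

import copy as _copy
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import lil_matrix

from ._lp import InfeasibleError, LPError, UnboundedError, solve_lp

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxVector",
    "FbaSettings",
    "ModelValidationError",
    "read_model",
    "write_model",
    "apply_diet",
    "solve_fba",
    "flux_variability",
    "enumerate_optimal_solutions",
    "validate_flux_vector",
    "DEFAULT_BOUND",
]

#: magnitude used for "unconstrained" bounds so every polytope stays bounded
DEFAULT_BOUND = 1000.0

JSON_SCHEMA_VERSION = "fluxcomm-model-1"


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    compartment: str = "c"
    name: str = ""
    annotation: dict = field(default_factory=dict)

    @property
    def base_id(self) -> str:
        """Metabolite identity without the compartment suffix (``glc_e`` -> ``glc``)."""
        suffix = "_" + self.compartment
        if self.id.endswith(suffix):
            return self.id[: -len(suffix)]
        return self.id


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    organism_tag: str | None = None
    annotation: dict = field(default_factory=dict)


@dataclass
class FluxVector:
    """One steady-state flux assignment; biomass entries are growth rates (h^-1)."""

    values: dict[str, float]
    objective_value: float

    def __getitem__(self, reaction_id: str) -> float:
        return self.values[reaction_id]

    def as_array(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.values[r] for r in reaction_ids], dtype=float)


@dataclass
class FbaSettings:
    steady_state_tolerance: float = 1e-9
    optimality_tolerance: float = 1e-9
    #: |flux| above this counts a reaction as active when comparing optima
    activity_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if self.steady_state_tolerance <= 0 or self.optimality_tolerance <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    biomass_ids: list[str] = field(default_factory=list)
    exchange_ids: set[str] = field(default_factory=set)
    annotation: dict = field(default_factory=dict)

    # ---- lookups -------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r} in model {self.id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r} in model {self.id!r}")

    def _met_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def exchange_metabolite(self, rxn_id: str) -> str:
        """The single metabolite touched by an exchange reaction."""
        rxn = self.reaction(rxn_id)
        if rxn_id not in self.exchange_ids or len(rxn.stoichiometry) != 1:
            raise ValueError(f"{rxn_id!r} is not an exchange reaction")
        return next(iter(rxn.stoichiometry))

    def exchanges_by_base(self) -> dict[str, str]:
        """Map base metabolite name (``glc``) -> exchange reaction id."""
        out: dict[str, str] = {}
        for rid in self.exchange_ids:
            met = self.metabolite(self.exchange_metabolite(rid))
            out[met.base_id] = rid
        return out

    # ---- numerics ------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions); toy models are desk-scale."""
        mets = {m.id: i for i, m in enumerate(self.metabolites)}
        S = lil_matrix((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                S[mets[met_id], j] = coef
        return S.toarray()

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # ---- validation ----------------------------------------------------
    def validate(self) -> None:
        met_ids = set()
        for m in self.metabolites:
            if m.id in met_ids:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            met_ids.add(m.id)
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id!r} has empty stoichiometry")
            for met_id, coef in r.stoichiometry.items():
                if met_id not in met_ids:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared metabolite {met_id!r}"
                    )
                if coef == 0:
                    raise ModelValidationError(
                        f"reaction {r.id!r} has a zero coefficient on {met_id!r}"
                    )
        for b in self.biomass_ids:
            if b not in seen:
                raise ModelValidationError(f"biomass reaction {b!r} not in model")
        for e in self.exchange_ids:
            if e not in seen:
                raise ModelValidationError(f"exchange reaction {e!r} not in model")
            if len(self._rxn_index()[e].stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {e!r} must touch exactly one metabolite"
                )


def validate_flux_vector(
    model: MetabolicModel, flux: FluxVector | np.ndarray, tolerance: float = 1e-9
) -> None:
    """Assert steady state and bound satisfaction for any flux vector.

    This is the package-wide feasibility validator: every flux produced by FBA
    or sampling must pass it.
    """
    if isinstance(flux, FluxVector):
        v = flux.as_array(model.reaction_ids)
    else:
        v = np.asarray(flux, dtype=float)
    S = model.stoichiometric_matrix()
    resid = np.abs(S @ v).max() if S.size else 0.0
    if resid > tolerance:
        raise ModelValidationError(f"steady-state residual {resid:.3e} > {tolerance:.1e}")
    lb, ub = model.bounds_arrays()
    if (v < lb - tolerance).any() or (v > ub + tolerance).any():
        j = int(np.argmax(np.maximum(lb - v, v - ub)))
        raise ModelValidationError(
            f"flux bound violated at reaction {model.reactions[j].id!r}"
        )


# ---------------------------------------------------------------------------
# diet application
# ---------------------------------------------------------------------------

def apply_diet(model: MetabolicModel, diet, strict: bool = True) -> MetabolicModel:
    """Return a copy whose exchange uptake capacities equal the diet's caps.

    Every exchange reaction absent from the diet gets uptake capacity 0;
    secretion (positive) direction is left unconstrained.  Diet caps are keyed
    by base metabolite name (``glc``, ``o2``), so the same diet applies to a
    mono-culture model and to a community model's lumen exchanges.  With
    ``strict`` (the default), a diet naming a metabolite the model cannot
    exchange raises; ``strict=False`` skips such entries, which is how one
    feeds e.g. a polymer-only diet to an organism lacking the transporter.
    """
    by_base = model.exchanges_by_base()
    missing = [m for m in diet.uptake_caps if m not in by_base]
    if missing and strict:
        raise KeyError(
            f"diet {diet.name!r} names metabolites with no exchange reaction: "
            f"{sorted(missing)}"
        )
    out = model.copy()
    for base, rid in by_base.items():
        cap = float(diet.uptake_caps.get(base, 0.0))
        out.reaction(rid).lower_bound = -cap
    return out


# ---------------------------------------------------------------------------
# FBA / FVA / alternate optima
# ---------------------------------------------------------------------------

def _objective_vector(model: MetabolicModel, objective: str) -> np.ndarray:
    ids = model.reaction_ids
    if objective not in ids:
        raise KeyError(f"objective reaction {objective!r} not in model {model.id!r}")
    c = np.zeros(len(ids))
    c[ids.index(objective)] = 1.0
    return c


def solve_fba(
    model: MetabolicModel, objective: str, settings: FbaSettings | None = None
) -> FluxVector:
    """Maximize the objective reaction subject to ``S v = 0`` and flux bounds."""
    settings = settings or FbaSettings()
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = _objective_vector(model, objective)
    sol = solve_lp(
        c,
        S,
        np.zeros(S.shape[0]),
        lb,
        ub,
        feasibility_tolerance=settings.steady_state_tolerance,
        optimality_tolerance=settings.optimality_tolerance,
    )
    flux = FluxVector(
        values=dict(zip(model.reaction_ids, sol.x.tolist())),
        objective_value=float(sol.objective),
    )
    validate_flux_vector(model, flux, tolerance=max(settings.steady_state_tolerance, 1e-7))
    return flux


def flux_variability(
    model: MetabolicModel,
    objective: str,
    fraction_of_optimum: float = 1.0,
    settings: FbaSettings | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux range at ``v_obj >= fraction * optimum``."""
    settings = settings or FbaSettings()
    opt = solve_fba(model, objective, settings).objective_value
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c_obj = _objective_vector(model, objective)
    A_ub = -c_obj[None, :]
    b_ub = np.array([-fraction_of_optimum * opt])
    out: dict[str, tuple[float, float]] = {}
    for j, rid in enumerate(model.reaction_ids):
        c = np.zeros(len(model.reactions))
        c[j] = 1.0
        lo = solve_lp(c, S, np.zeros(S.shape[0]), lb, ub, A_ub, b_ub, sense="min").objective
        hi = solve_lp(c, S, np.zeros(S.shape[0]), lb, ub, A_ub, b_ub, sense="max").objective
        out[rid] = (float(lo), float(hi))
    return out


def enumerate_optimal_solutions(
    model: MetabolicModel,
    objective: str,
    max_solutions: int = 10,
    settings: FbaSettings | None = None,
) -> list[FluxVector]:
    """Enumerate alternate optima with pairwise-distinct active-reaction sets.

    Iterative exclusion: after each optimum, a MILP integer cut forbids its
    binary activity pattern (``|v_j| > activity_threshold``) and asks for a
    new flux vector attaining the same objective value.
    """
    settings = settings or FbaSettings()
    if max_solutions < 1:
        raise ValueError("max_solutions must be >= 1")
    first = solve_fba(model, objective, settings)
    solutions = [first]
    eps = settings.activity_threshold
    opt = first.objective_value

    n = len(model.reactions)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c_obj = _objective_vector(model, objective)
    big_m = np.maximum(np.abs(lb), np.abs(ub))
    big_m[big_m == 0] = 1.0

    def active_set(flux: FluxVector) -> frozenset[str]:
        return frozenset(r for r, v in flux.values.items() if abs(v) > eps)

    seen = {active_set(first)}
    # variables: [v (n), y (n binary)]
    while len(solutions) < max_solutions:
        constraints = []
        zeros = np.zeros((S.shape[0], n))
        constraints.append(
            LinearConstraint(np.hstack([S, zeros]), np.zeros(S.shape[0]), np.zeros(S.shape[0]))
        )
        # optimality: c'v >= opt - tol
        constraints.append(
            LinearConstraint(
                np.hstack([c_obj, np.zeros(n)])[None, :],
                opt - max(settings.optimality_tolerance, 1e-7 * max(1.0, abs(opt))),
                np.inf,
            )
        )
        # linking |v_j| <= M_j y_j  (two one-sided rows)
        eye = np.eye(n)
        constraints.append(
            LinearConstraint(np.hstack([eye, -np.diag(big_m)]), -np.inf, np.zeros(n))
        )
        constraints.append(
            LinearConstraint(np.hstack([-eye, -np.diag(big_m)]), -np.inf, np.zeros(n))
        )
        # integer cuts: for each seen pattern A, sum_{j in A}(1 - y_j) + sum_{j not in A} y_j >= 1
        ids = model.reaction_ids
        for pattern in seen:
            row = np.zeros(2 * n)
            rhs = 1.0
            for j, rid in enumerate(ids):
                if rid in pattern:
                    row[n + j] = -1.0
                    rhs -= 1.0
                else:
                    row[n + j] = 1.0
            constraints.append(LinearConstraint(row[None, :], rhs, np.inf))
        c_milp = np.concatenate([np.zeros(n), np.ones(n)])  # parsimonious pattern
        integrality = np.concatenate([np.zeros(n), np.ones(n)])
        bounds_lo = np.concatenate([lb, np.zeros(n)])
        bounds_hi = np.concatenate([ub, np.ones(n)])
        from scipy.optimize import Bounds

        res = milp(
            c=c_milp,
            constraints=constraints,
            integrality=integrality,
            bounds=Bounds(bounds_lo, bounds_hi),
        )
        if not res.success:
            break  # no further distinct optimum exists
        v = res.x[:n]
        flux = FluxVector(
            values=dict(zip(ids, v.tolist())),
            objective_value=float(c_obj @ v),
        )
        pattern = active_set(flux)
        if pattern in seen:  # pragma: no cover - numerical guard
            break
        seen.add(pattern)
        solutions.append(flux)
    return solutions


# ---------------------------------------------------------------------------
# I/O: versioned JSON dialect and SBML level 3 (fbc) via cobrapy
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema": JSON_SCHEMA_VERSION,
        "id": model.id,
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, "name": m.name,
             "annotation": m.annotation}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "organism_tag": r.organism_tag,
                "annotation": r.annotation,
            }
            for r in model.reactions
        ],
        "biomass_ids": list(model.biomass_ids),
        "exchange_ids": sorted(model.exchange_ids),
        "annotation": model.annotation,
    }


def _model_from_dict(data: dict, source: str = "<json>") -> MetabolicModel:
    if data.get("schema") != JSON_SCHEMA_VERSION:
        raise ModelValidationError(
            f"{source}: unknown or missing schema tag {data.get('schema')!r}; "
            f"expected {JSON_SCHEMA_VERSION!r}"
        )
    for key in ("id", "metabolites", "reactions"):
        if key not in data:
            raise ModelValidationError(f"{source}: missing required key {key!r}")
    model = MetabolicModel(
        id=data["id"],
        metabolites=[
            Metabolite(
                id=m["id"],
                compartment=m.get("compartment", "c"),
                name=m.get("name", ""),
                annotation=m.get("annotation", {}),
            )
            for m in data["metabolites"]
        ],
        reactions=[
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                subsystem=r.get("subsystem", ""),
                organism_tag=r.get("organism_tag"),
                annotation=r.get("annotation", {}),
            )
            for r in data["reactions"]
        ],
        biomass_ids=list(data.get("biomass_ids", [])),
        exchange_ids=set(data.get("exchange_ids", [])),
        annotation=data.get("annotation", {}),
    )
    if not model.biomass_ids:
        warnings.warn(f"{source}: no biomass annotation; biomass_ids left empty")
    model.validate()
    return model


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML I/O and as a test oracle)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, name=m.name or m.id, compartment=m.compartment)
        mets[m.id] = cmet
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        cr.subsystem = r.subsystem or ""
        cr.notes["organism_tag"] = r.organism_tag or ""
        cr.notes["subsystem"] = r.subsystem or ""
        if r.id in model.biomass_ids:
            cr.notes["biomass"] = "true"
        rxns.append((cr, {mets[mid]: coef for mid, coef in r.stoichiometry.items()}))
    cm.add_metabolites(list(mets.values()))
    cm.add_reactions([cr for cr, _ in rxns])
    for cr, stoich in rxns:
        cr.add_metabolites(stoich)
    if model.biomass_ids:
        cm.objective = model.biomass_ids[0]
    return cm


def from_cobra(cm) -> MetabolicModel:
    mets = [
        Metabolite(id=m.id, compartment=m.compartment or "c", name=m.name or "")
        for m in cm.metabolites
    ]
    reactions = []
    biomass_ids = []
    for r in cm.reactions:
        tag = r.notes.get("organism_tag") or None
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                subsystem=r.notes.get("subsystem", r.subsystem or ""),
                organism_tag=tag,
            )
        )
        if str(r.notes.get("biomass", "")).lower() == "true":
            biomass_ids.append(r.id)
    compartment_of = {m.id: m.compartment for m in mets}
    exchange_ids = {
        r.id
        for r in reactions
        if len(r.stoichiometry) == 1
        and r.id not in biomass_ids
        and compartment_of[next(iter(r.stoichiometry))] in ("e", "u")
    }
    model = MetabolicModel(
        id=cm.id or "model",
        metabolites=mets,
        reactions=reactions,
        biomass_ids=biomass_ids,
        exchange_ids=exchange_ids,
    )
    if not biomass_ids:
        warnings.warn(f"SBML model {model.id!r}: no biomass annotation found")
    model.validate()
    return model


def write_model(model: MetabolicModel, path, format: str = "JSON") -> None:
    model.validate()
    fmt = format.upper()
    if fmt == "JSON":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
    elif fmt == "SBML":
        from cobra.io import write_sbml_model

        write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


def read_model(path, format: str = "JSON") -> MetabolicModel:
    fmt = format.upper()
    if fmt == "JSON":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as err:
                raise ModelValidationError(f"{path}: malformed JSON ({err})") from err
        return _model_from_dict(data, source=str(path))
    if fmt == "SBML":
        from cobra.io import read_sbml_model

        return from_cobra(read_sbml_model(str(path)))
    raise ValueError(f"unknown model format {format!r}")


# re-export LP errors under the module users touch
__all__ += ["InfeasibleError", "UnboundedError", "LPError"]
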