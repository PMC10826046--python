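"""Shared fixtures: tiny hand-checkable networks and an exhaustive LP oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fluxcomm.gem_core import MetabolicModel, Metabolite, Reaction


def linear_chain_model(cap: float = 10.0, biomass_lb: float = 0.0) -> MetabolicModel:
    """uptake (cap) -> conversion -> biomass, all 1:1 yields."""
    return MetabolicModel(
        "chain",
        metabolites=[Metabolite("s_e", "e"), Metabolite("x_c", "c")],
        reactions=[
            Reaction("EX_s_e", {"s_e": -1.0}, -cap, 1000.0),
            Reaction("CONV", {"s_e": -1.0, "x_c": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"x_c": -1.0}, biomass_lb, 1000.0),
        ],
        biomass_ids=["BIOMASS"],
        exchange_ids={"EX_s_e"},
    )


def cycle_model(cap: float = 10.0) -> MetabolicModel:
    """Two opposing reactions A<->B bounded [0, cap]: one uniform degree of freedom."""
    return MetabolicModel(
        "cycle",
        metabolites=[Metabolite("a_c", "c"), Metabolite("b_c", "c")],
        reactions=[
            Reaction("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, cap),
            Reaction("R2", {"b_c": -1.0, "a_c": 1.0}, 0.0, cap),
        ],
    )


@pytest.fixture
def chain():
    return linear_chain_model()


@pytest.fixture
def cycle():
    return cycle_model()


def brute_force_fba(model: MetabolicModel, objective: str) -> float:
    """Exhaustive vertex enumeration of the flux polytope (independent oracle).

    Vertices of {S v = 0, lb <= v <= ub} fix (n - rank S) fluxes at a bound;
    enumerate every such fixing, solve the square-ish system, keep feasible
    points, and return the best objective.  Only viable for toy networks.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    rank = np.linalg.matrix_rank(S, tol=1e-10)
    d = n - rank
    c = np.zeros(n)
    c[model.reaction_ids.index(objective)] = 1.0
    best = -np.inf
    for idx in itertools.combinations(range(n), d):
        for pattern in itertools.product((0, 1), repeat=d):
            rows = [S]
            rhs = [np.zeros(S.shape[0])]
            for j, side in zip(idx, pattern):
                e = np.zeros(n)
                e[j] = 1.0
                rows.append(e[None, :])
                rhs.append(np.array([lb[j] if side == 0 else ub[j]]))
            A = np.vstack(rows)
            b = np.concatenate(rhs)
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.abs(A @ v - b).max() > 1e-8:
                continue  # inconsistent fixing
            if (v < lb - 1e-8).any() or (v > ub + 1e-8).any():
                continue
            if np.abs(S @ v).max() > 1e-8:
                continue
            best = max(best, float(c @ v))
    return best
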