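"""Thin linear-programming layer over scipy's HiGHS interface.

All flux-balance problems in this package reduce to

    max  c' v
    s.t. A_eq v = b_eq,  A_ub v <= b_ub,  lb <= v <= ub

solved here with ``scipy.optimize.linprog(method="highs")``.  Keeping the
solver behind one function makes tolerances uniform and the backend swappable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog


class LPError(Exception):
    """Base class for linear-programming failures."""


class InfeasibleError(LPError):
    """The constraint set is empty."""


class UnboundedError(LPError):
    """The objective is unbounded; some exchange flux is missing a cap."""


@dataclass
class LPSolution:
    x: np.ndarray
    objective: float


def solve_lp(
    c: np.ndarray,
    A_eq: np.ndarray | None,
    b_eq: np.ndarray | None,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
    sense: str = "max",
    feasibility_tolerance: float = 1e-9,
    optimality_tolerance: float = 1e-9,
) -> LPSolution:
    """Solve an LP; raise :class:`InfeasibleError`/:class:`UnboundedError` on failure."""
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    bounds = np.column_stack([lb, ub])
    res = linprog(
        sign * c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": feasibility_tolerance,
            "dual_feasibility_tolerance": optimality_tolerance,
        },
    )
    if res.status == 2:
        raise InfeasibleError("linear program is infeasible")
    if res.status == 3:
        raise UnboundedError(
            "linear program is unbounded; cap the exchange reactions"
        )
    if not res.success:  # pragma: no cover - solver-internal failures
        raise LPError(f"LP solver failed: {res.message}")
    return LPSolution(x=np.asarray(res.x, dtype=float), objective=sign * res.fun)
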