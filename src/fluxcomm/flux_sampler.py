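"""Approximately uniform sampling of the steady-state flux polytope.

The target set is ``{v : S v = 0, lb <= v <= ub}``.  Equality constraints are
eliminated by an orthonormal null-space parameterization ``v = p + N u`` (rank
decided at a stated relative tolerance), leaving a bounded full-dimensional
polytope in ``u`` that is explored with artificial-centering hit-and-run
(ACHR): directions are drawn through the running center from a reservoir of
previously visited points, chords are computed exactly, and the step is
uniform along the chord.  Warmup steps from the Chebyshev center are
discarded, and kept samples are thinned by ``steps_per_point``.

Every emitted sample is feasible by construction; a hard validator re-checks
bounds and the steady-state residual before the set is returned.  Reactions
whose feasible range is numerically zero are pinned to equalities first, so
zero-volume faces (e.g. a biomass flux fixed at its optimum) sample correctly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from ._lp import InfeasibleError, UnboundedError, solve_lp
from .gem_core import FbaSettings, MetabolicModel, _model_to_dict, solve_fba, validate_flux_vector

__all__ = [
    "SamplerSettings",
    "FluxSampleSet",
    "sample_fluxes",
    "constrain_basal_growth",
    "convergence_diagnostics",
]

_RANK_RTOL = 1e-10  # relative tolerance for the numerical rank of S
_PIN_TOL = 1e-9  # FVA range below this pins a reaction to an equality


@dataclass(frozen=True)
class SamplerSettings:
    n_samples: int = 1000
    steps_per_point: int = 200
    seed: int = 0
    steady_state_tolerance: float = 1e-9
    warmup: int | None = None  # default: max(1000, 10 * polytope dimension)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.steps_per_point < 1:
            raise ValueError("steps_per_point must be >= 1")


@dataclass
class FluxSampleSet:
    samples: np.ndarray  # n_samples x n_reactions
    reaction_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def column(self, reaction_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(reaction_id)]

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def to_tsv(self, path, sidecar_path=None) -> None:
        self.dataframe().to_csv(path, sep="\t", index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.provenance, fh, indent=1, default=str)


def _model_digest(model: MetabolicModel) -> str:
    blob = json.dumps(_model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:16]


def _bounding_box(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feasible point plus per-reaction flux ranges (objective-free FVA)."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    zero = np.zeros(S.shape[0])
    try:
        feas = solve_lp(np.zeros(n), S, zero, lb, ub, sense="min").x
    except InfeasibleError:
        raise InfeasibleError(
            f"flux polytope of model {model.id!r} is empty; relax the bounds"
        )
    lo = np.empty(n)
    hi = np.empty(n)
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        try:
            lo[j] = solve_lp(c, S, zero, lb, ub, sense="min").objective
            hi[j] = solve_lp(c, S, zero, lb, ub, sense="max").objective
        except UnboundedError:
            raise UnboundedError(
                f"reaction {model.reactions[j].id!r} is unbounded; cap the "
                "exchange reactions before sampling"
            )
    return feas, lo, hi


def sample_fluxes(model: MetabolicModel, settings: SamplerSettings) -> FluxSampleSet:
    """Draw ``settings.n_samples`` approximately uniform steady-state fluxes.

    Deterministic for identical ``(model, settings)`` including the seed.
    """
    model.validate()
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    feas, lo, hi = _bounding_box(model)

    # pin numerically fixed reactions as equalities
    pinned = (hi - lo) < _PIN_TOL
    eq_rows = [S]
    eq_rhs = [np.zeros(S.shape[0])]
    for j in np.flatnonzero(pinned):
        row = np.zeros(n)
        row[j] = 1.0
        eq_rows.append(row[None, :])
        eq_rhs.append(np.array([(lo[j] + hi[j]) / 2.0]))
    A_eq = np.vstack(eq_rows)
    b_eq = np.concatenate(eq_rhs)

    p, *_ = np.linalg.lstsq(A_eq, b_eq, rcond=None)
    N = null_space(A_eq, rcond=_RANK_RTOL)
    d = N.shape[1]

    provenance = {
        "model_digest": _model_digest(model),
        "n_samples": settings.n_samples,
        "steps_per_point": settings.steps_per_point,
        "seed": settings.seed,
        "steady_state_tolerance": settings.steady_state_tolerance,
        "polytope_dimension": int(d),
        "algorithm": "achr-nullspace",
    }

    if d == 0:
        samples = np.repeat(p[None, :], settings.n_samples, axis=0)
        _validate_set(model, samples, settings.steady_state_tolerance)
        return FluxSampleSet(samples, model.reaction_ids, provenance)

    # inequality system G u <= h over free directions
    rows, rhs = [], []
    for j in range(n):
        if pinned[j]:
            continue
        nj = N[j]
        if np.abs(nj).max() < 1e-13:
            continue  # flux fixed at p_j inside the free subspace
        rows.append(nj)
        rhs.append(ub[j] - p[j])
        rows.append(-nj)
        rhs.append(p[j] - lb[j])
    G = np.array(rows)
    h = np.array(rhs)

    # Chebyshev center for a strictly interior start
    radius_scale = float(np.linalg.norm(hi - lo)) + 1.0
    norms = np.linalg.norm(G, axis=1)
    A_ub = np.hstack([G, norms[:, None]])
    c = np.zeros(d + 1)
    c[-1] = 1.0
    lo_u = np.full(d + 1, -radius_scale)
    hi_u = np.full(d + 1, radius_scale)
    lo_u[-1] = 0.0
    sol = solve_lp(c, None, None, lo_u, hi_u, A_ub=A_ub, b_ub=h, sense="max")
    u = sol.x[:d].copy()

    warmup = settings.warmup if settings.warmup is not None else max(1000, 10 * d)
    rng = np.random.default_rng(settings.seed)

    reservoir = [u.copy()]
    reservoir_cap = 500
    n_visited = 1
    center = u.copy()
    kept = np.empty((settings.n_samples, d))
    n_kept = 0
    total = warmup + settings.n_samples * settings.steps_per_point
    shrink = 1.0 - 1e-12

    for step in range(total):
        if len(reservoir) < 10 or rng.random() < 0.02:
            direction = rng.standard_normal(d)
        else:
            ref = reservoir[int(rng.integers(len(reservoir)))]
            direction = ref - center
        nrm = np.linalg.norm(direction)
        if nrm < 1e-13:
            direction = rng.standard_normal(d)
            nrm = np.linalg.norm(direction)
        direction /= nrm

        z = G @ direction
        slack = np.maximum(h - G @ u, 0.0)
        pos = z > 1e-13
        neg = z < -1e-13
        tmax = np.min(slack[pos] / z[pos]) if pos.any() else radius_scale
        tmin = -np.min(slack[neg] / -z[neg]) if neg.any() else -radius_scale
        if tmax - tmin > 1e-13:
            u = u + (rng.uniform(tmin, tmax) * shrink) * direction

        n_visited += 1
        center += (u - center) / n_visited
        if len(reservoir) < reservoir_cap:
            reservoir.append(u.copy())
        elif rng.random() < reservoir_cap / n_visited:
            reservoir[int(rng.integers(reservoir_cap))] = u.copy()

        if step >= warmup and (step - warmup + 1) % settings.steps_per_point == 0:
            kept[n_kept] = u
            n_kept += 1
            if n_kept == settings.n_samples:
                break

    samples = p[None, :] + kept @ N.T
    _validate_set(model, samples, settings.steady_state_tolerance)
    return FluxSampleSet(samples, model.reaction_ids, provenance)


def _validate_set(model: MetabolicModel, samples: np.ndarray, tolerance: float) -> None:
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    resid = np.abs(samples @ S.T).max() if S.size else 0.0
    tol = max(tolerance, 1e-9)
    if resid > tol:
        raise RuntimeError(f"sampler emitted non-steady-state flux (|Sv| = {resid:.2e})")
    if (samples < lb - tol).any() or (samples > ub + tol).any():
        raise RuntimeError("sampler emitted a sample outside the flux bounds")


def constrain_basal_growth(
    model: MetabolicModel,
    biomass_id: str,
    fraction: float = 0.1,
    settings: FbaSettings | None = None,
) -> MetabolicModel:
    """Copy of the model with biomass lower bound = ``fraction`` x FBA optimum.

    The protocol's basal growth rule: sampling is confined to states where the
    organism grows at least this fast.  A zero FBA optimum degrades to a no-op
    with a warning (basal bound 0).
    """
    flux = solve_fba(model, biomass_id, settings)
    g = flux.objective_value
    out = model.copy()
    if g <= 1e-9:
        warnings.warn(
            f"model {model.id!r}: FBA optimum of {biomass_id!r} is 0; "
            "basal bound left at 0"
        )
        basal = 0.0
    else:
        basal = fraction * g
        out.reaction(biomass_id).lower_bound = basal
    out.annotation.setdefault("basal_growth", {})[biomass_id] = {
        "fraction": fraction,
        "mono_optimum": g,
        "basal_bound": basal,
    }
    return out


def convergence_diagnostics(
    sample_set: FluxSampleSet, flag_multiple: float = 5.0
) -> pd.DataFrame:
    """Advisory per-reaction mixing diagnostics.

    Reports a lag-1 autocorrelation ESS proxy and the split-half mean
    discrepancy; a reaction is flagged when the two half-means differ by more
    than ``flag_multiple`` times the ESS-adjusted standard error.
    """
    X = sample_set.samples
    n = X.shape[0]
    if n < 10:
        raise ValueError("diagnostics need at least 10 samples")
    half = n // 2
    m1 = X[:half].mean(axis=0)
    m2 = X[half : 2 * half].mean(axis=0)
    var = X.var(axis=0, ddof=1)
    centered = X - X.mean(axis=0)
    denom = (centered**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(
            denom > 0, (centered[:-1] * centered[1:]).sum(axis=0) / denom, 0.0
        )
    rho = np.clip(rho, -0.999, 0.999)
    ess = np.clip(n * (1 - rho) / (1 + rho), 2.0, float(n))
    se_diff = 2.0 * np.sqrt(np.where(ess > 0, var / ess, 0.0))
    diff = np.abs(m1 - m2)
    flagged = (var > 0) & (diff > flag_multiple * se_diff)
    return pd.DataFrame(
        {
            "reaction": sample_set.reaction_ids,
            "mean": X.mean(axis=0),
            "split_half_discrepancy": diff,
            "ess": ess,
            "flagged": flagged,
        }
    )
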