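"""Lumped (pooled) community characterizations and distribution analytics.

Three views of a pooled model: (1) iterative per-species biomass optimization,
(2) unconstrained uniform flux sampling, and (3) sampling constrained to the
*optimal community* state — the largest growth rate g* simultaneously
achievable by every species, imposed as a shared biomass lower bound.

Comparisons between the optimization ensemble and the sampled distributions:
per-subsystem median normalized |flux|, per-reaction bidirectional KL
divergence (histogram estimator with shared bins and additive pseudocounts),
and the per-metabolite flux-sum turnover Phi_i = 1/2 sum_j |S_ij v_j|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lp import solve_lp
from .community_build import CommunityModel
from .flux_sampler import FluxSampleSet
from .gem_core import FbaSettings, FluxVector, MetabolicModel, solve_fba
from ._lp import InfeasibleError

__all__ = [
    "OptimalCommunityResult",
    "iterative_biomass_optimization",
    "optimal_community_growth",
    "pathway_flux_summary",
    "reaction_divergence",
    "flux_sum",
    "ensemble_to_array",
]

KL_BINS = 30
KL_PSEUDOCOUNT = 1.0
#: kl_sum class cutoffs: low < 0.05 <= medium <= 1.0 < high
KL_CLASS_CUTOFFS = (0.05, 1.0)


def _as_model(model_or_community) -> MetabolicModel:
    if isinstance(model_or_community, CommunityModel):
        return model_or_community.model
    return model_or_community


def iterative_biomass_optimization(
    pooled, settings: FbaSettings | None = None
) -> dict[str, FluxVector | None]:
    """One FBA solution per biomass reaction (each species maximized in turn).

    Per-species infeasibility is recorded as ``None``, not raised.
    """
    model = _as_model(pooled)
    out: dict[str, FluxVector | None] = {}
    for bio in model.biomass_ids:
        try:
            out[bio] = solve_fba(model, bio, settings)
        except InfeasibleError:
            out[bio] = None
    return out


@dataclass
class OptimalCommunityResult:
    g_star: float
    constrained_model: MetabolicModel


def optimal_community_growth(
    pooled, settings: FbaSettings | None = None
) -> OptimalCommunityResult:
    """Max-min community growth: max g s.t. v feasible and v_bio_k >= g for all k.

    One LP with an auxiliary scalar; the constrained model has every biomass
    lower bound set to g*.
    """
    settings = settings or FbaSettings()
    model = _as_model(pooled)
    if not model.biomass_ids:
        raise ValueError("pooled model has no biomass reactions")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    ids = model.reaction_ids
    # variables [v, g]; equalities S v = 0; inequalities g - v_bio_k <= 0
    A_eq = np.hstack([S, np.zeros((S.shape[0], 1))])
    rows = []
    for bio in model.biomass_ids:
        row = np.zeros(n + 1)
        row[ids.index(bio)] = -1.0
        row[-1] = 1.0
        rows.append(row)
    A_ub = np.array(rows)
    b_ub = np.zeros(len(rows))
    c = np.zeros(n + 1)
    c[-1] = 1.0
    g_cap = float(min(ub[ids.index(b)] for b in model.biomass_ids))
    sol = solve_lp(
        c,
        A_eq,
        np.zeros(S.shape[0]),
        np.concatenate([lb, [0.0]]),
        np.concatenate([ub, [g_cap]]),
        A_ub=A_ub,
        b_ub=b_ub,
        feasibility_tolerance=settings.steady_state_tolerance,
        optimality_tolerance=settings.optimality_tolerance,
    )
    g_star = float(sol.objective)
    constrained = model.copy()
    for bio in model.biomass_ids:
        constrained.reaction(bio).lower_bound = g_star
    return OptimalCommunityResult(g_star=g_star, constrained_model=constrained)


# ---------------------------------------------------------------------------
# distribution analytics
# ---------------------------------------------------------------------------

def ensemble_to_array(
    ensemble: dict[str, FluxVector | None] | list[FluxVector], reaction_ids: list[str]
) -> np.ndarray:
    """Stack FBA solutions into a (n_solutions x n_reactions) array."""
    if isinstance(ensemble, dict):
        vectors = [v for v in ensemble.values() if v is not None]
    else:
        vectors = list(ensemble)
    if not vectors:
        raise ValueError("empty flux ensemble")
    return np.vstack([v.as_array(reaction_ids) for v in vectors])


def _to_array(data, reaction_ids) -> np.ndarray:
    if isinstance(data, FluxSampleSet):
        return np.vstack([data.column(r) for r in reaction_ids]).T
    return np.atleast_2d(np.asarray(data, dtype=float))


def pathway_flux_summary(
    sampled,
    optimized,
    reaction_ids: list[str],
    subsystems: dict[str, str],
    normalization: str = "max-across-conditions",
    bounds: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-subsystem median normalized |flux| for two prediction methods.

    Each reaction's |flux| is normalized by the largest |flux| it attains
    across both conditions (default), so both axes land in [0, 1]; medians are
    taken within subsystem across reactions and samples/solutions.  Reactions
    without a subsystem annotation are grouped as "unassigned".
    """
    P = np.abs(_to_array(sampled, reaction_ids))
    Q = np.abs(_to_array(optimized, reaction_ids))
    if normalization == "max-across-conditions":
        scale = np.maximum(P.max(axis=0), Q.max(axis=0))
    elif normalization == "bound-relative":
        if bounds is None:
            raise ValueError("bound-relative normalization needs bounds")
        scale = np.array(
            [max(abs(bounds[r][0]), abs(bounds[r][1])) for r in reaction_ids]
        )
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    scale = np.where(scale > 0, scale, 1.0)
    Pn, Qn = P / scale, Q / scale
    sub = [subsystems.get(r) or "unassigned" for r in reaction_ids]
    rows = []
    for name in sorted(set(sub)):
        idx = [j for j, s in enumerate(sub) if s == name]
        rows.append(
            {
                "subsystem": name,
                "median_sampled": float(np.median(Pn[:, idx])),
                "median_optimized": float(np.median(Qn[:, idx])),
                "n_reactions": len(idx),
            }
        )
    return pd.DataFrame(rows)


def _histogram_kl(p_samples: np.ndarray, q_samples: np.ndarray) -> tuple[float, float]:
    lo = min(p_samples.min(), q_samples.min())
    hi = max(p_samples.max(), q_samples.max())
    if hi - lo < 1e-12:
        return 0.0, 0.0  # both distributions are the same point mass
    edges = np.linspace(lo, hi, KL_BINS + 1)
    p_counts = np.histogram(p_samples, bins=edges)[0] + KL_PSEUDOCOUNT
    q_counts = np.histogram(q_samples, bins=edges)[0] + KL_PSEUDOCOUNT
    p = p_counts / p_counts.sum()
    q = q_counts / q_counts.sum()
    kl_pq = float(np.sum(p * np.log(p / q)))
    kl_qp = float(np.sum(q * np.log(q / p)))
    return kl_pq, kl_qp


def _kl_class(kl_sum: float) -> str:
    low, high = KL_CLASS_CUTOFFS
    if kl_sum < low:
        return "low"
    if kl_sum <= high:
        return "medium"
    return "high"


def reaction_divergence(P, Q, reaction_ids: list[str]) -> pd.DataFrame:
    """Bidirectional KL divergence per reaction between two flux ensembles.

    ``P`` is typically the sampled distribution, ``Q`` the optimization
    ensemble (single FBA solutions or alternate optima).  Returns kl_forward,
    kl_backward, their sum, the median flux difference, and a
    low/medium/high class on the summed divergence.
    """
    Pa = _to_array(P, reaction_ids)
    Qa = _to_array(Q, reaction_ids)
    if Pa.shape[1] != Qa.shape[1]:
        raise ValueError("ensembles must cover the same reactions")
    records = []
    for j, rid in enumerate(reaction_ids):
        kl_f, kl_b = _histogram_kl(Pa[:, j], Qa[:, j])
        kl_sum = kl_f + kl_b
        records.append(
            {
                "reaction": rid,
                "kl_forward": kl_f,
                "kl_backward": kl_b,
                "kl_sum": kl_sum,
                "median_difference": float(np.median(Pa[:, j]) - np.median(Qa[:, j])),
                "class": _kl_class(kl_sum),
            }
        )
    return pd.DataFrame(records)


def flux_sum(samples, model: MetabolicModel) -> pd.DataFrame:
    """Metabolite turnover Phi_i = 1/2 sum_j |S_ij v_j| per sample; medians too."""
    V = _to_array(samples, model.reaction_ids)
    S = model.stoichiometric_matrix()
    phi = 0.5 * np.abs(V[:, None, :] * S[None, :, :]).sum(axis=2)  # samples x mets
    return pd.DataFrame(
        {
            "metabolite": model.metabolite_ids,
            "median_flux_sum": np.median(phi, axis=0),
            "mean_flux_sum": phi.mean(axis=0),
        }
    ).assign(n_samples=V.shape[0])
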