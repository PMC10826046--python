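# Methods

## Scope and model representation

`fluxcomm` operates on stoichiometric metabolic models: a matrix `S`
(metabolites × reactions), flux bounds `lb ≤ v ≤ ub`, a registry of biomass
drain reactions (one per organism present), and a registry of exchange
reactions. Exchange reactions touch exactly one metabolite and are written
export-positive throughout, so "uptake capacity c" means `lower_bound = -c`;
this matches the dominant SBML/AGORA convention and is applied uniformly —
diets, media and secretion tests all assume it. Models round-trip through a
versioned JSON dialect (`fluxcomm-model-1`) and through SBML Level 3 with flux
bounds (via cobrapy/libsbml); organism tags, subsystems and biomass flags
travel in reaction notes.

All linear programs are solved with HiGHS through `scipy.optimize.linprog`
(feasibility and optimality tolerances both 1e-9 by default). The FBA optimum
is deterministic; the optimal flux *vector* is not unique in general, which is
precisely the degeneracy the rest of the package characterizes. Alternate
optima with distinct activity patterns (|v| > 1e-6) are enumerated by MILP
integer cuts (`scipy.optimize.milp`): each accepted solution's binary activity
pattern is forbidden and a parsimonious new pattern attaining the same
objective is requested, stopping when none exists or the cap is reached.

## Flux sampler

The sampling target is the uniform distribution on
`{v : S v = 0, lb ≤ v ≤ ub}`. The kernel is artificial-centering hit-and-run
(ACHR) on a null-space parameterization rather than a Riemannian HMC sampler:
the target distribution is identical, the implementation is desk-scale
verifiable, and the kernel sits behind one function so alternatives can be
added. Mechanics:

- Objective-free per-reaction FVA first detects unbounded directions (an
  error instructing the caller to cap exchanges — every generated model uses
  a finite "unbounded" sentinel of 1000) and pins numerically fixed reactions
  (range < 1e-9) as equalities, so zero-volume faces (e.g. a biomass pinned
  at its optimum) sample correctly.
- The equalities `[S; pinned rows]` are eliminated with an orthonormal null
  space (numerical rank at relative tolerance 1e-10), leaving a bounded
  full-dimensional polytope `G u ≤ h`.
- The walk starts at the Chebyshev center; directions are drawn through the
  running center from a 500-point reservoir of previously visited states
  (2% fresh random directions); the step is uniform on the exact chord,
  shrunk by a factor `1 - 1e-12` to stay strictly interior.
- Defaults follow the study conditions: 1000 samples per run, 200 steps per
  point; warmup is `max(1000, 10 × dimension)` steps and is a declared
  choice (the source protocol reports thinning and sample counts but no
  burn-in).
- Determinism: one `numpy` PCG64 generator seeded from the settings; the same
  `(model, settings)` reproduce the sample set bit for bit. Derived seeds
  (protocol sub-steps, costless iterations) are small offsets of the user
  seed.
- Hard postcondition: every emitted sample satisfies the bounds and
  `|S v|∞ ≤ 1e-9`, re-checked by a validator before the set is returned.

On the one-degree-of-freedom cycle fixture the free flux is uniform on
[0, 10]; hit-and-run mixes in one step there, and the test suite checks a
Kolmogorov–Smirnov fit at n=1000, α=0.01, plus first/second moments against
cobrapy's OptGP sampler as an independent implementation of the same target.

Convergence diagnostics (split-half mean discrepancy against an
autocorrelation-adjusted standard error, flag multiple 5) are advisory, never
fatal: thinned toy-polytope chains are close to independent, and the flag
exists to catch gross non-mixing on larger inputs.

## Synthetic microbes and what they do (not) emulate

The generator builds 10–30 reaction microbe-like networks that are
carbon-balanced against a declared per-metabolite carbon mass (hexoses 6,
acetate 2, CO₂ 1; O₂, ammonium and vitamin-like cofactors 0): a capped carbon
uptake, a fermentative route (obligately secreting declared byproducts), a
respiratory route consuming oxygen at higher yield, an optional
cofactor-boosted route, and a single biomass drain consuming one precursor
unit (plus any required nutrients) per unit growth. Growth therefore equals
route yield × substrate consumption, so every fixture optimum is hand
solvable: yields 2/1 with cap 10 give growth 20 aerobic / 10 anaerobic.
There is no growth-associated maintenance. The precursor species is
organism-specific so that pooling does not merge biomass pools.

An optional *non-growth-associated* maintenance flux (a forced substrate burn,
the ATPM analog of real reconstructions) is the mechanism behind the
antagonistic fixtures: under the literal co-culture protocol — each biomass
maximized in its own LP with the partner merely active — an idle partner is
always feasible, so the co-culture optimum can never drop below the
mono-culture optimum unless the partner carries a forced flux that drains a
shared resource. The six motif recipes (disjoint substrates; shared substrate
with maintenance; reciprocal vitamin boosts; acetate donation; one-sided
maintenance; acetate-dependent parasite with maintenance) each reproduce their
motif exactly under the FBA protocol, with growths matching closed-form
values.

Two further fixtures serve specific analyses. The *growth-neutral
cross-feeding pair* (fermenter donating acetate to a nitrogen-capped consumer)
has co-culture FBA optima equal to the mono optima, which is the regime in
which the basal rule brackets the sampled community growth ratio exactly
between 10% and 100% of the FBA sum; a growth-boosting pair would put the
polytope floor below 10% of the co-culture ceiling. The *acetate rescue pair*
(consumer grows only on the donor's fermentation byproduct) drives the
costless-secretion mechanics tests.

What the toys do **not** emulate: realistic biomass compositions,
gene–protein–reaction rules, thermodynamic or crowding constraints, realistic
diet compositions, or taxon-specific network structure. Passing tests
demonstrate that the *protocols* behave as specified on networks whose ground
truth is provable, not that any biological conclusion about real communities
holds.

## Community constructions

**Compartmentalized join.** Each organism's exchange reaction becomes a
bidirectional transport between its tagged extracellular species and a shared
lumen species; one community exchange per lumen species connects to the
environment. Diets applied to the joined model constrain only the community
exchanges; lumen transports are unbounded in both directions (the organisms
may secrete and absorb freely — whether the original construction caps them
is unstated, so unbounded is the declared choice). Organism tagging suffixes
ids with a reserved `__` delimiter; pairing a model with itself auto-suffixes
copy indices. Correctness oracle: shutting off one organism (all its
reactions clamped to zero, biomass included) must reproduce the partner's
standalone FBA optimum under the same diet — tested across every fixture.

**Pooling.** The lumped model is a single-compartment union in which
reactions with identical canonical stoichiometry are consolidated to one copy
with interval-hull bounds (the widest feasible merge; the source material
does not specify a rule), except biomass reactions, which are never
consolidated — one growth readout per species. Note one consequence: forced
fluxes (maintenance) also consolidate, so a pooled model can under-count
per-organism maintenance; conversely the "pooling can only help" property
(pooled per-species optimum ≥ mono optimum) holds only for networks without
forced fluxes.

**Optimal community growth.** g\* maximizes a scalar g subject to feasibility
and `v_bio_k ≥ g` for every species — a single LP with one auxiliary
variable. The constrained model sets every biomass lower bound to g\*.

## Pairwise protocol and classification

FBA mode runs the seven steps literally: join, diet, two mono-culture FBAs
with the partner shut off, two co-culture FBAs (each organism's growth read
from its own LP), then classification at δ = 0.1. Zero-growth convention:
relative change is undefined at zero, so an organism with zero reference
growth reads *faster* only if its co-culture growth exceeds 1e-6 h⁻¹, and
never reads *slower*.

Sampling mode replaces the three growth measurements with uniform samples,
after bounding each biomass below by 0.1 × its mono FBA optimum (jointly
infeasible basal bounds are recorded on the result, not raised). Each
co-culture sample is classified against a per-organism reference growth. The
default reference is **quantile-matched**: the co-culture sample at rank r is
compared with the mono-culture distribution at the same quantile. Rationale:
with a fixed reference (mono median or mono FBA optimum), a pair with *no*
metabolic coupling — identical mono and co-culture growth distributions —
would classify mostly as parasitism/competition purely because wide uniform
marginals put ~45% of samples above and ~45% below any central reference;
quantile matching makes the uncoupled case read as neutral, which is the
correct null, and is consistent with ranking the sampled growth rates. The
median and FBA references remain available (`reference="median"|"fba"`).

Regime maps bin both organisms' co-culture growths into quantile bins
(default 20, so cells have comparable support); each cell takes the modal
per-sample call, ties broken by a fixed type order (mutualism <
commensalism < neutralism < amensalism < parasitism < competition). The
community growth ratio is `100 × (g_a + g_b)_sample / (g_a + g_b)_FBA-co`.
Frequency tables report per-type percentages plus the antagonistic
(competition+amensalism+parasitism), cooperative-or-net-neutral
(commensalism+neutralism+mutualism) and symmetrical
(mutualism+neutralism+competition) aggregates; for sampling mode both the
per-sample distribution and the modal call are available (modal is the
default for pair-level summaries).

## Lumped analytics

Pathway summaries normalize each reaction's |flux| by the maximum |flux| that
reaction attains across the two compared conditions (both axes in [0, 1];
per-reaction rather than per-subsystem normalization is a declared choice),
then take medians within subsystem across reactions and samples. KL
divergence per reaction uses 30 equal-width bins spanning the pooled range,
additive pseudocount 1 per bin, natural log, reported both directions plus
their sum; identical point masses give 0, and distinct point masses land in
distinct bins so the estimate stays finite. The estimator is n-sensitive
(pseudocounts shrink tail contributions), which is why the Gaussian
calibration test runs at n=5000 with a ±0.2 band around the analytic value.
Divergence classes default to low < 0.05 ≤ medium ≤ 1.0 < high on the summed
divergence — declared defaults, as the source thresholds are unstated.
Flux-sum uses the standard turnover definition Φ_i = ½ Σ_j |S_ij v_j|.

## Costless-secretion loop

Organisms are separate models sharing a media state. Setup closes every
uptake except the minimal media, the carbon sources (capped at
10 mmol gDW⁻¹ h⁻¹), and oxygen per the aerobic flag. Each iteration grows
every organism (FBA solution, alternate-optima ensemble, or a fresh sample
set re-seeded as seed + iteration), reads secretions off exchange fluxes
above ε = 1e-6 (below LP noise is not secretion), applies the threshold
(any > 0, most > 0.5 — so 750/1000 qualifies and 500/1000 does not —
all = 1.0), and adds new metabolites to the media with unbounded uptake
(configurable cap). The loop stops when no metabolite is new — at most one
iteration per extracellular metabolite — or flags the record unconverged at
the iteration cap.

Labels follow the N/C/M-digit-a/b convention: cross-feeding edges are
metabolites secreted by one organism (any iteration) and consumed by the
other in the final iteration; reciprocal edges give M, one direction C, none
N; the digit counts supplied carbon sources; suffix b marks both organisms
drawing on a common finitely-capped metabolite in the final iteration
(the flux-level operationalization of competition), a its absence. Runs in
which no organism ever grows form the distinguished no-growth category.

## Problem sizes and numerical choices

The test suite and the acceptance script run the sampling analyses at the
study conditions (1000 samples, 200 steps per point) on fixtures of 6–60
reactions; unit tests of mechanics use 50–300 samples. LP tolerances 1e-9;
activity threshold 1e-6; sampler pin tolerance 1e-9; null-space rank
tolerance 1e-10 relative. Ties and degenerate inputs: modal-call ties break
by the fixed type order; zero-variance flux distributions compare as point
masses; a zero FBA optimum downgrades the basal constraint to a warning and
a zero lower bound.

## Known limitations

- ACHR is approximately uniform; its directions depend on chain history, and
  no formal convergence guarantee is claimed. Diagnostics are advisory.
- The toy fixtures' small polytopes make growth marginals broad and nearly
  uniform; real genome-scale polytopes concentrate differently, so sampled
  call distributions on real models will differ quantitatively.
- The pooled construction deliberately ignores organism boundaries; per-
  organism constraints (maintenance, uptake caps) blur under consolidation.
- MILP-based optima enumeration scales exponentially in the worst case and is
  intended for desk-scale networks.
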