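# fluxcomm

Constraint-based models of microbial communities are usually interrogated with
flux balance analysis (FBA), which assumes every organism maximizes growth.
Uniform flux sampling drops that assumption and characterizes the *whole*
steady-state solution space, capturing sub-maximal phenotypes and population
heterogeneity. `fluxcomm` is a tested pipeline for comparing the two views
across the three standard community-modeling constructions:

1. **Compartmentalized pairing** — two genome-scale models joined through a
   shared lumen compartment; a seven-step protocol measures mono- and
   co-culture growth and classifies the pair into one of six ecological motifs
   (mutualism, commensalism, neutralism, amensalism, parasitism, competition)
   against a ±10% growth-change threshold.
2. **Lumped pooling** — all reactions merged into one supra-organism model
   (duplicated stoichiometries consolidated, one biomass reaction kept per
   species), characterized by per-species FBA, unconstrained sampling, and
   sampling constrained to the *optimal community growth* g\* (the max-min
   growth simultaneously achievable by every species).
3. **Costless secretion** — a quasi-dynamic loop that grows separate models on
   a shared minimal medium, adds secreted byproducts to the medium, and
   iterates to convergence, with *all*/*most*/*any* thresholds deciding when a
   sampled secretion counts.

It is aimed at systems-biology researchers who want these protocols on their
own models (SBML or the package's JSON dialect) or on self-contained synthetic
fixtures with engineered ground-truth interactions.

## The core quantities

For a model with stoichiometric matrix $S$ and flux bounds $l \le v \le u$:

- **FBA**: $\max\, v_{\mathrm{bio}}$ subject to $Sv = 0$, $l \le v \le u$.
- **Flux sampling**: approximately uniform draws from
  $\{v : Sv=0,\ l \le v \le u\}$ via artificial-centering hit-and-run on a
  null-space parameterization, with warmup and thinning. Before sampling a
  co-culture, each organism's biomass flux is bounded below by a *basal*
  growth rate — 10% of its mono-culture FBA optimum — excluding zero-growth
  states.
- **Interaction classification**: organism $i$ is *faster* in co-culture when
  $g_i^{co} > (1+\delta)\, g_i^{ref}$ and *slower* when
  $g_i^{co} < (1-\delta)\, g_i^{ref}$ with $\delta = 0.1$; the ordered label
  pair maps onto the six motifs.
- **Flux-sum**: metabolite turnover
  $\Phi_i = \tfrac12 \sum_j |S_{ij} v_j|$.
- **Divergence**: bidirectional Kullback–Leibler divergence between per-
  reaction flux distributions (histogram estimator, 30 shared bins,
  pseudocount 1), classed low/medium/high.

## Worked example

```python
from fluxcomm import (SamplerSettings, make_crossfeeding_pair, motif_diet,
                      pairwise_protocol_fba, pairwise_protocol_sampling)

a, b, expected = make_crossfeeding_pair("competition")
diet = motif_diet("competition")          # anaerobic, shared glucose at 10

call = pairwise_protocol_fba(a, b, diet)
print(call.type, call.growth_a_mono, call.growth_a_co)

res = pairwise_protocol_sampling(a, b, diet,
                                 SamplerSettings(n_samples=1000, seed=11))
print({t: f for t, f in res.call_distribution().items() if f > 0})
```

prints

```
competition 8.0 6.0
{'amensalism': 0.044, 'competition': 0.956}
```

Read: alone, each organism ferments the 10 units of shared glucose minus its
forced maintenance burn (growth 8.0 h⁻¹); in co-culture the partner's
maintenance drains the pool (growth 6.0, a 25% drop on both sides →
competition). Sampling the co-culture polytope instead of optimizing gives a
*distribution* of per-sample calls: 95.6% of sampled states still read as
competition, 4.4% as amensalism.

The same objects drive the lumped and costless analyses:

```python
from fluxcomm import pool_models, optimal_community_growth, run_costless
from fluxcomm import make_acetate_rescue_pair

fermenter, acetotroph = make_acetate_rescue_pair()
record = run_costless([fermenter, acetotroph], {}, ["glc"], mode="fba")
print(record.converged_at)    # 2 — acetate enters the media after round 1
```

A `fluxcomm` command-line tool exposes each stage
(`fluxcomm synth|fba|fva|optima|sample|join|pool|pairwise|lumped|costless`);
every subcommand reads/writes plain TSV and JSON.

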