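# covgrad

Meta-analysis of **countergradient and cogradient variation** — cryptic
local adaptation in which genetic and environmental effects on a trait
covary along an ecological gradient.  Written for evolutionary ecologists
who have (or simulate) common-garden / reciprocal-transplant summary data
and want the full inference chain:

1. **Effect sizes** — Hedges' d (small-sample corrected standardized mean
   difference) between the most disparate populations at each shared
   treatment, with the covariation-pattern inclusion rules
   (countergradient / cogradient / crossing GxE / plasticity only);
2. **Hierarchical Bayesian pooling** — d_i ~ N(θ_i, v_i) with
   θ_i = x_iᵀβ + u_study + w_trait:study + p_species,
   p ~ MVN(0, σ_p² A), A a taxonomy-derived relatedness matrix;
   random-effects-only models for the pooled genetic effect V_G and a
   metaregression with trait / gradient / taxonomic-class moderators,
   summarized as posterior means, medians, 95% credible intervals, the
   heterogeneity s.d. τ = √(σ_u² + σ_w²) and estimated marginal means;
3. **Compensation analysis** — home-vs-home Hedges' d for countergradient
   experiments, classified over/perfect/under at the ±0.5 band (±0.2
   sensitivity band).

A synthetic-data module generates reaction-norm experiments from the
decomposition V_P = V_E + V_G + V_GxE + 2 cov_GE and whole meta-datasets
with known truth, so every stage is testable without external downloads.
See `docs/methods.md` for the model, sampler and design details.

## Worked example

The numbered scripts under `analysis/` run the chain on a simulated
literature corpus (40 studies, 25 species, true pooled effect μ = 1.0):

```sh
python analysis/01_simulate_data.py        # observation + lineage tables
python analysis/02_extract_effect_sizes.py # classification + Hedges' d
python analysis/03_fit_random_effects.py   # pooled V_G per class
python analysis/04_metaregression.py       # moderator EMMs
python analysis/05_compensation.py         # home-phenotype matching
```

Output of steps 2, 3 and 5 (seed 11):

```
80 experiments:
  cogradient: 18
  countergradient: 49
  crossing_gxe: 11
  plasticity_only: 2
wrote 122 effect sizes -> effect_sizes_countergradient.csv
wrote 43 effect sizes -> effect_sizes_cogradient.csv

countergradient: pooled d = 0.97 (95% CI 0.37-1.58), tau = 0.40, phylo s.d. = 0.26 [n=122, max R-hat 1.017]
cogradient: pooled d = 0.83 (95% CI 0.11-1.54), tau = 0.39, phylo s.d. = 0.32 [n=43, max R-hat 1.011]

49 countergradient experiments:
  overcompensating: 16.3%
  perfectly compensating: 44.9%
  undercompensating: 38.8%
  d_comp 5%/95% quantiles: -1.81 / 1.03; range -3.65 to 2.11
  perfect at +/-0.2 band: 12.2%
```

Reading: experiments failing the inclusion rules (crossing reaction norms,
negligible genetic offset) are excluded with logged reasons; the pooled
posterior mean d ≈ 0.97 s.d. recovers the simulated genetic effect μ = 1.0
between the most disparate populations; and under half of countergradient
experiments fall in the conservative perfect-compensation band — home
phenotypes usually do not match exactly.

The same chain is available as one call:

```python
from covgrad import MetaScenario, RunConfig, run_pipeline
cfg = RunConfig(outdir="out", seed=11, preset="re_counter",
                scenario=MetaScenario(sigma_study=0.3,
                                      sigma_trait_study=0.3,
                                      sigma_phylo=0.2))
manifest = run_pipeline(cfg)   # artifact list with SHA-256 checksums
```

or from real data via `observations_path=` / `lineages_path=` (CSV schemas
in `covgrad.pipeline`; dispersion accepted as SD or SE).

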