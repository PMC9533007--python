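# Methods

## Scientific setting

Populations distributed along an environmental gradient (latitude,
elevation, temperature, salinity, ...) often diverge genetically in ways
that the environment masks or exaggerates.  Writing the phenotypic variance
as

    V_P = V_E + V_G + V_GxE + 2 cov_GE,

countergradient variation is the case cov_GE < 0 (genetic and environmental
effects oppose, so wild phenotypes look more similar than the genotypes
are) and cogradient variation the case cov_GE > 0.  Common-garden and
reciprocal-transplant experiments expose the genetic component: rearing the
populations in shared environments and comparing the most disparate
("polar") populations measures V_G directly as a standardized mean
difference.  This package implements that inference chain — effect-size
extraction, hierarchical Bayesian pooling with phylogenetic control, and a
descriptive compensation analysis — together with a generator of synthetic
experiments with known truth.

## Effect sizes (`covgrad.effect_sizes`)

Hedges' d with the small-sample correction J:

    d = J (m1 - m2) / s_pooled,
    s_pooled^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2),
    J = 1 - 3 / (4 (n1 + n2 - 2) - 1),
    v = 1/n1 + 1/n2 + d^2 / (2 (n1 + n2)),

the Hedges–Olkin large-sample variance used by standard meta-analysis
software.  One d is computed per treatment level shared by the polar pair
(the populations at the minimum and maximum gradient position; ties broken
lexicographically with a warning).  Treatments observed for only one polar
population are dropped pairwise, never imputed.  Experiments whose polar
pair shares fewer than two treatments are excluded — two or more common
environments are required to see a reaction norm at all.

Orientation: the sources of such data rarely state a sign convention, and
pooled effects are conventionally reported positive.  The minuend is the
population with the larger common-garden trait value averaged over the
shared treatments, so the experiment-mean d is >= 0; the chosen minuend is
recorded on every record for audit.  Dispersion may be ingested as SD or SE
(`sd = se * sqrt(n)`, logged at ingest).

Pattern classification applies, in order: *plasticity only* if |d| stays
below a negligibility threshold (default 0.2, the conventional small-effect
bound) in every treatment; *crossing GxE* if d changes sign across
treatments (rank order not maintained); otherwise the sign of cov_GE is the
sign of g * e, where g is the mean genetic difference (high- minus
low-position population across common gardens) and e the within-population
trait change from the low population's home treatment to the high
population's home treatment — negative product means countergradient,
positive cogradient.  Home environments are taken from explicit `is_home`
flags; when the two homes coincide or the environmental trend e is exactly
zero the covariance sign is undefined and the classifier raises rather than
guessing.

## Taxonomy pseudo-phylogeny (`covgrad.phylo_vcv`)

Without calibrated phylogenies across such disparate taxa, relatedness is
derived from taxonomic rank: a rooted tree with one node per shared rank
prefix and one unit of branch length per rank step (kingdom ... species,
configurable).  All species in a genus are then equidistant, all genera in
a family equidistant, and so on.  Tip-to-tip distance is
`2 * (ranks below and including the first disagreement)`.  The relatedness
matrix is A_ij = depth(MRCA) / total depth — equivalently the shared prefix
length over the number of ranks — giving unit diagonal and entries in
[0, 1].  A is checked symmetric and positive semidefinite (eigenvalue
tolerance -1e-10); non-ultrametric trees are rejected.  Missing
intermediate ranks are filled with placeholders unique to the child clade,
which preserves ultrametricity without inventing shared ancestry.  Lineages
are supplied in the input table; no live taxonomy service is queried.

## Hierarchical model (`covgrad.hier_meta`)

    d_i ~ N(theta_i, v_i),   v_i known
    theta_i = x_i' beta + u_study(i) + w_trait:study(i) + p_species(i)
    u ~ N(0, sigma_u^2),  w ~ N(0, sigma_w^2),  p ~ MVN(0, sigma_p^2 A)

The fixed part is an intercept (random-effects-only model: the pooled
genetic effect) or an intercept plus treatment-coded categorical moderators
(metaregression over trait, gradient and taxonomic class).  Trait-in-study
intercepts absorb the correlation among the several treatments' d values
from one experiment — the G x E signature — while the phylogenetic term
shares strength among related species.  No observation-level residual is
added beyond v_i.

Priors: Normal(0, 5^2) on the intercept, Normal(0, 2^2) on metaregression
coefficients (tighter, to rein in variance with many sparse levels),
half-Student-t(3, 2.5) on every random-effect s.d.  All are configurable;
an improper flat intercept prior is supported for degenerate-limit checks.

Sampling is blocked Gibbs, made robust by three exact ingredients:

- **Huang–Wand augmentation.**  Each half-t scale is represented as
  sigma^2 | a ~ InvGamma(df/2, df/a), a ~ InvGamma(1/2, 1/scale^2), whose
  marginal is exactly half-t(df, scale) and whose conditionals are
  conjugate.
- **Collapsed scale updates.**  Each sigma is slice-sampled on the log
  scale against the marginal likelihood with its own effects integrated
  out (per-group precision-weighted means are sufficient).  For the nested
  study / trait-in-study pair both u and w are integrated jointly — the
  per-study covariance is rank-one, handled in closed form — which removes
  the sigma_u/sigma_w trade-off; for the phylogenetic scale the species
  covariance sigma^2 A + D is evaluated directly (<= a few dozen species).
  This eliminates the funnel that stalls centered Gibbs near sigma = 0.
- **Location interweaving.**  The likelihood only identifies the intercept
  plus each block's mean, so the split (mu, eff) -> (mu - delta,
  eff + delta) is resampled from its exact conditional each iteration,
  decorrelating the intercept from the random effects.

Records are sorted canonically before sampling, so results are bit-stable
under permutations of the input; chains use independent seed streams
spawned from (seed, chain).  Scales may be pinned via `fixed_sigma`
(pinning at 0 recovers the fixed-effect inverse-variance meta-analysis in
closed form, used as a correctness gate).  With zero records the sampler
draws from the priors, another exactness check.

The heterogeneity statistic tau is reported per draw as
sqrt(sigma_u^2 + sigma_w^2) — the combined non-phylogenetic random-effect
s.d. — and summarized alongside the separate components, since the
phylogenetic s.d. is reported on its own.  Summaries are posterior mean,
median and central 95% interval.  Estimated marginal means evaluate the
linear predictor over the full reference grid (equal weights over the
other moderators' levels, random effects at zero), which is invariant to
the treatment-coding reference level.  Convergence diagnostics are
rank-normalized split R-hat and bulk ESS (ArviZ); the pipeline treats
max R-hat > 1.05 as failure.

## Compensation (`covgrad.compensation`)

For countergradient experiments, d_comp is Hedges' d between the two polar
populations' home-environment cells, oriented so that positive means the
genetically larger population also expresses the larger phenotype at home.
Classification: over if d_comp > 0.5, perfect if |d_comp| <= 0.5, under if
d_comp < -0.5 — a deliberately conservative band of one medium effect size
around zero — with 0.2 as a stricter sensitivity band.  Summaries report
label proportions, the range and the 5%/95% quantiles (linear interpolation
of order statistics, the type-7 convention; no method is canonical here and
type 7 is the common software default).  No model is fitted: the shares are
descriptive.

## Synthetic data (`covgrad.synthetic_data`)

`simulate_experiment` draws one common-garden table from the additive
decomposition: cell mean mu0 + G_p + E_t + I_pt with I_pt ~ N(0,
sigma_gxe^2) and within-cell residual s.d. sigma_resid generating the n
replicates each cell summarizes.  The home-treatment map pairs populations
ranked by G with treatments ranked by E — reversed for countergradient
scenarios, so corr(G, E_home) < 0 — and `sampling_noise=False` reports
exact population summaries (mean, sigma_resid) for closed-form checks.
Four canonical noiseless parameterizations reproduce the four reaction-norm
patterns deterministically.  `true_polar_effect` = (G_max - G_min) /
sigma_resid is the expected per-treatment d (over interaction draws);
it is undefined at sigma_resid = 0.

`simulate_meta_dataset` draws whole meta-datasets from the hierarchical
truth over a balanced random taxonomy (species shuffled into genera,
genera into families, etc., with configurable fan-out).  The default
design — 40 studies x 2 traits with (2, 3) effect sizes per trait = 200
records, 25 species, truth (mu, sigma_study, sigma_trait:study,
sigma_phylo) = (1.0, 0.5, 0.8, 0.5), v_i ~ U(0.05, 0.3) — is the package's
standard recovery condition; the v range is typical of two-group
standardized mean differences with 10–40 replicates per group.

`simulate_observations_from_meta` realizes each trait-in-study as an
actual two-population experiment whose genetic offset equals that group's
latent mean theta, so the full extraction chain (ingest -> classification
-> polar d -> model) can be exercised end to end.  Environmental spans are
drawn proportional to |theta| (lognormal ratio), reflecting that the
environmental and genetic effects covary by definition and spreading
experiments across over-, perfect and under-compensation.  Because
extracted effects are reported with positive orientation, latent means
that cross zero would be folded upward; the end-to-end demonstration
scenario therefore uses moderate random-effect s.d.s (0.3/0.3/0.2), which
keep essentially all latent group means positive so the pooled estimate is
comparable to mu.  The direct recovery checks use the full-spread defaults,
where d values keep their signs.

What the generator does *not* emulate: digitization error from reading
values off published figures, unequal replication within an experiment,
non-normal trait distributions, correlated sampling error between the d
values of one experiment (they share the same two populations), or
selection acting through time.  Passing recovery tests therefore shows the
inference machinery is correct under the stated model, not that literature
data meet its assumptions.

## Pipeline (`covgrad.pipeline`) and problem sizes

Stages run in order: ingest (strict schema with itemized row errors) ->
classification and inclusion filtering (every exclusion logged with its
reason) -> effect sizes -> taxonomy/relatedness -> model fit -> summaries
and EMMs -> compensation for the countergradient subset.  Outputs use fixed
six-significant-digit float formatting and sorted JSON keys; the manifest
lists each artifact with its SHA-256, so identical (config, seed, inputs)
give bit-identical runs.

Default MCMC: 4 chains, half warmup, 2000 iterations.  The analysis
scripts and tests run at 40 studies / 200 records with 2–4 chains of
1200–3000 iterations, sizes at which the collapsed sampler converges well
(max split R-hat ~1.02) in seconds on one core; larger runs only change
the iteration counts.

## Known limitations

- The taxonomy tree uses equal unit branch lengths per rank; real
  divergence times are not represented, so A is a coarse relatedness
  proxy (any A differences propagate to the phylogenetic s.d.).
- The compensation shares are descriptive; no uncertainty is attached.
- Moderator levels observed in only one study are weakly identified and
  rely on the coefficient prior; EMMs inherit that width.
- The covariation sign is undefined when the polar homes coincide or show
  no environmental trend; such experiments must be resolved upstream.
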