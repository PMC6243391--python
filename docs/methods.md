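# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Data model

Trait observations are long-format rows (one per leaf × trait) carrying
taxonomy (order/family/genus/species), site, plot, block, treatment
(`wild`, `control`, `local_transplant`, `warmed`, `cooled`) and origin site.
Long format was chosen so leaves with partial trait panels (nutrients and
isotopes are measured on subsets) need no sentinel values. Trait names are
canonicalised to an 11-symbol vocabulary (LA cm², LT mm, LDMC g/g,
SLA cm²/g, C/N/P %, C:N and N:P unitless, δ13C and δ15N ‰); unit conversion
is the caller's responsibility.

**Cleaning.** Rows with LDMC > 1 g/g, SLA < 5 or > 500 cm²/g, or N > 6.4 %
are removed (bounds exclusive: boundary values are retained). Rules are
applied in the fixed order LDMC → SLA → N for attribution of removals; since
each rule targets a single trait and rows are leaf × trait, the order only
fixes bookkeeping, not the retained set. Cleaning operates on the original
measurement scale and precedes any transformation.

**Transformation.** The multiplicative growth traits LA, LT and LDMC are
analysed on the natural-log scale *in the variance partitioning only*.
Community distributions, the plasticity index and the convergence
classification use the cleaned original scale: community means in original
units are the quantity of ecological interest, and the plasticity index is
undefined wherever a transformed trait crosses zero (log-LDMC does).

**"Unmanipulated conditions"** means wild-collected leaves plus both control
plot types — locally transplanted and untouched controls behave
indistinguishably and are pooled throughout.

## Nested variance partitioning

Model: `y = μ + b_order + b_family + b_genus + b_species + b_population + ε`,
all effects independent zero-mean Gaussians, population = species × site
(site nested within species, not crossed). Taxonomy serves as a proxy
phylogeny; branch-length information is deliberately absent.

Two estimators:

* **REML** (default): a mixed linear model with the top non-degenerate level
  as grouping factor, a random intercept for it, and variance components for
  each deeper level (statsmodels `MixedLM`). Chosen as default because field
  data are strongly unbalanced (leaf counts differ by site; many species
  occur at a single site, confounding species and population — resolved by
  mixed-model shrinkage and documented as a caveat).
* **Method of moments**: nested sums of squares of group means are equated
  to their expectations. With `T_l = Σ_g (group total)²/n_g` at level *l*,
  `E[T_l − T_{l−1}]` is linear in the σ² with coefficients
  `c(l, m) = Σ_cells n_cell²/n_parent`, giving a triangular system solved by
  back-substitution. This estimator is exactly unbiased, works on unbalanced
  data, and coincides with REML on balanced designs when all estimates are
  interior — which is why it serves as the independent oracle in the tests.

Negative moment estimates are truncated to zero **before** normalisation;
proportions are components over their post-truncation sum. Degenerate levels
(a level whose cells do not subdivide the parent's cells, e.g. a single
realised order) are reported as proportion 0 with a warning flag rather than
an error.

Two estimation facts shape the tests. First, with only 4 realised orders the
order-level proportion has sampling SD ≈ 0.13 whatever the estimator — no
single dataset can pin it to ±0.07 — so parameter recovery is checked by
averaging estimated proportions over replicate simulations. Second, the
summed component estimates do not equal the total sample variance exactly
(no such identity exists for nested ANOVA estimators); they agree only
asymptotically, which is what the consistency test asserts on a large
design.

## Bootstrapped community trait distributions

Per site and trait, each of B = 1000 replicates resamples every covered
species' trait pool with replacement, takes per-species means, and combines
them with fixed weights proportional to site-pooled biomass (renormalised
over covered species). The replicate statistic is the mean only; the
summary is the mean of replicate means with a 95 % percentile interval
(linear-interpolation quantiles; level 0 collapses to the median). BCa
intervals were considered and rejected as over-engineering for a mean.

By default each pool is resampled at its own size, which makes the replicate
distribution the classic nonparametric bootstrap of the biomass-weighted
mean — its percentile interval is then asymptotically calibrated without
tuning. A fixed per-species resample size `n_draws` is available as a knob;
the replicate mean is invariant to it, the interval width is not, and the
choice is recorded in the output.

Trait pools fall through four rungs: focal species at the focal site, focal
genus at the focal site, focal species anywhere, focal genus anywhere.
Genus rungs are sampled congener-rarefied: a congener is drawn uniformly,
then a leaf uniformly within it, so a congener with one leaf counts as much
as one with a hundred. Rarefaction applies only to genus rungs; the
species-anywhere rung pools sites directly. Species with no pool at all are
excluded and reported via the coverage fraction (covered biomass / total
biomass) rather than silently dropped. Weights are relative, so scaling all
biomass by a constant changes nothing. An unweighted (equal-weight) mode is
provided for sensitivity analyses.

**Calibration check.** The coverage test simulates 200 datasets (16 species,
one site, 10 leaves per species, Dirichlet(1) biomass) and asserts the 95 %
interval contains the true biomass-weighted community mean in 90–99 % of
them; measured rates sit near 92–95 %. Slight undercoverage is expected —
percentile intervals are first-order, and 10-leaf pools are small.

## Relative plasticity

Leaves are first averaged to plot-level species means. For each transplanted
turf and species, `H` is the mean of the origin block's control-plot means
(both control types pooled), `T` the transplanted turf's mean, and
`P_R = ||H − T|/H|`. The inner absolute value standardises the direction of
the shift, the outer one handles negative-valued traits (δ13C). `P_R` is
invariant to positive rescaling (unit changes) but intrinsically **not** to
additive shifts — both properties are asserted as tests. `H = 0` yields an
undefined-flagged record, excluded from tests. For display, `log(P_R)` drops
exact zeros with a reported count.

Whether traits respond more to cooling than warming is tested per trait by a
permutation test: the statistic is `mean(P_R | cooling) − mean(P_R |
warming)`; treatment labels are permuted within species × origin-site strata
(the grouping a mixed model would absorb as random effects), and
`p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)`. This replaces mixed-model
t-tests with Satterthwaite degrees of freedom: the permutation null is the
same scientific null, assumption-free and exactly specifiable; the
substitution is recorded in the run manifest. Under exchangeable arms the
p-values are uniform (asserted by a KS test across replicate datasets).

## Convergence classification and G-tests

For each species × site × trait under unmanipulated conditions, the home
summary is the sample mean, SD (n−1), and the exact central 99 %
t-interval `mean ± t(0.995, n−1)·sd/√n` (computed quantile, never
table-interpolated; n ≥ 2 required, leaf-level n). A transplanted mean
inside the interval is `no_change`; outside it, it is `converging` if
strictly closer to the destination community mean than the home mean was,
else `diverging` (ties → diverging). The start group is `destination` if the
home mean is strictly closer to the destination community mean than to the
home community mean (ties → home). Both tie rules are measure-zero under
continuous data. Community means are the bootstrapped biomass-weighted means
above (the only defined community mean in this analysis); "prior to
transplantation" is operationalised as the home mean, since pre-transplant
measurements do not exist in this design.

Outcomes are tabulated 3 × 2 (converging/diverging/no_change × start group,
and × warming/cooling) — keeping `no_change` as a row gives df = 2 — and
tested with `G = 2 Σ O ln(O/E)` (0·ln 0 = 0) against the upper chi-square
tail. All-zero rows/columns are dropped with df adjusted; a 1 × k table is
an error. G scales linearly with counts (`G(kO) = kG(O)`, asserted) and
approaches the Pearson χ² when all expected counts are large (asserted at
1 % for E ≥ 100).

**A caveat intrinsic to the classification.** The home mean `H` enters both
the start-group rule and the outcome rule, and the comparison of distances
regresses toward the destination mean: whenever home and destination
community means differ — even by compositional sampling noise alone —
populations starting far from the destination overshoot less often and are
labelled `converging` more often, so outcome × start group shows real
dependence even with zero plasticity. In simulations with heterogeneous
communities (occupancy 0.8, Dirichlet(1) biomass) the nominal-5 % G-test
rejected in 16–26 % of null replicates. The type-I experiment therefore uses
the configuration under which "no dependence beyond chance" is actually
attainable: statistically homogeneous communities (full occupancy, near-even
biomass, no gradient trend), where the measured rate is ~10 %. The power
experiment adds a directional community trend of 1 SD per site step —
without between-site community differences the start group carries no
signal — plus distance-dependent plasticity (π = 0.8 beyond 1 community SD,
0 otherwise); detection at p < 0.01 is essentially certain. Users applying
the classification to real data should read small outcome × start-group
effects with this artifact in mind.

## Synthetic-data generator

The generator is first-class, tested code and defines the conditions under
which every downstream stage is verified.

* **Taxonomy**: balanced tree (default 4 orders × 3 families × 3 genera ×
  3 species = 108 species, the order of magnitude of a real gradient
  campaign).
* **Traits**: leaf value = grand mean + nested Gaussian effects + noise on
  the analysis scale (log scale for LA/LT/LDMC, then exponentiated).
  Default variance proportions (order .1, family .1, genus .2, species .3,
  population .1, within .2) put ~40 % of variance at or below the population
  level. Per-trait grand means and total SDs are realistic alpine-grassland
  values (SLA 150 ± 40 cm²/g, LDMC ≈ 0.25 g/g, N 2.5 ± 0.8 %, …), so default
  data pass the cleaning thresholds almost untouched. An optional
  directional trend (`site_trend`, in total-SD units per site step) shifts
  population means along the gradient.
* **Sites and occupancy**: 4 sites ordered by elevation (S1 lowest/warmest,
  ~1.5 °C per step); each species occurs at each site with probability 0.8,
  giving the pool hierarchy real work.
* **Communities**: per site, biomass shares from a symmetric Dirichlet
  (α = 1, moderately uneven) scaled to a fixed plot total; the same
  occupancy stream as the trait generator keeps the two consistent.
* **Experiment**: per origin site, 7 blocks (the replicate count of the
  motivating field design), each with a control and a local-transplant plot
  at the origin plus a turf moved one site down (warmed) and one up
  (cooled); the 10 most abundant origin species are sampled with 5 leaves
  per species per plot. Control and local-transplant plots are
  distributionally identical, encoding the empirical finding that
  transplantation itself leaves traits unchanged.
* **Plasticity**: transplanted leaf expectation is
  `(1 − π)·μ_origin + π·(destination community mean)`, with π chosen by the
  start-distance class — `far` if |μ_origin − destination mean| exceeds one
  community SD (biomass-weighted leaf-level SD), else `near`. Defaults
  (π_near = 0, π_far = 0.8) encode convergence of populations that start far
  away; π < 0 models divergence. Linear interpolation is the simplest
  mechanism able to produce both convergence and divergence.
* **Determinism**: every output is a pure function of (config, seed);
  named sub-streams (occupancy, community, per-trait effects, experiment)
  are spawned from the seed so partial regeneration is stable.

What the generator does **not** emulate: spatial autocorrelation, temporal
dynamics, survival/mortality of transplants, non-Gaussian trait
distributions, covariance between traits, and real taxonomic imbalance.
Passing tests therefore demonstrate correctness of the estimators and the
pipeline under the stated model, not robustness to every property of field
data.

## Pipeline, sizes and numerical choices

Stages run clean → variance partition → community bootstrap → plasticity →
convergence; any failure aborts with a stage-named error; outputs are CSVs
written atomically plus a JSON manifest (config hash, seeds, row counts,
stage timings). All randomness flows from two seeds — simulation and
inference — and reruns reproduce numerically identical files (asserted).
Exit codes: 0 success, 2 configuration error, 3 data error.

Default problem sizes in tests and the acceptance script (64 replicate
simulations for recovery, 8-order design for estimator agreement, 200
datasets for coverage, 50 replicate pipelines per arm for power/type-I,
B = 1000 with 300 for the replicate-pipeline experiments) were chosen so
Monte-Carlo error is small relative to the asserted tolerances while the
whole suite runs in a few minutes on one CPU.

Open choices resolved here: cleaning precedes any pooling and is per-row, so
pooling order is irrelevant; the bootstrap weights by site-pooled (not
per-plot) biomass; congener rarefaction applies only to genus rungs; home
CIs use leaf-level n; both G-tests use the 3 × 2 form; the year of
collection does not enter the variance decomposition.

## Known limitations

* The moments estimator can truncate at zero on small top-level designs,
  after which REML and moments redistribute variance differently; agreement
  is guaranteed only for interior solutions on balanced data.
* Percentile intervals from 5-leaf pools undercover; the calibration check
  uses 10–20 leaves per species.
* The convergence classification's regression-to-the-mean artifact (above)
  is a property of the published procedure, faithfully reproduced, not
  removed.
* P_R is undefined for H = 0 and unstable for |H| near zero; traits whose
  values cross zero (δ15N, log-scale traits) should be interpreted with
  care. P_R is computed on the original measurement scale for this reason.
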