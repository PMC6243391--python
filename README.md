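# turftraits

Analysis pipeline for leaf functional-trait variation in reciprocal
turf-transplant experiments along elevation gradients.

Alpine plant communities experience roughly a 1.5 °C change in mean annual
temperature per step along such gradients, and whole-community turf
transplants (moving intact soil+vegetation blocks down- or up-slope) impose
warming or cooling on entire communities at once. Three questions drive the
analysis this package implements:

1. **How is trait variation structured?** How much leaf-trait variance sits
   within species and populations versus between species, genera, families
   and orders?
2. **How do community trait distributions change along the gradient?**
3. **When plants are transplanted, do their traits converge toward the trait
   mean of their destination community, or diverge from it?**

The package is written for ecologists who have (or want to simulate)
leaf-level trait tables, community biomass tables and a transplant design,
and want the full chain from raw measurements to inference, reproducibly and
with every stage testable against known ground truth.

## Methods implemented

* **Trait cleaning** — removal of physically impossible values
  (LDMC > 1 g/g, SLA outside 5–500 cm²/g, leaf N > 6.4 %), with per-rule
  accounting; natural-log transform of the multiplicative growth traits
  (LA, LT, LDMC) for the variance analysis.
* **Nested variance partitioning** — the random-effects decomposition
  `y = μ + b_order + b_family + b_genus + b_species + b_population + ε`
  (population = species × site, taxonomy standing in for phylogeny),
  estimated by REML (default) or by a nested method-of-moments ANOVA that
  doubles as an independent cross-check.
* **Bootstrapped community trait distributions** — per site, each of B
  replicates resamples every species' trait pool with replacement and takes
  the biomass-weighted mean of species means; missing species fall back
  through a four-rung pool hierarchy (species@site → genus@site →
  species@anywhere → genus@anywhere) with congener-rarefied sampling at the
  genus rungs; summaries are the replicate mean and a 95 % percentile
  interval.
* **Relative plasticity index** — for each species × trait × transplanted
  turf, `P_R = ||H − T| / H|` where `H` is the species' mean in the origin
  block's control plots and `T` its mean in the transplanted turf
  (a simplified Relative Distance Plasticity Index); warming-vs-cooling
  differences are tested per trait with permutation tests stratified by
  species × origin site.
* **Convergence classification and G-tests** — a transplanted mean outside
  the 99 % t-interval of its home population is a significant plastic
  response, classified *converging* or *diverging* by its distance to the
  destination community mean relative to where it started; 3 × 2 contingency
  tables (outcome × start group, outcome × warming/cooling) are tested with
  log-likelihood-ratio G-tests, `G = 2 Σ O ln(O/E)`, df = 2.
* **Synthetic data** — a generator for gradient + transplant datasets with
  configurable variance components, community structure, directional trends
  and distance-dependent plasticity, recording exact ground truth for every
  downstream stage.

## Worked example

```python
from turftraits import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    simulate=SimulationConfig(
        n_orders=3, families_per_order=2, genera_per_family=2,
        species_per_genus=3, n_sites=4, n_blocks=7,
        site_trend=0.8, plasticity_pi={"near": 0.0, "far": 0.8},
        traits=("SLA", "LDMC", "N"), seed=42,
    ),
    bootstrap_B=1000, n_perm=999, inference_seed=7, outdir="results_demo",
)
bundle = run_pipeline(config)
```

The simulated gradient has a directional SLA trend of 0.8 SD per site step,
and transplanted populations starting more than one community SD from their
destination community mean converge 80 % of the way toward it (`pi` = 0.8),
while populations starting nearby do not respond (`pi` = 0).

Bootstrapped community SLA means climb the gradient, with tight 95 %
intervals (site S1 is the lowest / warmest):

```
site  mean  ci_low  ci_high
  S1 161.1   159.4    162.9
  S2 193.3   191.6    194.9
  S3 218.9   217.6    220.3
  S4 248.8   247.2    250.4
```

The variance partition reflects the same structure: the directional trend
loads onto the population (species × site) level, which absorbs 78 % of SLA
variance in this configuration.

Classifying every transplanted species × trait observation and testing
outcome against where each population started gives

```
outcome            table            G  df        p
converging  700    start_group  372.9   2 1.08e-81
no_change   351    treatment    1.291   2   0.5243
diverging   209
```

— transplants overwhelmingly converge toward their destination community
mean when they start far from it, convergence does not depend on whether the
turf was warmed or cooled, and populations starting near the destination
mean mostly show no significant response. That is exactly the behaviour the
generator encodes, recovered end-to-end through cleaning, bootstrapping,
classification and inference.

The same stages are available from the shell:

```bash
turftraits simulate --seed 1 --out data/
turftraits run-all --config config.yaml
```

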