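# seedset

Statistical analysis of three-treatment hand-pollination experiments that
separate **pollen limitation** from **self-compatibility** and **inbreeding
depression** — using both seed production and seed germination as response
variables.

## The problem

In a standard mating-system experiment, each plant carries three treated
inflorescences:

* **open** — naturally pollinated, untouched;
* **outcrossed** — supplemented by hand with pollen from distant conspecifics;
* **autonomous** — bagged before stigma receptivity so only self pollen can
  arrive.

Counting only the seeds each inflorescence *produces* can mislead: a plant
may set plenty of selfed seed whose embryos are inviable. Post-zygotic
inbreeding depression then only shows up in *germination*. `seedset`
implements the full inferential workflow for such experiments, aimed at
pollination ecologists and restoration practitioners working with
wind-pollinated grasses and similar systems:

1. **Exclusion rule** — a plant enters the analysis only with a complete
   undamaged treatment triple (damaged or incomplete plants are dropped
   whole, and reported).
2. **Nonparametric bootstrap** — percentile 95% CIs for all pairwise
   site × treatment differences in group means, with the plant as the unit
   of replication. An interval containing zero ⇒ no significant difference.
3. **Per-plant indices** —
   * *index of plant fitness* `autonomous / outcrossed` (≈1 on seeds
     produced ⇒ selfing sets seed; ≈0 on germination ⇒ selfed seeds fail);
   * *pollen-limitation index*, default metric
     `1 − ln(open+1) / ln(outcrossed+1)` (0 = no limitation; CI excluding
     zero = evidence of limitation). Alternative metrics
     (`log_ratio`, `log_diff`) are available and always recorded in output.
4. **Regression models** — Poisson GLM as an overdispersion diagnostic,
   negative binomial GLM (log link, variance `μ + μ²/θ`, joint ML over
   coefficients and θ) for seed counts, and a binomial GLMM with a plant
   random intercept (Laplace or adaptive Gauss–Hermite marginal likelihood)
   for germination, with Tukey-adjusted pairwise treatment contrasts on the
   linear-predictor scale.
5. **Synthetic-data generator** — a calibrated simulator of the whole
   experiment (2 sites × 20 plants × 3 inflorescences, overdispersed counts,
   near-zero selfed germination, plant heterogeneity, occasional damage) so
   every stage is testable without field data.

## Worked example

```python
from seedset import (BootstrapSpec, default_config, exclude_damaged_plants,
                     fit_binomial_glmm, generate_experiment, tukey_contrasts)
from seedset.indices import summarize_all_indices
from seedset.regression import contrast_table

retained, _ = exclude_damaged_plants(generate_experiment(default_config(rng_seed=42)))
print(summarize_all_indices(retained, BootstrapSpec(10_000, 0.95, 11)).round(3))
print(contrast_table(tukey_contrasts(fit_binomial_glmm(retained))).round(4))
```

prints (abridged):

```
     site    measure        index_name  ...  estimate  ci_low  ci_high  evidence
   annual   produced           fitness  ...     1.199   0.886    1.542      True
triennial   produced           fitness  ...     1.888   1.250    2.745      True
   annual germinated           fitness  ...     0.000   0.000    0.000     False
triennial germinated           fitness  ...     0.044   0.000    0.119     False

   level_a    level_b  estimate     se       z  p_unadjusted  p_tukey
autonomous       open   -4.5549 0.7157 -6.3647        0.0000   0.0000
autonomous outcrossed   -4.6210 0.7163 -6.4513        0.0000   0.0000
      open outcrossed   -0.0661 0.1389 -0.4758        0.6342   0.8827
```

Read: on seeds *produced* the fitness index excludes zero at both sites
(bagged inflorescences set about as much seed as supplemented ones — the
plants can self-fertilize), but on seeds *germinated* it is pinned near zero
(selfed seeds are not viable). The GLMM agrees: autonomous germination sits
~4.6 log odds below the other treatments (Tukey-adjusted p < 0.0001), while
open vs outcrossed is indistinguishable — severe embryonic inbreeding
depression with no pollen limitation.

The `examples/` directory holds one short narrative script per capability
(`01` simulation, `02` bootstrap comparisons, `03` indices, `04` regression
models, `05` the full pipeline), and the same workflow is scriptable from a
shell:

```bash
seedset simulate --out exp.csv --seed 42
seedset analyze --in exp.csv --out-dir report/
seedset report --in-dir report/ --format json
```

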