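# Methods

## Experimental structure assumed

One record per treated inflorescence: plant, site (`annual` / `triennial`
burn regime), treatment (`open`, `outcrossed`, `autonomous`), seeds
produced, seeds germinated, damage flag. Each plant carries exactly one
inflorescence per treatment, so plant and inflorescence-within-treatment
coincide as the replication unit. Plants lacking a complete undamaged
triple are excluded whole: a damaged inflorescence makes the zero it might
have produced uninterpretable, and requiring full triples keeps the
per-plant indices well-defined. Exclusion is idempotent and the retained
row count is always three per retained plant.

## Synthetic-data generator

The generator emulates the experiment the analysis was built for, not a
generic data set:

* **Design.** 2 sites × 20 plants × 3 inflorescences by default.
* **Seed counts.** Negative binomial with per-cell means fixed at the six
  observed group means (annual: 30.7 / 32.1 / 30.2; triennial: 31.0 / 43.3 /
  44.2 for outcrossed / autonomous / open) and a common dispersion
  θ = 4.0 (variance μ + μ²/θ). The per-cell θ implied by the observed
  mean–SD pairs spans ≈2.5–6.4; 4.0 is a single frozen compromise that
  reproduces SDs of roughly 10–21 seeds and guarantees variance > mean in
  every cell.
* **Germination.** Binomial per inflorescence given its seed count, with
  log-odds = intercept −3.4 (annual, open) + treatment effect (open 0,
  outcrossed 0, autonomous −4.5) + site effect (+1.5 for triennial) + a
  per-plant N(0, 0.7²) random intercept. These values imply ≈3% germination
  for open/outcrossed at the annual site, ≈14% at the triennial site, and
  < 0.2% for autonomous selfing everywhere — the near-zero selfed-viability
  regime the analysis is designed to detect. The site effect exists in the
  generator even though the default downstream GLMM is treatment-only: the
  generator must be able to produce site differences; the analysis decides
  what to model.
* **Damage.** Independent per inflorescence with probability 0.025, giving
  ≈1.5 excluded plants per site in expectation (matching the one-and-two
  excluded plants of the motivating design).
* **Reproducibility.** One seed, split into fixed substreams (random
  intercepts → counts → germination → damage); identical configurations
  give byte-identical tables.

What it does **not** emulate: time-resolved germination (final counts
only), granivory or its bagging countermeasures, fungal infection, spatial
arrangement, or genet structure. Passing tests therefore demonstrate that
the *statistical machinery* behaves correctly under the assumed generative
model, not that the model captures every feature of field data.

## Bootstrap inference

Percentile method throughout: resample with replacement at the original
size, take the (α/2, 1−α/2) quantiles of the replicate statistics (linear
interpolation between order statistics; the rule is recorded in every
result). Pairwise mean differences resample each group independently —
groups are not paired within plants, matching a comparison of group means
(a plant-paired variant would estimate a different, within-plant quantity).
Default 10 000 replicates; below 1 000 a warning is raised. The decision
rule is deliberately simple and uniform: a 95% interval containing zero ⇒
no significant difference / no evidence. BCa or studentized intervals are
out of scope; the percentile interval at n ≈ 19 runs mildly anticonservative
(measured type-I ≈ 7% against a nominal 5%), which the calibration tests
treat as part of the method rather than a defect to hide.

## Indices

Both indices are computed per plant and bootstrapped within site.

* **Fitness index** `autonomous / outcrossed`: a plain ratio, no offset.
  Undefined when the outcrossed value is 0; such plants are excluded from
  that summary and counted, never silently dropped.
* **Pollen limitation**: from `L_o = ln(open+1)`, `L_x = ln(outcrossed+1)`
  the default metric is `1 − L_o/L_x`. The defining expression for this
  index admits several typographic readings (ratio, difference, one minus
  ratio); only `1 − L_o/L_x` is zero when open equals outcrossed, which is
  what testing the index *against zero* requires. The bare ratio and the
  log difference are selectable alternatives, and every output records the
  metric used; it must never be changed silently.

A caveat the test suite surfaces: for a measure with counts near zero
(germination of ~1 seed per inflorescence), conditioning on a nonzero
outcrossed count biases the default pollen-limitation metric upward, and
its CI can exclude zero without any true limitation. With the calibrated
generator this occurs in most runs at the annual site; it is a property of
the index definition at near-zero counts, not of the implementation.
Interpret the germination-based pollen-limitation index with caution when
counts are this sparse.

## Regression models

All fixed-effect structures are treatment-only with dummy coding and the
alphabetical reference level (`autonomous`); site can be examined through
the bootstrap stage, and the contrasts are reported for all pairs so the
reference choice is cosmetic.

* **Poisson GLM** (log link), fitted by IRLS, is a diagnostic: residual
  deviance `2 Σ[y ln(y/μ̂) − (y − μ̂)]` (zero-count terms set to 0) far above
  the residual df indicates overdispersion.
* **Negative binomial GLM** (NB2): alternate IRLS for β (working weights
  μ/(1+μ/θ)) with bounded 1-D ML for θ until the log-likelihood changes by
  < 1e-8 (cap 100 cycles; IRLS parameter tolerance 1e-6, cap 200). Standard
  errors come from the observed information of the joint (β, log θ)
  likelihood by central differences, so β SEs account for θ estimation.
  If the 1-D search runs into its upper bound region (θ > 1e5) the data are
  not overdispersed; the fit is reported as the Poisson solution with
  θ = 1e6 and an explicit equivalence warning.
* **Binomial GLMM** with plant random intercept: marginal likelihood per
  plant integrates the intercept out; the integral is evaluated by Laplace
  (default) or adaptive Gauss–Hermite quadrature (nodes centred at each
  plant's conditional mode, scaled by the curvature there; 15 nodes by
  default, log-sum-exp for stability). Conditional modes come from a damped
  Newton iteration vectorised over plants. The likelihood is maximised over
  (β, log σ) by Nelder–Mead followed by a BFGS polish; σ below 1e-6
  degenerates exactly to the pooled binomial likelihood. Plants whose
  trials are all zero carry no information and are dropped with a warning.
  Complete separation (a treatment with no successes anywhere — exactly
  what near-zero selfed germination produces in many synthetic runs) has no
  finite MLE; fits with any |β| > 15 are returned flagged rather than
  rejected, and downstream outputs carry the flag.
* **Tukey contrasts**: estimates and SEs from the coefficient covariance;
  `p_tukey = P(Q_k > |z|·√2)` with the studentized-range law at infinite
  df (the asymptotic z-based convention for GLM/GLMM marginal means), k = 3
  treatment groups; unadjusted p from the standard normal. The studentized
  range is evaluated by `scipy.stats.studentized_range`; the test suite
  verifies it against direct numeric integration of the range distribution.

## Pipeline

A single master seed fans out via fixed `SeedSequence` spawning into
per-stage seeds (bootstrap on each measure, indices), all recorded in the
report, so every random result is reproducible in isolation. Stage failures
(e.g. a non-converging model) are reported as warnings without aborting the
other stages; validation failures stop the run. Reports serialize to CSV
tables plus one consolidated JSON; figures are deliberately out of scope —
tables are the canonical output.

## Problem sizes used in the checks

Distributional checks use what each needs for stable Monte-Carlo error:
cell-mean calibration at 8 000 plants/site (the 2% band is then several MC
SEs wide at θ = 4), bootstrap coverage at 500 simulations × 1 000
replicates, type-I calibration at 500 simulations, negative-binomial
recovery at n = 2 000 per treatment, GLMM contrast recovery over 50
simulated experiments of 40 plants. The end-to-end qualitative check runs
one default-sized experiment (40 plants) with 10 000 bootstrap replicates.

## Known limitations

* The percentile bootstrap is mildly anticonservative at these sample
  sizes (see above); no BCa correction is provided.
* The GLMM offers a single scalar random intercept; no observation-level
  random effects, no site×treatment interactions, no zero-inflation.
* Laplace underestimates the marginal likelihood slightly for small
  binomial denominators; AGQ is provided for verification and agrees with
  brute-force quadrature to 1e-6 on toy problems.
* The pollen-limitation index is unstable for near-zero count measures
  (see Indices above).
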