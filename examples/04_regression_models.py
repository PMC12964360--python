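"""Count GLMs and the germination GLMM with Tukey-adjusted contrasts.

The Poisson fit is a lack-of-fit diagnostic: residual deviance far above
the residual degrees of freedom reveals overdispersion, motivating the
negative binomial GLM. Germination is modelled as binomial counts per
inflorescence with a plant-level random intercept.
"""

from seedset import (
    default_config,
    exclude_damaged_plants,
    fit_binomial_glmm,
    fit_negbin_glm,
    fit_poisson_glm,
    generate_experiment,
    tukey_contrasts,
)
from seedset.regression import contrast_table

retained, _ = exclude_damaged_plants(generate_experiment(default_config(rng_seed=42)))

po = fit_poisson_glm(retained)
print(f"Poisson: residual deviance {po.residual_deviance:.1f} on {po.residual_df} df"
      " -> strongly overdispersed (a well-fitting Poisson would be ~1 per df)")

nb = fit_negbin_glm(retained)
print(f"Negative binomial: theta = {nb.theta:.2f}, logLik = {nb.log_likelihood:.1f}")
print(contrast_table(tukey_contrasts(nb)).round(4).to_string(index=False))
print("-> seed-production contrasts are small on the log scale; any "
      "open-vs-outcrossed signal traces to the larger triennial open mean, "
      "since this model pools sites\n")

glmm = fit_binomial_glmm(retained)
print(f"Binomial GLMM ({glmm.method}): plant intercept SD = {glmm.re_sd:.2f}")
print(contrast_table(tukey_contrasts(glmm)).round(4).to_string(index=False))
# The autonomous treatment sits several log odds below open and outcrossed
# (selfed seeds barely germinate); open vs outcrossed is near zero.
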