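"""Synthetic experiment tables with the structure the analysis assumes.

Each plant carries exactly three treated inflorescences (open, outcrossed,
autonomous). Seeds produced are negative-binomial with a configured
(site, treatment) mean and common dispersion theta; seeds germinated are
binomial given seeds produced, with success log-odds
``intercept + treatment effect + site effect + plant random intercept``.
Damage strikes inflorescences independently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SITES, TREATMENTS, SimulationConfig

#: CSV column order shared with :mod:`seedset.io`.
COLUMNS = [
    "plant_id",
    "site",
    "treatment",
    "seeds_produced",
    "seeds_germinated",
    "damaged",
]


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_experiment(config: SimulationConfig) -> pd.DataFrame:
    """Generate one experiment table from ``config``.

    Returns a DataFrame with one row per treated inflorescence and columns
    ``plant_id, site, treatment, seeds_produced, seeds_germinated, damaged``.
    Identical configs (including ``rng_seed``) give identical tables.

    The random stream is split into fixed substreams drawn in the order
    plant random intercepts -> counts -> germination -> damage, so growing
    the design never perturbs earlier draws within a substream.
    """
    config.validate()

    n = config.n_plants_per_site
    # substreams in fixed order: intercepts, counts, germination, damage
    ss = np.random.SeedSequence(config.rng_seed).spawn(4)
    rng_re, rng_cnt, rng_germ, rng_dmg = (np.random.default_rng(s) for s in ss)

    prefix = {"annual": "A", "triennial": "T"}
    rows_site, rows_plant, rows_treat = [], [], []
    for site in SITES:
        for i in range(n):
            pid = f"{prefix[site]}{i + 1:03d}"
            for treatment in TREATMENTS:
                rows_site.append(site)
                rows_plant.append(pid)
                rows_treat.append(treatment)

    site_arr = np.array(rows_site)
    treat_arr = np.array(rows_treat)
    plant_arr = np.array(rows_plant)

    # one random intercept per plant, in plant order
    plant_ids = [f"{prefix[s]}{i + 1:03d}" for s in SITES for i in range(n)]
    b = rng_re.normal(0.0, config.plant_re_sd, size=len(plant_ids))
    b_of = dict(zip(plant_ids, b))

    theta = config.seed_count_dispersion
    mu = np.array(
        [config.seed_count_mean[(s, t)] for s, t in zip(rows_site, rows_treat)]
    )
    # NB(mu, theta): numpy parameterization n=theta, p=theta/(theta+mu)
    produced = rng_cnt.negative_binomial(theta, theta / (theta + mu))

    eta = (
        config.germ_logit_intercept
        + np.array([config.germ_logit_treatment_effects[t] for t in rows_treat])
        + np.where(site_arr == "triennial", config.germ_logit_site_effect, 0.0)
        + np.array([b_of[p] for p in rows_plant])
    )
    germinated = rng_germ.binomial(produced, _expit(eta))

    damaged = rng_dmg.random(len(rows_plant)) < config.damage_prob

    return pd.DataFrame(
        {
            "plant_id": plant_arr,
            "site": site_arr,
            "treatment": treat_arr,
            "seeds_produced": produced.astype(int),
            "seeds_germinated": germinated.astype(int),
            "damaged": damaged.astype(int),
        },
        columns=COLUMNS,
    )
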