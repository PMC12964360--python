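"""Per-plant mating-system indices and their site-level bootstrap summaries.

Two statistics are computed from each plant's treatment triple, for either
measurement type (seeds produced or seeds germinated):

* the **index of plant fitness** — the plain ratio of the bagged
  (autonomous) value to the outcross-supplemented value; values near zero
  indicate that selfing fails for that measure;
* the **pollen-limitation index** — built from ``L_o = ln(open + 1)`` and
  ``L_x = ln(outcrossed + 1)``. The default metric is ``1 - L_o / L_x``,
  which is zero when natural pollination matches supplementation, positive
  under limitation, and at most 1 (attained only when the open count is
  zero). The bare ratio ``L_o / L_x`` and the difference ``L_x - L_o`` are
  available as alternative metrics; the metric used is recorded in all
  outputs and must not be changed silently.

Evidence at the site level uses the same rule as the pairwise comparisons:
a 95% bootstrap interval over the defined per-plant values that excludes
zero is evidence of the phenomenon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import BootstrapResult, BootstrapSpec, bootstrap_plant_statistic

PL_METRICS = ("one_minus_log_ratio", "log_ratio", "log_diff")
DEFAULT_PL_METRIC = "one_minus_log_ratio"


@dataclass
class IndexSummary:
    """Site-level bootstrap summary of one per-plant index."""

    site: str
    measure: str
    index_name: str  # "fitness" or "pollen_limitation"
    metric: str  # pollen-limitation metric, or "ratio" for fitness
    n_plants_used: int
    n_plants_undefined: int
    boot: BootstrapResult

    @property
    def evidence(self) -> bool:
        """True iff the CI excludes zero."""
        return not self.boot.contains_zero


def fitness_index(autonomous_value: float, outcrossed_value: float) -> float:
    """Ratio of the bagged to the outcross-supplemented value.

    Returns NaN (undefined) when the outcrossed value is zero; such plants
    are excluded from site summaries and counted as undefined.
    """
    if outcrossed_value == 0:
        return math.nan
    return autonomous_value / outcrossed_value


def pollen_limitation_index(
    open_value: float, outcrossed_value: float, metric: str = DEFAULT_PL_METRIC
) -> float:
    """Pollen-limitation index from one plant's open and outcrossed counts.

    With ``L_o = ln(open + 1)`` and ``L_x = ln(outcrossed + 1)``:
    ``one_minus_log_ratio`` (default) is ``1 - L_o / L_x``; ``log_ratio``
    is ``L_o / L_x``; ``log_diff`` is ``L_x - L_o``. The ratio metrics are
    undefined (NaN) when the outcrossed count is zero.
    """
    if metric not in PL_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {PL_METRICS}")
    lo = math.log(open_value + 1.0)
    lx = math.log(outcrossed_value + 1.0)
    if metric == "log_diff":
        return lx - lo
    if lx == 0.0:
        return math.nan
    return lo / lx if metric == "log_ratio" else 1.0 - lo / lx


def plant_triplets(records: pd.DataFrame, measure: str = "produced") -> pd.DataFrame:
    """Pivot retained records into one row per plant with the three
    per-treatment values of the chosen measure."""
    col = {"produced": "seeds_produced", "germinated": "seeds_germinated"}.get(measure)
    if col is None:
        raise ValueError(f"measure must be 'produced' or 'germinated', got {measure!r}")
    wide = records.pivot_table(
        index=["plant_id", "site"], columns="treatment", values=col, aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    missing = wide[["open", "outcrossed", "autonomous"]].isna().any(axis=1)
    if missing.any():
        bad = wide.loc[missing, "plant_id"].iloc[0]
        raise ValueError(
            f"plant {bad!r} lacks a complete treatment triple; run "
            "exclude_damaged_plants first"
        )
    wide["measure"] = measure
    return wide[["plant_id", "site", "measure", "open", "outcrossed", "autonomous"]]


def per_plant_indices(
    records: pd.DataFrame,
    measure: str = "produced",
    metric: str = DEFAULT_PL_METRIC,
) -> pd.DataFrame:
    """Both indices for every retained plant, with a ``defined`` flag.

    Returns a long table (plant_id, site, measure, index_name, metric,
    value, defined); undefined plants are kept as rows, never dropped.
    """
    trip = plant_triplets(records, measure)
    rows = []
    for r in trip.itertuples(index=False):
        fit = fitness_index(r.autonomous, r.outcrossed)
        pl = pollen_limitation_index(r.open, r.outcrossed, metric)
        rows.append((r.plant_id, r.site, measure, "fitness", "ratio", fit))
        rows.append((r.plant_id, r.site, measure, "pollen_limitation", metric, pl))
    out = pd.DataFrame(
        rows, columns=["plant_id", "site", "measure", "index_name", "metric", "value"]
    )
    out["defined"] = ~out["value"].isna()
    return out


def site_index_summary(
    per_plant: pd.DataFrame,
    site: str,
    index_name: str,
    spec: BootstrapSpec,
) -> IndexSummary:
    """Bootstrap one index over a site's defined per-plant values.

    Requires at least two defined values; undefined plants are counted in
    ``n_plants_undefined``.
    """
    sub = per_plant[(per_plant["site"] == site) & (per_plant["index_name"] == index_name)]
    defined = sub[sub["defined"]]
    if len(defined) < 2:
        raise ValueError(
            f"site {site!r}, index {index_name!r}: need >= 2 defined per-plant "
            f"values, have {len(defined)}"
        )
    boot = bootstrap_plant_statistic(defined["value"].to_numpy(), spec)
    return IndexSummary(
        site=site,
        measure=str(sub["measure"].iloc[0]),
        index_name=index_name,
        metric=str(sub["metric"].iloc[0]),
        n_plants_used=int(len(defined)),
        n_plants_undefined=int(len(sub) - len(defined)),
        boot=boot,
    )


def summarize_all_indices(
    records: pd.DataFrame,
    spec: BootstrapSpec,
    metric: str = DEFAULT_PL_METRIC,
) -> pd.DataFrame:
    """Index summaries for every site x measure x index combination.

    Per-summary seeds are derived from ``spec.rng_seed`` in a fixed order so
    individual summaries can be reproduced in isolation.
    """
    sites = sorted(records["site"].unique())
    combos = [
        (site, measure, index_name)
        for measure in ("produced", "germinated")
        for index_name in ("fitness", "pollen_limitation")
        for site in sites
    ]
    streams = np.random.SeedSequence(spec.rng_seed).spawn(len(combos))
    rows = []
    for (site, measure, index_name), ss in zip(combos, streams):
        seed = int(ss.generate_state(1)[0] % 2**31)
        sub_spec = BootstrapSpec(spec.n_boot, spec.ci_level, seed)
        pp = per_plant_indices(records, measure)
        s = site_index_summary(pp, site, index_name, sub_spec)
        rows.append(
            {
                "site": s.site,
                "measure": s.measure,
                "index_name": s.index_name,
                "metric": s.metric,
                "n_plants_used": s.n_plants_used,
                "n_plants_undefined": s.n_plants_undefined,
                "estimate": s.boot.estimate,
                "ci_low": s.boot.ci_low,
                "ci_high": s.boot.ci_high,
                "evidence": s.evidence,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
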