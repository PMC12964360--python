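"""End-to-end analysis: validate -> exclude -> summarize -> bootstrap ->
indices -> regression, with seed fan-out and a consolidated report.

A single master seed is split into per-stage seeds through a fixed
derivation, so any stage can be re-run in isolation from the seeds recorded
in the report. Random results in the report are therefore exactly
reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from ._version import __version__
from .bootstrap import (
    BootstrapSpec,
    pairwise_differences,
    pairwise_long_table,
    pairwise_matrix,
)
from .glmm import fit_binomial_glmm
from .indices import DEFAULT_PL_METRIC, summarize_all_indices
from .io import ExclusionReport, exclude_damaged_plants, summarize_groups, validate_records
from .regression import contrast_table, fit_negbin_glm, fit_poisson_glm, tukey_contrasts

log = logging.getLogger("seedset")

MEASURES = ("produced", "germinated")
_STAGES = ("bootstrap_produced", "bootstrap_germinated", "indices")


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    """Fixed fan-out of the master seed into per-stage seeds (< 2**31)."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        stage: int(ss.generate_state(1)[0] % 2**31)
        for stage, ss in zip(_STAGES, children)
    }


@dataclass
class RunReport:
    """Everything one analysis run computed, with full provenance."""

    provenance: dict[str, Any]
    exclusion: ExclusionReport
    group_summaries: dict[str, pd.DataFrame]
    pairwise: dict[str, pd.DataFrame]
    index_summaries: pd.DataFrame
    model_fits: dict[str, Any]
    contrasts: dict[str, pd.DataFrame]
    seeds: dict[str, int]
    warnings: list[str] = field(default_factory=list)
    version: str = __version__

    def to_dir(self, out_dir: str | Path) -> None:
        """Write all tables as CSV plus a consolidated JSON report."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for measure in self.group_summaries:
            self.group_summaries[measure].to_csv(
                out / f"group_summary_{measure}.csv", index=False
            )
            self.pairwise[measure].to_csv(
                out / f"pairwise_differences_{measure}.csv", index=False
            )
        self.index_summaries.to_csv(out / "index_summaries.csv", index=False)
        for name, tab in self.contrasts.items():
            tab.to_csv(out / f"contrasts_{name}.csv", index=False)
        (out / "report.json").write_text(json.dumps(self.to_json_dict(), indent=2))

    def to_json_dict(self) -> dict:
        def fitdict(f) -> dict:
            d = {
                "family": f.family,
                "link": f.link,
                "coefficients": f.coefficients,
                "log_likelihood": f.log_likelihood,
                "warnings": f.warnings,
            }
            if hasattr(f, "theta"):
                d.update(
                    theta=f.theta,
                    residual_deviance=f.residual_deviance,
                    residual_df=f.residual_df,
                    standard_errors=f.standard_errors,
                )
            else:
                d.update(re_sd=f.re_sd, method=f.method, n_groups=f.n_groups,
                         fixed_se=f.fixed_se)
            return d

        return {
            "version": self.version,
            "provenance": self.provenance,
            "seeds": self.seeds,
            "exclusion": {
                "excluded_plant_ids": self.exclusion.excluded_plant_ids,
                "retained_n": self.exclusion.retained_n,
            },
            "group_summaries": {
                m: df.to_dict(orient="records") for m, df in self.group_summaries.items()
            },
            "pairwise": {
                m: df.to_dict(orient="records") for m, df in self.pairwise.items()
            },
            "index_summaries": self.index_summaries.to_dict(orient="records"),
            "model_fits": {k: fitdict(v) for k, v in self.model_fits.items()},
            "contrasts": {
                k: df.to_dict(orient="records") for k, df in self.contrasts.items()
            },
            "warnings": self.warnings,
        }


def run_analysis(
    records: pd.DataFrame,
    master_seed: int = 0,
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    pl_metric: str = DEFAULT_PL_METRIC,
    glmm_method: str = "laplace",
    agq_nodes: int = 15,
    provenance: dict[str, Any] | None = None,
) -> RunReport:
    """Run every analysis stage on a validated record table.

    Model non-convergence in one stage is reported without aborting the
    others; validation failures stop the run before any analysis.
    """
    t0 = time.perf_counter()
    records = validate_records(records)
    retained, exclusion = exclude_damaged_plants(records)
    log.info("exclusion: retained %s", exclusion.retained_n)

    seeds = derive_stage_seeds(master_seed)
    warnings_list: list[str] = []

    group_summaries: dict[str, pd.DataFrame] = {}
    pairwise: dict[str, pd.DataFrame] = {}
    for measure in MEASURES:
        col = "seeds_produced" if measure == "produced" else "seeds_germinated"
        group_summaries[measure] = summarize_groups(retained, measure)
        groups = {
            (site, treat): g[col].to_numpy(dtype=float)
            for (site, treat), g in retained.groupby(["site", "treatment"])
        }
        spec = BootstrapSpec(n_boot, ci_level, seeds[f"bootstrap_{measure}"])
        pairwise[measure] = pairwise_long_table(pairwise_differences(groups, spec))
        log.info("bootstrap (%s): %d pairs", measure, len(pairwise[measure]))

    idx_spec = BootstrapSpec(n_boot, ci_level, seeds["indices"])
    index_summaries = summarize_all_indices(retained, idx_spec, metric=pl_metric)
    log.info("indices: %d summaries", len(index_summaries))

    model_fits: dict[str, Any] = {}
    contrasts: dict[str, pd.DataFrame] = {}
    for name, fitter in (
        ("poisson_produced", lambda: fit_poisson_glm(retained)),
        ("negbin_produced", lambda: fit_negbin_glm(retained)),
        (
            "glmm_germination",
            lambda: fit_binomial_glmm(
                retained, method=glmm_method, agq_nodes=agq_nodes
            ),
        ),
    ):
        try:
            fit = fitter()
            model_fits[name] = fit
            warnings_list.extend(f"{name}: {w}" for w in fit.warnings)
            if name != "poisson_produced":
                contrasts[name] = contrast_table(tukey_contrasts(fit))
        except Exception as exc:  # keep other stages alive
            warnings_list.append(f"{name} failed: {exc}")
            log.warning("%s failed: %s", name, exc)

    prov = dict(provenance or {})
    prov.setdefault("master_seed", master_seed)
    prov.update(
        n_boot=n_boot,
        ci_level=ci_level,
        pl_metric=pl_metric,
        glmm_method=glmm_method,
        agq_nodes=agq_nodes,
    )
    log.info("analysis finished in %.1f s", time.perf_counter() - t0)
    return RunReport(
        provenance=prov,
        exclusion=exclusion,
        group_summaries=group_summaries,
        pairwise=pairwise,
        index_summaries=index_summaries,
        model_fits=model_fits,
        contrasts=contrasts,
        seeds=seeds,
        warnings=warnings_list,
    )


def table1_matrices(report: RunReport, retained: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Rebuild the upper-triangle comparison matrices from a report."""
    out = {}
    for measure, long in report.pairwise.items():
        from .bootstrap import PairwiseDifference

        results = [
            PairwiseDifference(
                group_a=(r.site_a, r.treatment_a),
                group_b=(r.site_b, r.treatment_b),
                diff_mean=r.diff_mean,
                ci_low=r.ci_low,
                ci_high=r.ci_high,
                contains_zero=bool(r.contains_zero),
                significant=bool(r.significant),
            )
            for r in long.itertuples(index=False)
        ]
        out[measure] = pairwise_matrix(results)
    return out
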