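"""Nonparametric bootstrap of group means and pairwise mean differences.

All intervals are percentile intervals (quantiles of the replicate
distribution, linear interpolation between order statistics). The decision
rule throughout the package is the one used for the experiment: a 95%
interval that contains zero is read as no significant difference / no
evidence of the phenomenon. The plant is the unit of replication — each
group's values are per-plant inflorescence measurements and are resampled
with replacement within the group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

QUANTILE_RULE = "percentile, linear interpolation between order statistics"


@dataclass
class BootstrapSpec:
    """Replicate count, interval level and seed for one bootstrap run."""

    n_boot: int = 10_000
    ci_level: float = 0.95
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be a positive integer")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_boot < 1000:
            warnings.warn(
                f"n_boot = {self.n_boot} is below 1000; reported intervals "
                "may be unstable",
                stacklevel=3,
            )


@dataclass
class BootstrapResult:
    """Point estimate and percentile CI of a bootstrapped statistic."""

    estimate: float  # mean of the replicate distribution
    ci_low: float
    ci_high: float
    n_boot: int
    ci_level: float
    seed: int
    method: str = QUANTILE_RULE

    @property
    def contains_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


@dataclass
class PairwiseDifference:
    """Bootstrapped difference of two group means, mean(a) - mean(b)."""

    group_a: tuple[str, str]
    group_b: tuple[str, str]
    diff_mean: float
    ci_low: float
    ci_high: float
    contains_zero: bool
    significant: bool


def _replicate_means(values: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    return values[idx].mean(axis=1)


def bootstrap_mean(values, spec: BootstrapSpec) -> BootstrapResult:
    """Bootstrap the mean of ``values``: resample with replacement at the
    original size ``n_boot`` times; return the mean of replicate means and
    the central percentile interval."""
    spec.validate()
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap_mean requires a non-empty sample")
    rng = np.random.default_rng(spec.rng_seed)
    means = _replicate_means(values, spec.n_boot, rng)
    alpha = 1.0 - spec.ci_level
    lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapResult(
        estimate=float(means.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=spec.n_boot,
        ci_level=spec.ci_level,
        seed=spec.rng_seed,
    )


def bootstrap_plant_statistic(per_plant_values, spec: BootstrapSpec) -> BootstrapResult:
    """Bootstrap a per-plant statistic (same contract as :func:`bootstrap_mean`).

    Provided separately so index pipelines carry their own seed.
    """
    return bootstrap_mean(per_plant_values, spec)


def pairwise_differences(
    groups: dict[tuple[str, str], "np.ndarray | list[float]"],
    spec: BootstrapSpec,
) -> list[PairwiseDifference]:
    """Bootstrap all unordered pairwise differences of group means.

    For each pair, every replicate resamples each group's plants
    independently with replacement and records the difference of replicate
    means. ``contains_zero`` iff the percentile interval covers 0;
    ``significant`` is its negation. Six site x treatment groups give the
    15 pairs of the experiment's comparison table.
    """
    spec.validate()
    if len(groups) < 2:
        raise ValueError("pairwise_differences requires at least two groups")
    arrays: dict[tuple[str, str], np.ndarray] = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {label} is empty")
        arrays[label] = arr

    labels = list(arrays)
    pairs = list(combinations(labels, 2))
    # one independent substream per pair, in fixed pair order
    streams = np.random.SeedSequence(spec.rng_seed).spawn(len(pairs))
    alpha = 1.0 - spec.ci_level

    out = []
    for (a, b), ss in zip(pairs, streams):
        rng = np.random.default_rng(ss)
        diffs = _replicate_means(arrays[a], spec.n_boot, rng) - _replicate_means(
            arrays[b], spec.n_boot, rng
        )
        lo, hi = np.quantile(diffs, [alpha / 2.0, 1.0 - alpha / 2.0])
        contains = bool(lo <= 0.0 <= hi)
        out.append(
            PairwiseDifference(
                group_a=a,
                group_b=b,
                diff_mean=float(diffs.mean()),
                ci_low=float(lo),
                ci_high=float(hi),
                contains_zero=contains,
                significant=not contains,
            )
        )
    return out


def pairwise_long_table(results: list[PairwiseDifference]) -> pd.DataFrame:
    """Long-format table: one row per pair."""
    return pd.DataFrame(
        {
            "site_a": [r.group_a[0] for r in results],
            "treatment_a": [r.group_a[1] for r in results],
            "site_b": [r.group_b[0] for r in results],
            "treatment_b": [r.group_b[1] for r in results],
            "diff_mean": [r.diff_mean for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "contains_zero": [r.contains_zero for r in results],
            "significant": [r.significant for r in results],
        }
    )


def pairwise_matrix(results: list[PairwiseDifference]) -> pd.DataFrame:
    """Upper-triangle matrix of ``"ci_low, ci_high"`` strings, shaped like
    the experiment's published comparison table."""
    labels: list[tuple[str, str]] = []
    for r in results:
        for g in (r.group_a, r.group_b):
            if g not in labels:
                labels.append(g)
    names = [f"{s}, {t}" for s, t in labels]
    mat = pd.DataFrame("", index=names, columns=names)
    for r in results:
        i = f"{r.group_a[0]}, {r.group_a[1]}"
        j = f"{r.group_b[0]}, {r.group_b[1]}"
        cell = f"{r.ci_low:.1f}, {r.ci_high:.1f}"
        if r.contains_zero:
            cell += " (ns)"
        mat.loc[i, j] = cell
    return mat
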