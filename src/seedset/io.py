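"""Reading, validation, exclusion filtering and group summaries.

The canonical on-disk format is a comma-separated UTF-8 table with header
``plant_id,site,treatment,seeds_produced,seeds_germinated,damaged``.
A plant enters the analysis only if it has exactly one undamaged record for
each of the three treatments; otherwise all its records are dropped and the
plant is listed in the exclusion report. This mirrors field practice where
a bent or detached inflorescence makes the whole plant uninterpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SITES, TREATMENTS
from .simulate import COLUMNS


class ValidationError(ValueError):
    """A record table violates the schema; the message names the rows."""


@dataclass
class GroupSummary:
    """n/mean/SD for one site x treatment cell."""

    site: str
    treatment: str
    n_plants: int
    mean: float
    sd: float  # sample SD (n-1); NaN when n < 2


@dataclass
class ExclusionReport:
    """Plants removed by the damaged/incomplete-triple rule, per site."""

    excluded_plant_ids: dict[str, list[str]] = field(default_factory=dict)
    retained_n: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "excluded_plant_ids": self.excluded_plant_ids,
                "retained_n": self.retained_n,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a record table and return it with canonical dtypes.

    Raises :class:`ValidationError` naming the first offending row for:
    missing columns, unknown site/treatment labels, negative or non-integer
    counts, ``seeds_germinated > seeds_produced``, duplicated
    (plant, treatment) pairs, or a plant appearing at two sites. A missing
    germination count is tolerated only on damaged records.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    df = df[COLUMNS].copy()

    def bad(mask: pd.Series, why: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise ValidationError(f"row {row}: {why}")

    bad(~df["site"].isin(SITES), f"site must be one of {SITES}")
    bad(~df["treatment"].isin(TREATMENTS), f"treatment must be one of {TREATMENTS}")

    for col in ("seeds_produced", "seeds_germinated", "damaged"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if col == "seeds_germinated":
            # sentinel: blank germination allowed only on damaged rows
            damaged = pd.to_numeric(df["damaged"], errors="coerce").fillna(0) != 0
            bad(vals.isna() & ~damaged, f"non-integer or missing {col}")
            vals = vals.fillna(0)
        else:
            bad(vals.isna(), f"non-integer or missing {col}")
        bad(vals % 1 != 0, f"{col} must be an integer")
        bad(vals < 0, f"{col} must be non-negative")
        df[col] = vals.astype(int)

    bad(~df["damaged"].isin((0, 1)), "damaged must be 0 or 1")
    bad(df["seeds_germinated"] > df["seeds_produced"], "seeds_germinated > seeds_produced")
    bad(df.duplicated(["plant_id", "treatment"]), "duplicate (plant_id, treatment) pair")

    sites_per_plant = df.groupby("plant_id")["site"].nunique()
    multi = sites_per_plant[sites_per_plant > 1]
    if len(multi):
        raise ValidationError(f"plant {multi.index[0]!r} appears at more than one site")
    return df


def read_records(path: str | Path) -> pd.DataFrame:
    """Read and validate an experiment CSV."""
    df = pd.read_csv(path, dtype={"plant_id": str})
    return validate_records(df)


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write an experiment table in the canonical CSV dialect."""
    df[COLUMNS].to_csv(path, index=False)


def exclude_damaged_plants(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop every plant lacking a complete undamaged treatment triple.

    A plant is retained iff it has exactly one undamaged record for each of
    the three treatments. The report lists excluded plants and retained
    counts per site. Idempotent.
    """
    report = ExclusionReport(
        excluded_plant_ids={s: [] for s in SITES}, retained_n={s: 0 for s in SITES}
    )
    if df.empty:
        return df.copy(), ExclusionReport()

    ok = df["damaged"] == 0
    undamaged = df[ok]
    counts = undamaged.groupby(["plant_id", "treatment"]).size().unstack(fill_value=0)
    complete = counts.index[
        (counts.reindex(columns=list(TREATMENTS), fill_value=0) == 1).all(axis=1)
    ]
    keep = set(complete)

    site_of = df.drop_duplicates("plant_id").set_index("plant_id")["site"]
    for pid, site in site_of.items():
        if pid in keep:
            report.retained_n[site] += 1
        else:
            report.excluded_plant_ids[site].append(pid)

    retained = df[df["plant_id"].isin(keep)].reset_index(drop=True)
    return retained, report


def summarize_groups(df: pd.DataFrame, measure: str = "produced") -> pd.DataFrame:
    """Per-cell n, mean and sample SD of seeds produced or germinated.

    Cells are ordered (annual, triennial) x (outcrossed, autonomous, open).
    With a single plant in a cell the SD is reported as missing.
    """
    col = {"produced": "seeds_produced", "germinated": "seeds_germinated"}.get(measure)
    if col is None:
        raise ValueError(f"measure must be 'produced' or 'germinated', got {measure!r}")

    order = [(s, t) for s in SITES for t in ("outcrossed", "autonomous", "open")]
    rows = []
    grouped = df.groupby(["site", "treatment"])[col]
    for site, treatment in order:
        try:
            vals = grouped.get_group((site, treatment))
        except KeyError:
            vals = pd.Series([], dtype=float)
        n = len(vals)
        rows.append(
            GroupSummary(
                site=site,
                treatment=treatment,
                n_plants=n,
                mean=float(vals.mean()) if n else float("nan"),
                sd=float(vals.std(ddof=1)) if n >= 2 else float("nan"),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
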