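"""Bioactivity standardization to pChEMBL and class-level comparison.

Raw activity tables (ChEMBL-style extracts) are filtered to records with a
direct target relationship, a standard activity type (IC50, EC50, Ki, Kd)
and defined units (nM or uM); values are standardized to pChEMBL
(-log10 of the molar activity, higher = stronger binding); multiple assays
for one compound-target pair collapse to the best (highest) pChEMBL; targets
are summarized and compound classes compared with a two-tailed independent
samples t-test (Welch by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STANDARD_TYPES = frozenset({"IC50", "EC50", "Ki", "Kd"})
DIRECT_RELATIONSHIPS = frozenset({"D", "direct", "direct interaction"})
_UNIT_TO_MOLAR = {"nM": 1e-9, "uM": 1e-6}
_UNIT_ALIASES = {"nm": "nM", "nM": "nM", "um": "uM", "uM": "uM", "µM": "uM", "µm": "uM"}

ACTIVITY_COLUMNS = [
    "compound_id",
    "cls",
    "target_id",
    "target_name",
    "target_class",
    "activity_type",
    "value",
    "units",
    "relationship",
]


def filter_records(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep records passing the three inclusion criteria; report exclusions.

    Criteria: (1) direct target relationship, (2) standard activity type,
    (3) specified units (nM/uM) with a positive numeric value. Returns the
    retained records and a per-criterion rejection count table. A record
    failing several criteria is counted once under the first failed one.
    """
    df = raw.copy()
    df["units"] = df["units"].map(lambda u: _UNIT_ALIASES.get(str(u).strip(), None))
    value = pd.to_numeric(df["value"], errors="coerce")

    fail1 = ~df["relationship"].isin(DIRECT_RELATIONSHIPS)
    fail2 = ~df["activity_type"].isin(STANDARD_TYPES)
    fail3 = df["units"].isna() | value.isna() | (value <= 0)

    reason = np.select(
        [fail1, fail2, fail3],
        ["relationship_not_direct", "nonstandard_activity_type", "undefined_units_or_value"],
        default="",
    )
    kept = df[reason == ""].copy()
    kept["value"] = value[reason == ""]
    rejections = (
        pd.Series(reason[reason != ""])
        .value_counts()
        .rename_axis("criterion")
        .reset_index(name="n_rejected")
    )
    return kept, rejections


def to_pchembl(value: float, units: str) -> float:
    """pChEMBL = -log10 of the molar activity value (nM -> 1e-9, uM -> 1e-6)."""
    unit = _UNIT_ALIASES.get(str(units).strip())
    if unit is None:
        raise ValueError(f"unsupported units: {units!r}")
    if not value > 0:
        raise ValueError("activity value must be positive")
    return -math.log10(value * _UNIT_TO_MOLAR[unit])


def add_pchembl(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized pChEMBL column for filtered records."""
    out = records.copy()
    molar = out["value"].astype(float) * out["units"].map(_UNIT_TO_MOLAR).astype(float)
    out["pchembl"] = -np.log10(molar)
    return out


def collapse_best(records: pd.DataFrame) -> pd.DataFrame:
    """One row per (compound, target): the assay with maximal pChEMBL.

    Ties keep the earliest input row (stable, input-order deterministic).
    """
    idx = records.groupby(["compound_id", "target_id"], sort=False)["pchembl"].idxmax()
    return records.loc[idx.sort_values()].reset_index(drop=True)


def target_summaries(records: pd.DataFrame) -> pd.DataFrame:
    """Per-target distinct-compound count, mean and max pChEMBL (mean-descending)."""
    grouped = records.groupby("target_name").agg(
        count=("compound_id", "nunique"),
        mean=("pchembl", "mean"),
        max=("pchembl", "max"),
    )
    return (
        grouped.sort_values(["mean", "count"], ascending=[False, False])
        .reset_index()
    )


@dataclass(frozen=True)
class ClassComparison:
    n_per_class: dict[str, int]
    mean_per_class: dict[str, float]
    sd_per_class: dict[str, float]
    t_statistic: float
    p_value: float
    target_diversity_per_class: dict[str, int]
    welch: bool


def compare_classes(
    records: pd.DataFrame,
    classes: tuple[str, str] = ("flavonoid", "phenolic_acid"),
    welch: bool = True,
) -> ClassComparison:
    """Two-tailed independent-samples t-test on pChEMBL between two classes.

    Welch (unequal variance) by default — the class samples have unequal
    sizes and spreads; the pooled-variance test is available via
    ``welch=False``. Target diversity is the number of distinct targets
    with any record in each class.
    """
    samples = {}
    for cls in classes:
        x = records.loc[records["cls"] == cls, "pchembl"].to_numpy(dtype=float)
        if x.size < 2:
            raise ValueError(f"class {cls!r} absent or has fewer than 2 records")
        samples[cls] = x
    a, b = (samples[c] for c in classes)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    diversity = {
        cls: int(records.loc[records["cls"] == cls, "target_id"].nunique())
        for cls in classes
    }
    return ClassComparison(
        n_per_class={c: int(samples[c].size) for c in classes},
        mean_per_class={c: float(np.mean(samples[c])) for c in classes},
        sd_per_class={c: float(np.std(samples[c], ddof=1)) for c in classes},
        t_statistic=float(t),
        p_value=float(p),
        target_diversity_per_class=diversity,
        welch=welch,
    )


__all__ = [
    "STANDARD_TYPES",
    "DIRECT_RELATIONSHIPS",
    "ACTIVITY_COLUMNS",
    "filter_records",
    "to_pchembl",
    "add_pchembl",
    "collapse_best",
    "target_summaries",
    "ClassComparison",
    "compare_classes",
]
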