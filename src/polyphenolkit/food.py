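"""Food-source concentration standardization, profiling and tier stratification.

Concentrations are standardized to mg/kg (mg/100 g x 10); per-(compound,
food) minimum/maximum/median statistics, per-food totals, per-food-group
profiles (total, compound diversity, primary compound) and three
concentration tiers — high (>7000 mg/kg), medium (2000-7000 mg/kg,
inclusive) and lower (500-2000 mg/kg) — follow. Totals over duplicate
(compound, food) measurements use the pair median by default (robust to a
single aberrant assay); mean or max are selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

FOOD_GROUPS = (
    "herbs and spices",
    "fruits",
    "vegetables",
    "beverages (non-tea)",
    "teas",
    "cereals and cereal products",
    "nuts and seeds",
    "soy and soy products",
)

_UNIT_FACTORS = {"mg/kg": 1.0, "mg/100g": 10.0}


@dataclass(frozen=True)
class TierConfig:
    high_min: float = 7000.0
    mid_min: float = 2000.0
    low_min: float = 500.0

    def __post_init__(self):
        if not (self.low_min < self.mid_min < self.high_min):
            raise ValueError("tier bounds must satisfy low_min < mid_min < high_min")


def standardize(value: float, unit: str) -> float:
    """One concentration standardized to mg/kg; raises for unknown units."""
    factor = _UNIT_FACTORS.get(str(unit).strip())
    if factor is None:
        raise ValueError(f"unknown concentration unit: {unit!r}")
    v = float(value)
    if v < 0:
        raise ValueError("concentration must be non-negative")
    return v * factor


def standardize_table(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize a concentration table; exclude unusable rows with reasons.

    Rows with unknown units, non-numeric values (e.g. ``trace``), negative
    values or sub-detection flags are excluded — never silently coerced —
    and reported. Zero concentrations are retained but flagged.
    """
    df = raw.copy()
    value = pd.to_numeric(df["concentration"], errors="coerce")
    factor = df["unit"].map(lambda u: _UNIT_FACTORS.get(str(u).strip()))
    below_det = (
        df["below_detection"].fillna(False).astype(bool)
        if "below_detection" in df
        else pd.Series(False, index=df.index)
    )

    reasons = pd.Series("", index=df.index)
    reasons[value.isna()] = "non_quantifiable_value"
    reasons[(reasons == "") & factor.isna()] = "unknown_unit"
    reasons[(reasons == "") & (value < 0)] = "negative_value"
    reasons[(reasons == "") & below_det] = "below_detection_limit"

    kept = df[reasons == ""].copy()
    kept["concentration_mg_kg"] = value[reasons == ""] * factor[reasons == ""]
    kept["original_unit"] = df.loc[reasons == "", "unit"]
    kept["zero_flag"] = kept["concentration_mg_kg"] == 0
    excluded = df[reasons != ""].copy()
    excluded["reason"] = reasons[reasons != ""]
    for _, row in excluded.iterrows():
        logger.info(
            "excluded concentration row (%s): %s / %s",
            row["reason"], row.get("compound_name"), row.get("food_name"),
        )
    return kept, excluded


def per_pair_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Min/max/median (linear interpolation) per (compound, food) pair."""
    return (
        records.groupby(["compound_name", "food_name"])["concentration_mg_kg"]
        .agg(["min", "max", "median", "count"])
        .reset_index()
    )


def _pair_aggregated(records: pd.DataFrame, agg: str) -> pd.DataFrame:
    keys = ["compound_name", "food_name"]
    extra = [c for c in ("food_group",) if c in records.columns]
    return (
        records.groupby(keys + extra, as_index=False)["concentration_mg_kg"].agg(agg)
    )


def food_totals(records: pd.DataFrame, agg: str = "median") -> pd.DataFrame:
    """Total content per food (sum over compounds of the pair ``agg``), rank-descending."""
    pairs = _pair_aggregated(records, agg)
    totals = (
        pairs.groupby("food_name", as_index=False)["concentration_mg_kg"]
        .sum()
        .rename(columns={"concentration_mg_kg": "total_mg_kg"})
        .sort_values(["total_mg_kg", "food_name"], ascending=[False, True])
        .reset_index(drop=True)
    )
    totals["rank"] = range(1, len(totals) + 1)
    return totals


@dataclass(frozen=True)
class FoodGroupProfile:
    food_group: str
    total: float
    n_compounds: int
    primary_compound: str
    primary_pct: float
    primary_tie: bool = False


def group_profiles(records: pd.DataFrame, agg: str = "median") -> list[FoodGroupProfile]:
    """Per-group total, compound diversity, and primary compound share.

    A compound's contribution within a group is its pair-aggregated
    concentration summed over all the group's foods; the primary compound is
    the largest contributor (ties broken lexicographically and flagged).
    """
    pairs = _pair_aggregated(records, agg)
    profiles = []
    for group, sub in pairs.groupby("food_group", sort=True):
        by_compound = (
            sub.groupby("compound_name")["concentration_mg_kg"].sum().sort_index()
        )
        total = float(by_compound.sum())
        top_value = by_compound.max()
        top_candidates = by_compound[by_compound == top_value].index.tolist()
        primary = sorted(top_candidates)[0]
        if len(top_candidates) > 1:
            logger.warning("primary-compound tie in %s: %s", group, top_candidates)
        profiles.append(
            FoodGroupProfile(
                food_group=str(group),
                total=total,
                n_compounds=int(by_compound.size),
                primary_compound=primary,
                primary_pct=100.0 * float(top_value) / total if total > 0 else 0.0,
                primary_tie=len(top_candidates) > 1,
            )
        )
    return profiles


def tier_classify(total: float, config: TierConfig = TierConfig()) -> str:
    """Concentration tier of a food total: high / medium / lower / below_range.

    Boundary convention: high is strictly above ``high_min``; medium is the
    closed interval [mid_min, high_min]; lower is [low_min, mid_min).
    """
    if total > config.high_min:
        return "high"
    if total >= config.mid_min:
        return "medium"
    if total >= config.low_min:
        return "lower"
    return "below_range"


def tier_table(totals: pd.DataFrame, config: TierConfig = TierConfig()) -> pd.DataFrame:
    out = totals.copy()
    out["tier"] = out["total_mg_kg"].map(lambda t: tier_classify(t, config))
    return out


__all__ = [
    "FOOD_GROUPS",
    "TierConfig",
    "standardize",
    "standardize_table",
    "per_pair_stats",
    "food_totals",
    "FoodGroupProfile",
    "group_profiles",
    "tier_classify",
    "tier_table",
]
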