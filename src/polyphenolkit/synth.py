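"""Synthetic phytochemical record generator.

Emulates the statistical structure of cross-database polyphenol extracts so
every pipeline stage is testable without downloads: compound tables built by
deterministic scaffold decoration (guaranteeing chemically valid, subclass-
faithful structures), ChEMBL-style activity tables with per-class truncated
normal pChEMBL distributions, and FoodDB-style concentration tables whose
food totals span the three concentration tiers. Every draw flows through a
single integer-seeded generator; the same seed yields byte-identical tables.
Ground truth (class parameters, deliberately corrupted records, per-food
target totals) is always written alongside the generated tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, rdBase

from .errors import PolyphenolkitError


class GenerationError(PolyphenolkitError):
    """A decoration request could not be satisfied for a scaffold."""


# ---------------------------------------------------------------------------
# scaffold library


@dataclass(frozen=True)
class ScaffoldLibrary:
    """Named parent cores plus decoration fragments (dummy atom = attachment)."""

    scaffolds: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_SCAFFOLDS)
    )
    decorations: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_DECORATIONS)
    )


_DEFAULT_SCAFFOLDS = {
    "flavanones": "O=C1CC(c2ccccc2)Oc2ccccc21",
    "flavones": "O=c1cc(-c2ccccc2)oc2ccccc12",
    "flavonols": "O=c1c(O)c(-c2ccccc2)oc2ccccc12",
    "isoflavonoids": "O=c1c(-c2ccccc2)coc2ccccc12",
    "flavan-3-ols": "OC1Cc2ccccc2OC1c1ccccc1",
    "anthocyanins": "Oc1cc2cc(O)cc(O)c2[o+]c1-c1ccccc1",
    "chalcones": "O=C(/C=C/c1ccccc1)c1ccccc1",
    "hydroxycinnamic acids": "OC(=O)/C=C/c1ccccc1",
    "hydroxybenzoic acids": "OC(=O)c1ccccc1",
}

_DEFAULT_DECORATIONS = {
    # weights chosen to mirror the hydroxyl-rich substitution chemistry of
    # natural polyphenols: hydroxylation dominates, then O-methylation,
    # O-glycosylation, sulfation
    "hydroxyl": "*O",
    "methoxy": "*OC",
    "glucosyl": "*OC1OC(CO)C(O)C(O)C1O",
    "sulfate": "*OS(=O)(=O)O",
}

_DECORATION_WEIGHTS = {"hydroxyl": 0.45, "methoxy": 0.25, "glucosyl": 0.2, "sulfate": 0.1}

SUBCLASS_TO_CLS = {
    "flavanones": "flavonoid",
    "flavones": "flavonoid",
    "flavonols": "flavonoid",
    "isoflavonoids": "flavonoid",
    "flavan-3-ols": "flavonoid",
    "anthocyanins": "flavonoid",
    "chalcones": "flavonoid",
    "hydroxycinnamic acids": "phenolic_acid",
    "hydroxybenzoic acids": "phenolic_acid",
}


def _attach(mol: Chem.Mol, atom_idx: int, frag_smiles: str) -> Chem.Mol | None:
    """Bond a dummy-marked fragment to ``atom_idx``; None if chemistry refuses."""
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    offset = mol.GetNumAtoms()
    dummy = next(
        a.GetIdx()
        for a in combo.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetIdx() >= offset
    )
    anchor = combo.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
    combo.AddBond(atom_idx, anchor, Chem.BondType.SINGLE)
    combo.RemoveAtom(dummy)
    out = combo.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _open_aromatic_positions(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]


def decorate(
    scaffold_smiles: str,
    rng: np.random.Generator,
    library: ScaffoldLibrary,
    n_decorations: int,
    force: tuple[str, ...] = (),
) -> Chem.Mol | None:
    """Apply ``n_decorations`` random substitutions to a scaffold.

    ``force`` prepends specific decoration names (e.g. repeated glycosylation
    for deliberately heavy compounds). Returns None when no open aromatic
    position remains.
    """
    mol = Chem.MolFromSmiles(scaffold_smiles)
    names = list(library.decorations)
    weights = np.array([_DECORATION_WEIGHTS.get(n, 0.1) for n in names], dtype=float)
    weights /= weights.sum()
    plan = list(force) + [
        names[i]
        for i in rng.choice(len(names), size=max(n_decorations - len(force), 0), p=weights)
    ]
    for deco in plan:
        positions = _open_aromatic_positions(mol)
        if not positions:
            return None
        pos = int(rng.choice(positions))
        nxt = _attach(mol, pos, library.decorations[deco])
        if nxt is None:
            return None
        mol = nxt
    return mol


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ActivityClassModel:
    mu: float
    sigma: float
    min: float
    max: float

    def __post_init__(self):
        if self.sigma <= 0 or not self.min < self.max:
            raise ValueError("require sigma > 0 and min < max")


@dataclass
class SynthesisConfig:
    """Generator settings; defaults encode the study conditions being emulated."""

    seed: int = 0
    n_flavonoids: int = 715
    n_phenolic_acids: int = 239
    subclass_proportions: dict[str, float] = field(
        default_factory=lambda: {
            # flavonoid subclass weights from the reported unique-compound
            # counts (flavonols 324, isoflavonoids 198, flavones 156,
            # flavanones 93, anthocyanins 89, chalcones 45, flavan-3-ols 20)
            "flavonols": 324,
            "isoflavonoids": 198,
            "flavones": 156,
            "flavanones": 93,
            "anthocyanins": 89,
            "chalcones": 45,
            "flavan-3-ols": 20,
            # phenolic acid subclasses (hydroxycinnamic 167, hydroxybenzoic 89)
            "hydroxycinnamic acids": 167,
            "hydroxybenzoic acids": 89,
        }
    )
    registry_coverage: dict[str, float] = field(
        default_factory=lambda: {
            "flavonols": 0.58,
            "isoflavonoids": 0.52,
            "flavones": 0.54,
            "anthocyanins": 0.71,
            "chalcones": 0.38,
            "hydroxycinnamic acids": 0.62,
            "hydroxybenzoic acids": 0.58,
            # unreported subclasses: mid-range coverage
            "flavanones": 0.55,
            "flavan-3-ols": 0.55,
        }
    )
    n_misclassified_heavy: int = 3
    activity_model: dict[str, ActivityClassModel] = field(
        default_factory=lambda: {
            "flavonoid": ActivityClassModel(7.26, 1.09, 6.01, 9.70),
            "phenolic_acid": ActivityClassModel(6.98, 0.94, 6.01, 9.00),
        }
    )
    n_activities: dict[str, int] = field(
        default_factory=lambda: {"flavonoid": 239, "phenolic_acid": 141}
    )
    target_pool_sizes: dict[str, int] = field(
        default_factory=lambda: {"flavonoid": 67, "phenolic_acid": 33}
    )
    shared_targets: tuple[str, ...] = ("SLCO1B1", "SLCO1B3", "p53")
    violating_fraction: float = 0.0
    duplicate_assay_fraction: float = 0.15
    foods_per_group: dict[str, int] = field(
        default_factory=lambda: {
            "herbs and spices": 6,
            "fruits": 8,
            "vegetables": 6,
            "beverages (non-tea)": 4,
            "teas": 4,
            "cereals and cereal products": 3,
            "nuts and seeds": 3,
            "soy and soy products": 2,
        }
    )
    compounds_per_food: tuple[int, int] = (3, 12)
    food_total_lognorm: tuple[float, float] = (math.log(3000.0), 0.9)
    tier_anchors: tuple[tuple[str, float], ...] = (
        ("herbs and spices", 14500.0),
        ("fruits", 4500.0),
        ("nuts and seeds", 1500.0),
    )
    dominant_group: str = "beverages (non-tea)"
    dominant_share: float = 0.95
    duplicate_measurement_fraction: float = 0.2

    def __post_init__(self):
        for p in self.registry_coverage.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("coverage probabilities must lie in [0, 1]")
        for cls, size in self.target_pool_sizes.items():
            if size < len(self.shared_targets):
                raise ValueError(f"target pool for {cls} smaller than shared list")
        if not 0.0 <= self.violating_fraction < 1.0:
            raise ValueError("violating_fraction must lie in [0, 1)")


# ---------------------------------------------------------------------------
# compounds


def _subclass_counts(config: SynthesisConfig) -> dict[str, int]:
    """Largest-remainder apportionment of class totals over subclasses."""
    counts: dict[str, int] = {}
    for cls, total in (
        ("flavonoid", config.n_flavonoids),
        ("phenolic_acid", config.n_phenolic_acids),
    ):
        subs = {
            s: w
            for s, w in config.subclass_proportions.items()
            if SUBCLASS_TO_CLS.get(s) == cls
        }
        wsum = sum(subs.values())
        raw = {s: total * w / wsum for s, w in subs.items()}
        floored = {s: int(math.floor(v)) for s, v in raw.items()}
        remainder = total - sum(floored.values())
        for s in sorted(raw, key=lambda s: (raw[s] - floored[s], s), reverse=True)[
            :remainder
        ]:
            floored[s] += 1
        counts.update(floored)
    return counts


def generate_compounds(
    config: SynthesisConfig,
    library: ScaffoldLibrary | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the compound table plus ground-truth labels.

    Structures are unique by canonical SMILES within a run; InChIKeys are
    derived from the generated structures; registry numbers follow the
    per-subclass coverage probabilities. ``n_misclassified_heavy`` compounds
    are poly-glycosylated to inflate their mass and filed under
    ``hydroxybenzoic acids`` with a ground-truth flag (the ellagitannin
    misfiling scenario).
    """
    library = library or ScaffoldLibrary()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    counts = _subclass_counts(config)
    rows = []
    seen: set[str] = set()
    truth_misclassified: list[str] = []
    idx = 0
    with rdBase.BlockLogs():
        for subclass in sorted(counts):
            scaffold = library.scaffolds[subclass]
            coverage = config.registry_coverage.get(subclass, 0.5)
            for _ in range(counts[subclass]):
                mol = None
                for _attempt in range(200):
                    n_dec = int(rng.integers(1, 6))
                    cand = decorate(scaffold, rng, library, n_dec)
                    if cand is None:
                        continue
                    smi = Chem.MolToSmiles(cand)
                    if smi not in seen:
                        mol, smiles = cand, smi
                        break
                else:
                    raise GenerationError(
                        f"could not generate a unique decoration of {subclass!r}"
                    )
                seen.add(smiles)
                cid = f"SYN{idx:05d}"
                rows.append(
                    {
                        "compound_id": cid,
                        "name": f"syn-{subclass.replace(' ', '-')}-{idx:04d}",
                        "cls": SUBCLASS_TO_CLS[subclass],
                        "subclass": subclass,
                        "inchikey": Chem.MolToInchiKey(mol),
                        "registry_number": (
                            f"CHEMBL{1000000 + idx}" if rng.random() < coverage else None
                        ),
                        "smiles": smiles,
                        "source": "synthetic",
                    }
                )
                idx += 1
        # deliberately misfiled heavy compounds: poly-glycosylated flavonol
        # cores labelled as hydroxybenzoic acids
        for k in range(config.n_misclassified_heavy):
            mol = None
            for _attempt in range(200):
                cand = decorate(
                    library.scaffolds["flavonols"],
                    rng,
                    library,
                    5,
                    force=("glucosyl",) * 4,
                )
                if cand is None:
                    continue
                smi = Chem.MolToSmiles(cand)
                if smi not in seen:
                    mol, smiles = cand, smi
                    break
            else:
                raise GenerationError("could not generate unique heavy compound")
            seen.add(smiles)
            cid = f"SYN{idx:05d}"
            truth_misclassified.append(cid)
            rows.append(
                {
                    "compound_id": cid,
                    "name": f"syn-heavy-misfiled-{k:02d}",
                    "cls": "phenolic_acid",
                    "subclass": "hydroxybenzoic acids",
                    "inchikey": Chem.MolToInchiKey(mol),
                    "registry_number": None,
                    "smiles": smiles,
                    "source": "synthetic",
                }
            )
            idx += 1
    df = pd.DataFrame(rows)
    truth = {
        "subclass_counts": counts,
        "registry_coverage": dict(config.registry_coverage),
        "misclassified_heavy_ids": truth_misclassified,
    }
    return df, truth


# ---------------------------------------------------------------------------
# activities


def _truncated_normal(
    rng: np.random.Generator, model: ActivityClassModel, size: int
) -> np.ndarray:
    """Rejection-sampled truncated normal draws (simple and exact)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(model.mu, model.sigma, size=size)
        keep = draw[(draw >= model.min) & (draw <= model.max)]
        take = min(keep.size, size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


_TARGET_CLASS_CYCLE = (
    "kinase",
    "transporter",
    "nuclear receptor",
    "DNA repair",
    "protease",
    "other enzyme",
)


def _target_pools(config: SynthesisConfig) -> dict[str, list[str]]:
    pools = {}
    for cls, size in config.target_pool_sizes.items():
        own = [f"{cls[:4].upper()}-T{i:03d}" for i in range(size - len(config.shared_targets))]
        pools[cls] = list(config.shared_targets) + own
    return pools


def generate_activities(
    config: SynthesisConfig,
    compounds: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a raw ChEMBL-style activity table plus ground truth.

    Valid records carry truncated-normal pChEMBL values back-converted to
    assay values in deliberately mixed nM/uM units over unique
    (compound, target) pairs; ``duplicate_assay_fraction`` adds weaker
    duplicate assays for the collapse step to discard; ``violating_fraction``
    of each class's records are corrupted to fail exactly one filter
    criterion each (cycling over the three criteria), with identities
    recorded in the ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    pools = _target_pools(config)
    rows = []
    truth: dict = {"violating": [], "n_valid": {}, "n_pairs": {}, "model": {}}
    rid = 0
    for cls in sorted(config.n_activities):
        model = config.activity_model[cls]
        n_total = config.n_activities[cls]
        n_violating = int(round(config.violating_fraction * n_total))
        n_valid = n_total - n_violating
        truth["n_valid"][cls] = n_valid
        truth["model"][cls] = dataclasses.asdict(model)
        ids = compounds.loc[compounds["cls"] == cls, "compound_id"].tolist()
        if not ids:
            raise GenerationError(f"no compounds of class {cls!r} to assign activities")
        pool = pools[cls]
        pchembl = _truncated_normal(rng, model, n_total)
        used_pairs: set[tuple[str, str]] = set()
        pairs: list[tuple[str, str]] = []
        while len(pairs) < n_total:
            pair = (str(rng.choice(ids)), str(rng.choice(pool)))
            if pair not in used_pairs:
                used_pairs.add(pair)
                pairs.append(pair)
        for i, ((cid, target), p) in enumerate(zip(pairs, pchembl)):
            unit = str(rng.choice(["nM", "uM"]))
            molar = 10.0 ** (-p)
            value = molar / (1e-9 if unit == "nM" else 1e-6)
            row = {
                "record_id": f"ACT{rid:05d}",
                "compound_id": cid,
                "cls": cls,
                "target_id": target,
                "target_name": target,
                "target_class": _TARGET_CLASS_CYCLE[
                    pool.index(target) % len(_TARGET_CLASS_CYCLE)
                ],
                "activity_type": str(rng.choice(["IC50", "EC50", "Ki", "Kd"])),
                "value": value,
                "units": unit,
                "relationship": "D",
            }
            if i >= n_valid:
                criterion = (i - n_valid) % 3 + 1
                if criterion == 1:
                    row["relationship"] = "H"
                elif criterion == 2:
                    row["activity_type"] = "Inhibition"
                else:
                    row["units"] = "%"
                truth["violating"].append(
                    {"record_id": row["record_id"], "criterion": criterion, "cls": cls}
                )
            rows.append(row)
            rid += 1
            # weaker duplicate assay for some valid records
            if i < n_valid and rng.random() < config.duplicate_assay_fraction:
                p_dup = max(p - abs(rng.normal(0.3, 0.2)), 0.1)
                unit2 = str(rng.choice(["nM", "uM"]))
                dup = dict(row)
                dup["record_id"] = f"ACT{rid:05d}"
                dup["value"] = 10.0 ** (-p_dup) / (1e-9 if unit2 == "nM" else 1e-6)
                dup["units"] = unit2
                rows.append(dup)
                rid += 1
        truth["n_pairs"][cls] = n_valid
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# foods


def generate_foods(
    config: SynthesisConfig,
    compounds: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a FoodDB-style concentration table plus ground truth.

    Per-food totals are log-normal draws; the tier-anchor foods are pinned
    to fixed totals so the three concentration tiers are always exercised;
    ``dominant_group`` gets one compound holding ``dominant_share`` of its
    leading food's total (the single-compound-dominated profile). A fraction
    of (compound, food) pairs receives duplicate measurements, and units are
    randomly reported as mg/kg or mg/100 g.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    names = compounds["name"].tolist()
    if not names:
        raise GenerationError("no compounds available for food assignment")
    mu, sigma = config.food_total_lognorm
    anchors = {group: total for group, total in config.tier_anchors}
    # one compound dominates every food of the dominant group, so its share
    # of the group total is ~dominant_share
    dominant_compound = str(names[int(rng.integers(len(names)))])
    rows = []
    truth_foods = []
    for group in sorted(config.foods_per_group):
        n_foods = config.foods_per_group[group]
        for j in range(n_foods):
            food = f"food-{group.replace(' ', '-')}-{j:02d}"
            if j == 0 and group in anchors:
                total = anchors[group]
            else:
                total = float(np.clip(rng.lognormal(mu, sigma), 200.0, 16000.0))
            lo, hi = config.compounds_per_food
            k = int(rng.integers(lo, hi + 1))
            members = [str(x) for x in rng.choice(names, size=min(k, len(names)), replace=False)]
            if group == config.dominant_group:
                if dominant_compound in members:
                    members.remove(dominant_compound)
                members = [dominant_compound] + members
                shares = np.empty(len(members))
                shares[0] = config.dominant_share
                rest = rng.dirichlet(np.ones(len(members) - 1)) if len(members) > 1 else []
                shares[1:] = (1.0 - config.dominant_share) * np.asarray(rest)
            else:
                shares = rng.dirichlet(np.ones(len(members)))
            truth_foods.append(
                {"food_name": food, "food_group": group, "true_total": total}
            )
            for compound, share in zip(members, shares):
                conc = total * float(share)
                n_meas = (
                    int(rng.integers(2, 4))
                    if rng.random() < config.duplicate_measurement_fraction
                    else 1
                )
                for _ in range(n_meas):
                    # duplicates jitter around the true value; the median of
                    # an odd replicate set equals one observed value
                    reported = conc if n_meas == 1 else conc * float(rng.uniform(0.8, 1.2))
                    if rng.random() < 0.5:
                        unit, value = "mg/kg", reported
                    else:
                        unit, value = "mg/100g", reported / 10.0
                    rows.append(
                        {
                            "compound_name": compound,
                            "food_name": food,
                            "food_group": group,
                            "concentration": value,
                            "unit": unit,
                        }
                    )
    df = pd.DataFrame(rows)
    truth = {
        "foods": truth_foods,
        "tier_anchors": {g: t for g, t in config.tier_anchors},
        "dominant_group": config.dominant_group,
        "dominant_share": config.dominant_share,
        "dominant_compound": dominant_compound,
    }
    return df, truth


# ---------------------------------------------------------------------------
# run directory


def write_run(config: SynthesisConfig, outdir) -> Path:
    """Generate all three tables and write them under ``outdir/seed-<seed>``.

    Writes compounds.csv, activities.csv, foods.csv, ground_truth.json and
    config.json; returns the run directory path.
    """
    rundir = Path(outdir) / f"seed-{config.seed}"
    rundir.mkdir(parents=True, exist_ok=True)
    compounds, truth_c = generate_compounds(config)
    activities, truth_a = generate_activities(config, compounds)
    foods, truth_f = generate_foods(config, compounds)
    compounds.to_csv(rundir / "compounds.csv", index=False)
    activities.to_csv(rundir / "activities.csv", index=False)
    foods.to_csv(rundir / "foods.csv", index=False)
    truth = {"compounds": truth_c, "activities": truth_a, "foods": truth_f}
    (rundir / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    (rundir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True, default=list)
    )
    return rundir


__all__ = [
    "GenerationError",
    "ScaffoldLibrary",
    "ActivityClassModel",
    "SynthesisConfig",
    "decorate",
    "generate_compounds",
    "generate_activities",
    "generate_foods",
    "write_run",
]
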