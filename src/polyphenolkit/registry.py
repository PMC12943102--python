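"""Compound registry: ingestion, cross-source reconciliation, coverage and outlier reports.

Compound records arrive as delimited tables exported from phytochemical
databases (PhytoHub-style, Phenol-Explorer-style, ChEMBL-style extracts).
Records from different sources describing the same molecule are merged on
the full 27-character InChIKey; per-subclass identifier coverage and
molecular-weight outliers (typically misclassified heavy compounds such as
ellagitannins filed under simple phenolic acids) are reported downstream.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError

logger = logging.getLogger(__name__)

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: subclass -> compound class taxonomy used to fill/validate the `cls` field
DEFAULT_TAXONOMY: dict[str, str] = {
    "flavonols": "flavonoid",
    "flavones": "flavonoid",
    "flavanones": "flavonoid",
    "flavan-3-ols": "flavonoid",
    "isoflavones": "flavonoid",
    "isoflavonoids": "flavonoid",
    "anthocyanins": "flavonoid",
    "chalcones": "flavonoid",
    "hydroxycinnamic acids": "phenolic_acid",
    "hydroxybenzoic acids": "phenolic_acid",
}

#: default precedence used to pick field values when merging sources
DEFAULT_PRECEDENCE: tuple[str, ...] = ("phytohub", "phenol_explorer", "chembl")

DEFAULT_COLUMN_MAP = {
    "compound_id": "compound_id",
    "name": "name",
    "cls": "cls",
    "subclass": "subclass",
    "inchikey": "inchikey",
    "registry_number": "registry_number",
    "smiles": "smiles",
}


@dataclass
class CompoundRecord:
    """One compound with identifiers and per-database provenance."""

    compound_id: str
    name: str
    cls: str
    subclass: str
    inchikey: str | None = None
    registry_number: str | None = None
    smiles: str | None = None
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.inchikey is not None and not INCHIKEY_RE.match(self.inchikey):
            raise ValueError(f"malformed InChIKey: {self.inchikey!r}")


@dataclass(frozen=True)
class OutlierConfig:
    """Settings for molecular-weight outlier flagging."""

    z_threshold: float = 3.0
    robust: bool = False

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


@dataclass
class ConflictEntry:
    inchikey: str
    field: str
    values: dict[str, str]  # source -> value
    winner: str


@dataclass
class ReconcileResult:
    records: list[CompoundRecord]
    conflicts: list[ConflictEntry]
    skeleton_matches: list[tuple[str, str]]  # pairs of full keys sharing connectivity block


def _clean_cell(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    return text or None


def load_compound_table(
    path,
    source_tag: str,
    column_map: dict[str, str] | None = None,
    taxonomy: dict[str, str] | None = None,
) -> list[CompoundRecord]:
    """Load one delimited compound table into records tagged with ``source_tag``.

    Missing identifiers are recorded as ``None`` (never empty strings); the
    row count is preserved. A missing mandatory column (name, and at least
    one of cls/subclass) raises :class:`SchemaError` naming the column.
    """
    colmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    taxonomy = taxonomy if taxonomy is not None else DEFAULT_TAXONOMY
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)

    if colmap["name"] not in df.columns:
        raise SchemaError(f"missing mandatory column: {colmap['name']!r}", column=colmap["name"])
    has_cls = colmap["cls"] in df.columns
    has_subclass = colmap["subclass"] in df.columns
    if not has_subclass:
        raise SchemaError(
            f"missing mandatory column: {colmap['subclass']!r}", column=colmap["subclass"]
        )

    records = []
    for i, row in df.iterrows():
        subclass = _clean_cell(row.get(colmap["subclass"])) or "unknown"
        cls = _clean_cell(row.get(colmap["cls"])) if has_cls else None
        if cls is None:
            cls = taxonomy.get(subclass.lower(), "other")
        cid = _clean_cell(row.get(colmap["compound_id"])) or f"{source_tag}:{i}"
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=_clean_cell(row.get(colmap["name"])) or cid,
                cls=cls,
                subclass=subclass,
                inchikey=_clean_cell(row.get(colmap["inchikey"])),
                registry_number=_clean_cell(row.get(colmap["registry_number"])),
                smiles=_clean_cell(row.get(colmap["smiles"])),
                sources=frozenset({source_tag}),
            )
        )
    return records


def _rank(record: CompoundRecord, precedence: tuple[str, ...]) -> int:
    ranks = [precedence.index(s) for s in record.sources if s in precedence]
    return min(ranks) if ranks else len(precedence)


def reconcile(
    collections: list[list[CompoundRecord]],
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> ReconcileResult:
    """Merge records sharing a full InChIKey across source collections.

    Fields of a merged record are filled by first-non-absent value scanning
    sources in ``precedence`` order; disagreements on class/subclass labels
    are recorded as conflict entries (the precedence source wins). Records
    lacking an InChIKey are kept unmerged. Records that share only the
    14-character connectivity block are reported as skeleton matches but not
    merged — stereoisomers are distinct compounds here.
    """
    pool = [r for coll in collections for r in coll]
    keyed: dict[str, list[CompoundRecord]] = {}
    keyless: list[CompoundRecord] = []
    for rec in pool:
        if rec.inchikey is None:
            keyless.append(rec)
        else:
            keyed.setdefault(rec.inchikey, []).append(rec)

    conflicts: list[ConflictEntry] = []
    merged: list[CompoundRecord] = []
    for key in sorted(keyed):
        group = sorted(
            keyed[key], key=lambda r: (_rank(r, precedence), sorted(r.sources), r.compound_id)
        )
        base = group[0]
        out = replace(base, sources=frozenset().union(*(r.sources for r in group)))
        for fld in ("cls", "subclass", "registry_number", "smiles", "name"):
            values = {}
            for rec in group:
                v = getattr(rec, fld)
                if v is not None:
                    values.setdefault(v, sorted(rec.sources)[0])
            if getattr(out, fld) is None and values:
                out = replace(out, **{fld: next(iter(values))})
            if fld in ("cls", "subclass") and len(values) > 1:
                winner = getattr(out, fld)
                conflicts.append(
                    ConflictEntry(
                        inchikey=key,
                        field=fld,
                        values={src: val for val, src in values.items()},
                        winner=winner,
                    )
                )
                logger.warning(
                    "merge conflict on %s for %s: %s (winner: %s)", fld, key, values, winner
                )
        merged.append(out)

    skeletons: dict[str, list[str]] = {}
    for key in sorted(keyed):
        skeletons.setdefault(key[:14], []).append(key)
    skeleton_matches = [
        (a, b)
        for block in skeletons.values()
        if len(block) > 1
        for i, a in enumerate(block)
        for b in block[i + 1:]
    ]
    return ReconcileResult(merged + keyless, conflicts, skeleton_matches)


def coverage_summary(records: list[CompoundRecord]) -> pd.DataFrame:
    """Per-subclass count of unique compounds and registry-number coverage.

    Uniqueness is by InChIKey where present, else by surrogate compound id.
    Percentages are unrounded; rounding is presentation-time only.
    """
    if not records:
        return pd.DataFrame(
            columns=["subclass", "n_unique", "n_with_registry", "pct_with_registry"]
        )
    seen: dict[str, CompoundRecord] = {}
    for rec in records:
        key = rec.inchikey or f"id:{rec.compound_id}"
        seen.setdefault(key, rec)
    rows = []
    by_subclass: dict[str, list[CompoundRecord]] = {}
    for rec in seen.values():
        by_subclass.setdefault(rec.subclass, []).append(rec)
    for subclass in sorted(by_subclass):
        group = by_subclass[subclass]
        n = len(group)
        n_reg = sum(1 for r in group if r.registry_number is not None)
        rows.append(
            {
                "subclass": subclass,
                "n_unique": n,
                "n_with_registry": n_reg,
                "pct_with_registry": 100.0 * n_reg / n,
            }
        )
    return pd.DataFrame(rows)


def flag_mass_outliers(
    records: list[CompoundRecord],
    mw_lookup: dict[str, float],
    config: OutlierConfig = OutlierConfig(),
    reference: tuple[float, float] | None = None,
) -> list[tuple[str, float, bool]]:
    """Flag compounds whose molecular weight is atypical for their subclass.

    The z-score of each candidate uses location/scale computed on the other
    members of its subclass (leave-one-out), so a single extreme compound
    cannot mask itself. ``reference=(loc, scale)`` overrides this with fixed
    population statistics (e.g. a published class mean and SD). With
    ``config.robust`` the location/scale are a 10%-trimmed mean and the SD of
    the trimmed sample. Subclasses with fewer than three weighted records are
    skipped with a warning. Flagged compounds are reported, never dropped.
    """
    by_subclass: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        if rec.compound_id in mw_lookup:
            by_subclass.setdefault(rec.subclass, []).append(rec)

    results: list[tuple[str, float, bool]] = []
    for subclass in sorted(by_subclass):
        group = by_subclass[subclass]
        if reference is None and len(group) < 3:
            warnings.warn(
                f"subclass {subclass!r} has fewer than 3 records with MW; skipped",
                stacklevel=2,
            )
            continue
        mws = np.array([mw_lookup[r.compound_id] for r in group], dtype=float)
        for i, rec in enumerate(group):
            if reference is not None:
                loc, scale = reference
            else:
                others = np.delete(mws, i)
                if config.robust:
                    loc = stats.trim_mean(others, 0.1)
                    scale = float(np.std(stats.trimboth(others, 0.1), ddof=1))
                else:
                    loc = float(np.mean(others))
                    scale = float(np.std(others, ddof=1))
            z = (mws[i] - loc) / scale if scale > 0 else 0.0
            flagged = abs(z) > config.z_threshold
            if flagged:
                logger.info(
                    "MW outlier: %s (%s) z=%.2f in subclass %s",
                    rec.compound_id,
                    rec.name,
                    z,
                    subclass,
                )
            results.append((rec.compound_id, float(z), flagged))
    return results


def records_to_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    """Tabular view of compound records (sources joined with ';')."""
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "cls": r.cls,
                "subclass": r.subclass,
                "inchikey": r.inchikey,
                "registry_number": r.registry_number,
                "smiles": r.smiles,
                "sources": ";".join(sorted(r.sources)),
            }
            for r in records
        ]
    )
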