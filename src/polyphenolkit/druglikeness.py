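"""Drug-likeness scoring and score-distribution analysis.

Two complementary metrics are supported: the from-scratch QED score
(:mod:`polyphenolkit.qed`) and a fragment-based drug-likeness score in the
DataWarrior style — fragment contributions summed over matched substructures
and normalized by the square root of the number of matches, where positive
values indicate drug-like character. Proprietary fragment dictionaries are
not reproduced; externally computed scores can be ingested from a keyed CSV
instead, or a user-supplied :class:`FragmentScoreTable` can be scored
directly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .errors import EmptySummaryError, FragmentTableError, StructureError
from .qed import qed

logger = logging.getLogger(__name__)


class FragmentScoreTable:
    """Mapping of substructure SMARTS patterns to contribution values.

    Patterns are validated at construction; an invalid pattern raises
    :class:`FragmentTableError` immediately rather than at scoring time.
    """

    def __init__(self, contributions: dict[str, float]):
        if not contributions:
            raise FragmentTableError("fragment table is empty")
        self.patterns: list[tuple[str, Chem.Mol, float]] = []
        for smarts, value in contributions.items():
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise FragmentTableError(f"invalid substructure pattern: {smarts!r}")
            if not math.isfinite(value):
                raise FragmentTableError(f"non-finite contribution for {smarts!r}")
            self.patterns.append((smarts, patt, float(value)))


def fragment_sum_score(structure, table: FragmentScoreTable) -> float:
    """Sum matched fragment contributions, normalized by sqrt(#matches).

    Every occurrence of every pattern counts as one matched fragment and
    contributes that pattern's value. A structure matching no fragment scores
    0 with a warning (no evidence either way).
    """
    mol = Chem.MolFromSmiles(structure) if isinstance(structure, str) else structure
    if mol is None:
        raise StructureError(str(structure))
    total = 0.0
    n = 0
    for _, patt, value in table.patterns:
        hits = len(mol.GetSubstructMatches(patt))
        total += hits * value
        n += hits
    if n == 0:
        warnings.warn("no fragments matched; score defaults to 0", stacklevel=2)
        return 0.0
    return total / math.sqrt(n)


@dataclass(frozen=True)
class DruglikenessRecord:
    compound_id: str
    qed: float | None
    dw_score: float | None
    complete_structure: bool


def score_table(
    compounds: pd.DataFrame,
    smiles_col: str = "smiles",
    id_col: str = "compound_id",
    weights: str = "mean",
) -> pd.DataFrame:
    """Per-compound QED scores; unparseable/missing structures give NaN.

    Complete-case principle: a QED value is present exactly when the
    structure parsed.
    """
    rows = []
    for _, rec in compounds.iterrows():
        row = {"compound_id": rec[id_col], "qed": np.nan, "complete_structure": False}
        try:
            row["qed"] = qed(rec[smiles_col], weights=weights)
            row["complete_structure"] = True
        except StructureError as err:
            logger.info("QED skipped: %s", err)
        rows.append(row)
    return pd.DataFrame(rows)


def ingest_scores(
    path,
    registry: pd.DataFrame,
    key: str = "name",
    score_col: str = "dw_score",
    column_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Left-join an external score file (keyed by name or InChIKey) onto the registry.

    Duplicate keys in the score file keep the first occurrence; duplicates
    and unmatched score rows are returned in the report.
    """
    colmap = {key: key, score_col: score_col, **(column_map or {})}
    scores = pd.read_csv(path)
    scores = scores.rename(columns={v: k for k, v in colmap.items()})
    if scores.empty:
        merged = registry.copy()
        merged[score_col] = np.nan
        return merged, {"n_matched": 0, "duplicates": [], "unmatched": []}
    dup_mask = scores.duplicated(subset=[key], keep="first")
    duplicates = scores.loc[dup_mask, key].tolist()
    scores = scores[~dup_mask]
    merged = registry.merge(scores[[key, score_col]], on=key, how="left")
    matched_keys = set(registry[key].dropna())
    unmatched = [k for k in scores[key] if k not in matched_keys]
    report = {
        "n_matched": int(merged[score_col].notna().sum()),
        "duplicates": duplicates,
        "unmatched": unmatched,
    }
    return merged, report


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    skewness: float
    degenerate: bool = False  # constant sample: sd 0, skewness reported as 0


def summarize(scores) -> DistributionSummary:
    """Distribution summary with moment-based (Fisher-Pearson g1) skewness.

    Quartiles use linear interpolation. A constant sample has undefined
    skewness; it is reported as 0 with the ``degenerate`` flag set.
    """
    x = np.asarray(pd.Series(scores).dropna(), dtype=float)
    if x.size == 0:
        raise EmptySummaryError("cannot summarize an empty sample")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    degenerate = bool(np.all(x == x[0]))
    skew = 0.0 if degenerate else float(stats.skew(x, bias=True))
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return DistributionSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(np.min(x)),
        max=float(np.max(x)),
        skewness=skew,
        degenerate=degenerate,
    )


def correlation_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Pairwise complete-case Pearson correlation matrix.

    Returns the symmetric matrix (diagonal exactly 1) and the list of column
    pairs with fewer than two complete cases (left NaN).
    """
    numeric = table.select_dtypes(include=[np.number])
    corr = numeric.corr(method="pearson", min_periods=2)
    insufficient = []
    cols = list(numeric.columns)
    for i, a in enumerate(cols):
        corr.loc[a, a] = 1.0
        for b in cols[i + 1:]:
            n_complete = int((numeric[a].notna() & numeric[b].notna()).sum())
            if n_complete < 2:
                insufficient.append((a, b))
    return corr, insufficient


__all__ = [
    "FragmentScoreTable",
    "fragment_sum_score",
    "DruglikenessRecord",
    "score_table",
    "ingest_scores",
    "DistributionSummary",
    "summarize",
    "correlation_matrix",
]
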