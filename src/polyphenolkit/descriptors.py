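"""Molecular descriptors and rule-based oral drug-likeness filters.

Eight descriptors are computed from SMILES with RDKit: average molecular
weight, Crippen LogP, hydrogen-bond donors (counted as OH + NH group
occurrences, i.e. hydrogens on oxygen or nitrogen), Lipinski hydrogen-bond
acceptors (the literal N + O atom count), rotatable bonds, Ertl topological
polar surface area, aromatic rings, and stereocenters (assigned plus
unassigned by default). Compliance with Lipinski's Rule of 5 (at most one
violation allowed) and the Veber rules (both criteria required) uses
inclusive thresholds throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .errors import StructureError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DescriptorVector:
    mw: float  # Da, average mass
    logp: float  # Crippen estimate
    hbd: int  # OH + NH group occurrences
    hba_lipinski: int  # N + O atom count
    rotb: int
    tpsa: float  # Angstrom^2
    arom_rings: int
    chiral_centers: int


@dataclass(frozen=True)
class RuleThresholds:
    ro5_mw_max: float = 500.0
    ro5_logp_max: float = 5.0
    ro5_hbd_max: int = 5
    ro5_hba_max: int = 10
    ro5_violations_allowed: int = 1
    veber_rotb_max: int = 10
    veber_tpsa_max: float = 140.0


@dataclass(frozen=True)
class ComplianceResult:
    violations: tuple[str, ...]
    compliant: bool


def _mol_from_smiles(smiles) -> Chem.Mol:
    if smiles is None or not isinstance(smiles, str) or not smiles.strip():
        raise StructureError(str(smiles), "missing structure")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    return mol


def compute_descriptors(
    smiles: str, include_unassigned_stereo: bool = True
) -> DescriptorVector:
    """Compute the eight-descriptor vector for one SMILES structure.

    Structures are used as given (no desalting or neutralization — the
    source databases list parent structures); multi-fragment inputs are
    logged. Raises :class:`StructureError` for unparseable input so callers
    can exclude the record (complete-case analysis).
    """
    mol = _mol_from_smiles(smiles)
    if len(Chem.GetMolFrags(mol)) > 1:
        logger.info("multi-fragment structure used as given: %s", smiles)

    hbd = sum(
        a.GetTotalNumHs() for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)
    )
    hba = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8))
    stereo = Chem.FindMolChiralCenters(
        mol, includeUnassigned=include_unassigned_stereo, useLegacyImplementation=False
    )
    return DescriptorVector(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=int(hbd),
        hba_lipinski=int(hba),
        rotb=int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        arom_rings=int(rdMolDescriptors.CalcNumAromaticRings(mol)),
        chiral_centers=len(stereo),
    )


def assess_ro5(d: DescriptorVector, t: RuleThresholds = RuleThresholds()) -> ComplianceResult:
    """Lipinski Rule-of-5 check: compliant iff at most one threshold is exceeded."""
    violations = []
    if d.mw > t.ro5_mw_max:
        violations.append(f"MW>{t.ro5_mw_max:g}")
    if d.logp > t.ro5_logp_max:
        violations.append(f"LogP>{t.ro5_logp_max:g}")
    if d.hbd > t.ro5_hbd_max:
        violations.append(f"HBD>{t.ro5_hbd_max}")
    if d.hba_lipinski > t.ro5_hba_max:
        violations.append(f"HBA>{t.ro5_hba_max}")
    return ComplianceResult(tuple(violations), len(violations) <= t.ro5_violations_allowed)


def assess_veber(d: DescriptorVector, t: RuleThresholds = RuleThresholds()) -> ComplianceResult:
    """Veber check: compliant iff rotatable bonds <= 10 and TPSA <= 140 A^2."""
    violations = []
    if d.rotb > t.veber_rotb_max:
        violations.append(f"ROTB>{t.veber_rotb_max}")
    if d.tpsa > t.veber_tpsa_max:
        violations.append(f"TPSA>{t.veber_tpsa_max:g}")
    return ComplianceResult(tuple(violations), not violations)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_weight(formula: str) -> float:
    """Average molecular weight from a molecular formula (e.g. ``C48H28O30``).

    Independent of any structure: useful for cross-checking descriptor MW
    against a published formula.
    """
    table = Chem.GetPeriodicTable()
    pos = 0
    total = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        total += table.GetAtomicWeight(m.group(1)) * int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return total


def descriptor_table(
    df: pd.DataFrame,
    smiles_col: str = "smiles",
    id_col: str = "compound_id",
    thresholds: RuleThresholds = RuleThresholds(),
) -> pd.DataFrame:
    """Descriptor table keyed by compound id with a parse-status column.

    Rows whose structure fails to parse get ``parse_status='error'`` and NaN
    descriptors; they are retained so downstream complete-case handling is
    explicit rather than silent.
    """
    rows = []
    for _, rec in df.iterrows():
        row = {"compound_id": rec[id_col]}
        try:
            d = compute_descriptors(rec[smiles_col])
        except StructureError:
            row["parse_status"] = "error"
        else:
            row.update(d.__dict__)
            row["parse_status"] = "ok"
            row["ro5_compliant"] = assess_ro5(d, thresholds).compliant
            row["veber_compliant"] = assess_veber(d, thresholds).compliant
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "DescriptorVector",
    "RuleThresholds",
    "ComplianceResult",
    "compute_descriptors",
    "assess_ro5",
    "assess_veber",
    "formula_weight",
    "descriptor_table",
]
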