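"""Quantitative Estimate of Drug-likeness (QED), implemented from first principles.

QED maps eight molecular properties — molecular weight (MW), Crippen LogP
(ALOGP), hydrogen-bond acceptors (HBA, SMARTS-defined), hydrogen-bond donors
(HBD), polar surface area (PSA), rotatable bonds (ROTB, strict definition),
aromatic rings (AROM) and structural-alert count (ALERTS) — through
per-property asymmetric double sigmoid (ADS) desirability functions and
combines them as a weighted geometric mean:

    QED = exp( sum_i w_i ln d_i(x_i) / sum_i w_i ),   d_i in (0, 1]

The ADS coefficients, property weights, acceptor SMARTS and Brenk-style
alert patterns are published parameter data bundled in
``data/qed_params.json`` (provenance documented there). The default weights
are the "weighted-mean" variant; unit weights are available via
``weights="unit"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .errors import StructureError

PROPERTY_NAMES = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")

#: floor applied to each desirability before the log transform
DESIRABILITY_FLOOR = 1e-6


@dataclass(frozen=True)
class DesirabilityParams:
    """Coefficients of one asymmetric double sigmoid plus its normalizer."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    d_max: float

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")


@lru_cache(maxsize=1)
def _load_params() -> dict:
    raw = json.loads(
        resources.files("polyphenolkit.data").joinpath("qed_params.json").read_text()
    )
    ads = {
        name: DesirabilityParams(
            a=p["A"], b=p["B"], c=p["C"], d=p["D"], e=p["E"], f=p["F"], d_max=p["DMAX"]
        )
        for name, p in raw["ads"].items()
    }
    acceptors = tuple(Chem.MolFromSmarts(s) for s in raw["acceptor_smarts"])
    alerts = tuple(Chem.MolFromSmarts(s) for s in raw["alert_smarts"])
    return {
        "ads": ads,
        "weights_mean": raw["weights_mean"],
        "acceptors": acceptors,
        "alerts": alerts,
    }


def ads_params(name: str) -> DesirabilityParams:
    """The published ADS coefficient set for one QED property."""
    return _load_params()["ads"][name]


def default_weights() -> dict[str, float]:
    return dict(_load_params()["weights_mean"])


def _safe_exp(t: float) -> float:
    """exp saturating to +inf instead of overflowing (deep-tail evaluation)."""
    try:
        return math.exp(t)
    except OverflowError:
        return math.inf


def desirability(x: float, p: DesirabilityParams) -> float:
    """Evaluate one ADS desirability at ``x``, normalized to (0, 1] by d_max.

    The raw double sigmoid is ``a + b/(1+exp(-(x-c+d/2)/e)) *
    (1 - 1/(1+exp(-(x-c-d/2)/f)))``; both tails decay to ``a``. Division by
    the function's maximum ``d_max`` puts the mode at 1.
    """
    exp1 = 1.0 + _safe_exp(-(x - p.c + p.d / 2.0) / p.e)
    exp2 = 1.0 + _safe_exp(-(x - p.c - p.d / 2.0) / p.f)
    raw = p.a + p.b / exp1 * (1.0 - 1.0 / exp2)
    return raw / p.d_max


def _as_mol(structure) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    if not isinstance(structure, str) or not structure.strip():
        raise StructureError(str(structure), "missing structure")
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(structure)
    return mol


def qed_properties(structure) -> dict[str, float]:
    """The eight raw QED property values for a structure (SMILES or Mol).

    HBA counts matches of the acceptor SMARTS definitions (not the Lipinski
    N+O count); ROTB uses the strict rotatable-bond definition; ALERTS is the
    number of alert patterns with at least one match.
    """
    mol = Chem.RemoveHs(_as_mol(structure))
    params = _load_params()
    arom = sum(
        1
        for ring in mol.GetRingInfo().BondRings()
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
    )
    return {
        "MW": Descriptors.MolWt(mol),
        "ALOGP": Crippen.MolLogP(mol),
        "HBA": float(
            sum(len(mol.GetSubstructMatches(patt)) for patt in params["acceptors"])
        ),
        "HBD": float(rdMolDescriptors.CalcNumHBD(mol)),
        "PSA": rdMolDescriptors.CalcTPSA(mol),
        "ROTB": float(
            rdMolDescriptors.CalcNumRotatableBonds(
                mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
            )
        ),
        "AROM": float(arom),
        "ALERTS": float(
            sum(1 for patt in params["alerts"] if mol.HasSubstructMatch(patt))
        ),
    }


def qed_from_properties(props: dict[str, float], weights: str | dict = "mean") -> float:
    """Weighted geometric mean of the eight desirabilities."""
    params = _load_params()
    if weights == "mean":
        w = params["weights_mean"]
    elif weights == "unit":
        w = {name: 1.0 for name in PROPERTY_NAMES}
    else:
        w = dict(weights)
    num = 0.0
    den = 0.0
    for name in PROPERTY_NAMES:
        d = max(desirability(props[name], params["ads"][name]), DESIRABILITY_FLOOR)
        num += w[name] * math.log(d)
        den += w[name]
    return math.exp(num / den)


def qed(structure, weights: str | dict = "mean") -> float:
    """QED score in [0, 1] for a SMILES string or RDKit molecule."""
    return qed_from_properties(qed_properties(structure), weights=weights)


__all__ = [
    "PROPERTY_NAMES",
    "DesirabilityParams",
    "ads_params",
    "default_weights",
    "desirability",
    "qed_properties",
    "qed_from_properties",
    "qed",
]
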