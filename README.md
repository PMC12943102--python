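# polyphenolkit

Cross-database characterization of dietary flavonoids and phenolic acids:
identifier reconciliation, molecular descriptors and drug-likeness scoring,
bioactivity standardization, and food-source concentration profiling.

Polyphenols are among the most studied plant secondary metabolites, but the
data needed to evaluate them as pharmaceutical leads or dietary targets is
scattered across specialized databases: compound identity and classification
(PhytoHub- and Phenol-Explorer-style extracts), bioactivity against protein
targets (ChEMBL-style activity tables), and occurrence in foods
(FoodDB-style concentration tables). `polyphenolkit` is a toolkit for
integrating such extracts into one reproducible analysis: it merges records
across sources by full InChIKey, computes physicochemical descriptors and
rule-based filters, scores drug-likeness, standardizes heterogeneous assay
results to a single affinity scale, and profiles which foods and food groups
carry which compounds at what concentrations. A deterministic synthetic-data
generator emulates all the table kinds, so the whole pipeline is testable
offline.

## What it computes

**QED (Quantitative Estimate of Drug-likeness)** — implemented from first
principles. Eight properties (MW, ALOGP, HBA, HBD, PSA, ROTB, AROM, ALERTS)
are each mapped through an asymmetric double-sigmoid desirability function
*d<sub>i</sub>(x)* and combined as a weighted geometric mean:

```
QED = exp( Σᵢ wᵢ ln dᵢ(xᵢ) / Σᵢ wᵢ )  ∈ [0, 1]
```

The published desirability coefficients, property weights, acceptor SMARTS
and Brenk structural-alert patterns ship as a data file with documented
provenance (`src/polyphenolkit/data/qed_params.json`).

**Rule filters** — Lipinski Rule of 5 (MW ≤ 500 Da, LogP ≤ 5, HBD ≤ 5,
HBA ≤ 10; compliant with at most one violation) and the Veber rules
(rotatable bonds ≤ 10 and TPSA ≤ 140 Å², both required). HBD is counted as
OH + NH occurrences and HBA as the literal N + O atom count.

**Fragment-sum drug-likeness** — DataWarrior-style aggregation over a
pluggable fragment-score table: Σ vᵢ over matched substructures divided by
√(number of matches); positive = drug-like. Externally computed scores can
also be ingested from CSV.

**pChEMBL standardization** — activity records with a direct target
relationship, a standard type (IC50, EC50, Ki, Kd) and defined units
(nM/uM) are converted to pChEMBL = −log₁₀(molar value); multiple assays per
compound–target pair collapse to the strongest; classes are compared with a
two-tailed Welch t-test.

**Food profiling** — concentrations standardized to mg/kg (mg/100 g × 10),
per-food totals and ranks, per-group totals/diversity/primary compound, and
stratification into high (>7000 mg/kg), medium (2000–7000) and lower
(500–2000) content tiers.

## Worked example

```python
from polyphenolkit.qed import qed, qed_properties
from polyphenolkit.descriptors import compute_descriptors, assess_ro5, assess_veber
from polyphenolkit.bioactivity import to_pchembl

sativanone = "COc1ccc(C2COc3cc(O)ccc3C2=O)c(OC)c1"
print("QED =", round(qed(sativanone), 3))
d = compute_descriptors(sativanone)
print(d.mw, d.logp, d.hbd, d.hba_lipinski, d.tpsa)
print(assess_ro5(d).compliant, assess_veber(d).compliant)
print(to_pchembl(100, "nM"))
```

prints

```
QED = 0.944
300.31 2.77 1 5 64.99
True True
7.0
```

Sativanone (an isoflavanone) scores QED 0.944 — near the ideal end of the
scale, consistent with its moderate mass (300.31 Da), balanced lipophilicity
(Crippen LogP 2.77), single hydrogen-bond donor and small polar surface
area; it passes both Lipinski and Veber filters. A 100 nM IC50 standardizes
to pChEMBL 7.0.

The full pipeline is also exposed as a CLI:

```sh
polyphenolkit synth --seed 7 --out runs/          # synthetic tables
polyphenolkit run-all config.yaml                 # registry → … → food stages
polyphenolkit report runs/out                     # manifest summary
```

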