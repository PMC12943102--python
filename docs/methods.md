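# Methods

This note documents the models, parameter choices and numerical conventions
behind `polyphenolkit`, and what the synthetic-data generator does and does
not emulate.

## Compound registry

Records are merged across source extracts on the **full 27-character
InChIKey**. Records sharing only the 14-character connectivity block are
reported as *skeleton matches* but never merged: for polyphenols
(flavan-3-ol epimers, glycoside anomers) stereochemistry distinguishes real
compounds. Field values on merge follow a configurable source-precedence
order, by default `phytohub > phenol_explorer > chembl`, reflecting the role
of the first two as primary identification sources; class/subclass
disagreements are logged as conflict entries and the precedence source wins.
Compounds with neither InChIKey nor SMILES keep a surrogate id and are
excluded from structure-dependent stages (complete-case analysis).
Reconciliation is idempotent and order-insensitive under a fixed precedence.

Coverage summaries (per-subclass unique-compound counts and
registry-number percentages) are computed on whatever collection is passed,
so they can be produced both before and after cross-source merging; the
percentage is stored unrounded.

**Mass-outlier flagging.** The z-score of a candidate's molecular weight
uses location/scale estimated from the *other* members of its subclass
(leave-one-out), so a single extreme compound cannot mask itself; a
`robust` option uses a 10%-trimmed mean/SD for contaminated subclasses, and
fixed published reference statistics can be supplied instead. Default
threshold |z| > 3. Flagged compounds are reported, never dropped — the
intended use is surfacing misfiled heavy compounds (ellagitannins recorded
as simple hydroxybenzoic acids) for manual reclassification.

## Descriptors and rule filters

Eight descriptors per structure, computed with RDKit primitives: average
molecular weight; Crippen LogP; hydrogen-bond donors counted as **OH + NH
group occurrences** (hydrogens on O/N — a primary amine contributes 2),
which differs from donor-atom counting; hydrogen-bond acceptors as the
**literal N + O atom count**; rotatable bonds (terminal bonds excluded);
Ertl TPSA; aromatic rings; and stereocenters counting both assigned and
unassigned centers by default (a flag restricts to assigned-only), since
the inclusive count better reflects three-dimensional complexity.

Thresholds are inclusive ("no greater than", "or less"): Ro5 compliance
allows at most one violation of MW ≤ 500, LogP ≤ 5, HBD ≤ 5, HBA ≤ 10;
Veber compliance requires both ROTB ≤ 10 and TPSA ≤ 140 Å². Structures are
used as given — no desalting or neutralization, because the source
databases list parent structures; multi-fragment inputs are logged.
Unparseable structures raise a typed error carrying the offending text and
are excluded downstream as incomplete cases.

Note on aromaticity: ring-oxygen TPSA contributions follow the toolkit's
aromaticity perception (a flavone pyranone ring counts its oxygen at the
aromatic-ring value 13.14 Å² rather than the 9.23 Å² ether value); the
descriptor tests pin this convention.

## QED

The QED machinery is authored here: the asymmetric double sigmoid

d(x) = a + b / (1 + e^{-(x-c+d/2)/e}) · (1 − 1/(1 + e^{-(x-c-d/2)/f})),

normalized by its maximum `d_max` so the mode maps to 1, evaluated for MW,
ALOGP, HBA (SMARTS acceptor definitions), HBD, PSA, ROTB (strict rotatable
bonds), AROM (aromatic ring count) and ALERTS (number of matching
structural-alert patterns), then combined as the weighted geometric mean of
desirabilities. The **weighted-mean variant is the default**; unit weights
are available via `weights="unit"`. Numerical conventions: exponentials
saturate to +inf in the deep tails instead of overflowing, and each
desirability is floored at 1e-6 before the log transform so the geometric
mean is defined even at pathological property values.

Coefficients, weights, acceptor SMARTS and the Brenk alert set are
published parameter data (Bickerton et al. 2012 and Brenk et al. 2008, as
distributed with the reference implementation) and ship in
`data/qed_params.json`; the test suite cross-checks the implementation
against the independent reference implementation to ≤1e-9 on a structure
panel spanning flavonoid subclasses, conjugates and alert-bearing
molecules.

## Fragment-sum drug-likeness and score statistics

The fragment score is (Σ vᵢ over matched substructure occurrences)/√n,
with n the number of occurrences; a structure matching nothing scores 0
with a warning, since absence of fragments is no evidence either way.
Pattern validity is enforced when the table is constructed, not at scoring
time. Proprietary fragment dictionaries are out of scope; externally
computed scores are ingested by left-join on name or InChIKey, keeping the
first of duplicate keys and reporting duplicates and unmatched rows.

Distribution summaries use the moment-based Fisher–Pearson skewness g1
(no small-sample correction) and linearly interpolated quartiles — common
statistical-package defaults. A constant sample reports skewness 0 with a
`degenerate` flag. Correlation matrices are pairwise complete-case Pearson;
pairs with fewer than two complete cases are reported and left missing.

## Bioactivity

Three inclusion criteria, applied in order for rejection accounting:
(1) direct target relationship; (2) activity type in {IC50, EC50, Ki, Kd};
(3) defined units (nM or uM, µ-sign tolerated) with a positive numeric
value. Unknown units are rejected, never converted. pChEMBL =
−log₁₀(molar value). Per compound–target pair the maximal pChEMBL is kept;
ties keep the earliest input row (stable and deterministic). Target
summaries report distinct-compound counts with mean and max pChEMBL,
mean-descending.

The class comparison is a two-tailed independent-samples t-test on
collapsed per-pair pChEMBL values. **Welch's unequal-variance form is the
default** because the class samples have unequal sizes and spreads; the
pooled form is available (`welch=False`), and the comparison can equally be
run on uncollapsed per-record values by passing that table. Target
diversity is the distinct-target count per class.

## Food mapping

mg/100 g values are multiplied by 10; mg/kg pass through. Non-numeric
values ("trace"), sub-detection flags and unknown units are excluded with
per-row reasons; zeros are retained and flagged. Where a (compound, food)
pair has several measurements, totals use the **pair median** (robust to a
single aberrant assay; mean/max selectable) while min/max/median are all
reported per pair. A group's primary compound is the largest per-compound
sum across the group's foods, ties broken lexicographically and flagged.
Tier boundaries: high strictly > 7000 mg/kg, medium the closed interval
[2000, 7000] (so exactly 7000 is medium), lower [500, 2000), and an
explicit `below_range` tier rather than silent omission. Group totals
conserve mass: they sum to the total of all pair-aggregated standardized
concentrations.

## Synthetic data generator

The generator's defaults encode the study conditions the pipeline assumes:

- **Compounds** — 715 flavonoids and 239 phenolic acids, apportioned over
  subclasses by the reported unique-compound counts (flavonols 324,
  isoflavonoids 198, flavones 156, flavanones 93, anthocyanins 89,
  chalcones 45, flavan-3-ols 20; hydroxycinnamic 167, hydroxybenzoic 89 —
  largest-remainder rounding), with per-subclass registry-number coverage
  probabilities 0.58/0.52/0.54/0.71/0.38/0.62/0.58 as reported and 0.55
  (mid-range) for the two unreported subclasses. Structures are built by
  deterministic scaffold decoration — flavanone, flavone, flavonol,
  isoflavanone-type, flavan-3-ol, flavylium, chalcone, hydroxycinnamic and
  hydroxybenzoic cores decorated with hydroxylation, O-methylation,
  O-glucosylation and sulfation at open aromatic positions — rather than
  random graph generation, guaranteeing valid, subclass-faithful chemistry;
  uniqueness is enforced by canonical SMILES and InChIKeys derive from the
  structures. Three deliberately misfiled heavy compounds (flavonol cores
  carrying four glucosyl units, labelled hydroxybenzoic acids) emulate the
  ellagitannin misclassification scenario, with ground-truth flags.
- **Activities** — per-class truncated normal pChEMBL: flavonoids
  N(7.26, 1.09²) on [6.01, 9.70], phenolic acids N(6.98, 0.94²) on
  [6.01, 9.00], with 239 and 141 records by default; truncation by
  rejection sampling (simple and exact). Values are back-converted to
  assay values in deliberately mixed nM/uM units over unique
  compound–target pairs drawn from pools of 67 (flavonoid) and 33
  (phenolic-acid) targets sharing SLCO1B1, SLCO1B3 and p53. A configurable
  fraction of records is corrupted to fail exactly one filter criterion
  each, and a configurable fraction of pairs receives weaker duplicate
  assays for the collapse step to discard; both are recorded in ground
  truth.
- **Foods** — per-group foods with log-normal totals split over member
  compounds by Dirichlet shares; three anchor foods are pinned to totals
  14 500, 4 500 and 1 500 mg/kg so all three tiers are always exercised;
  one group (beverages) has a single compound holding 95% of every food's
  total, exercising primary-compound logic; 20% of pairs get duplicate
  jittered measurements and units are randomly reported as mg/kg or
  mg/100 g.

All randomness flows through one integer-seeded NumPy generator; a fixed
seed reproduces byte-identical tables across runs. Ground truth is always
written beside the tables so tests never reverse-engineer it from outputs.

What the generator does **not** emulate: realistic assay noise beyond
truncated normals, inter-database identifier disagreement rates, genuine
FoodDB concentration marginals, or chemically faithful ellagitannin
structures. Passing tests therefore demonstrate the pipeline's correctness
and statistical calibration under these stated conditions, not fidelity of
any particular real-world extract.

## Problem sizes in the test suite

Unit tests run on hand-enumerable fixtures (≤50 rows). The Monte-Carlo
calibration check uses 200 replicates at the default activity sample sizes
(239/141), chosen to estimate the rejection rate to within a few percent;
the registry/descriptor tests use generator runs of 60–100 compounds, which
already cover every subclass scaffold.

## Known limitations

- Drug-likeness metrics were parameterized on oral synthetic drugs and can
  undervalue natural products absorbed by active transport; scores are
  screening aids, not exclusion criteria.
- The fragment-sum score depends entirely on the supplied fragment table;
  no fragment dictionary is bundled.
- The registry treats the full InChIKey as ground truth for identity;
  tautomer- or salt-variant keys are distinct records.
- ChEMBL-style target classes are free text; no ontology mapping is
  attempted.
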