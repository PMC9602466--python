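# Methods

This note records the scientific and numerical choices behind `bbbfp`: what
each component assumes, which parameters matter, and what the synthetic
fixtures do and do not establish about real data.

## Library preparation (`chemprep`)

Standardization keeps the largest organic fragment (salt stripping),
neutralizes formal charges where valence permits (carboxylates and
phenolates are protonated, ammoniums deprotonated; quaternary nitrogens
stay charged), strips stereochemistry, and emits canonical SMILES.  The
operation is idempotent: re-standardizing its own output is a no-op.
Stereochemistry is deliberately discarded — stereoisomers collapse onto one
record — trading chemical fidelity for a cheaper, duplicate-free library;
any stereo-dependent permeation difference is invisible downstream.

Deduplication hashes molecules to ECFP4 (Morgan radius 2, 1024 bits) and
groups pairs with Tanimoto ≥ threshold by single linkage.  The default
threshold is 1.0 — exact fingerprint duplicates only — because any looser
cutoff merges genuinely distinct chemotypes in ways that are hard to audit.
The group representative is the member with the lexicographically smallest
canonical SMILES: an arbitrary but reproducible rule, standing in for a
curator's manual pick.

3D preparation embeds a conformer (ETKDGv3, seeded) and minimizes it with
MMFF94, capped at 5000 iterations.  Any embedding or force-field
parameterization failure excludes the molecule rather than propagating
broken geometry; the audit log records every exclusion with its reason.

## Scaffold analysis (`scaffolds`)

Murcko decomposition keeps ring systems plus connecting linkers and removes
terminal side chains; acyclic molecules map to an `ACYCLIC` sentinel and are
excluded from scaffold statistics.  Per-scaffold permeation probability is
the positive fraction over *labeled* members only; unlabeled members count
toward group size but not probability.  Categorization uses p > 0.6 →
permeable, p < 0.4 → non-permeable, with both boundaries inclusive on the
neutral side — a literal reading of "between 0.4 and 0.6".  Specific (not
atom-type-abstracted) frameworks are used, canonicalized with the same
SMILES routine as `chemprep` so groups are stable across runs.

## Residue-contact fingerprint (`dockparse`)

A residue is "contacted" when any of its heavy atoms lies within 4.0 Å of
any ligand heavy atom.  The cutoff is a conventional close-contact distance,
exposed as a parameter; hydrogens are ignored throughout because docked
PDBQT files carry only polar hydrogens and mixing H-aware with H-blind
inputs would bias contacts.  The schema is frequency-built: residues are
ranked by the number of *distinct ligands* contacting them (multiple poses
of one ligand count once), the top k = 62 are kept, and ties break by
(chain, residue number) ascending so schema construction is deterministic.
Only the rank-1 (best-scored) pose feeds the schema by default.  The schema
serializes to JSON and round-trips bit-exactly; fingerprints are meaningless
across different schemas, so the schema id travels with every CSV.

## Interaction typing (`interactions`)

Nine types, in fixed bit order: Hydrophobic, HBDonor, HBAcceptor, Cationic,
Anionic, CationPi, PiCation, PiStacking, VdWContact.  Direction is from the
ligand's perspective (HBDonor = ligand donates; CationPi = ligand cation
over a receptor ring).  Default geometry, all configurable:

| interaction | threshold |
|---|---|
| Hydrophobic | d ≤ 4.5 Å between apolar atoms |
| HBDonor / HBAcceptor | donor–acceptor d ≤ 3.5 Å; D–H···A ≥ 130° when an explicit H exists, distance-only otherwise |
| Cationic / Anionic | charge-center d ≤ 4.5 Å |
| CationPi / PiCation | cation–centroid d ≤ 4.5 Å, ≤ 30° off the ring normal |
| PiStacking | face-to-face d ≤ 5.5 Å with plane angle ≤ 30°, or edge-to-face d ≤ 6.5 Å with plane angle in [50°, 90°] |
| VdWContact | d ≤ r₁ + r₂ (Bondi radii, bundled) + tolerance (default 0) |

Ligand features are perceived from the bond graph (SDF input with bond
orders and charges) via SMARTS: donors are N/O bearing H; acceptors are
N/O with an available lone pair (quaternary N and nitro O excluded);
cations/anions are formally charged atoms not balanced by an adjacent
counter-charge; hydrophobes are C/S/halogen atoms with no N/O/F or charged
neighbor; aromatic rings come from ring perception, with the centroid and
an SVD-fit unit normal.  Receptor files carry no bond orders, so residues
get template features keyed on standard atom names (ASP/GLU carboxylate
midpoints as anion centers, LYS NZ and the ARG guanidinium centroid as
cations, PHE/TYR/TRP/HIS rings, side-chain plus backbone donors/acceptors).
Histidine is modeled neutral (ring + ambident N donor/acceptor): its
protonation state is unknowable from a static structure.  Receptor donors
have no hydrogens, so receptor-side H-bonds are distance-only — a known
source of over-detection relative to H-aware pipelines.

The fingerprint is one bit per type at complex level: it answers "does this
pose make any interaction of type t", not "with which residue" — that
resolution lives in the residue fingerprint instead.

## 2D pharmacophore fingerprint (`pharm2d`)

Six feature families (HD, HA, AR, HY, BG, AG) are matched by SMARTS bundled
in a versioned data file; overlapping matches of different families are
kept, duplicate matches of one family on the same atom set collapse.
Inter-feature distance is the minimum shortest bond-path length between the
features' atom sets — topological, not geometric, so no conformer is
needed.  Distances are discretized into 13 contiguous integer bins

(1)(2)(3)(4)(5–7)(8)(9–11)(12–20)(21–22)(23–24)(25–26)(27–28)(29–∞);

a distance of 0 (features sharing atoms) is below the lowest edge and the
combination is discarded.  Triangles must pass a binned triangle
inequality: the smallest realizable value of the largest bin must not
exceed the sum of the largest realizable values of the other two.

Every admissible combination — a family pair with one bin, or a family
triple *paired with* its three binned edges, canonicalized under the
symmetry of the triangle — maps to exactly one bit.  Exhaustive
enumeration gives 273 pair bits + 39,698 triangle bits = **39,971 bits**,
and the index table is verified to be a bijection onto [0, 39971).  The
bin edges were calibrated once so that the enumeration lands exactly on
this published fingerprint size; the upper bins are sparse in drug-like
chemistry (few molecules have 25+-bond feature separations) and function
as reserved range.  The pairing of families with distance assignments is
essential: a scheme that keys bits on (sorted families) × (sorted
distances) independently always has a bit count divisible by 7 with six
families (21 pair- and 56 triple-multisets), and no such scheme can reach
this total.  Calibration details live with the schema file; changing
either the SMARTS or the bins changes the bit space and is a
schema-version bump.

## Benchmark (`mlbench`)

Stratified k-fold assignment is its own implementation: per class, indices
are shuffled with a seeded generator and dealt cyclically into folds, the
starting fold rotating between classes.  This keeps per-fold class counts
within one of proportional allocation, is deterministic given the seed, and
— unlike off-the-shelf splitters — accepts classes smaller than k (some
folds then see none of that class), which matters for rare-scaffold
stratification.  Folds are verified disjoint at run time.

Metrics are evaluated from the confusion matrix exactly as written
(accuracy, precision, recall, F1, MCC); a vanishing denominator yields 0
with a `degenerate` flag rather than NaN, so aggregation never silently
drops folds.  AUROC uses the Mann–Whitney rank formulation with average
ranks for ties, computed from decision scores (predict_proba when the model
has it, decision_function otherwise).

Models and hyperparameters: uniform-random dummy baseline, RBF-kernel SVM,
500-tree random forest, Bernoulli naive Bayes — the latter chosen because
all feature sets here are binary bitvectors.  Hyperparameters are fixed
defaults, not tuned: the benchmark's job is comparing representations under
one protocol, and determinism is worth more than squeezing out points.
Feature concatenation offsets bit indices by cumulative lengths in a fixed
configuration order, so combined feature sets are reproducible.

## Synthetic fixtures (`fixtures`)

Toy complexes place idealized residue templates 25 Å apart on a line and
position small ligand fragments analytically so each requested interaction
type is satisfied with ≥ 0.2–0.3 Å / ≥ 10° margin while no unintended type
fires (e.g. π-stacks sit at 5.0 Å so ring carbons stay outside the 4.5 Å
hydrophobic cutoff; H-bonds sit at 3.2 Å, outside the O···O van der Waals
sum).  A ≤ 0.02 Å seeded jitter makes distinct seeds produce distinct but
equally valid files.  Labeled libraries draw scaffolds from five templates
and plant a positive-defining substituent (a tertiary-amine marker) with a
per-scaffold probability; the observed label is the planted truth XOR a
Bernoulli noise flip from a separately seeded stream.

What passing on fixtures shows: the parsers, geometry, schema construction
and CV plumbing are correct end to end, and the learners can recover a
planted, linearly accessible substructure signal.  What it does not show:
performance on real BBB data — real poses have correlated contacts, real
libraries have scaffold imbalance and label noise far messier than a
Bernoulli flip, and fixture geometry never stresses borderline thresholds.
Benchmark numbers on fixtures are plumbing checks, not permeability claims.

## Problem sizes

The default test and acceptance workloads are sized for a laptop-class
single core: 200-molecule libraries, 50-complex oracle sweeps, 10⁴-sample
dummy-baseline checks, full 39,971-bit enumeration (~10⁵ combination
candidates).  Each completes in seconds; the entire suite runs in well
under a minute.

## Known limitations

* No tautomer canonicalization beyond charge neutralization; tautomers may
  survive deduplication as distinct records.
* Docking itself is out of scope: poses are inputs.  The grid configuration
  object (center 160/145.4/142.88 Å, 40 Å box, matching the P-gp channel
  setup) is carried for an external docking wrapper only.
* No water-mediated or halogen-bond interaction types; the 9-type set is a
  documented convention pinned by the fingerprint width.
* Receptor-side H-bond detection is distance-only (no hydrogens in
  receptor files); expect some over-counting of HBAcceptor events.
* Topological pharmacophores ignore conformation: a pair 8 bonds apart may
  be spatially adjacent in the folded conformer.
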