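"""Molecule library preparation: standardize, filter, deduplicate, embed.

The pipeline mirrors common practice for assembling a QSAR-ready library:

1. parse SMILES, keep the largest organic fragment (salt stripping),
   neutralize formal charges where valence permits, drop stereochemistry,
   and emit canonical SMILES;
2. drop single-heavy-atom entries (noble gases, bare ions, water);
3. group exact/near duplicates by ECFP4 Tanimoto similarity and keep one
   representative per group;
4. generate a 3D conformer and minimize it with MMFF94; molecules that
   cannot be embedded or parameterized are excluded rather than guessed.
"""

from __future__ import annotations

import csv
import logging
from typing import Iterable, Mapping, Optional, Sequence, Union

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem import rdFingerprintGenerator

from .types import BitFingerprint, DedupGroup, MoleculeRecord, Rejection

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

ECFP4_SCHEMA = "ecfp4"


def _standardized_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError("SMILES failed to parse")
    # largest organic fragment, then charge neutralization (MolVS-style)
    mol = rdMolStandardize.LargestFragmentChooser(preferOrganic=True).choose(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    Chem.RemoveStereochemistry(mol)
    Chem.SanitizeMol(mol)
    return mol


def parse_and_standardize(
    smiles: str, mol_id: str = "", label: str = "unknown"
) -> Union[MoleculeRecord, Rejection]:
    """Standardize one SMILES string.

    Returns a :class:`MoleculeRecord` with canonical SMILES, or a
    :class:`Rejection` carrying the parse/standardization error so a batch
    run can keep going.
    """
    if not smiles:
        return Rejection(mol_id, smiles, "empty SMILES")
    try:
        mol = _standardized_mol(smiles)
    except Exception as exc:  # RDKit raises a zoo of exception types
        return Rejection(mol_id, smiles, f"standardization failed: {exc}")
    canonical = Chem.MolToSmiles(mol)
    return MoleculeRecord(
        id=mol_id or canonical,
        smiles_canonical=canonical,
        label=label,  # type: ignore[arg-type]
        provenance=f"standardized from {smiles!r}",
    )


def is_excluded_single_atom(record: MoleculeRecord) -> bool:
    """True iff the standardized molecule has exactly one heavy atom.

    Catches noble gases, bare metals and water, none of which belong in an
    organic drug library.
    """
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:
        raise ValueError(f"record {record.id} does not re-parse")
    return mol.GetNumHeavyAtoms() == 1


def mol_from_record(record: MoleculeRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:
        raise ValueError(f"record {record.id} does not re-parse")
    return mol


def ecfp4(record: MoleculeRecord, nbits: int = 1024) -> BitFingerprint:
    """Extended-connectivity fingerprint, radius 2, hashed to ``nbits``."""
    if nbits <= 0:
        raise ValueError("nbits must be positive")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)
    fp = gen.GetFingerprint(mol_from_record(record))
    return BitFingerprint.from_bits(ECFP4_SCHEMA, nbits, fp.GetOnBits())


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """|A∩B| / |A∪B|; two empty fingerprints are defined as identical (1.0)."""
    if a.length != b.length:
        raise ValueError(f"length mismatch: {a.length} != {b.length}")
    sa, sb = set(a.set_bits), set(b.set_bits)
    union = len(sa | sb)
    if union == 0:
        return 1.0
    return len(sa & sb) / union


def dedup_groups(
    fps: Sequence[tuple[str, BitFingerprint]],
    threshold: float = 1.0,
    smiles_by_id: Optional[Mapping[str, str]] = None,
) -> list[DedupGroup]:
    """Single-linkage grouping of fingerprints with Tanimoto >= threshold.

    The representative of each group is the member with the lexicographically
    smallest canonical SMILES (falling back to the smallest id when no
    SMILES mapping is supplied) — a deterministic stand-in for picking one
    member by eye.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if not fps:
        return []
    ids = [i for i, _ in fps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in input")

    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    if threshold >= 1.0:
        # exact-duplicate fast path: hash on the bit pattern
        by_bits: dict[tuple[int, tuple[int, ...]], str] = {}
        for i, fp in fps:
            key = (fp.length, fp.set_bits)
            if key in by_bits:
                union(i, by_bits[key])
            else:
                by_bits[key] = i
    else:
        for a in range(len(fps)):
            for b in range(a + 1, len(fps)):
                if tanimoto(fps[a][1], fps[b][1]) >= threshold:
                    union(fps[a][0], fps[b][0])

    members: dict[str, list[str]] = {}
    for i in ids:
        members.setdefault(find(i), []).append(i)

    def sort_key(mol_id: str):
        if smiles_by_id is not None and mol_id in smiles_by_id:
            return (smiles_by_id[mol_id], mol_id)
        return (mol_id, mol_id)

    groups = []
    for group_ids in members.values():
        rep = min(group_ids, key=sort_key)
        groups.append(DedupGroup(tuple(sorted(group_ids)), rep))
    groups.sort(key=lambda g: g.member_ids)
    return groups


def embed_and_optimize_3d(
    record: MoleculeRecord, max_steps: int = 5000, seed: int = 0xF00D
) -> Optional[MoleculeRecord]:
    """Embed a conformer (ETKDG) and minimize it with MMFF94.

    Returns the record with its conformer populated, or None when embedding
    or force-field setup fails within ``max_steps`` — such molecules are
    excluded from the 3D library rather than carried with broken geometry.
    """
    try:
        mol = Chem.AddHs(mol_from_record(record))
        params = AllChem.ETKDGv3()
        params.randomSeed = seed
        if AllChem.EmbedMolecule(mol, params) != 0:
            return None
        status = AllChem.MMFFOptimizeMolecule(mol, maxIters=max_steps)
        if status == -1:  # force field could not be parameterized
            return None
        mol = Chem.RemoveHs(mol)
        conf = mol.GetConformer()
        atoms = tuple(
            (
                a.GetSymbol(),
                conf.GetAtomPosition(a.GetIdx()).x,
                conf.GetAtomPosition(a.GetIdx()).y,
                conf.GetAtomPosition(a.GetIdx()).z,
            )
            for a in mol.GetAtoms()
        )
    except Exception as exc:
        logger.warning("3D embedding failed for %s: %s", record.id, exc)
        return None
    return MoleculeRecord(
        id=record.id,
        smiles_canonical=record.smiles_canonical,
        label=record.label,
        conformer=atoms,
        provenance=record.provenance + "; 3D MMFF94",
    )


# ---------------------------------------------------------------------------
# library-level IO


def read_library_csv(path) -> list[tuple[str, str, str]]:
    """Read ``id,smiles,label`` rows; label 1/0/NA -> positive/negative/unknown."""
    label_map = {"1": "positive", "0": "negative", "NA": "unknown", "": "unknown"}
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                (row["id"], row["smiles"], label_map.get(row.get("label", "NA"), "unknown"))
            )
    return rows


def standardize_library(
    rows: Iterable[tuple[str, str, str]],
    dedup_threshold: float = 1.0,
    embed_3d: bool = False,
    seed: int = 0xF00D,
) -> tuple[list[MoleculeRecord], list[tuple[str, str, str]]]:
    """Run the full preparation pipeline over (id, smiles, label) rows.

    Returns the retained records and an audit log of (id, action, reason)
    with one row per exclusion.
    """
    audit: list[tuple[str, str, str]] = []
    records: list[MoleculeRecord] = []
    for mol_id, smiles, label in rows:
        res = parse_and_standardize(smiles, mol_id, label)
        if isinstance(res, Rejection):
            audit.append((res.id, "rejected", res.reason))
            continue
        if is_excluded_single_atom(res):
            audit.append((res.id, "excluded", "single heavy atom"))
            continue
        records.append(res)

    fps = [(r.id, ecfp4(r)) for r in records]
    smiles_by_id = {r.id: r.smiles_canonical for r in records}
    keep = set()
    for group in dedup_groups(fps, threshold=dedup_threshold, smiles_by_id=smiles_by_id):
        keep.add(group.representative_id)
        for m in group.member_ids:
            if m != group.representative_id:
                audit.append((m, "deduplicated", f"duplicate of {group.representative_id}"))
    records = [r for r in records if r.id in keep]

    if embed_3d:
        embedded = []
        for r in records:
            out = embed_and_optimize_3d(r, seed=seed)
            if out is None:
                audit.append((r.id, "neglected", "3D embedding/optimization failed"))
            else:
                embedded.append(out)
        records = embedded
    return records, audit


def write_sdf(records: Sequence[MoleculeRecord], path) -> None:
    """Write records (with conformers when present) to an SDF file."""
    writer = Chem.SDWriter(str(path))
    try:
        for r in records:
            mol = mol_from_record(r)
            if r.conformer is not None:
                mol = Chem.AddHs(mol)
                mol = Chem.RemoveHs(mol)
                conf = Chem.Conformer(mol.GetNumAtoms())
                if mol.GetNumAtoms() != len(r.conformer):
                    raise ValueError(f"conformer atom count mismatch for {r.id}")
                for i, (_, x, y, z) in enumerate(r.conformer):
                    conf.SetAtomPosition(i, (x, y, z))
                mol.AddConformer(conf, assignId=True)
            mol.SetProp("_Name", r.id)
            mol.SetProp("label", r.label)
            writer.write(mol)
    finally:
        writer.close()


def write_audit_csv(audit: Sequence[tuple[str, str, str]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "action", "reason"])
        w.writerows(audit)
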