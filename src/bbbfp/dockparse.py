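"""Receptor/pose parsing and the residue-contact fingerprint.

The residue fingerprint encodes which binding-site residues a docked ligand
touches.  Its schema is built empirically: dock a library of known substrates,
collect the residues within a distance cutoff of any ligand heavy atom, rank
residues by how many distinct ligands contact them, and keep the top k
(k = 62 by default).  A pose is then encoded as a k-bit vector with bit i set
iff schema residue i is contacted.

File handling notes: receptors come as PDB or PDBQT (fixed-width ATOM/HETATM
records; PDBQT adds partial charge and AutoDock atom-type columns), poses as
multi-model PDBQT (Vina output, best pose first) or SDF.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .types import BitFingerprint

#: residue key = (chain, residue_name, residue_number)
ResidueKey = tuple[str, str, int]

RESIDUE_FP_SCHEMA = "residue-contact"

# AutoDock atom types that are NOT ordinary element symbols
_AUTODOCK_ELEMENTS = {
    "A": "C",  # aromatic carbon
    "OA": "O",
    "NA": "N",
    "SA": "S",
    "HD": "H",
    "HS": "H",
    "NS": "N",
    "OS": "O",
    "CL": "Cl",
    "BR": "Br",
}


@dataclass(frozen=True)
class ReceptorAtom:
    serial: int
    atom_name: str
    element: str
    chain: str
    residue_name: str
    residue_number: int
    x: float
    y: float
    z: float
    partial_charge: Optional[float] = None

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain, self.residue_name, self.residue_number)


@dataclass(frozen=True)
class Receptor:
    atoms: tuple[ReceptorAtom, ...]

    def residue_keys(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key)
        return list(seen)

    def heavy_coords_by_residue(self) -> dict[ResidueKey, np.ndarray]:
        groups: dict[ResidueKey, list[list[float]]] = {}
        for a in self.atoms:
            if a.element == "H":
                continue
            groups.setdefault(a.residue_key, []).append([a.x, a.y, a.z])
        return {k: np.asarray(v) for k, v in groups.items()}


@dataclass(frozen=True)
class DockedPose:
    ligand_id: str
    atoms: tuple[tuple[str, float, float, float], ...]
    pose_rank: int = 1  # 1 = best
    score: Optional[float] = None  # kcal/mol

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("pose must contain at least one atom")
        if self.pose_rank < 1:
            raise ValueError("pose_rank must be >= 1")

    def heavy_coords(self) -> np.ndarray:
        pts = [[x, y, z] for (el, x, y, z) in self.atoms if el != "H"]
        if not pts:
            raise ValueError(f"pose {self.ligand_id} has no heavy atoms")
        return np.asarray(pts)


@dataclass(frozen=True)
class ResidueSchema:
    """Fixed, ordered list of residue keys defining fingerprint bit positions."""

    keys: tuple[ResidueKey, ...]

    def __post_init__(self) -> None:
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("schema residue keys must be unique")

    def __len__(self) -> int:
        return len(self.keys)

    def to_json(self) -> str:
        return json.dumps([[c, n, i] for (c, n, i) in self.keys])

    @classmethod
    def from_json(cls, text: str) -> "ResidueSchema":
        return cls(tuple((c, n, int(i)) for (c, n, i) in json.loads(text)))


@dataclass(frozen=True)
class DockingConfig:
    """Grid parameters carried as configuration for an external docking run."""

    center: tuple[float, float, float] = (160.0, 145.4, 142.88)
    box_edge: float = 40.0

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")


# ---------------------------------------------------------------------------
# parsing


class ParseError(ValueError):
    def __init__(self, path, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _element_from_record(line: str, is_pdbqt: bool) -> str:
    if is_pdbqt:
        adtype = line[77:79].strip().upper()
        if adtype in _AUTODOCK_ELEMENTS:
            return _AUTODOCK_ELEMENTS[adtype]
        if adtype:
            return adtype.capitalize()
    el = line[76:78].strip()
    if el:
        return el.capitalize()
    # fall back on the atom name (PDB convention: columns 13-16)
    name = line[12:16].strip()
    if name[:2].upper() in ("CL", "BR"):
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError("cannot infer element")


def _parse_atom_line(line: str, path, line_no: int, is_pdbqt: bool) -> ReceptorAtom:
    try:
        serial = int(line[6:11])
        atom_name = line[12:16].strip()
        chain = line[21].strip() or "A"
        residue_name = line[17:20].strip()
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        charge = None
        if is_pdbqt and len(line) >= 76 and line[70:76].strip():
            charge = float(line[70:76])
        element = _element_from_record(line, is_pdbqt)
    except (ValueError, IndexError) as exc:
        raise ParseError(path, line_no, f"malformed ATOM/HETATM record: {exc}") from None
    if not residue_name:
        raise ParseError(path, line_no, "empty residue name")
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise ParseError(path, line_no, "non-finite coordinates")
    return ReceptorAtom(
        serial, atom_name, element, chain, residue_name, residue_number, x, y, z, charge
    )


def read_receptor(path, drop_waters: bool = True) -> Receptor:
    """Parse a receptor PDB or PDBQT file (ATOM/HETATM records)."""
    is_pdbqt = str(path).lower().endswith(".pdbqt")
    atoms: list[ReceptorAtom] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(path, line_no, "truncated ATOM/HETATM record")
            atom = _parse_atom_line(line, path, line_no, is_pdbqt)
            if drop_waters and atom.residue_name in ("HOH", "WAT"):
                continue
            atoms.append(atom)
    if not atoms:
        raise ParseError(path, 0, "no ATOM/HETATM records found")
    return Receptor(tuple(atoms))


def read_pose_set(path, ligand_id: Optional[str] = None) -> list[DockedPose]:
    """Read docked poses from multi-model PDBQT or SDF; rank = file order."""
    spath = str(path)
    if spath.lower().endswith((".sdf", ".mol")):
        return _read_poses_sdf(path, ligand_id)
    return _read_poses_pdbqt(path, ligand_id)


def _read_poses_pdbqt(path, ligand_id: Optional[str]) -> list[DockedPose]:
    lid = ligand_id or _stem(path)
    poses: list[DockedPose] = []
    atoms: list[tuple[str, float, float, float]] = []
    score: Optional[float] = None
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                in_model, saw_model = True, True
                atoms, score = [], None
            elif line.startswith("ENDMDL"):
                if not atoms:
                    raise ParseError(path, line_no, "MODEL with no atoms")
                poses.append(DockedPose(lid, tuple(atoms), len(poses) + 1, score))
                in_model = False
            elif line.startswith("REMARK VINA RESULT:"):
                try:
                    score = float(line.split(":", 1)[1].split()[0])
                except (ValueError, IndexError):
                    raise ParseError(path, line_no, "unparseable VINA RESULT") from None
            elif line.startswith(("ATOM", "HETATM")):
                a = _parse_atom_line(line, path, line_no, is_pdbqt=True)
                atoms.append((a.element, a.x, a.y, a.z))
    if not saw_model:
        if not atoms:
            raise ParseError(path, 0, "no poses found")
        poses.append(DockedPose(lid, tuple(atoms), 1, score))
    elif in_model:
        raise ParseError(path, 0, "unterminated MODEL block")
    if not poses:
        raise ParseError(path, 0, "no poses found")
    return poses


def _read_poses_sdf(path, ligand_id: Optional[str]) -> list[DockedPose]:
    from rdkit import Chem

    poses = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for mol in supplier:
        if mol is None:
            continue
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
        name = ligand_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else _stem(path))
        score = float(mol.GetProp("score")) if mol.HasProp("score") else None
        poses.append(DockedPose(name, atoms, len(poses) + 1, score))
    if not poses:
        raise ParseError(path, 0, "no poses found")
    return poses


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# ---------------------------------------------------------------------------
# contacts and the residue fingerprint


def contact_residues(
    pose: DockedPose, receptor: Receptor, cutoff: float = 4.0
) -> set[ResidueKey]:
    """Residues with any heavy atom within ``cutoff`` A of any ligand heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = pose.heavy_coords()
    out: set[ResidueKey] = set()
    for key, coords in receptor.heavy_coords_by_residue().items():
        d2 = ((coords[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
        if (d2 <= cutoff * cutoff).any():
            out.add(key)
    return out


def residue_frequency(
    contacts: Iterable[tuple[str, set[ResidueKey]]]
) -> dict[ResidueKey, int]:
    """Count, per residue, the number of *distinct ligands* contacting it."""
    per_ligand: dict[str, set[ResidueKey]] = {}
    n = 0
    for ligand_id, keys in contacts:
        n += 1
        per_ligand.setdefault(ligand_id, set()).update(keys)
    if n == 0:
        raise ValueError("need at least one contact record")
    freq: dict[ResidueKey, int] = {}
    for keys in per_ligand.values():
        for k in keys:
            freq[k] = freq.get(k, 0) + 1
    return freq


def build_residue_schema(freq: Mapping[ResidueKey, int], k: int = 62) -> ResidueSchema:
    """Top-k residues by descending contact count.

    Ties break by (chain, residue_number) ascending.  When fewer than k
    residues were ever contacted the schema is simply shorter (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not freq:
        raise ValueError("empty frequency map")
    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][2], kv[0][1]))
    keys = tuple(key for key, _ in ranked[:k])
    if len(keys) < k:
        import logging

        logging.getLogger(__name__).warning(
            "only %d residues observed; schema shorter than k=%d", len(keys), k
        )
    return ResidueSchema(keys)


def residue_fingerprint(
    pose: DockedPose,
    receptor: Receptor,
    schema: ResidueSchema,
    cutoff: float = 4.0,
) -> BitFingerprint:
    """k-bit vector: bit i set iff schema residue i is contacted by the pose."""
    if len(schema) == 0:
        raise ValueError("schema must be nonempty")
    touched = contact_residues(pose, receptor, cutoff)
    bits = [i for i, key in enumerate(schema.keys) if key in touched]
    return BitFingerprint.from_bits(RESIDUE_FP_SCHEMA, len(schema), bits)


def fingerprints_to_csv(
    fps: Sequence[tuple[str, BitFingerprint]], path, sparse: bool = True
) -> None:
    """Write fingerprints as CSV; sparse form is ``ligand_id,set_bits``."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if sparse:
            w.writerow(["ligand_id", "schema", "length", "set_bits"])
            for lid, fp in fps:
                w.writerow([lid, fp.schema_id, fp.length, " ".join(map(str, fp.set_bits))])
        else:
            if not fps:
                return
            n = fps[0][1].length
            w.writerow(["ligand_id"] + [f"bit_{i}" for i in range(n)])
            for lid, fp in fps:
                w.writerow([lid] + list(fp.to_dense()))


def fingerprints_from_csv(path) -> list[tuple[str, BitFingerprint]]:
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            bits = [int(b) for b in row["set_bits"].split()] if row["set_bits"] else []
            out.append(
                (
                    row["ligand_id"],
                    BitFingerprint.from_bits(row["schema"], int(row["length"]), bits),
                )
            )
    return out
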