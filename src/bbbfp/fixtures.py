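"""Deterministic synthetic test data: toy complexes, contacts, libraries.

Nothing here is physically realistic — receptors are idealized residues on
a widely spaced line, poses are small ligand fragments placed analytically
so that each requested interaction type is realized with a comfortable
geometric margin (>= 0.2 A / 10 deg) while no *other* type fires.  That is
the point: every generated artifact carries machine-readable ground truth,
so the parsing, contact and interaction-typing code paths can be tested
end to end without any external structure or database.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import RWMol
from rdkit.Geometry import Point3D

from .chemprep import parse_and_standardize
from .dockparse import ResidueKey
from .types import MoleculeRecord

# ---------------------------------------------------------------------------
# residue templates (idealized local geometry, Angstrom)

_BACKBONE = [
    ("N", "N", (-1.46, 0.0, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (0.53, 1.42, 0.0)),
    ("O", "O", (1.74, 1.58, 0.0)),
]


def _phe_ring() -> list[tuple[str, str, tuple[float, float, float]]]:
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    cx, cy, cz, r = 0.0, -0.9, 3.4, 1.39
    out = []
    for i, n in enumerate(names):
        a = math.radians(60.0 * i)
        out.append((n, "C", (cx + r * math.cos(a), cy + r * math.sin(a), cz)))
    return out


_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": list(_BACKBONE),
    "ALA": _BACKBONE + [("CB", "C", (-0.50, -0.77, 1.21))],
    "SER": _BACKBONE + [("CB", "C", (-0.50, -0.77, 1.21)), ("OG", "O", (-0.05, -0.25, 2.40))],
    "LEU": _BACKBONE
    + [
        ("CB", "C", (-0.56, -0.77, 1.21)),
        ("CG", "C", (-0.06, -0.26, 2.56)),
        ("CD1", "C", (1.44, -0.40, 2.66)),
        ("CD2", "C", (-0.70, -1.02, 3.70)),
    ],
    "ASP": _BACKBONE
    + [
        ("CB", "C", (-0.50, -0.77, 1.21)),
        ("CG", "C", (-0.04, -0.24, 2.57)),
        ("OD1", "O", (1.17, -0.08, 2.78)),
        ("OD2", "O", (-0.83, 0.40, 3.32)),
    ],
    "LYS": _BACKBONE
    + [
        ("CB", "C", (-0.50, -0.77, 1.21)),
        ("CG", "C", (0.00, -0.30, 2.56)),
        ("CD", "C", (-0.60, -1.00, 3.73)),
        ("CE", "C", (-0.10, -0.55, 5.07)),
        ("NZ", "N", (-0.70, -1.25, 6.20)),
    ],
    "PHE": _BACKBONE + [("CB", "C", (-0.50, -0.77, 1.21))] + _phe_ring(),
}

#: residue used to realize each interaction type
_TYPE_RESIDUE = {
    "Hydrophobic": "LEU",
    "HBDonor": "ALA",
    "HBAcceptor": "SER",
    "Cationic": "ASP",
    "Anionic": "LYS",
    "CationPi": "PHE",
    "PiCation": "LYS",
    "PiStacking": "PHE",
    "VdWContact": "ALA",
}

_SPACING = 25.0  # A between pocket residues; far beyond every cutoff


@dataclass(frozen=True)
class ComplexSpec:
    """Requested interaction types for one synthetic complex."""

    interaction_types: tuple[str, ...] = ()
    seed: int = 0
    ligand_id: str = "toy_ligand"

    def __post_init__(self) -> None:
        for t in self.interaction_types:
            if t not in _TYPE_RESIDUE:
                raise ValueError(f"cannot construct interaction type {t}")


def _pdb_line(serial, name, resname, chain, resnum, x, y, z, element) -> str:
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


class _LigandBuilder:
    """Accumulates disconnected ligand fragments into one RDKit mol."""

    def __init__(self) -> None:
        self.mol = RWMol()
        self.coords: list[tuple[float, float, float]] = []

    def add_fragment(self, atoms, bonds) -> list[int]:
        """atoms: (symbol, charge, (x,y,z)); bonds: (i, j, order) local indices."""
        base = self.mol.GetNumAtoms()
        for sym, charge, xyz in atoms:
            a = Chem.Atom(sym)
            if charge:
                a.SetFormalCharge(charge)
            if sym == "H":
                a.SetNoImplicit(True)
            self.mol.AddAtom(a)
            self.coords.append(tuple(xyz))
        order_map = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
        }
        for i, j, order in bonds:
            self.mol.AddBond(base + i, base + j, order_map[order])
        return list(range(base, self.mol.GetNumAtoms()))

    def to_molblock(self, name: str) -> str:
        mol = self.mol.GetMol()
        Chem.SanitizeMol(mol)
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, (x, y, z) in enumerate(self.coords):
            conf.SetAtomPosition(i, Point3D(x, y, z))
        mol.AddConformer(conf)
        mol.SetProp("_Name", name)
        return Chem.MolToMolBlock(mol)


def _place_fragment(builder: _LigandBuilder, itype: str,
                    template_atoms: dict[str, np.ndarray], jit: np.ndarray) -> None:
    """Place the ligand fragment realizing one interaction type.

    ``template_atoms`` maps atom names of the host residue to absolute
    coordinates; ``jit`` is a small (<=0.05 A) deterministic jitter.
    """
    up = np.array([0.0, 0.0, 1.0])
    if itype == "Hydrophobic":
        p = template_atoms["CD1"] + np.array([0.0, 0.0, 4.0]) + jit
        builder.add_fragment([("C", 0, p)], [])
    elif itype == "HBDonor":
        acc = template_atoms["O"]
        u = np.array([1.0, 0.0, 0.0])
        o = acc + 3.2 * u + jit
        h = o - 0.96 * u
        c = o + 1.40 * u
        builder.add_fragment(
            [("O", 0, o), ("H", 0, h), ("C", 0, c)], [(0, 1, 1), (0, 2, 1)]
        )
    elif itype == "HBAcceptor":
        og = template_atoms["OG"]
        o = og + 3.2 * up + jit
        c1 = o + np.array([1.26, 0.0, 0.75])
        c2 = o + np.array([-1.26, 0.0, 0.75])
        builder.add_fragment(
            [("O", 0, o), ("C", 0, c1), ("C", 0, c2)], [(0, 1, 1), (0, 2, 1)]
        )
    elif itype == "Cationic":
        od1, od2, cg = template_atoms["OD1"], template_atoms["OD2"], template_atoms["CG"]
        mid = 0.5 * (od1 + od2)
        n = mid - cg
        n = n / np.linalg.norm(n)
        p = mid + 4.2 * n + jit
        builder.add_fragment([("N", 1, p)], [])
    elif itype == "Anionic":
        nz = template_atoms["NZ"]
        o1 = nz + 4.0 * up + jit
        c2 = o1 + np.array([0.0, 1.15, 0.50])
        o3 = c2 + np.array([1.05, 0.65, 0.0])
        c4 = c2 + np.array([-0.85, 0.95, 1.00])
        builder.add_fragment(
            [("O", -1, o1), ("C", 0, c2), ("O", 0, o3), ("C", 0, c4)],
            [(0, 1, 1), (1, 2, 2), (1, 3, 1)],
        )
    elif itype == "CationPi":
        ring = [template_atoms[n] for n in ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")]
        centroid = np.mean(ring, axis=0)
        p = centroid + 4.0 * up + jit * 0.0  # keep exactly on the ring axis
        builder.add_fragment([("N", 1, p)], [])
    elif itype == "PiCation":
        nz = template_atoms["NZ"]
        centroid = nz + 4.0 * up
        _add_benzene(builder, centroid)
    elif itype == "PiStacking":
        ring = [template_atoms[n] for n in ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")]
        centroid = np.mean(ring, axis=0) + 5.0 * up
        _add_benzene(builder, centroid)
    elif itype == "VdWContact":
        cb = template_atoms["CB"]
        o = cb + 2.9 * up + jit
        c1 = o + np.array([1.26, 0.0, 0.75])
        c2 = o + np.array([-1.26, 0.0, 0.75])
        builder.add_fragment(
            [("O", 0, o), ("C", 0, c1), ("C", 0, c2)], [(0, 1, 1), (0, 2, 1)]
        )
    else:  # pragma: no cover
        raise ValueError(itype)


def _add_benzene(builder: _LigandBuilder, centroid: np.ndarray) -> None:
    atoms = []
    for i in range(6):
        a = math.radians(60.0 * i)
        atoms.append(
            ("C", 0, centroid + 1.39 * np.array([math.cos(a), math.sin(a), 0.0]))
        )
    bonds = [(i, (i + 1) % 6, 1 if i % 2 else 2) for i in range(6)]
    builder.add_fragment(atoms, bonds)


def make_toy_complex(
    spec: ComplexSpec,
) -> tuple[str, str, list[tuple[str, ResidueKey]]]:
    """Build (receptor PDB text, pose SDF text, ground-truth event types).

    The ground truth lists exactly the (type, residue) contacts the
    geometry realizes; detection on the parsed files must reproduce the
    type set exactly.
    """
    rng = random.Random(spec.seed)
    pdb_lines = []
    truth: list[tuple[str, ResidueKey]] = []
    builder = _LigandBuilder()
    serial = 1

    # a default pocket even when no interactions are requested
    pocket = list(spec.interaction_types) or ["__empty__"]
    resnum = 0
    for slot, itype in enumerate(pocket):
        resname = _TYPE_RESIDUE.get(itype, "GLY")
        resnum += 1
        offset = np.array([_SPACING * slot, 0.0, 0.0])
        placed: dict[str, np.ndarray] = {}
        for name, element, xyz in _TEMPLATES[resname]:
            p = np.asarray(xyz) + offset
            placed[name] = p
            pdb_lines.append(
                _pdb_line(serial, name, resname, "A", resnum, p[0], p[1], p[2], element)
            )
            serial += 1
        if itype != "__empty__":
            jit = np.array(
                [rng.uniform(-0.02, 0.02), rng.uniform(-0.02, 0.02), 0.0]
            )
            _place_fragment(builder, itype, placed, jit)
            truth.append((itype, ("A", resname, resnum)))

    if not spec.interaction_types:
        # inert ligand parked far from the pocket
        builder.add_fragment([("C", 0, np.array([-20.0, 0.0, 0.0]))], [])

    pdb_text = "\n".join(pdb_lines + ["END"]) + "\n"
    sdf_text = builder.to_molblock(spec.ligand_id) + "$$$$\n"
    return pdb_text, sdf_text, truth


# ---------------------------------------------------------------------------
# substrate-contact records


def make_substrate_contacts(
    n_substrates: int,
    residue_pool: Sequence[ResidueKey],
    seed: int = 0,
    p_contact: float = 0.5,
) -> tuple[list[tuple[str, set[ResidueKey]]], dict[ResidueKey, int]]:
    """Random per-substrate residue contact sets plus the true frequency table."""
    if n_substrates < 1:
        raise ValueError("need at least one substrate")
    rng = random.Random(seed)
    records: list[tuple[str, set[ResidueKey]]] = []
    freq: dict[ResidueKey, int] = {}
    for i in range(n_substrates):
        touched = {r for r in residue_pool if rng.random() < p_contact}
        if not touched:  # guarantee at least one contact per substrate
            touched = {residue_pool[rng.randrange(len(residue_pool))]}
        records.append((f"sub_{i:03d}", touched))
        for r in touched:
            freq[r] = freq.get(r, 0) + 1
    return records, freq


# ---------------------------------------------------------------------------
# labeled molecule libraries

#: scaffold templates with one substitution site
DEFAULT_SCAFFOLD_TEMPLATES = (
    "c1ccc({r})cc1",          # benzene
    "c1ccnc({r})c1",          # pyridine
    "C1CCC({r})CC1",          # cyclohexane
    "c1ccc2cc({r})ccc2c1",    # naphthalene
    "C1CN({r})CCN1",          # piperazine
)

#: substituent whose presence defines the planted positive class
MARKER_SUBSTITUENT = "CCN(C)C"

_DECOY_SUBSTITUENTS = ("C", "CC", "O", "OC", "F", "Cl", "C(C)C", "CCO")


@dataclass(frozen=True)
class LibrarySpec:
    n: int = 200
    scaffold_templates: tuple[str, ...] = DEFAULT_SCAFFOLD_TEMPLATES
    #: per-scaffold probability of drawing the marker (=> positive) substituent
    pos_fraction: tuple[float, ...] | float = 0.5
    noise_rate: float = 0.0
    seed: int = 0
    #: separate stream for label flips so the same library can be re-noised
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_rate < 0.5):
            raise ValueError("noise rate must lie in [0, 0.5)")
        if self.n < 1:
            raise ValueError("n must be positive")


def make_labeled_library(spec: LibrarySpec) -> tuple[list[MoleculeRecord], dict]:
    """Generate a labeled SMILES library with planted substructure signal.

    A molecule is truly positive iff it carries the marker substituent;
    the observed label is the truth XOR a Bernoulli(noise_rate) flip.
    Ground truth records the scaffold template, true label and flip mask
    per molecule.
    """
    rng = random.Random(spec.seed)
    rng_noise = random.Random(spec.seed if spec.noise_seed is None else spec.noise_seed)
    if isinstance(spec.pos_fraction, float):
        pos_frac = [spec.pos_fraction] * len(spec.scaffold_templates)
    else:
        pos_frac = list(spec.pos_fraction)
        if len(pos_frac) != len(spec.scaffold_templates):
            raise ValueError("pos_fraction length must match scaffold pool")

    records: list[MoleculeRecord] = []
    truth: dict = {"molecules": {}, "templates": list(spec.scaffold_templates)}
    for i in range(spec.n):
        t = rng.randrange(len(spec.scaffold_templates))
        positive = rng.random() < pos_frac[t]
        if positive:
            sub = MARKER_SUBSTITUENT
        else:
            sub = _DECOY_SUBSTITUENTS[rng.randrange(len(_DECOY_SUBSTITUENTS))]
        smiles = spec.scaffold_templates[t].format(r=sub)
        flip = rng_noise.random() < spec.noise_rate
        label = positive ^ flip
        mol_id = f"mol_{i:04d}"
        rec = parse_and_standardize(
            smiles, mol_id, "positive" if label else "negative"
        )
        if not isinstance(rec, MoleculeRecord):  # pragma: no cover
            raise RuntimeError(f"generator produced invalid SMILES {smiles}")
        records.append(rec)
        truth["molecules"][mol_id] = {
            "template_index": t,
            "true_positive": positive,
            "flipped": flip,
            "smiles": smiles,
        }
    return records, truth


def library_to_csv(records: Sequence[MoleculeRecord], path) -> None:
    import csv

    lab = {"positive": "1", "negative": "0", "unknown": "NA"}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "label"])
        for r in records:
            w.writerow([r.id, r.smiles_canonical, lab[r.label]])


def truth_to_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
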