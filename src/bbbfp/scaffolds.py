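"""Bemis-Murcko scaffold decomposition and permeability categorization.

A molecule's Murcko scaffold is its ring systems plus the acyclic linkers
connecting them, with all terminal side chains removed.  Grouping a labeled
library by scaffold and computing the fraction of BBB-permeable members per
group gives a per-scaffold permeation probability, categorized as

* permeable      when probability > 0.6,
* non_permeable  when probability < 0.4,
* neutral        on the closed interval [0.4, 0.6].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chemprep import mol_from_record
from .types import ACYCLIC, MoleculeRecord

Category = Literal["permeable", "neutral", "non_permeable"]

PERMEABLE_ABOVE = 0.6
NON_PERMEABLE_BELOW = 0.4


@dataclass(frozen=True)
class ScaffoldGroup:
    scaffold_smiles: str  # canonical SMILES or the ACYCLIC sentinel
    member_ids: tuple[str, ...]
    n_pos: int
    n_neg: int

    @property
    def probability(self) -> float | None:
        """Positive fraction over labeled members; None when none are labeled."""
        denom = self.n_pos + self.n_neg
        return self.n_pos / denom if denom else None

    @property
    def category(self) -> Category | None:
        p = self.probability
        return None if p is None else categorize_scaffold(p)


def murcko_scaffold(record: MoleculeRecord) -> str:
    """Canonical SMILES of the Murcko scaffold, or ACYCLIC for ring-free input."""
    mol = mol_from_record(record)
    if mol.GetRingInfo().NumRings() == 0:
        return ACYCLIC
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ACYCLIC
    return Chem.MolToSmiles(scaffold)


def categorize_scaffold(probability: float) -> Category:
    if not (0.0 <= probability <= 1.0):
        raise ValueError("probability must lie in [0, 1]")
    if probability > PERMEABLE_ABOVE:
        return "permeable"
    if probability < NON_PERMEABLE_BELOW:
        return "non_permeable"
    return "neutral"


def group_by_scaffold(
    records: Sequence[MoleculeRecord],
) -> tuple[list[ScaffoldGroup], list[str]]:
    """Group records by canonical scaffold SMILES.

    Returns (groups, acyclic_ids).  Acyclic molecules are collected
    separately and excluded from scaffold statistics.
    """
    by_scaffold: dict[str, list[MoleculeRecord]] = {}
    acyclic: list[str] = []
    for r in records:
        s = murcko_scaffold(r)
        if s == ACYCLIC:
            acyclic.append(r.id)
        else:
            by_scaffold.setdefault(s, []).append(r)
    groups = []
    for smiles in sorted(by_scaffold):
        members = by_scaffold[smiles]
        n_pos = sum(1 for m in members if m.label == "positive")
        n_neg = sum(1 for m in members if m.label == "negative")
        groups.append(
            ScaffoldGroup(smiles, tuple(sorted(m.id for m in members)), n_pos, n_neg)
        )
    groups.sort(key=lambda g: (-len(g.member_ids), g.scaffold_smiles))
    return groups, sorted(acyclic)


def scaffold_summary(groups: Sequence[ScaffoldGroup], top_k: int = 10) -> dict:
    """Group count, singleton fraction, per-category counts, top-k by size."""
    if not groups:
        raise ValueError("need at least one scaffold group")
    n = len(groups)
    singleton = sum(1 for g in groups if len(g.member_ids) == 1)
    cats = {"permeable": 0, "neutral": 0, "non_permeable": 0, "unlabeled": 0}
    for g in groups:
        cats[g.category or "unlabeled"] += 1
    biggest = sorted(groups, key=lambda g: (-len(g.member_ids), g.scaffold_smiles))[:top_k]
    return {
        "n_groups": n,
        "singleton_fraction": singleton / n,
        "category_counts": cats,
        "top_groups": [(g.scaffold_smiles, len(g.member_ids)) for g in biggest],
    }


def scaffold_table(groups: Sequence[ScaffoldGroup]) -> pd.DataFrame:
    """Long-form scaffold report: one row per scaffold group."""
    return pd.DataFrame(
        {
            "scaffold_smiles": [g.scaffold_smiles for g in groups],
            "n_members": [len(g.member_ids) for g in groups],
            "n_pos": [g.n_pos for g in groups],
            "n_neg": [g.n_neg for g in groups],
            "probability": [g.probability for g in groups],
            "category": [g.category for g in groups],
        }
    )
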