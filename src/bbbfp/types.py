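"""Core value types shared across the fingerprint pipeline.

Everything here is a plain, hashable-ish dataclass: molecules with an
optional 3D conformer and a binary permeation label, schema-tagged sparse
bitvectors, and the small record types the docking and benchmarking layers
exchange.  Heavier chemistry objects (RDKit mols, receptor structures) live
in their own modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

Label = Literal["positive", "negative", "unknown"]

#: Sentinel scaffold value for molecules without any ring system.
ACYCLIC = "ACYCLIC"


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized molecule: canonical SMILES plus optional conformer/label."""

    id: str
    smiles_canonical: str
    label: Label = "unknown"
    #: list of (element, x, y, z) in Angstrom, or None when no 3D structure.
    conformer: Optional[tuple[tuple[str, float, float, float], ...]] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.conformer is not None:
            if len(self.conformer) == 0:
                raise ValueError("conformer must contain at least one atom")
            for (_, x, y, z) in self.conformer:
                if not all(map(_finite, (x, y, z))):
                    raise ValueError("conformer coordinates must be finite")


@dataclass(frozen=True)
class Rejection:
    """A molecule that could not be standardized; keeps batches alive."""

    id: str
    input_smiles: str
    reason: str


def _finite(v: float) -> bool:
    return v == v and abs(v) != float("inf")


@dataclass(frozen=True)
class BitFingerprint:
    """Schema-tagged sparse bitvector.

    ``set_bits`` is a strictly increasing tuple of indices in ``[0, length)``.
    """

    schema_id: str
    length: int
    set_bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("fingerprint length must be positive")
        prev = -1
        for b in self.set_bits:
            if not (0 <= b < self.length):
                raise ValueError(f"bit {b} outside [0, {self.length})")
            if b <= prev:
                raise ValueError("set_bits must be strictly increasing")
            prev = b

    @classmethod
    def from_bits(cls, schema_id: str, length: int, bits: Sequence[int]) -> "BitFingerprint":
        return cls(schema_id, length, tuple(sorted(set(int(b) for b in bits))))

    def to_dense(self):
        import numpy as np

        v = np.zeros(self.length, dtype=np.uint8)
        if self.set_bits:
            v[list(self.set_bits)] = 1
        return v


@dataclass(frozen=True)
class DedupGroup:
    """One similarity group from deduplication; representative is a member."""

    member_ids: tuple[str, ...]
    representative_id: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("group must be nonempty")
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a group member")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Accuracy/precision/recall/F1/MCC (+ optional AUROC) for one evaluation.

    Metrics whose denominator vanished are reported as 0.0 and listed in
    ``degenerate``.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auroc: Optional[float] = None
    degenerate: tuple[str, ...] = field(default_factory=tuple)
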