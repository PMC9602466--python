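"""Ligand-based 2-point/3-point topological pharmacophore fingerprint.

A molecule is abstracted into pharmacophoric features from six families —
hydrogen-bond donor (HD), acceptor (HA), aromatic ring (AR), hydrophobe
(HY), basic group (BG), acidic group (AG) — and every pair and triangle of
features, with inter-feature distances measured as shortest bond-path
lengths and discretized into bins, sets one bit of a fixed combinatorial
bit space.

The bit space enumerates every admissible combination exactly once:
combinations are canonicalized under the symmetry of the triangle (the
family tuple is sorted; the distance assignment is reduced to a canonical
representative of its orbit), and binned triangles must admit a geometric
realization (the binned triangle inequality: the smallest value of the
largest bin must not exceed the sum of the largest values of the other
two).  Under the default schema — 6 families and 13 contiguous topological
distance bins — exhaustive enumeration yields 273 pair bits + 39,698
triangle bits = 39,971 bits.  The bin edges are calibrated so the
enumeration lands exactly on that total; they are carried, with the family
SMARTS, in a versioned package data file so the schema is reproducible
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from itertools import combinations, permutations, product
from typing import Optional, Sequence

from rdkit import Chem

from .types import BitFingerprint

PHARM2D_SCHEMA_ID = "pharm2d-v1"

_INF = float("inf")
_SCHEMA_CACHE: list = []


@dataclass(frozen=True)
class PharmFeature:
    family: str
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise ValueError("feature must cover at least one atom")


@dataclass(frozen=True)
class Pharm2DSchema:
    """Feature families, SMARTS, distance bins and the bit-index bijection."""

    families: tuple[str, ...]
    smarts: dict[str, tuple[str, ...]]
    #: inclusive integer bond-count ranges; upper bound None = unbounded
    bins: tuple[tuple[int, Optional[int]], ...]
    total_bits: int
    min_points: int = 2
    max_points: int = 3

    def bin_of(self, distance: int) -> Optional[int]:
        """Bin index for an integer bond-path distance, or None if below range."""
        for i, (lo, hi) in enumerate(self.bins):
            if distance >= lo and (hi is None or distance <= hi):
                return i
        return None

    def _bin_hi(self, b: int) -> float:
        hi = self.bins[b][1]
        return _INF if hi is None else float(hi)

    def triangle_ok(self, d: tuple[int, int, int]) -> bool:
        """Binned triangle filter: the three bins must admit real distances
        forming a triangle (min of the largest bin <= sum of the maxima of
        the other two)."""
        s = sorted(d, key=lambda b: self.bins[b][0])
        return self.bins[s[2]][0] <= self._bin_hi(s[0]) + self._bin_hi(s[1])

    def canonical_pair(self, fams: tuple[int, int], b: int) -> tuple:
        return (tuple(sorted(fams)), (b,))

    def canonical_triplet(
        self, fams: tuple[int, int, int], d: tuple[int, int, int]
    ) -> tuple:
        """Orbit-canonical form of a family-labeled triangle.

        ``d = (d12, d13, d23)`` are bin indices for the edges between
        vertices (1,2), (1,3), (2,3).  Vertex permutations act jointly on
        families and edges; the representative is the lexicographic minimum.
        """
        best = None
        for p in permutations((0, 1, 2)):
            fp = (fams[p[0]], fams[p[1]], fams[p[2]])
            dp = (_edge(d, p, 0, 1), _edge(d, p, 0, 2), _edge(d, p, 1, 2))
            cand = (fp, dp)
            if best is None or cand < best:
                best = cand
        return best

    def _index_table(self) -> dict[tuple, int]:
        # lazy per-instance cache (the dataclass is frozen, so go via object)
        cached = getattr(self, "_table_cache", None)
        if cached is None:
            cached = {c: i for i, c in enumerate(self._enumerate_combinations())}
            object.__setattr__(self, "_table_cache", cached)
        return cached

    def _enumerate_combinations(self):
        """Deterministically ordered, duplicate-free list of admissible combos.

        Pairs come first (sorted family pair x bin), then triangles in
        lexicographic order of their canonical representative.  Triangle
        representatives are generated directly from the symmetry class of
        the family multiset, which makes the enumeration a bijection by
        construction.
        """
        nf, nb = len(self.families), len(self.bins)
        if self.min_points <= 2 <= self.max_points:
            for f1 in range(nf):
                for f2 in range(f1, nf):
                    for b in range(nb):
                        yield ((f1, f2), (b,))
        if self.max_points < 3:
            return
        for f1 in range(nf):
            for f2 in range(f1, nf):
                for f3 in range(f2, nf):
                    for d in product(range(nb), repeat=3):
                        if not self._is_canonical_dist((f1, f2, f3), d):
                            continue
                        if not self.triangle_ok(d):
                            continue
                        yield ((f1, f2, f3), d)

    @staticmethod
    def _is_canonical_dist(fams: tuple[int, int, int], d: tuple[int, int, int]) -> bool:
        f1, f2, f3 = fams
        d12, d13, d23 = d
        if f1 == f2 == f3:
            return d12 <= d13 <= d23
        if f1 == f2:  # swapping vertices 1,2 maps d13 <-> d23
            return d13 <= d23
        if f2 == f3:  # swapping vertices 2,3 maps d12 <-> d13
            return d12 <= d13
        return True

    def bit_index(self, combo: tuple) -> int:
        return self._index_table()[combo]

    def compiled_smarts(self) -> dict[str, tuple[Chem.Mol, ...]]:
        cached = getattr(self, "_smarts_cache", None)
        if cached is None:
            cached = {
                fam: tuple(Chem.MolFromSmarts(s) for s in patterns)
                for fam, patterns in self.smarts.items()
            }
            object.__setattr__(self, "_smarts_cache", cached)
        return cached


def _edge(d: tuple[int, int, int], p, a: int, b: int) -> int:
    u, v = sorted((p[a], p[b]))
    return d[{(0, 1): 0, (0, 2): 1, (1, 2): 2}[(u, v)]]


def default_schema() -> Pharm2DSchema:
    """The bundled, calibrated schema (6 families, 13 bins, 39,971 bits).

    The instance is shared (it is immutable and caches its index table).
    """
    if not _SCHEMA_CACHE:
        _SCHEMA_CACHE.append(_load_default_schema())
    return _SCHEMA_CACHE[0]


def _load_default_schema() -> Pharm2DSchema:
    raw = json.loads(
        resources.files("bbbfp.data").joinpath("pharm_families.json").read_text()
    )
    return Pharm2DSchema(
        families=tuple(raw["families"]),
        smarts={k: tuple(v) for k, v in raw["smarts"].items()},
        bins=tuple((lo, hi) for lo, hi in raw["bins"]),
        total_bits=int(raw["total_bits"]),
    )


def enumerate_bit_space(schema: Pharm2DSchema) -> int:
    """Exhaustively count admissible combinations; must equal total_bits."""
    n = sum(1 for _ in schema._enumerate_combinations())
    if n != schema.total_bits:
        raise ValueError(
            f"schema inconsistent: enumerated {n} combinations, "
            f"declared total_bits {schema.total_bits}"
        )
    return n


def detect_pharm_features(
    mol: Chem.Mol, schema: Optional[Pharm2DSchema] = None
) -> list[PharmFeature]:
    """SMARTS-driven feature perception on the 2D molecular graph.

    Overlapping matches from different families are kept; duplicate matches
    of one family on an identical atom set are collapsed.
    """
    schema = schema or default_schema()
    feats: list[PharmFeature] = []
    seen: set[tuple[str, frozenset[int]]] = set()
    for fam in schema.families:
        for patt in schema.compiled_smarts()[fam]:
            for match in mol.GetSubstructMatches(patt):
                key = (fam, frozenset(match))
                if key in seen:
                    continue
                seen.add(key)
                feats.append(PharmFeature(fam, tuple(sorted(match))))
    return feats


def _feature_distance(dm, a: PharmFeature, b: PharmFeature) -> int:
    """Shortest topological path between two features' atom sets."""
    return int(min(dm[i][j] for i in a.atom_indices for j in b.atom_indices))


def molecule_bits(
    features: Sequence[PharmFeature],
    mol: Chem.Mol,
    schema: Optional[Pharm2DSchema] = None,
) -> BitFingerprint:
    """Set one bit per admissible 2- and 3-point feature combination.

    Feature instances with identical atom sets never form a combination
    (their distance is 0, below the lowest bin edge) and are dropped, as
    are binned triangles failing the triangle filter.
    """
    schema = schema or default_schema()
    fam_idx = {f: i for i, f in enumerate(schema.families)}
    for f in features:
        if any(i >= mol.GetNumAtoms() for i in f.atom_indices):
            raise ValueError("feature references an invalid atom index")
    dm = Chem.GetDistanceMatrix(mol)
    bits: set[int] = set()

    for a, b in combinations(features, 2):
        d = _feature_distance(dm, a, b)
        bb = schema.bin_of(d)
        if bb is None:
            continue
        combo = schema.canonical_pair((fam_idx[a.family], fam_idx[b.family]), bb)
        bits.add(schema.bit_index(combo))

    for a, b, c in combinations(features, 3):
        b12 = schema.bin_of(_feature_distance(dm, a, b))
        b13 = schema.bin_of(_feature_distance(dm, a, c))
        b23 = schema.bin_of(_feature_distance(dm, b, c))
        if b12 is None or b13 is None or b23 is None:
            continue
        d = (b12, b13, b23)
        if not schema.triangle_ok(d):
            continue
        fams = (fam_idx[a.family], fam_idx[b.family], fam_idx[c.family])
        combo = schema.canonical_triplet(fams, d)
        bits.add(schema.bit_index(combo))

    return BitFingerprint.from_bits(PHARM2D_SCHEMA_ID, schema.total_bits, bits)


def pharm_fingerprint(mol: Chem.Mol, schema: Optional[Pharm2DSchema] = None) -> BitFingerprint:
    """Convenience: perceive features and fingerprint in one call."""
    schema = schema or default_schema()
    return molecule_bits(detect_pharm_features(mol, schema), mol, schema)
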