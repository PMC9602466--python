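"""Feature perception, geometric interaction typing, and the 9-bit FP."""

import math
import random

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from bbbfp import interactions as ia
from bbbfp.interactions import (
    AromaticRing,
    ChemFeatureSet,
    DonorPoint,
    FeaturePoint,
    GeometryThresholds,
    InteractionEvent,
)


def _mol3d(smiles):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 7
    AllChem.EmbedMolecule(mol, params)
    return mol


class TestLigandPerception:
    def test_ethylammonium(self):
        f = ia.perceive_ligand_features(_mol3d("CC[NH3+]"))
        assert len(f.cations) == 1
        assert len(f.donors) == 1
        assert len(f.rings) == 0
        assert len(f.anions) == 0

    def test_benzene(self):
        f = ia.perceive_ligand_features(_mol3d("c1ccccc1"))
        assert len(f.rings) == 1 and len(f.rings[0].members) == 6
        assert len(f.hydrophobic) == 6
        assert len(f.donors) == 0 and len(f.acceptors) == 0
        assert np.linalg.norm(f.rings[0].n) == pytest.approx(1.0)

    def test_acetate(self):
        f = ia.perceive_ligand_features(_mol3d("CC(=O)[O-]"))
        assert len(f.anions) == 1
        assert len(f.acceptors) == 2  # carbonyl O and charged O
        assert len(f.cations) == 0

    def test_requires_coordinates(self):
        with pytest.raises(ValueError):
            ia.perceive_ligand_features(Chem.MolFromSmiles("CCO"))


class TestResidueTemplates:
    def _features(self, types, seed=0):
        from bbbfp import dockparse as dp
        from bbbfp import fixtures as fx

        pdb, _, _ = fx.make_toy_complex(fx.ComplexSpec(types, seed=seed))
        import io, tempfile, os

        with tempfile.TemporaryDirectory() as d:
            p = os.path.join(d, "r.pdb")
            open(p, "w").write(pdb)
            return ia.perceive_residue_features(dp.read_receptor(p))

    def test_asp_anion_on_carboxylate_midpoint(self):
        feats = self._features(("Cationic",))  # hosts an ASP
        (key, fs), = feats.items()
        assert key[1] == "ASP"
        assert len(fs.anions) == 1
        od = [a for a in fs.atoms if a[0] == "O"]
        # midpoint of the two side-chain oxygens (backbone O is an acceptor only)
        assert len(fs.acceptors) >= 2

    def test_phe_ring_has_six_members(self):
        feats = self._features(("CationPi",))
        (_, fs), = feats.items()
        assert len(fs.rings) == 1 and len(fs.rings[0].members) == 6

    def test_unknown_residue_skipped(self):
        from bbbfp import dockparse as dp

        atoms = (dp.ReceptorAtom(1, "O", "O", "A", "LIG", 1, 0, 0, 0),)
        assert ia.perceive_residue_features(dp.Receptor(atoms)) == {}


def _lig_point(kind, xyz, with_h=None):
    fp = FeaturePoint((0,), tuple(xyz))
    if kind == "donor":
        return DonorPoint(fp, tuple(with_h) if with_h else ())
    return fp


class TestDetectionThresholds:
    KEY = ("A", "GLY", 1)

    def _res(self, **kw):
        return {self.KEY: ChemFeatureSet(**kw)}

    def test_hbond_distance_and_angle(self):
        acc = self._res(acceptors=(FeaturePoint(("O",), (2.9, 0, 0)),))
        # donor with explicit H pointing at the acceptor: 170 deg
        h = (0.94, 0.17, 0.0)
        lig = ChemFeatureSet(donors=(_lig_point("donor", (0, 0, 0), [h]),))
        ev = ia.detect_interactions(lig, acc)
        assert [e.type for e in ev] == ["HBDonor"]
        assert ev[0].angle > 160

        far = self._res(acceptors=(FeaturePoint(("O",), (3.6, 0, 0)),))
        assert ia.detect_interactions(lig, far) == []

        # bad angle: H points away
        lig_bad = ChemFeatureSet(
            donors=(_lig_point("donor", (0, 0, 0), [(-0.96, 0, 0)]),)
        )
        assert ia.detect_interactions(lig_bad, acc) == []

    def test_pi_stacking_face_to_face(self):
        ring_r = AromaticRing(("r",), (0, 0, 0), (0, 0, 1))
        ring_l = AromaticRing((1,), (0.5, 0, 3.8), (0, 0, 1))
        res = self._res(rings=(ring_r,))
        ev = ia.detect_interactions(ChemFeatureSet(rings=(ring_l,)), res)
        assert [e.type for e in ev] == ["PiStacking"]

    def test_pi_stacking_edge_to_face(self):
        ring_r = AromaticRing(("r",), (0, 0, 0), (0, 0, 1))
        ring_l = AromaticRing((1,), (0, 0, 6.0), (1, 0, 0))  # perpendicular
        ev = ia.detect_interactions(
            ChemFeatureSet(rings=(ring_l,)), self._res(rings=(ring_r,))
        )
        assert [e.type for e in ev] == ["PiStacking"]
        # too far even for edge-to-face
        ring_far = AromaticRing((1,), (0, 0, 6.6), (1, 0, 0))
        assert ia.detect_interactions(
            ChemFeatureSet(rings=(ring_far,)), self._res(rings=(ring_r,))
        ) == []

    def test_cation_pi_angle_gate(self):
        ring = AromaticRing(("r",), (0, 0, 0), (0, 0, 1))
        on_axis = ChemFeatureSet(cations=(FeaturePoint((0,), (0, 0, 4.0)),))
        off_axis = ChemFeatureSet(cations=(FeaturePoint((0,), (3.5, 0, 1.0)),))
        assert [e.type for e in ia.detect_interactions(on_axis, self._res(rings=(ring,)))] == ["CationPi"]
        assert ia.detect_interactions(off_axis, self._res(rings=(ring,))) == []

    def test_vdw_uses_radius_sum(self):
        res = self._res(atoms=(("C", 0.0, 0.0, 0.0),))
        near = ChemFeatureSet(atoms=(("O", 3.1, 0.0, 0.0),))   # 3.1 < 1.7+1.52
        far = ChemFeatureSet(atoms=(("O", 3.3, 0.0, 0.0),))
        assert [e.type for e in ia.detect_interactions(near, res)] == ["VdWContact"]
        assert ia.detect_interactions(far, res) == []


# ---------------------------------------------------------------------------
# brute-force oracle


def _naive_detect(lig, residues, th, radii):
    """Independent re-derivation of every geometric rule (pure math)."""

    def dist(p, q):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))

    def ang(u, v):
        du = math.sqrt(sum(x * x for x in u))
        dv = math.sqrt(sum(x * x for x in v))
        c = sum(a * b for a, b in zip(u, v)) / (du * dv)
        return math.degrees(math.acos(max(-1, min(1, c))))

    def axang(n, v):
        a = ang(n, v)
        return min(a, 180 - a)

    out = []
    for key, res in residues.items():
        for lp in lig.hydrophobic:
            for rp in res.hydrophobic:
                if dist(lp.coord, rp.coord) <= th.hydrophobic_max:
                    out.append(("Hydrophobic", lp.members, key))
        for d in lig.donors:
            for a in res.acceptors:
                dd = dist(d.heavy.coord, a.coord)
                if dd > th.hbond_max:
                    continue
                if d.h_coords:
                    best = max(
                        ang(
                            tuple(x - y for x, y in zip(d.heavy.coord, h)),
                            tuple(x - y for x, y in zip(a.coord, h)),
                        )
                        for h in d.h_coords
                    )
                    if best < th.hbond_angle_min:
                        continue
                out.append(("HBDonor", d.heavy.members, key))
        for a in lig.acceptors:
            for d in res.donors:
                if dist(a.coord, d.heavy.coord) <= th.hbond_max:
                    out.append(("HBAcceptor", a.members, key))
        for c in lig.cations:
            for an in res.anions:
                if dist(c.coord, an.coord) <= th.ionic_max:
                    out.append(("Cationic", c.members, key))
        for an in lig.anions:
            for c in res.cations:
                if dist(an.coord, c.coord) <= th.ionic_max:
                    out.append(("Anionic", an.members, key))
        for c in lig.cations:
            for r in res.rings:
                if dist(c.coord, r.centroid) <= th.cation_pi_max:
                    v = tuple(a - b for a, b in zip(c.coord, r.centroid))
                    if axang(r.normal, v) <= th.cation_pi_angle_max:
                        out.append(("CationPi", c.members, key))
        for r in lig.rings:
            for c in res.cations:
                if dist(r.centroid, c.coord) <= th.cation_pi_max:
                    v = tuple(a - b for a, b in zip(c.coord, r.centroid))
                    if axang(r.normal, v) <= th.cation_pi_angle_max:
                        out.append(("PiCation", r.members, key))
        for rl in lig.rings:
            for rr in res.rings:
                d = dist(rl.centroid, rr.centroid)
                plane = axang(rl.normal, rr.normal)
                lo, hi = th.pi_stack_etf_angle_range
                if (d <= th.pi_stack_ftf_max and plane <= th.pi_stack_ftf_angle_max) or (
                    d <= th.pi_stack_etf_max and lo <= plane <= hi
                ):
                    out.append(("PiStacking", rl.members, key))
        for (e1, *p1) in lig.atoms:
            for (e2, *p2) in res.atoms:
                if e1 in radii and e2 in radii:
                    if dist(p1, p2) <= radii[e1] + radii[e2] + th.vdw_tolerance:
                        out.append(("VdWContact", (e1,), key))
    return sorted(out)


def _random_feature_set(rng, for_residue=False):
    def pt(i):
        return FeaturePoint((i,), (rng.uniform(-6, 6), rng.uniform(-6, 6), rng.uniform(-6, 6)))

    def unit():
        v = np.array([rng.gauss(0, 1) for _ in range(3)])
        v = v / np.linalg.norm(v)
        return tuple(v)

    rings = tuple(
        AromaticRing((f"r{i}",), pt(i).coord, unit()) for i in range(rng.randint(0, 2))
    )
    donors = tuple(
        DonorPoint(pt(i), ((pt(i).coord[0] + rng.uniform(-1, 1),
                            pt(i).coord[1] + rng.uniform(-1, 1),
                            pt(i).coord[2] + rng.uniform(-1, 1)),)
                   if (not for_residue and rng.random() < 0.7) else ())
        for i in range(rng.randint(0, 2))
    )
    return ChemFeatureSet(
        hydrophobic=tuple(pt(i) for i in range(rng.randint(0, 3))),
        donors=donors,
        acceptors=tuple(pt(i) for i in range(rng.randint(0, 2))),
        cations=tuple(pt(i) for i in range(rng.randint(0, 2))),
        anions=tuple(pt(i) for i in range(rng.randint(0, 2))),
        rings=rings,
        atoms=tuple(
            (rng.choice(["C", "N", "O", "S"]),
             rng.uniform(-6, 6), rng.uniform(-6, 6), rng.uniform(-6, 6))
            for i in range(rng.randint(0, 4))
        ),
    )


def test_detection_matches_naive_oracle_on_random_complexes():
    """50 seeded random synthetic complexes, 100% event agreement."""
    rng = random.Random(20240101)
    th = GeometryThresholds()
    radii = ia.vdw_radii()
    for _ in range(50):
        lig = _random_feature_set(rng)
        residues = {
            ("A", "GLY", i + 1): _random_feature_set(rng, for_residue=True)
            for i in range(rng.randint(1, 3))
        }
        got = sorted((e.type, e.ligand_members, e.residue)
                     for e in ia.detect_interactions(lig, residues, th))
        assert got == _naive_detect(lig, residues, th, radii)


def _rigid_transform(rng):
    # random rotation (QR of a Gaussian matrix) + translation
    m = np.array([[rng.gauss(0, 1) for _ in range(3)] for _ in range(3)])
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    t = np.array([rng.uniform(-20, 20) for _ in range(3)])
    return q, t


def _transform_set(fs, q, t):
    def tp(p):
        return tuple(q @ np.asarray(p) + t)

    def tv(v):
        return tuple(q @ np.asarray(v))

    return ChemFeatureSet(
        hydrophobic=tuple(FeaturePoint(f.members, tp(f.coord)) for f in fs.hydrophobic),
        donors=tuple(
            DonorPoint(FeaturePoint(d.heavy.members, tp(d.heavy.coord)),
                       tuple(tp(h) for h in d.h_coords))
            for d in fs.donors
        ),
        acceptors=tuple(FeaturePoint(f.members, tp(f.coord)) for f in fs.acceptors),
        cations=tuple(FeaturePoint(f.members, tp(f.coord)) for f in fs.cations),
        anions=tuple(FeaturePoint(f.members, tp(f.coord)) for f in fs.anions),
        rings=tuple(
            AromaticRing(r.members, tp(r.centroid), tv(r.normal)) for r in fs.rings
        ),
        atoms=tuple((e, *tp(p)) for (e, *p) in fs.atoms),
    )


def test_rigid_motion_invariance():
    rng = random.Random(99)
    for _ in range(10):
        lig = _random_feature_set(rng)
        residues = {("A", "GLY", 1): _random_feature_set(rng, for_residue=True)}
        base = ia.detect_interactions(lig, residues)
        q, t = _rigid_transform(rng)
        moved = ia.detect_interactions(
            _transform_set(lig, q, t),
            {k: _transform_set(v, q, t) for k, v in residues.items()},
        )
        assert [(e.type, e.ligand_members, e.residue) for e in base] == [
            (e.type, e.ligand_members, e.residue) for e in moved
        ]
        for e1, e2 in zip(base, moved):
            assert e1.distance == pytest.approx(e2.distance, abs=1e-6)


class TestFingerprint:
    def test_empty_events(self):
        fp = ia.interaction_fingerprint([])
        assert fp.length == 9 and fp.set_bits == ()

    def test_exact_bits(self):
        key = ("A", "GLY", 1)
        events = [
            InteractionEvent("HBDonor", (0,), key, 2.9),
            InteractionEvent("Hydrophobic", (1,), key, 4.0),
        ]
        fp = ia.interaction_fingerprint(events)
        assert set(fp.set_bits) == {
            ia.INTERACTION_TYPES.index("Hydrophobic"),
            ia.INTERACTION_TYPES.index("HBDonor"),
        }

    def test_monotone_under_event_addition_and_removal(self):
        key = ("A", "GLY", 1)
        events = [InteractionEvent("Cationic", (0,), key, 4.0)]
        base = set(ia.interaction_fingerprint(events).set_bits)
        more = events + [InteractionEvent("PiStacking", (1,), key, 5.0)]
        grown = set(ia.interaction_fingerprint(more).set_bits)
        assert base <= grown
        # removing every event of one type clears exactly that bit
        cleared = set(ia.interaction_fingerprint(events).set_bits)
        assert grown - cleared == {ia.INTERACTION_TYPES.index("PiStacking")}

    def test_schema_is_fixed_nine(self):
        assert len(ia.INTERACTION_TYPES) == 9
        assert ia.INTERACTION_TYPES[0] == "Hydrophobic"
        with pytest.raises(ValueError):
            InteractionEvent("Halogen", (0,), ("A", "GLY", 1), 3.0)
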