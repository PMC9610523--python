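"""Geometric interaction detection between receptor and ligand."""

import numpy as np
import pytest

from posekit.graph import AtomNode, Bond, BondOrder, MoleculeGraph
from posekit.interactions import (
    InteractionKind,
    detect_interactions,
)
from posekit.synthdata import permute_atoms

from conftest import benzene_ring, mk


def labelled(spec, bonds, res_name="ALA", res_num=1, chain="A"):
    atoms = [
        AtomNode(e, xyz, i, name=f"{e}{i}", res_name=res_name, res_num=res_num, chain=chain)
        for i, (e, xyz) in enumerate(spec)
    ]
    bl = [Bond(*b) if len(b) == 3 else Bond(b[0], b[1]) for b in bonds]
    return MoleculeGraph(atoms, bl)


class TestHbond:
    def test_donor_to_acceptor_with_good_angle(self):
        # N-H donor; H...O nearly linear (D-H...A = 160 deg), N...O = 2.91
        ligand = mk([("N", (0.0, 0.0, 0.0)), ("H", (1.0, 0.0, 0.0))], [(0, 1)])
        a = (1.0 + 1.95 * np.cos(np.radians(20)), 1.95 * np.sin(np.radians(20)), 0.0)
        receptor = labelled([("O", a)], [], res_name="SER", res_num=17)
        recs = detect_interactions(receptor, ligand, {InteractionKind.HBOND})
        assert len(recs) == 1
        r = recs[0]
        assert r.kind is InteractionKind.HBOND
        assert r.residue == "A:SER17"
        assert r.distance == pytest.approx(2.91, abs=0.02)
        assert r.angle == pytest.approx(160.0, abs=1.0)

    def test_bent_geometry_rejected(self):
        # same distance but D-H...A angle ~70 deg; sulfur acceptor cannot
        # donate back, so no record survives the angle check
        ligand = mk([("N", (0.0, 0.0, 0.0)), ("H", (1.0, 0.0, 0.0))], [(0, 1)])
        receptor = labelled([("S", (0.0, 2.9, 0.0))], [])
        recs = detect_interactions(receptor, ligand, {InteractionKind.HBOND})
        assert recs == []

    def test_far_apart_is_empty(self):
        ligand = mk([("N", (0.0, 0.0, 0.0))], [])
        receptor = labelled([("O", (15.0, 0.0, 0.0))], [])
        assert detect_interactions(receptor, ligand) == []

    def test_no_explicit_hydrogens_distance_only(self):
        ligand = mk([("O", (0.0, 0.0, 0.0))], [])
        receptor = labelled([("N", (2.9, 0.0, 0.0))], [])
        recs = detect_interactions(receptor, ligand, {InteractionKind.HBOND})
        assert len(recs) == 1 and recs[0].angle is None


class TestIonic:
    def test_amidinium_to_phosphate(self):
        # ligand amidinium: C bonded to two terminal N
        ligand = mk(
            [("C", (0.0, 0.0, 0.0)), ("N", (1.3, 0.2, 0.0)), ("N", (-0.6, 1.15, 0.0)),
             ("C", (-0.7, -1.2, 0.0))],
            [(0, 1, BondOrder.DOUBLE), (0, 2), (0, 3)],
        )
        # receptor phosphate: P with two terminal O; one O 3.4 from ligand N
        receptor = labelled(
            [("P", (4.2, 1.6, 0.0)), ("O", (4.62, 0.16, 0.0)), ("O", (4.8, 2.4, 1.2)),
             ("O", (2.7, 1.7, 0.1))],
            [(0, 1), (0, 2), (0, 3)],
            res_name="DG", res_num=4,
        )
        recs = detect_interactions(receptor, ligand, {InteractionKind.IONIC})
        assert recs, "expected at least one ionic contact"
        assert all(r.kind is InteractionKind.IONIC for r in recs)
        assert any(r.distance < 4.0 for r in recs)

    def test_like_charges_do_not_pair(self):
        ligand = mk([("C", (0.0, 0.0, 0.0)), ("N", (1.4, 0.0, 0.0))], [(0, 1)])  # amine +
        receptor = labelled([("C", (3.0, 0.0, 0.0)), ("N", (4.4, 0.0, 0.0))], [(0, 1)])
        assert detect_interactions(receptor, ligand, {InteractionKind.IONIC}) == []


class TestHydrophobicAndMetal:
    def test_apolar_carbon_contact(self):
        ligand = mk([("C", (0.0, 0.0, 0.0)), ("C", (1.5, 0.0, 0.0))], [(0, 1)])
        receptor = labelled([("C", (0.0, 3.5, 0.0))], [], res_name="LEU", res_num=3)
        recs = detect_interactions(receptor, ligand, {InteractionKind.HYDROPHOBIC})
        assert len(recs) == 2  # both ligand carbons within 4.0
        assert recs[0].distance <= recs[1].distance

    def test_polar_carbon_excluded(self):
        ligand = mk([("C", (0.0, 0.0, 0.0)), ("O", (1.4, 0.0, 0.0))], [(0, 1)])
        receptor = labelled([("C", (0.0, 3.5, 0.0))], [])
        assert detect_interactions(receptor, ligand, {InteractionKind.HYDROPHOBIC}) == []

    def test_zinc_coordination(self):
        ligand = mk([("N", (0.0, 0.0, 0.0)), ("C", (1.4, 0.0, 0.0))], [(0, 1)])
        receptor = labelled([("Zn", (0.0, 2.1, 0.0))], [], res_name="ZN", res_num=200)
        recs = detect_interactions(receptor, ligand, {InteractionKind.METAL})
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(2.1, abs=1e-9)

    def test_metal_beyond_cutoff(self):
        ligand = mk([("N", (0.0, 0.0, 0.0))], [])
        receptor = labelled([("Zn", (0.0, 3.2, 0.0))], [])
        assert detect_interactions(receptor, ligand, {InteractionKind.METAL}) == []


class TestPiStacking:
    def test_parallel_rings(self):
        lig = benzene_ring(kekule=False, z=0.0)
        rec_ring = benzene_ring(kekule=False, z=3.6)
        receptor = labelled(
            [(a.element, a.position) for a in rec_ring.atoms],
            [(b.i, b.j, b.order) for b in rec_ring.bonds],
            res_name="PHE", res_num=12,
        )
        recs = detect_interactions(receptor, lig, {InteractionKind.PI_STACKING})
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.6, abs=1e-6)
        assert recs[0].angle == pytest.approx(0.0, abs=1.0)

    def test_oblique_rings_rejected(self):
        lig = benzene_ring(kekule=False)
        tilted = benzene_ring(kekule=False)
        coords = tilted.coords
        theta = np.radians(45)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        coords = coords @ rot.T + np.array([0.0, 0.0, 4.0])
        tilted = tilted.with_coords(coords)
        receptor = labelled(
            [(a.element, a.position) for a in tilted.atoms],
            [(b.i, b.j, b.order) for b in tilted.bonds],
        )
        assert detect_interactions(receptor, lig, {InteractionKind.PI_STACKING}) == []


class TestReportProperties:
    def _scene(self):
        ligand = mk(
            [("N", (0.0, 0.0, 0.0)), ("C", (1.5, 0.0, 0.0)), ("C", (3.0, 0.0, 0.0))],
            [(0, 1), (1, 2)],
        )
        receptor = labelled(
            [("O", (0.0, 2.9, 0.0)), ("C", (3.0, 3.6, 0.0))],
            [],
            res_name="THR", res_num=8,
        )
        return receptor, ligand

    def test_kind_restriction_is_exact_subset(self):
        receptor, ligand = self._scene()
        full = detect_interactions(receptor, ligand)
        only_hb = detect_interactions(receptor, ligand, {InteractionKind.HBOND})
        expected = [r for r in full if r.kind is InteractionKind.HBOND]
        assert [(r.kind, r.distance) for r in only_hb] == [
            (r.kind, r.distance) for r in expected
        ]

    def test_stable_under_ligand_relabelling(self):
        receptor, ligand = self._scene()
        before = detect_interactions(receptor, ligand)
        after = detect_interactions(receptor, permute_atoms(ligand, seed=5))
        key = lambda recs: sorted(
            (r.kind.value, r.residue, round(r.distance, 6)) for r in recs
        )
        assert key(before) == key(after)

    def test_missing_residue_labels_warns(self):
        ligand = mk([("N", (0.0, 0.0, 0.0))], [])
        receptor = mk([("O", (2.9, 0.0, 0.0))], [])
        with pytest.warns(UserWarning, match="residue"):
            recs = detect_interactions(receptor, ligand, {InteractionKind.HBOND})
        assert recs[0].residue == ""

    def test_sorted_by_distance(self):
        receptor, ligand = self._scene()
        recs = detect_interactions(receptor, ligand)
        assert [r.distance for r in recs] == sorted(r.distance for r in recs)
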