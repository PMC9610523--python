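"""Geometric receptor-ligand interaction detection.

Replaces visual inspection of a docked pose with a machine-readable
report of five interaction classes — hydrogen bonds, ionic contacts,
hydrophobic contacts, pi-stacking and metal coordination — detected by
standard literature distance/angle criteria (all thresholds
configurable):

* HBOND:   donor(N/O)–acceptor(N/O/S) distance <= 3.5 Å; when an explicit
  hydrogen rides the donor, the D–H...A angle must be >= 120 deg.
* IONIC:   oppositely charged groups (carboxylate, phosphate,
  guanidinium/amidinium, protonated amine, metal cation) <= 4.0 Å.
* HYDROPHOBIC: apolar carbon to apolar carbon <= 4.0 Å (a carbon is
  apolar when bonded to no N/O).
* PI_STACKING: aromatic 5/6-ring centroids <= 5.5 Å with interplanar
  angle <= 30 deg (parallel) or within 60–90 deg (T-shaped).
* METAL:   metal ion to N/O/S <= 2.8 Å.

Records are sorted by distance and name the receptor residue when the
receptor carries residue labels (PDB input); otherwise atom indices are
reported with a warning.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._elements import METALS
from .graph import BondOrder, MoleculeGraph


class InteractionKind(enum.Enum):
    HBOND = "hbond"
    IONIC = "ionic"
    HYDROPHOBIC = "hydrophobic"
    PI_STACKING = "pi_stacking"
    METAL = "metal"


@dataclass
class InteractionCriteria:
    """Distance (Å) and angle (degrees) thresholds."""

    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    ionic_distance: float = 4.0
    hydrophobic_distance: float = 4.0
    pi_centroid_distance: float = 5.5
    pi_parallel_angle: float = 30.0
    pi_tshape_range: tuple[float, float] = (60.0, 90.0)
    metal_distance: float = 2.8


@dataclass
class InteractionRecord:
    kind: InteractionKind
    ligand_atom: int
    receptor_atom: int
    distance: float
    residue: str = ""
    angle: Optional[float] = None

    def sort_key(self) -> tuple:
        return (round(self.distance, 6), self.kind.value, self.residue,
                self.ligand_atom, self.receptor_atom)


def _residue_label(mol: MoleculeGraph, i: int) -> str:
    a = mol.atoms[i]
    if not a.res_name:
        return ""
    chain = f"{a.chain}:" if a.chain else ""
    return f"{chain}{a.res_name}{a.res_num}"


def _apolar_carbons(mol: MoleculeGraph) -> set[int]:
    out = set()
    for i, a in enumerate(mol.atoms):
        if a.element != "C":
            continue
        if all(mol.atoms[j].element not in ("N", "O") for j in mol.neighbours(i)):
            out.add(i)
    return out


def _donors_acceptors(mol: MoleculeGraph) -> tuple[dict[int, list[int]], set[int]]:
    """(donor heavy atom → attached H indices, acceptor heavy atoms)."""
    donors: dict[int, list[int]] = {}
    acceptors: set[int] = set()
    any_h = any(a.is_hydrogen for a in mol.atoms)
    for i, a in enumerate(mol.atoms):
        if a.element in ("N", "O"):
            hs = [j for j in mol.neighbours(i) if mol.atoms[j].is_hydrogen]
            # without explicit hydrogens every N/O is a potential donor
            if hs or not any_h:
                donors[i] = hs
            acceptors.add(i)
        elif a.element == "S":
            acceptors.add(i)
    return donors, acceptors


def _charged_groups(mol: MoleculeGraph) -> list[tuple[int, int]]:
    """(atom index, charge sign) for recognisably charged group atoms.

    Pattern based: carboxylate/phosphate oxygens are negative;
    guanidinium/amidinium nitrogens and primary/secondary amine
    nitrogens are positive; bare metal cations are positive.
    """
    out: list[tuple[int, int]] = []
    heavy_nbrs = {
        i: [j for j in mol.neighbours(i) if not mol.atoms[j].is_hydrogen]
        for i in range(len(mol))
    }
    for i, a in enumerate(mol.atoms):
        if a.element == "C":
            term_o = [j for j in heavy_nbrs[i]
                      if mol.atoms[j].element == "O" and len(heavy_nbrs[j]) == 1]
            term_n = [j for j in heavy_nbrs[i]
                      if mol.atoms[j].element == "N" and len(heavy_nbrs[j]) <= 2]
            if len(term_o) >= 2:        # carboxylate
                out.extend((j, -1) for j in term_o)
            n_nbrs = [j for j in heavy_nbrs[i] if mol.atoms[j].element == "N"]
            if len(n_nbrs) >= 2 and len(term_n) >= 1:   # guanidinium/amidinium
                out.extend((j, +1) for j in n_nbrs)
        elif a.element == "P":
            term_o = [j for j in heavy_nbrs[i]
                      if mol.atoms[j].element == "O" and len(heavy_nbrs[j]) == 1]
            if len(term_o) >= 2:        # phosphate
                out.extend((j, -1) for j in term_o)
        elif a.element == "N":
            nbrs = heavy_nbrs[i]
            if len(nbrs) == 1 and mol.atoms[nbrs[0]].element == "C":
                # primary amine nitrogen, protonatable
                c = nbrs[0]
                c_term_n = [j for j in heavy_nbrs[c]
                            if mol.atoms[j].element == "N" and len(heavy_nbrs[j]) == 1]
                if len(c_term_n) < 2:   # amidinium handled above
                    out.append((i, +1))
        elif a.element in METALS and not heavy_nbrs[i]:
            out.append((i, +1))
    return sorted(set(out))


def _aromatic_rings(mol: MoleculeGraph) -> list[list[int]]:
    """5/6-membered rings of C/N atoms that are flat enough to stack."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(mol)))
    g.add_edges_from(b.key for b in mol.bonds)
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        if not all(mol.atoms[i].element in ("C", "N", "S", "O") for i in cycle):
            continue
        pts = mol.coords[cycle]
        centred = pts - pts.mean(axis=0)
        # planarity: smallest singular value ~ out-of-plane thickness
        s = np.linalg.svd(centred, compute_uv=False)
        if s[-1] < 0.35:
            rings.append(sorted(cycle))
    return rings


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[-1]


def detect_interactions(
    receptor: MoleculeGraph,
    ligand: MoleculeGraph,
    kinds: Optional[Iterable[InteractionKind]] = None,
    criteria: Optional[InteractionCriteria] = None,
) -> list[InteractionRecord]:
    """Detect receptor-ligand interactions in a shared frame.

    ``kinds`` restricts the report (default: all five classes); the
    result is exactly the corresponding subset of the full report.
    Records are sorted by distance and identified by residue label and
    coordinates, so they are stable under ligand atom relabelling.
    """
    kinds_set = set(kinds) if kinds is not None else set(InteractionKind)
    crit = criteria or InteractionCriteria()
    if not any(a.res_name for a in receptor.atoms):
        warnings.warn("receptor has no residue labels; reporting atom indices only",
                      stacklevel=2)
    records: list[InteractionRecord] = []
    rc, lc = receptor.coords, ligand.coords
    if len(receptor) == 0 or len(ligand) == 0:
        return records
    tree = cKDTree(rc)

    def close_pairs(lig_idx: Sequence[int], rec_idx: set[int], cutoff: float):
        for li in lig_idx:
            for ri in tree.query_ball_point(lc[li], cutoff):
                if ri in rec_idx:
                    d = float(np.linalg.norm(lc[li] - rc[ri]))
                    if 0 < d <= cutoff:
                        yield li, ri, d

    if InteractionKind.HBOND in kinds_set:
        records += _detect_hbonds(receptor, ligand, crit, close_pairs)
    if InteractionKind.IONIC in kinds_set:
        lig_charged = _charged_groups(ligand)
        rec_charged = dict(_charged_groups(receptor))
        rec_by_sign = {s: {i for i, si in rec_charged.items() if si == s} for s in (-1, 1)}
        for li, sign in lig_charged:
            for li2, ri, d in close_pairs([li], rec_by_sign[-sign], crit.ionic_distance):
                records.append(InteractionRecord(
                    InteractionKind.IONIC, li2, ri, d, _residue_label(receptor, ri)))
    if InteractionKind.HYDROPHOBIC in kinds_set:
        lig_c = sorted(_apolar_carbons(ligand))
        rec_c = _apolar_carbons(receptor)
        for li, ri, d in close_pairs(lig_c, rec_c, crit.hydrophobic_distance):
            records.append(InteractionRecord(
                InteractionKind.HYDROPHOBIC, li, ri, d, _residue_label(receptor, ri)))
    if InteractionKind.PI_STACKING in kinds_set:
        records += _detect_pi_stacking(receptor, ligand, crit)
    if InteractionKind.METAL in kinds_set:
        # metal may sit on either side (receptor cofactor is the usual case)
        lig_dona = {i for i, a in enumerate(ligand.atoms) if a.element in ("N", "O", "S")}
        rec_metals = {i for i, a in enumerate(receptor.atoms) if a.element in METALS}
        for li, ri, d in close_pairs(sorted(lig_dona), rec_metals, crit.metal_distance):
            records.append(InteractionRecord(
                InteractionKind.METAL, li, ri, d, _residue_label(receptor, ri)))
        lig_metals = [i for i, a in enumerate(ligand.atoms) if a.element in METALS]
        rec_dona = {i for i, a in enumerate(receptor.atoms)
                    if a.element in ("N", "O", "S")}
        for li, ri, d in close_pairs(lig_metals, rec_dona, crit.metal_distance):
            records.append(InteractionRecord(
                InteractionKind.METAL, li, ri, d, _residue_label(receptor, ri)))
    records.sort(key=lambda r: r.sort_key())
    return records


def _detect_hbonds(receptor, ligand, crit, close_pairs):
    records = []
    lig_don, lig_acc = _donors_acceptors(ligand)
    rec_don, rec_acc = _donors_acceptors(receptor)
    lc, rc = ligand.coords, receptor.coords

    def angle_ok(d_pos, h_positions, a_pos):
        if not len(h_positions):
            return True, None
        best = None
        for h in h_positions:
            v1, v2 = d_pos - h, a_pos - h
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            if best is None or ang > best:
                best = ang
        return best >= crit.hbond_angle, best

    # ligand donor → receptor acceptor
    for li, ri, d in close_pairs(sorted(lig_don), rec_acc, crit.hbond_distance):
        ok, ang = angle_ok(lc[li], [lc[h] for h in lig_don[li]], rc[ri])
        if ok:
            records.append(InteractionRecord(
                InteractionKind.HBOND, li, ri, d, _residue_label(receptor, ri), ang))
    # receptor donor → ligand acceptor
    for li, ri, d in close_pairs(sorted(lig_acc), set(rec_don), crit.hbond_distance):
        ok, ang = angle_ok(rc[ri], [rc[h] for h in rec_don[ri]], lc[li])
        if ok and not any(
            r.ligand_atom == li and r.receptor_atom == ri and r.kind is InteractionKind.HBOND
            for r in records
        ):
            records.append(InteractionRecord(
                InteractionKind.HBOND, li, ri, d, _residue_label(receptor, ri), ang))
    return records


def _detect_pi_stacking(receptor, ligand, crit):
    records = []
    lig_rings = _aromatic_rings(ligand)
    rec_rings = _aromatic_rings(receptor)
    for lr in lig_rings:
        lcen, lnorm = _ring_plane(ligand.coords[lr])
        for rr in rec_rings:
            rcen, rnorm = _ring_plane(receptor.coords[rr])
            d = float(np.linalg.norm(lcen - rcen))
            if not 0 < d <= crit.pi_centroid_distance:
                continue
            cosang = abs(float(np.dot(lnorm, rnorm)))
            ang = float(np.degrees(np.arccos(np.clip(cosang, 0, 1))))
            lo, hi = crit.pi_tshape_range
            if ang <= crit.pi_parallel_angle or lo <= ang <= hi:
                records.append(InteractionRecord(
                    InteractionKind.PI_STACKING, lr[0], rr[0], d,
                    _residue_label(receptor, rr[0]), ang))
    return records
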