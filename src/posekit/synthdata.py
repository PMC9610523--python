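"""Synthetic molecules, poses and peptides for matcher/cluster testing.

Everything here is generated programmatically and deterministically from
a seed: random valence-legal molecular graphs with self-consistent 3D
coordinates, seeded atom permutations and coordinate noise, planted
pose-cluster sets written in the supported file dialects, and small
glycine/alanine peptides for the backbone mode.

Geometry is kept compatible with distance-based bond perception: bonded
pairs sit near 1.5 Å, non-bonded pairs are rejected below 2.2 Å, and
rings are grown as regular polygons, so a generated molecule written to
PDBQT (which carries no bond table) re-reads with exactly the bonds it
was built with.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from ._elements import MAX_VALENCE
from .graph import AtomNode, Bond, BondOrder, MoleculeGraph
from .io import Format, write_structures, write_vina_pdbqt

_BOND_LENGTH = 1.5
_MIN_NONBONDED = 2.2


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one random molecule."""

    n_heavy_atoms: int = 8
    element_palette: tuple[str, ...] = ("C", "C", "C", "N", "O")
    branching_probability: float = 0.3
    ring_probability: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_heavy_atoms < 1:
            raise ValueError("need at least one atom")
        for p in (self.branching_probability, self.ring_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def _free_valence(element: str, used: float) -> float:
    return MAX_VALENCE.get(element, 4) - used


def generate_molecule(spec: SyntheticSpec) -> MoleculeGraph:
    """Random connected molecule: optional ring seed plus tree growth.

    With probability ``ring_probability`` (and enough atoms) the
    molecule starts from a regular 5- or 6-ring of carbons; remaining
    atoms are attached one by one to a parent with free valence, at
    ~1.5 Å in a clash-rejected random direction.  A terminal oxygen on a
    carbon with two spare valences occasionally becomes a double bond,
    so signatures exercise the bond order-class.  Deterministic per
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_heavy_atoms
    elements: list[str] = []
    positions: list[np.ndarray] = []
    bonds: list[Bond] = []
    used_valence: list[float] = []

    def add_atom(element: str, pos: np.ndarray) -> int:
        elements.append(element)
        positions.append(pos)
        used_valence.append(0.0)
        return len(elements) - 1

    def add_bond(i: int, j: int, order: BondOrder) -> None:
        bonds.append(Bond(i, j, order))
        used_valence[i] += order.value if order is not BondOrder.AROMATIC else 1.5
        used_valence[j] += order.value if order is not BondOrder.AROMATIC else 1.5

    ring_size = 0
    if n >= 6 and rng.random() < spec.ring_probability:
        ring_size = int(rng.choice([5, 6]))
    if ring_size:
        radius = _BOND_LENGTH / (2 * np.sin(np.pi / ring_size))
        for k in range(ring_size):
            theta = 2 * np.pi * k / ring_size
            add_atom("C", np.array([radius * np.cos(theta), radius * np.sin(theta), 0.0]))
        for k in range(ring_size):
            add_bond(k, (k + 1) % ring_size, BondOrder.SINGLE)
    else:
        add_atom(str(rng.choice(spec.element_palette)), np.zeros(3))

    while len(elements) < n:
        open_atoms = [i for i in range(len(elements))
                      if _free_valence(elements[i], used_valence[i]) >= 1]
        if not open_atoms:
            break
        if rng.random() < spec.branching_probability:
            parent = int(rng.choice(open_atoms))
        else:
            parent = open_atoms[-1]
        element = str(rng.choice(spec.element_palette))
        placed = None
        for _ in range(80):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            pos = positions[parent] + v * (_BOND_LENGTH + rng.uniform(-0.05, 0.05))
            dists = [np.linalg.norm(pos - q) for k, q in enumerate(positions) if k != parent]
            if not dists or min(dists) >= _MIN_NONBONDED:
                placed = pos
                break
        if placed is None:
            # crowded parent: retire it and try again
            used_valence[parent] = MAX_VALENCE.get(elements[parent], 4)
            continue
        idx = add_atom(element, placed)
        order = BondOrder.SINGLE
        if (
            element == "O"
            and _free_valence("O", 0) >= 2
            and _free_valence(elements[parent], used_valence[parent]) >= 2
            and rng.random() < 0.3
        ):
            order = BondOrder.DOUBLE
        add_bond(parent, idx, order)

    atoms = [AtomNode(e, tuple(map(float, p)), i)
             for i, (e, p) in enumerate(zip(elements, positions))]
    return MoleculeGraph(atoms, bonds, name=f"synth-{spec.seed}")


def valence_legal(mol: MoleculeGraph) -> bool:
    """Every atom's total bond order within its element's valence cap."""
    used = [0.0] * len(mol)
    for b in mol.bonds:
        w = 1.5 if b.order is BondOrder.AROMATIC else float(b.order.value)
        used[b.i] += w
        used[b.j] += w
    return all(used[i] <= MAX_VALENCE.get(a.element, 4) + 1e-9
               for i, a in enumerate(mol.atoms))


def permute_atoms(mol: MoleculeGraph, seed: int = 0) -> MoleculeGraph:
    """Re-order atoms by a seeded random permutation (coordinates ride
    along; bonds are re-indexed)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(mol))           # new_index -> old_index
    inverse = np.empty_like(perm)
    inverse[perm] = np.arange(len(mol))
    atoms = [replace(mol.atoms[old], original_index=new)
             for new, old in enumerate(perm)]
    bonds = [Bond(int(inverse[b.i]), int(inverse[b.j]), b.order) for b in mol.bonds]
    return MoleculeGraph(atoms, bonds, mol.name, mol.properties)


def perturb_coordinates(mol: MoleculeGraph, sigma: float, seed: int = 0) -> MoleculeGraph:
    """Add i.i.d. Gaussian noise of scale ``sigma`` (Å) per coordinate."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return mol
    rng = np.random.default_rng(seed)
    return mol.with_coords(mol.coords + rng.normal(scale=sigma, size=(len(mol), 3)))


def translate(mol: MoleculeGraph, shift: Sequence[float]) -> MoleculeGraph:
    return mol.with_coords(mol.coords + np.asarray(shift, dtype=float))


def _perception_consistent(mol: MoleculeGraph) -> bool:
    from .io import perceive_bonds

    perceived = {b.key for b in perceive_bonds(mol).bonds}
    return perceived == {b.key for b in mol.bonds}


@dataclass
class PoseSet:
    """A planted-cluster pose file plus its ground truth."""

    text: str
    format: Format
    poses: list[MoleculeGraph]
    labels: list[int]          # planted cluster id per pose, in file order
    scores: list[float]


def generate_pose_set(
    base: MoleculeGraph,
    k_clusters: int = 3,
    intra_spread: float = 0.2,
    separation: float = 3.0,
    sizes: Union[int, Sequence[int]] = 5,
    seed: int = 0,
    format: Format = Format.PDBQT,
    shuffle: bool = True,
) -> PoseSet:
    """Planted pose clusters written as a Vina PDBQT or scored SDF.

    ``k_clusters`` rigid translations of ``base`` spaced ``separation``
    Å apart along a line, each populated with perturbed copies (noise
    scale ``intra_spread``).  Scores are drawn so the most populated
    cluster has the most favourable (lowest) mean score.  Requires
    ``separation > 2 * intra_spread``.
    """
    if separation <= 2 * intra_spread:
        raise ValueError("separation must exceed twice the intra-cluster spread")
    sizes_list = [int(sizes)] * k_clusters if isinstance(sizes, int) else list(sizes)
    if len(sizes_list) != k_clusters:
        raise ValueError("one size per cluster required")
    rng = np.random.default_rng(seed)
    # most populated cluster gets the best (most negative) mean score
    order = sorted(range(k_clusters), key=lambda c: -sizes_list[c])
    mean_score = {c: -10.0 + rank * 1.5 for rank, c in enumerate(order)}
    poses: list[MoleculeGraph] = []
    labels: list[int] = []
    scores: list[float] = []
    for c in range(k_clusters):
        centre = translate(base, (separation * c, 0.0, 0.0))
        for m in range(sizes_list[c]):
            for _ in range(100):
                sub = int(rng.integers(0, 2**31 - 1))
                pose = perturb_coordinates(centre, intra_spread, seed=sub)
                # PDBQT carries no bond table: keep only noise draws whose
                # geometry re-perceives to the molecule's own bonds
                if format is not Format.PDBQT or _perception_consistent(pose):
                    break
            poses.append(pose)
            labels.append(c)
            scores.append(float(mean_score[c] + rng.normal(scale=0.1)))
    if shuffle:
        perm = rng.permutation(len(poses))
        poses = [poses[i] for i in perm]
        labels = [labels[i] for i in perm]
        scores = [scores[i] for i in perm]
    if format is Format.PDBQT:
        text = write_vina_pdbqt(poses, scores)
    elif format is Format.SDF:
        tagged = []
        for p, s in zip(poses, scores):
            props = dict(p.properties)
            props["docking_score"] = f"{s:.3f}"
            tagged.append(MoleculeGraph(p.atoms, p.bonds, p.name, props))
        poses = tagged
        text = write_structures(tagged, Format.SDF)
    else:
        raise ValueError("pose sets are written as PDBQT or SDF")
    return PoseSet(text, format, poses, labels, scores)


# -- peptides ------------------------------------------------------------


def generate_peptide(
    n_residues: int, sequence: Optional[str] = None, seed: int = 0,
    with_names: bool = True,
) -> MoleculeGraph:
    """Heavy-atom glycine/alanine peptide with explicit N-Ca-C'(=O) motifs.

    ``sequence`` is a string over {G, A}; when omitted it is drawn from
    the seed.  The chain is an extended zig-zag with ~1.5 Å bonds, a
    double-bonded carbonyl oxygen per residue and a terminal OXT.
    ``with_names=False`` drops the PDB atom names so the backbone must
    be recovered by graph search, as for a nameless SDF/MOL2 input.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(["G", "A"], size=n_residues))
    if len(sequence) != n_residues or set(sequence) - {"G", "A"}:
        raise ValueError("sequence must be a G/A string of length n_residues")
    atoms: list[AtomNode] = []
    bonds: list[Bond] = []
    dx, dy = 1.25, 0.85

    def backbone_pos(t: int) -> tuple[float, float, float]:
        return (dx * t, dy * (t % 2), 0.0)

    def add(element: str, pos, name: str, res: int) -> int:
        if with_names:
            atoms.append(AtomNode(element, tuple(map(float, pos)), len(atoms),
                                  name=name,
                                  res_name="ALA" if sequence[res] == "A" else "GLY",
                                  res_num=res + 1, chain="A"))
        else:
            atoms.append(AtomNode(element, tuple(map(float, pos)), len(atoms)))
        return len(atoms) - 1

    prev_c = None
    t = 0
    for r in range(n_residues):
        n_i = add("N", backbone_pos(t), "N", r)
        ca_i = add("C", backbone_pos(t + 1), "CA", r)
        c_i = add("C", backbone_pos(t + 2), "C", r)
        o_pos = np.array(backbone_pos(t + 2)) + np.array([0.0, 0.35, 1.25])
        o_i = add("O", o_pos, "O", r)
        bonds += [Bond(n_i, ca_i), Bond(ca_i, c_i), Bond(c_i, o_i, BondOrder.DOUBLE)]
        if prev_c is not None:
            bonds.append(Bond(prev_c, n_i))
        if sequence[r] == "A":
            cb_pos = np.array(backbone_pos(t + 1)) + np.array([0.0, 0.35, -1.45])
            cb_i = add("C", cb_pos, "CB", r)
            bonds.append(Bond(ca_i, cb_i))
        prev_c = c_i
        t += 3
    oxt_i = add("O", backbone_pos(t), "OXT", n_residues - 1)
    bonds.append(Bond(prev_c, oxt_i))
    return MoleculeGraph(atoms, bonds, name=f"peptide-{sequence}")
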