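"""Molecular graph data model.

A molecule is represented as an undirected graph whose nodes are atoms
(element symbol plus a 3D position in a fixed Cartesian frame, in Å) and
whose edges are covalent bonds carrying an order class.  Atom matching,
RMSD and interaction detection all operate on this container.

Hydrogens are carried by the graph but are stripped before any RMSD or
matching step; surviving atoms remember their position in the source
record through ``original_index`` so mappings can be reported against the
input file ordering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np


class BondOrder(enum.Enum):
    """Bond order class used by atom signatures."""

    SINGLE = 1
    DOUBLE = 2
    TRIPLE = 3
    AROMATIC = 4

    def __repr__(self) -> str:  # compact in test diffs
        return self.name


#: Elements treated as hydrogen (deuterium/tritium symbols included).
HYDROGEN_LIKE = frozenset({"H", "D", "T"})


@dataclass(frozen=True)
class AtomNode:
    """One atom: element symbol, position (Å) and provenance metadata.

    ``name``/``res_name``/``res_num``/``chain`` are populated from PDB-style
    records and are optional; graph algorithms never rely on them.
    """

    element: str
    position: tuple[float, float, float]
    original_index: int
    name: str = ""
    res_name: str = ""
    res_num: int = 0
    chain: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.original_index}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in HYDROGEN_LIKE


@dataclass(frozen=True)
class Bond:
    """Undirected bond between two atom indices with an order class."""

    i: int
    j: int
    order: BondOrder = BondOrder.SINGLE

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-bonds are not allowed")

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


class MoleculeGraph:
    """Atoms plus bonds; the structure every operation consumes.

    Parameters
    ----------
    atoms:
        Ordered atoms.  Indices used by ``bonds`` refer to this order.
    bonds:
        Covalent bonds as :class:`Bond` (duplicates rejected).
    name:
        Free-text molecule name (e.g. the SDF title line).
    properties:
        Tag → text map (SDF data tags, REMARK payloads ...).
    """

    def __init__(
        self,
        atoms: Sequence[AtomNode],
        bonds: Iterable[Bond] = (),
        name: str = "",
        properties: Optional[dict[str, str]] = None,
    ) -> None:
        self.atoms: list[AtomNode] = list(atoms)
        self.name = name
        self.properties: dict[str, str] = dict(properties or {})
        self.bonds: list[Bond] = []
        seen: set[tuple[int, int]] = set()
        n = len(self.atoms)
        for b in bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond {b.key} references atom outside 0..{n - 1}")
            if b.key in seen:
                raise ValueError(f"duplicate bond {b.key}")
            seen.add(b.key)
            self.bonds.append(b)
        self._adj: Optional[dict[int, list[tuple[int, BondOrder]]]] = None

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return (
            f"MoleculeGraph(name={self.name!r}, n_atoms={len(self.atoms)}, "
            f"n_bonds={len(self.bonds)})"
        )

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of positions in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def adjacency(self) -> dict[int, list[tuple[int, BondOrder]]]:
        """index → list of (neighbour index, bond order), cached."""
        if self._adj is None:
            adj: dict[int, list[tuple[int, BondOrder]]] = {
                i: [] for i in range(len(self.atoms))
            }
            for b in self.bonds:
                adj[b.i].append((b.j, b.order))
                adj[b.j].append((b.i, b.order))
            self._adj = adj
        return self._adj

    def neighbours(self, i: int) -> list[int]:
        return [j for j, _ in self.adjacency()[i]]

    def bond_order(self, i: int, j: int) -> Optional[BondOrder]:
        for k, order in self.adjacency()[i]:
            if k == j:
                return order
        return None

    def with_coords(self, coords: np.ndarray) -> "MoleculeGraph":
        """Copy of the graph with replaced positions (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, position=tuple(float(x) for x in coords[i]))
            for i, a in enumerate(self.atoms)
        ]
        return MoleculeGraph(atoms, self.bonds, self.name, self.properties)


# -- signatures ----------------------------------------------------------


@dataclass(frozen=True)
class AtomSignature:
    """Local environment of an atom: element + sorted neighbour multiset.

    Two atoms get equal signatures iff they have the same element and the
    same multiset of (neighbour element, bond order-class) pairs, which is
    invariant under any relabelling of the molecule.
    """

    element: str
    neighbours: tuple[tuple[str, str], ...]  # ((element, order name), ...) sorted


def atom_signature(mol: MoleculeGraph, index: int, strict: bool = True) -> AtomSignature:
    """Signature of atom ``index``.

    With ``strict=False`` the bond order-class is dropped from the
    neighbour multiset (element + degree environment only), the fallback
    used when formats disagree on bond orders.
    """
    if not 0 <= index < len(mol):
        raise IndexError(f"atom index {index} out of range")
    nbrs = []
    for j, order in mol.adjacency()[index]:
        nbrs.append((mol.atoms[j].element, order.name if strict else ""))
    return AtomSignature(mol.atoms[index].element, tuple(sorted(nbrs)))


# -- hydrogen stripping --------------------------------------------------


def strip_hydrogens(mol: MoleculeGraph) -> MoleculeGraph:
    """Heavy-atom subgraph; ``original_index`` of survivors is preserved.

    Idempotent; an all-hydrogen molecule yields an empty graph, which is
    rejected downstream by matching/RMSD.
    """
    keep = [i for i, a in enumerate(mol.atoms) if not a.is_hydrogen]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [mol.atoms[i] for i in keep]
    bonds = [
        Bond(remap[b.i], remap[b.j], b.order)
        for b in mol.bonds
        if b.i in remap and b.j in remap
    ]
    return MoleculeGraph(atoms, bonds, mol.name, mol.properties)


# -- connectivity --------------------------------------------------------


def connected_components(mol: MoleculeGraph) -> list[set[int]]:
    """Partition atom indices by connectivity.

    Ordered by component size descending, then by smallest member index,
    so multi-fragment ligands (salt pairs) are matched deterministically.
    """
    n = len(mol)
    seen = [False] * n
    comps: list[set[int]] = []
    adj = mol.adjacency()
    for start in range(n):
        if seen[start]:
            continue
        comp = {start}
        seen[start] = True
        stack = [start]
        while stack:
            u = stack.pop()
            for v, _ in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    comp.add(v)
                    stack.append(v)
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


# -- aromatic normalisation ----------------------------------------------


def normalise_aromatic_rings(mol: MoleculeGraph) -> MoleculeGraph:
    """Re-class Kekulé rings (alternating single/double cycle) as aromatic.

    File formats disagree on aromatic encoding: MOL2 marks bonds "ar" and
    SDF may either use order 4 or a Kekulé alternation.  Normalising both
    spellings to :attr:`BondOrder.AROMATIC` before signature computation
    lets a Kekulé SDF match an aromatic MOL2 of the same ligand.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(mol)))
    order_of: dict[tuple[int, int], BondOrder] = {}
    for b in mol.bonds:
        g.add_edge(*b.key)
        order_of[b.key] = b.order
    aromatic: set[tuple[int, int]] = set()
    for cycle in nx.cycle_basis(g):
        k = len(cycle)
        if k < 4 or k % 2 != 0:
            continue
        ring_orders = []
        ok = True
        for idx in range(k):
            i, j = cycle[idx], cycle[(idx + 1) % k]
            key = (i, j) if i < j else (j, i)
            o = order_of.get(key)
            if o is None:
                ok = False
                break
            ring_orders.append((key, o))
        if not ok:
            continue
        orders = [o for _, o in ring_orders]
        alternating = all(
            {orders[idx], orders[(idx + 1) % k]} == {BondOrder.SINGLE, BondOrder.DOUBLE}
            for idx in range(k)
        )
        if alternating:
            aromatic.update(key for key, _ in ring_orders)
    if not aromatic:
        return mol
    bonds = [
        Bond(b.i, b.j, BondOrder.AROMATIC if b.key in aromatic else b.order)
        for b in mol.bonds
    ]
    return MoleculeGraph(mol.atoms, bonds, mol.name, mol.properties)
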