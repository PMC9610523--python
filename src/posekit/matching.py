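"""Label-invariant atom correspondence between two conformers.

Docked poses and a reference structure of the same ligand usually carry
their atoms in different orders, so RMSD is only defined once an atom
correspondence is established.  Finding it is a graph-isomorphism search
(non-polynomial in general); :func:`match_atoms` uses a greedy
depth-first traversal that, at each branching step, ranks the candidate
assignments by the positional RMSD of everything assigned so far and
follows the minimising branch, backtracking on dead ends within a
bounded budget.  :func:`brute_force_match` enumerates *all* compatible
isomorphisms (via NetworkX's VF2 matcher) and returns the global
minimum-RMSD mapping; it serves as the exact oracle for small molecules.

Atoms are compared through local signatures — element, covalently bound
neighbour elements, and bond order-classes.  When bond orders disagree
between file formats, a relaxed ladder step drops the order-class from
the signature.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import IncompatibleMoleculesError, MatchingFailureError, PosekitError
from .graph import (
    AtomSignature,
    MoleculeGraph,
    atom_signature,
    connected_components,
    strip_hydrogens,
)

#: Default number of alternative-branch expansions allowed per root pair.
DEFAULT_BACKTRACK_BUDGET = 1000


@dataclass
class AtomMapping:
    """Bijection between reference and probe heavy-atom indices.

    ``pairs`` lists (reference index, probe index) in reference order;
    indices refer to the hydrogen-stripped graphs.
    """

    pairs: list[tuple[int, int]]
    complete: bool
    strictness: str = "strict"

    def __post_init__(self) -> None:
        refs = [r for r, _ in self.pairs]
        probes = [p for _, p in self.pairs]
        if len(set(refs)) != len(refs) or len(set(probes)) != len(probes):
            raise ValueError("mapping is not bijective")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        arr = np.asarray(sorted(self.pairs), dtype=int)
        return arr[:, 0], arr[:, 1]


def pairs_rmsd(ref: MoleculeGraph, probe: MoleculeGraph, pairs: Sequence[tuple[int, int]]) -> float:
    """Positional RMSD over the given index pairs (no superposition)."""
    if not pairs:
        raise ValueError("empty mapping")
    arr = np.asarray(pairs, dtype=int)
    d = ref.coords[arr[:, 0]] - probe.coords[arr[:, 1]]
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def _prepare(ref: MoleculeGraph, probe: MoleculeGraph) -> tuple[MoleculeGraph, MoleculeGraph]:
    ref_h = strip_hydrogens(ref)
    probe_h = strip_hydrogens(probe)
    if len(ref_h) == 0 or len(probe_h) == 0:
        raise MatchingFailureError("no heavy atoms to match")
    if len(ref_h) != len(probe_h):
        raise IncompatibleMoleculesError(
            f"heavy-atom counts differ ({len(ref_h)} vs {len(probe_h)})"
        )
    if Counter(ref_h.elements) != Counter(probe_h.elements):
        raise IncompatibleMoleculesError("element multisets differ")
    return ref_h, probe_h


# -- greedy DFS ----------------------------------------------------------


class _BudgetExhausted(Exception):
    pass


def _dfs_order(mol: MoleculeGraph, atoms: Sequence[int], root: int) -> list[int]:
    """Deterministic DFS preorder of a connected component from ``root``."""
    in_comp = set(atoms)
    order, seen = [], set()
    stack = [root]
    while stack:
        u = stack.pop()
        if u in seen:
            continue
        seen.add(u)
        order.append(u)
        nbrs = sorted(j for j in mol.neighbours(u) if j in in_comp and j not in seen)
        stack.extend(reversed(nbrs))
    return order


def _greedy_from_roots(
    ref: MoleculeGraph,
    probe: MoleculeGraph,
    ref_atoms: Sequence[int],
    probe_atoms: Sequence[int],
    ref_root: int,
    probe_root: int,
    sig_ref: dict[int, AtomSignature],
    sig_probe: dict[int, AtomSignature],
    strict: bool,
    budget: int,
) -> Optional[list[tuple[int, int]]]:
    """Greedy best-first DFS assignment; returns the first complete mapping.

    The reference component is traversed in a fixed DFS preorder; each
    reference atom is assigned the compatible probe atom that minimises
    the squared-distance increment (equivalently the partial RMSD over
    everything assigned so far), with backtracking on dead ends.  Each
    non-first candidate taken anywhere counts against the budget.
    """
    order = _dfs_order(ref, ref_atoms, ref_root)
    probe_set = set(probe_atoms)
    rc, pc = ref.coords, probe.coords
    mapping: dict[int, int] = {}
    used: set[int] = set()
    spent = 0

    def candidates(r: int) -> list[int]:
        mapped_nbrs = [(r2, mapping[r2]) for r2 in ref.neighbours(r) if r2 in mapping]
        cands = []
        for p in probe_set:
            if p in used or sig_probe[p] != sig_ref[r]:
                continue
            ok = True
            for r2, p2 in mapped_nbrs:
                po = probe.bond_order(p, p2)
                if po is None:
                    ok = False
                    break
                if strict and po != ref.bond_order(r, r2):
                    ok = False
                    break
            if ok:
                cands.append(p)
        cands.sort(key=lambda p: (float(np.sum((rc[r] - pc[p]) ** 2)), p))
        return cands

    def extend(t: int) -> bool:
        nonlocal spent
        if t == len(order):
            return True
        r = order[t]
        for rank, p in enumerate(candidates(r)):
            if rank > 0:
                spent += 1
                if spent > budget:
                    raise _BudgetExhausted
            mapping[r] = p
            used.add(p)
            if extend(t + 1):
                return True
            del mapping[r]
            used.discard(p)
        return False

    if sig_probe[probe_root] != sig_ref[ref_root]:
        return None
    try:
        mapping[ref_root] = probe_root
        used.add(probe_root)
        if extend(1):
            return sorted(mapping.items())
    except (_BudgetExhausted, RecursionError):
        return None
    return None


def _component_signatures(
    mol: MoleculeGraph, strict: bool
) -> dict[int, AtomSignature]:
    return {i: atom_signature(mol, i, strict=strict) for i in range(len(mol))}


def _match_component(
    ref: MoleculeGraph,
    probe: MoleculeGraph,
    ref_atoms: Sequence[int],
    probe_atoms: Sequence[int],
    strict: bool,
    budget: int,
    sig_ref: dict[int, AtomSignature],
    sig_probe: dict[int, AtomSignature],
) -> Optional[list[tuple[int, int]]]:
    """Best greedy mapping for one connected component over all root pairs."""
    counts = Counter(sig_ref[i] for i in ref_atoms)
    # rarest signature, tie-break by lowest atom index
    ref_root = min(ref_atoms, key=lambda i: (counts[sig_ref[i]], i))
    root_sig = sig_ref[ref_root]
    probe_roots = sorted(p for p in probe_atoms if sig_probe[p] == root_sig)
    best: Optional[list[tuple[int, int]]] = None
    best_rmsd = np.inf
    for p_root in probe_roots:
        pairs = _greedy_from_roots(
            ref, probe, ref_atoms, probe_atoms, ref_root, p_root,
            sig_ref, sig_probe, strict, budget,
        )
        if pairs is None:
            continue
        r = pairs_rmsd(ref, probe, pairs)
        if r < best_rmsd - 1e-12:
            best, best_rmsd = pairs, r
    return best


def match_atoms(
    ref: MoleculeGraph,
    probe: MoleculeGraph,
    backtrack_budget: int = DEFAULT_BACKTRACK_BUDGET,
) -> AtomMapping:
    """Greedy DFS atom correspondence between two conformers.

    Hydrogens are stripped first; returned indices refer to the stripped
    graphs.  Root selection: the reference atom with the rarest signature
    (lowest index on ties); every probe atom sharing that signature is
    tried as probe root and the mapping with the lowest full-molecule
    RMSD wins.  Multi-fragment ligands are matched per connected
    component, pairing components by size and element multiset.

    Raises
    ------
    IncompatibleMoleculesError
        Different heavy-atom counts or element multisets.
    MatchingFailureError
        No complete mapping found within the backtrack budget (the
        exhaustive :func:`brute_force_match` may still succeed for small
        molecules).
    """
    ref_h, probe_h = _prepare(ref, probe)
    for strict in (True, False):
        sig_ref = _component_signatures(ref_h, strict)
        sig_probe = _component_signatures(probe_h, strict)
        if Counter(sig_ref.values()) != Counter(sig_probe.values()):
            continue
        ref_comps = connected_components(ref_h)
        probe_comps = connected_components(probe_h)
        if len(ref_comps) != len(probe_comps):
            raise IncompatibleMoleculesError("different number of fragments")
        pairs = _match_fragments(
            ref_h, probe_h, ref_comps, probe_comps, strict,
            backtrack_budget, sig_ref, sig_probe,
        )
        if pairs is not None:
            return AtomMapping(pairs, complete=True,
                               strictness="strict" if strict else "relaxed")
    raise MatchingFailureError(
        "no complete mapping within the backtrack budget; "
        "brute_force_match may succeed for small molecules"
    )


def _fragment_key(mol: MoleculeGraph, comp: set[int]) -> tuple:
    return (len(comp), tuple(sorted(mol.atoms[i].element for i in comp)))


def _match_fragments(
    ref: MoleculeGraph,
    probe: MoleculeGraph,
    ref_comps: list[set[int]],
    probe_comps: list[set[int]],
    strict: bool,
    budget: int,
    sig_ref: dict[int, AtomSignature],
    sig_probe: dict[int, AtomSignature],
) -> Optional[list[tuple[int, int]]]:
    used = [False] * len(probe_comps)
    all_pairs: list[tuple[int, int]] = []
    for rcomp in ref_comps:
        key = _fragment_key(ref, rcomp)
        best_pairs, best_rmsd, best_idx = None, np.inf, -1
        for idx, pcomp in enumerate(probe_comps):
            if used[idx] or _fragment_key(probe, pcomp) != key:
                continue
            pairs = _match_component(
                ref, probe, sorted(rcomp), sorted(pcomp), strict,
                budget, sig_ref, sig_probe,
            )
            if pairs is None:
                continue
            r = pairs_rmsd(ref, probe, pairs)
            if r < best_rmsd - 1e-12:
                best_pairs, best_rmsd, best_idx = pairs, r, idx
        if best_pairs is None:
            return None
        used[best_idx] = True
        all_pairs.extend(best_pairs)
    return sorted(all_pairs)


# -- exhaustive oracle ---------------------------------------------------


def brute_force_match(
    ref: MoleculeGraph,
    probe: MoleculeGraph,
    max_atoms: int = 14,
) -> AtomMapping:
    """Globally optimal mapping by exhaustive isomorphism enumeration.

    Enumerates every element- and bond-order-preserving isomorphism
    between the hydrogen-stripped graphs (VF2) and returns the one with
    minimal positional RMSD; ties go to the lexicographically smallest
    pair list.  Intended as a validation oracle — cost grows
    factorially, hence the ``max_atoms`` guard.
    """
    import networkx as nx
    from networkx.algorithms import isomorphism as iso

    ref_h, probe_h = _prepare(ref, probe)
    n = len(ref_h)
    if n > max_atoms:
        raise PosekitError(
            f"brute_force_match limited to {max_atoms} heavy atoms (got {n})"
        )

    def to_nx(mol: MoleculeGraph) -> "nx.Graph":
        g = nx.Graph()
        for i, a in enumerate(mol.atoms):
            g.add_node(i, element=a.element)
        for b in mol.bonds:
            g.add_edge(b.i, b.j, order=b.order.name)
        return g

    g_ref, g_probe = to_nx(ref_h), to_nx(probe_h)
    node_match = iso.categorical_node_match("element", None)
    for strict, strictness in ((True, "strict"), (False, "relaxed")):
        edge_match = iso.categorical_edge_match("order", None) if strict else None
        gm = iso.GraphMatcher(g_ref, g_probe, node_match=node_match, edge_match=edge_match)
        best_pairs: Optional[list[tuple[int, int]]] = None
        best_rmsd = np.inf
        for m in gm.isomorphisms_iter():
            pairs = sorted(m.items())
            r = pairs_rmsd(ref_h, probe_h, pairs)
            if r < best_rmsd - 1e-12 or (
                abs(r - best_rmsd) <= 1e-12 and (best_pairs is None or pairs < best_pairs)
            ):
                best_pairs, best_rmsd = pairs, r
        if best_pairs is not None:
            return AtomMapping(best_pairs, complete=True, strictness=strictness)
    raise MatchingFailureError("no isomorphism between the two graphs")
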