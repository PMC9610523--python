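"""Positional RMSD between a reference pose and docked poses.

The statistic is

    RMSD = sqrt( (1/N) * sum_i  delta_i^2 )

where N is the number of (heavy) ligand atoms and delta_i the Euclidean
distance between corresponding atoms of the two structures.  All
coordinates are taken in the shared receptor frame and **no
superposition is performed**: a rigid displacement of the probe
contributes fully.  This is the quantity of interest for re-docking
evaluation, where "how far from the experimental pose" includes the
placement, not just the conformation.  Alignment-based (Kabsch) RMSD
would give different, generally smaller, values.

Two calculation modes exist: all heavy atoms (default), and a
backbone-restricted mode for peptide ligands that keeps only the
repeating N-Calpha-C'(=O) backbone atoms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import IncompatibleMoleculesError, MatchingFailureError, NotAPeptideError, PosekitError
from .graph import BondOrder, MoleculeGraph, strip_hydrogens
from .matching import AtomMapping, match_atoms, pairs_rmsd


class RMSDMode(enum.Enum):
    ALL_HEAVY = "all"
    BACKBONE = "backbone"


@dataclass
class RMSDResult:
    """RMSD of one pose against the reference.

    ``value`` is in Å over ``n_atoms`` mapped atoms; ``error`` carries a
    per-pose failure message when batch processing continued past it.
    """

    value: Optional[float]
    mode: RMSDMode
    n_atoms: int
    pose_index: int = 0
    mapping: Optional[AtomMapping] = None
    error: str = ""

    @property
    def ok(self) -> bool:
        return self.error == ""


def compute_rmsd(
    ref: MoleculeGraph,
    probe: MoleculeGraph,
    mapping: AtomMapping,
    mode: RMSDMode = RMSDMode.ALL_HEAVY,
    atom_subset: Optional[set[int]] = None,
) -> RMSDResult:
    """RMSD over a complete mapping's atom pairs (indices of the
    hydrogen-stripped graphs).

    ``atom_subset`` restricts the sum to reference atoms in the subset
    (used by backbone mode).
    """
    if not mapping.complete:
        raise MatchingFailureError("RMSD requires a complete atom mapping")
    ref_h, probe_h = strip_hydrogens(ref), strip_hydrogens(probe)
    pairs = mapping.pairs
    if atom_subset is not None:
        pairs = [(r, p) for r, p in pairs if r in atom_subset]
        if not pairs:
            raise PosekitError("atom subset excludes every mapped atom")
    value = pairs_rmsd(ref_h, probe_h, pairs)
    return RMSDResult(value=value, mode=mode, n_atoms=len(pairs), mapping=mapping)


def rmsd_all(
    ref: MoleculeGraph,
    poses: Sequence[MoleculeGraph],
    mode: RMSDMode = RMSDMode.ALL_HEAVY,
    backbone_carbonyl_oxygen: bool = True,
) -> list[RMSDResult]:
    """RMSD of every pose against one reference, matching re-run per pose.

    Failures (incompatible pose, matching failure) are reported in the
    per-pose result instead of aborting the batch.
    """
    results: list[RMSDResult] = []
    subset: Optional[set[int]] = None
    if mode is RMSDMode.BACKBONE:
        subset = backbone_filter(ref, include_carbonyl_oxygen=backbone_carbonyl_oxygen)
    for idx, pose in enumerate(poses):
        try:
            mapping = match_atoms(ref, pose)
            res = compute_rmsd(ref, pose, mapping, mode=mode, atom_subset=subset)
            res.pose_index = idx
        except PosekitError as exc:
            res = RMSDResult(value=None, mode=mode, n_atoms=0,
                             pose_index=idx, error=str(exc))
        results.append(res)
    return results


# -- peptide backbone ----------------------------------------------------

_BACKBONE_NAMES = {"N", "CA", "C"}


def backbone_filter(
    mol: MoleculeGraph, include_carbonyl_oxygen: bool = True
) -> set[int]:
    """Indices (in the hydrogen-stripped graph) of peptide backbone atoms.

    Uses PDB atom names (N/CA/C/O) when every residue carries them;
    otherwise searches the graph for the repeating N-Calpha-C'(=O) motif:
    a carbon bonded to a nitrogen and to a carbonyl carbon, residues
    chained through the C'-N peptide bond.  The carbonyl oxygen is part
    of the backbone by default (N, Calpha, C', O per residue);
    ``include_carbonyl_oxygen=False`` restricts to N/Calpha/C'.

    Raises :class:`NotAPeptideError` when no motif is present.
    """
    m = strip_hydrogens(mol)
    named = _backbone_by_names(m, include_carbonyl_oxygen)
    if named is not None:
        return named
    motifs = _residue_motifs(m)
    if not motifs:
        raise NotAPeptideError(
            "no peptide backbone motif (N-Calpha-C'=O) found; "
            "use the all-heavy-atom mode for non-peptide ligands"
        )
    chain = _longest_residue_chain(m, motifs)
    out: set[int] = set()
    for n, ca, c, o in chain:
        out.update((n, ca, c))
        if include_carbonyl_oxygen:
            out.add(o)
    return out


def _backbone_by_names(m: MoleculeGraph, include_o: bool) -> Optional[set[int]]:
    if not all(a.name for a in m.atoms):
        return None
    wanted = _BACKBONE_NAMES | ({"O"} if include_o else set())
    hits = {i for i, a in enumerate(m.atoms) if a.name in wanted}
    # plausible only if at least one full residue worth of names is present
    names = {m.atoms[i].name for i in hits}
    if _BACKBONE_NAMES <= names:
        return hits
    return None


def _residue_motifs(m: MoleculeGraph) -> list[tuple[int, int, int, int]]:
    """All (N, Calpha, C', O) motifs: Calpha carbon bonded to an N and to
    a carbon bearing a double-bonded (or perceived single) terminal O."""
    motifs = []
    for ca, atom in enumerate(m.atoms):
        if atom.element != "C":
            continue
        n_nbrs = [j for j in m.neighbours(ca) if m.atoms[j].element == "N"]
        if not n_nbrs:
            continue
        for c in m.neighbours(ca):
            if m.atoms[c].element != "C":
                continue
            oxy = [
                j
                for j in m.neighbours(c)
                if m.atoms[j].element == "O"
                and len(m.neighbours(j)) == 1
                and m.bond_order(c, j) in (BondOrder.DOUBLE, BondOrder.SINGLE, BondOrder.AROMATIC)
            ]
            carbonyl = [j for j in oxy if m.bond_order(c, j) is BondOrder.DOUBLE]
            o = carbonyl[0] if carbonyl else (oxy[0] if oxy else None)
            if o is None:
                continue
            for n in n_nbrs:
                motifs.append((n, ca, c, o))
    return motifs


def _longest_residue_chain(
    m: MoleculeGraph, motifs: list[tuple[int, int, int, int]]
) -> list[tuple[int, int, int, int]]:
    """Longest simple chain of motifs linked through C'(i)-N(i+1) bonds."""
    links: dict[int, list[int]] = {i: [] for i in range(len(motifs))}
    for i, (_, _, c, _) in enumerate(motifs):
        for j, (n2, _, _, _) in enumerate(motifs):
            if i != j and m.bond_order(c, n2) is not None:
                links[i].append(j)

    best: list[int] = []

    def walk(path: list[int], used_atoms: set[int]) -> None:
        nonlocal best
        if len(path) > len(best):
            best = list(path)
        for j in links[path[-1]]:
            atoms_j = set(motifs[j])
            if j not in path and not (atoms_j & used_atoms):
                walk(path + [j], used_atoms | atoms_j)

    for i in range(len(motifs)):
        walk([i], set(motifs[i]))
    return [motifs[i] for i in best]
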