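# posekit

Label-invariant ligand RMSD, docking-pose clustering and receptor–ligand
interaction reports, as a Python library with a small CLI.

## Who this is for

Anyone evaluating molecular docking — in particular re-docking
benchmarks, where a ligand is removed from an experimental complex,
docked back, and the protocol is judged by how far each predicted pose
lies from the experimental one.  Docking programs relabel atoms and
write a zoo of file formats, so the two bookkeeping steps that precede
any judgement (finding the atom correspondence, and reading
SDF/MOL/MOL2/PDB/PDBQT with their scores) are handled here, along with
the two analyses that follow (pairwise-RMSD pose clustering and a
geometric interaction report).

## The statistic

For a reference pose and a docked pose of the same molecule,

    RMSD = sqrt( (1/N) * Σᵢ δᵢ² )

with N the number of heavy atoms and δᵢ the Euclidean distance between
corresponding atoms **in the shared receptor frame — no superposition is
performed**, so a rigid displacement contributes fully.  The
correspondence is recovered by a greedy depth-first graph matcher: atoms
are graph nodes, bonds are edges, candidate assignments at each
branching step are ranked by the partial RMSD of everything assigned so
far, and the minimising branch is followed (with bounded backtracking).
An exhaustive isomorphism-enumeration oracle (`brute_force_match`)
validates the greedy result on small molecules.

Pose sets are clustered on their pairwise RMSD matrix with the gromos
neighbour-count algorithm (default) or single-/complete-linkage
agglomeration, with a configurable cutoff (default 1.0 Å) and minimum
cluster size (default 4).  Details, conventions and limitations are in
`docs/methods.md`.

## Worked example

Generate a synthetic docking result (three planted pose clusters around
a 10-atom molecule, Vina-style PDBQT with scores), then analyse it:

```python
from pathlib import Path
from posekit import Format, write_structures
from posekit.synthdata import SyntheticSpec, generate_molecule, generate_pose_set

base = generate_molecule(SyntheticSpec(n_heavy_atoms=10, seed=11))
Path("reference.sdf").write_text(write_structures([base], Format.SDF))
ps = generate_pose_set(base, k_clusters=3, intra_spread=0.2,
                       separation=3.0, sizes=[5, 3, 2], seed=12)
Path("poses.pdbqt").write_text(ps.text)
```

```
$ posekit rmsd --ref reference.sdf --poses poses.pdbqt
pose_index	rmsd_angstrom	n_atoms	mode
0	0.323	10	all
1	6.246	10	all
2	3.372	10	all
3	0.293	10	all
4	3.485	10	all
5	3.470	10	all
6	6.236	10	all
7	0.342	10	all
8	0.276	10	all
9	0.250	10	all
```

Each row is one pose's positional RMSD to the reference over its 10
heavy atoms: five poses sit on the reference (~0.3 Å, the planted
0.2 Å-noise cluster), three were translated ~3.4 Å away and two ~6.2 Å
— the matcher recovered the correspondence although every PDBQT model
lists its atoms in its own order.

```
$ posekit cluster --input poses.pdbqt --program vina --cutoff 1.0 --min-size 1
cluster	size	members	representative	score
1	5	0 3 7 8 9	0	-10.191
2	3	2 4 5	2	-8.506
3	2	1 6	1	-6.918
```

The gromos algorithm recovers the three planted clusters exactly; the
most populated cluster carries the most favourable (most negative) Vina
score, the representative (listed first among the members) being the
cluster centre.  `posekit interact --receptor rec.pdb --ligand lig.sdf`
reports hydrogen bonds, ionic, hydrophobic, π-stacking and metal
contacts for a pose, and `posekit fixtures` writes synthetic test
inputs.

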