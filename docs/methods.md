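# Methods

## Problem setting

Re-docking benchmarks remove a ligand from an experimentally determined
complex, dock it back, and judge the protocol by how far each predicted
pose lies from the experimental one.  The distance of record is the
positional root-mean-square deviation

    RMSD = sqrt( (1/N) * sum_i delta_i^2 )

over the N heavy atoms of the ligand, where delta_i is the Euclidean
distance between corresponding atoms.  Two practical obstacles motivate
this package: docking programs relabel atoms, so the correspondence must
be recovered before the sum is defined; and a docking run produces many
poses, which are best digested by clustering their pairwise RMSD matrix.

**No superposition is performed.**  Poses and reference share the
receptor's coordinate frame, and a rigid displacement contributes fully
to the RMSD.  This is deliberate: for pose evaluation, *where* the
ligand sits is as important as its internal conformation.  A
Kabsch-superposed RMSD would report systematically smaller values and is
out of scope.

Hydrogens are stripped before matching and RMSD (deuterium is treated as
hydrogen).  Values are reported to three decimals.

## Atom matching

A molecule is an undirected graph: atoms are nodes, covalent bonds are
edges.  Each atom carries a *signature* — its element plus the sorted
multiset of (neighbour element, bond order-class) pairs — which is
invariant under relabelling.  Exact minimum-RMSD correspondence is a
graph-isomorphism search and non-polynomial in general, so the default
matcher is greedy:

1. **Root selection.**  The reference atom with the rarest signature is
   the root (lowest index on ties); rare signatures minimise branching.
   Every probe atom sharing that signature is tried as a probe root.
2. **Greedy DFS.**  The reference component is traversed in a fixed
   depth-first preorder from the root.  Each reference atom is assigned
   the unused probe atom that (a) has the same signature, (b) is bonded
   to the images of all already-assigned reference neighbours with
   matching order-classes, and (c) minimises the squared-distance
   increment — equivalently, the candidates at each branching step are
   ranked by the partial RMSD over everything assigned so far, and the
   minimising branch is followed.  The enumeration is incremental
   (atom-at-a-time) rather than whole-neighbour-set-at-a-time; the two
   explore the same assignment space.
3. **Backtracking.**  On a dead end the search backtracks; each
   non-first candidate taken anywhere costs one unit of a budget of
   1,000 alternative expansions per root pair, after which that root
   pair is abandoned.  The first complete mapping found best-first *is*
   the greedy result for that root pair.
4. **Result.**  Over all probe roots, the complete mapping with the
   lowest full-molecule RMSD is returned.

A strictness ladder tolerates format disagreements on bond orders:
strict signatures (with order-classes) are tried first; if no complete
mapping exists, signatures fall back to element + neighbour-element
multiset.  Kekulé rings (alternating single/double cycles of even
length) are re-classed as aromatic on input, so a Kekulé SDF matches an
aromatic MOL2 of the same ligand.  Multi-fragment ligands (salt pairs)
are matched per connected component, pairing components by size and
element multiset, because a DFS cannot cross fragments.

`brute_force_match` is the validation oracle: it enumerates *all*
element- and order-preserving isomorphisms (NetworkX VF2) and returns
the global minimum-RMSD mapping, ties broken by the lexicographically
smallest pair list.  It is capped at 14 heavy atoms by default.  The
greedy matcher can never beat it, and on the random toy suite used in
the tests it equals it in every case measured.

A note on symmetric molecules: the matched RMSD is a minimum over
symmetry-equivalent correspondences, so for a molecule with graph
automorphisms even a pure rigid translation can be measured along a
symmetry image at less than the translation distance.  The exactness
tests therefore pin the correspondence with a self-match (distance 0)
before translating.

## Backbone mode for peptide ligands

For peptide ligands the RMSD can be restricted to the backbone.  When
PDB atom names are present, atoms named N/CA/C (and O by default) are
selected.  Otherwise the graph is searched for the repeating
N–Cα–C′(=O) motif: a carbon bonded to a nitrogen and to a carbon
carrying a terminal oxygen; residues are chained through the C′–N
peptide bond and the longest consistent chain wins.  The carbonyl
oxygen is included by default (the conventional four-atom backbone);
`include_carbonyl_oxygen=False` restricts to N/Cα/C′.  Non-peptides
raise a dedicated error recommending the all-heavy-atom mode.

## Clustering

The pairwise matrix holds the heavy-atom positional RMSD between every
pose pair.  When all poses list the same element sequence (one docking
output file) input order is trusted and coordinates are compared
directly; otherwise per-pair matching is invoked.

* **gromos** (default): each remaining pose counts its neighbours at
  RMSD ≤ cutoff; the pose with the most neighbours (lowest index on
  ties) becomes a centre and leaves the pool with its neighbours.
  Cluster sizes are non-increasing in formation order.  The centre is
  the representative.
* **single / complete linkage**: agglomerative; inter-cluster distance
  is the minimum (single) or maximum (complete) cross-pair RMSD; the
  closest pair of clusters is merged while its distance is strictly
  below the cutoff, ties broken by the lexicographically smallest
  (smallest-member, smallest-member) pair.  Final clusters are ordered
  by size descending, then smallest member.  The representative is the
  best-scoring member (scores are lower-is-better for Vina and
  Chemgauss), falling back to the lowest pose index.

Boundary conventions differ on purpose: gromos neighbourhoods use
≤ cutoff, linkage merges use < cutoff.  For continuous distance data the
two readings coincide almost surely, which is why single linkage at
cutoff c partitions poses exactly into the connected components of the
≤ c threshold graph (verified against an independent component finder,
and against SciPy's hierarchical clustering, on random matrices).

Defaults mirror common practice for tens of poses: cutoff 1.0 Å,
minimum cluster size 4; groups below the minimum size are reported as
unclustered.  With small pose sets a minimum size of 1 is the sensible
choice.  The naive O(N³) agglomeration is deliberate: docking outputs
are tens of poses, and the transparent implementation keeps the
paper-specific tie-break and cutoff semantics explicit rather than
adapting a library call; SciPy serves as the cross-check instead.

## Interaction report

The interaction detector replaces visual inspection with geometric
criteria (thresholds configurable, defaults from the structural-biology
literature): hydrogen bonds (N/O donor to N/O/S acceptor ≤ 3.5 Å,
D–H···A ≥ 120° when an explicit hydrogen rides the donor; without
explicit hydrogens the criterion is distance-only), ionic contacts
(pattern-detected carboxylate/phosphate anions vs.
guanidinium/amidinium/primary-amine cations ≤ 4.0 Å), hydrophobic
contacts (apolar C···C ≤ 4.0 Å, apolar meaning no N/O neighbour),
π-stacking (5/6-ring centroids ≤ 5.5 Å, interplanar angle ≤ 30° or
60–90°), and metal coordination (metal to N/O/S ≤ 2.8 Å).  Charges are
inferred from connectivity patterns, not formal charge fields, because
most docking files carry none.  Records name the receptor residue when
labels exist and are sorted by distance, so the report is stable under
ligand relabelling.

## File handling

SDF (V2000 only; V3000 is rejected with a clear message), MOL, MOL2,
PDB/ENT and PDBQT are read; SDF and PDB are written; gzip-wrapped input
is accepted.  PDB-family records without CONECT get bonds perceived
from distances (sum of covalent radii + 0.45 Å).  PDBQT atom types are
mapped to elements through the AutoDock type table ("OA" → O, "A" → C,
…).  Scores come from `REMARK VINA RESULT` lines (Vina) or from an
ordered list of SDF data-tag names (FRED/HYBRID Chemgauss spellings,
then generic fallbacks); a missing score produces a warning and a
`None` record, and representative selection then falls back to pose
order.  All coordinates are ångströms in one shared frame.

## Synthetic data

The generator exists so every pipeline property is testable without
external downloads.  `generate_molecule` grows a random connected,
valence-legal graph: an optional regular 5/6-ring seed, then
atom-by-atom tree growth at ~1.5 Å bond length with clash rejection
(non-bonded pairs ≥ 2.2 Å), occasional double-bonded terminal oxygens.
Because bonded distances stay inside and non-bonded distances outside
the bond-perception window, a generated molecule written to PDBQT
re-reads with exactly its own bonds; pose-set noise draws that would
violate this are redrawn (the noise scale is unchanged — the draw is
conditioned on producing a chemically self-consistent file).

`generate_pose_set` plants k clusters as rigid translations spaced
`separation` Å apart along a line, each populated with copies perturbed
at `intra_spread` Å per coordinate, and assigns scores so the most
populated cluster has the best mean.  The canonical test conditions are
k = 3, separation 3 Å, spread 0.2 Å, cutoff 1.0 Å: within-cluster RMSDs
concentrate near `spread·√6 ≈ 0.49` Å and between-cluster RMSDs near
3 Å, so exact recovery is expected and verified.  Toy-suite matching
conditions are ≤ 12 heavy atoms, random permutation, 0.1 Å coordinate
noise, 100 molecules.

What the generator does **not** emulate: realistic bond geometry
(angles, torsions, conjugation), conformational flexibility (pose
clusters differ by rigid translation only), receptor context, and score
distributions of real docking programs.  Passing tests therefore
demonstrate the correctness of matching, RMSD and clustering logic, not
docking accuracy on real chemistry; the published worked examples
(5CGC ligand 0.297 Å, netropsin/1DNE 2.219 Å, 4 and 7 gromos clusters)
are wired as an integration test that runs whenever the original input
files are placed under `tests/data/redocking/`.

## Numerical choices and limitations

* Strict comparisons use a 1e-12 slack for "better than" decisions in
  matcher root selection so floating-point noise cannot flip
  deterministic tie-breaks; mapping ties resolve to the
  lexicographically smallest pair list.
* Problem sizes in the default suite and acceptance script (100 toy
  molecules, 200 random matrices, 16-pose planted sets, 5 round-trip
  sets) were chosen to make the statistical checks stable across seeds
  while keeping a full run in seconds.
* The greedy matcher is not guaranteed optimal; on adversarial
  symmetric molecules with large coordinate noise it can exceed the
  exhaustive minimum, which is why the oracle exists and why batch APIs
  report per-pose failures instead of aborting.
* Bond perception cannot distinguish bond orders; perceived PDB/PDBQT
  graphs rely on the relaxed signature ladder when matched against
  order-annotated formats.
* Chirality is ignored: enantiomeric correspondences are accepted if
  graph-compatible.  Stereochemistry-aware matching is a non-goal.
* Charged-group and aromatic-ring pattern detection are heuristics;
  unusual chemotypes (ylides, metallocenes) may be missed by the
  interaction detector.
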