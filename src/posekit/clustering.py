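"""Docking-pose clustering on a pairwise RMSD matrix.

Workflow: compute the N x N matrix of pairwise positional RMSD values
between docked poses, then group poses with one of three algorithms:

* **gromos** — iteratively, every remaining pose counts its neighbours
  (poses within the RMSD cutoff); the pose with the most neighbours
  becomes a cluster centre and, together with its neighbours, leaves the
  pool.  Cluster sizes are non-increasing in formation order, and the
  centre is the representative.
* **single linkage** — agglomerative; the distance between two clusters
  is the *lowest* pairwise member RMSD.  Leaves outliers as singletons.
* **complete linkage** — agglomerative; the distance is the *highest*
  pairwise member RMSD, so every cluster's diameter stays below the
  cutoff.

Agglomeration merges the closest pair while its linkage distance is
strictly below the cutoff.  Groups smaller than the minimum cluster size
are reported as unclustered.  Defaults: cutoff 1.0 Å, minimum size 4.
Linkage representatives are the best-scoring member (scores are
"lower = better" for Vina and Chemgauss); with no scores, the lowest
pose index stands in.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import IncompatibleMoleculesError, PosekitError
from .graph import MoleculeGraph, strip_hydrogens
from .matching import match_atoms, pairs_rmsd


class Algorithm(enum.Enum):
    GROMOS = "gromos"
    SINGLE = "single"
    COMPLETE = "complete"


@dataclass
class ClusteringParams:
    algorithm: Algorithm = Algorithm.GROMOS
    cutoff: float = 1.0
    min_size: int = 4

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive (got {self.cutoff})")
        if self.min_size < 1:
            raise ValueError(f"min-size must be >= 1 (got {self.min_size})")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise pose-RMSD matrix in Å."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any() or not np.isfinite(v).all():
            raise ValueError("distances must be finite and non-negative")
        self.values = v

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class Cluster:
    members: list[int]
    representative: int
    representative_score: Optional[float] = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Clustering:
    clusters: list[Cluster]
    unclustered: list[int]
    params: ClusteringParams

    def membership(self) -> dict[int, int]:
        """pose index → cluster ordinal (unclustered poses absent)."""
        out = {}
        for cid, c in enumerate(self.clusters):
            for m in c.members:
                out[m] = cid
        return out


def pairwise_matrix(poses: Sequence[MoleculeGraph]) -> DistanceMatrix:
    """All-against-all heavy-atom positional RMSD between poses.

    When every pose lists the same element sequence (the usual case for
    one docking output file) coordinates are compared directly in input
    order; otherwise per-pair atom matching is invoked.
    """
    n = len(poses)
    if n < 2:
        raise PosekitError("pairwise matrix needs at least 2 poses")
    stripped = [strip_hydrogens(p) for p in poses]
    same_order = all(s.elements == stripped[0].elements for s in stripped)
    mat = np.zeros((n, n))
    if same_order and len(stripped[0]) > 0:
        coords = np.stack([s.coords for s in stripped])
        diff = coords[:, None, :, :] - coords[None, :, :, :]
        mat = np.sqrt(np.mean(np.sum(diff**2, axis=-1), axis=-1))
        mat[np.diag_indices(n)] = 0.0
    else:
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    mapping = match_atoms(stripped[i], stripped[j])
                    d = pairs_rmsd(stripped[i], stripped[j], mapping.pairs)
                except PosekitError as exc:
                    raise IncompatibleMoleculesError(
                        f"poses {i} and {j} cannot be compared: {exc}"
                    ) from exc
                mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat)


# -- gromos --------------------------------------------------------------


def gromos_cluster(
    matrix: DistanceMatrix,
    params: Optional[ClusteringParams] = None,
    scores: Optional[Sequence[Optional[float]]] = None,
) -> Clustering:
    """Neighbour-count clustering.

    Repeatedly: among remaining poses, count neighbours within the
    cutoff (``d <= cutoff``); the pose with the highest count (lowest
    index on ties) is the next cluster's centre and representative, and
    it leaves the pool with its neighbours.  Clusters below the minimum
    size are moved to ``unclustered``.
    """
    params = params or ClusteringParams(algorithm=Algorithm.GROMOS)
    d = matrix.values
    pool = list(range(matrix.size))
    raw: list[Cluster] = []
    while pool:
        counts = {i: sum(1 for j in pool if j != i and d[i, j] <= params.cutoff) for i in pool}
        centre = min(pool, key=lambda i: (-counts[i], i))
        members = [centre] + [j for j in pool if j != centre and d[centre, j] <= params.cutoff]
        raw.append(Cluster(sorted(members), representative=centre))
        pool = [i for i in pool if i not in set(members)]
    return _finalise(raw, params, scores, rep_rule="centre")


# -- agglomerative linkage ----------------------------------------------


def linkage_cluster(
    matrix: DistanceMatrix,
    params: ClusteringParams,
    scores: Optional[Sequence[Optional[float]]] = None,
) -> Clustering:
    """Single- or complete-linkage agglomeration under a cutoff.

    Starting from singletons, the pair of clusters with the lowest
    linkage distance (min over cross pairs for single, max for complete)
    is merged while that distance is strictly below the cutoff.  Ties
    are broken by the lexicographically smallest (smallest-member,
    smallest-member) index pair.  The representative of each final
    cluster is its best-scoring member (lowest index fallback).
    """
    if params.algorithm not in (Algorithm.SINGLE, Algorithm.COMPLETE):
        raise ValueError("linkage_cluster handles SINGLE and COMPLETE only")
    d = matrix.values
    agg = np.min if params.algorithm is Algorithm.SINGLE else np.max
    clusters: list[list[int]] = [[i] for i in range(matrix.size)]
    while len(clusters) > 1:
        best = None  # (dist, min_i, min_j, a, b)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = float(agg(d[np.ix_(clusters[a], clusters[b])]))
                lo, hi = sorted((min(clusters[a]), min(clusters[b])))
                key = (dist, lo, hi)
                if best is None or key < best[:3]:
                    best = (*key, a, b)
        if best is None or best[0] >= params.cutoff:
            break
        _, _, _, a, b = best
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    raw = [Cluster(c, representative=c[0]) for c in clusters]
    return _finalise(raw, params, scores, rep_rule="score")


def _finalise(
    raw: list[Cluster],
    params: ClusteringParams,
    scores: Optional[Sequence[Optional[float]]],
    rep_rule: str,
) -> Clustering:
    kept: list[Cluster] = []
    unclustered: list[int] = []
    for c in raw:
        if c.size < params.min_size:
            unclustered.extend(c.members)
            continue
        if rep_rule == "score":
            c.representative = _best_scoring(c.members, scores)
        if scores is not None and c.representative < len(scores):
            c.representative_score = scores[c.representative]
        kept.append(c)
    return Clustering(kept, sorted(unclustered), params)


def _best_scoring(members: list[int], scores: Optional[Sequence[Optional[float]]]) -> int:
    if scores is None:
        return min(members)
    usable = [m for m in members if m < len(scores) and scores[m] is not None]
    if not usable:
        return min(members)
    return min(usable, key=lambda m: (scores[m], m))


# -- reporting -----------------------------------------------------------


def cluster_report(
    clustering: Clustering,
    scores: Optional[Sequence[Optional[float]]] = None,
) -> tuple[pd.DataFrame, list[tuple[Optional[float], int]]]:
    """Cluster table plus bar-plot series.

    Table columns: cluster id, size, member pose indices (representative
    first), representative score.  The bar-plot series pairs each
    cluster's representative score (x) with its size (y).
    """
    rows = []
    series: list[tuple[Optional[float], int]] = []
    for cid, c in enumerate(clustering.clusters):
        rep_score = c.representative_score
        if rep_score is None and scores is not None and c.representative < len(scores):
            rep_score = scores[c.representative]
        members = [c.representative] + [m for m in c.members if m != c.representative]
        rows.append(
            {
                "cluster": cid + 1,
                "size": c.size,
                "members": " ".join(str(m) for m in members),
                "representative": c.representative,
                "score": rep_score,
            }
        )
        series.append((rep_score, c.size))
    table = pd.DataFrame(rows, columns=["cluster", "size", "members", "representative", "score"])
    return table, series
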