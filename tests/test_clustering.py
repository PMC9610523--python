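"""Pose clustering: pairwise matrix, gromos, linkage, reports."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.sparse.csgraph import connected_components as cc
from scipy.spatial.distance import squareform

from posekit.clustering import (
    Algorithm,
    ClusteringParams,
    DistanceMatrix,
    cluster_report,
    gromos_cluster,
    linkage_cluster,
    pairwise_matrix,
)
from posekit.synthdata import (
    SyntheticSpec,
    generate_molecule,
    generate_pose_set,
    permute_atoms,
    translate,
)


def random_matrix(rng, n=12, scale=2.0):
    d = rng.uniform(0, scale, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d)


def dm(values):
    return DistanceMatrix(np.array(values, dtype=float))


class TestPairwiseMatrix:
    def test_identical_poses_zero_matrix(self):
        mol = generate_molecule(SyntheticSpec(n_heavy_atoms=8, seed=1))
        mat = pairwise_matrix([mol, mol, mol])
        assert np.allclose(mat.values, 0.0)

    def test_translation_gives_exact_entry(self):
        mol = generate_molecule(SyntheticSpec(n_heavy_atoms=8, seed=2))
        mat = pairwise_matrix([mol, translate(mol, (2.0, 0.0, 0.0))])
        assert mat.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_per_pair_matching_on_reordered_poses(self):
        mol = generate_molecule(SyntheticSpec(n_heavy_atoms=8, seed=3))
        shifted = translate(mol, (1.5, 0.0, 0.0))
        mat = pairwise_matrix([mol, permute_atoms(shifted, seed=7)])
        assert mat.values[0, 1] == pytest.approx(1.5, abs=1e-9)

    def test_planted_set_separates_within_and_between(self):
        base = generate_molecule(SyntheticSpec(n_heavy_atoms=10, seed=4))
        ps = generate_pose_set(base, k_clusters=2, intra_spread=0.15,
                               separation=4.0, sizes=4, seed=5, shuffle=False)
        mat = pairwise_matrix(ps.poses)
        labels = np.array(ps.labels)
        within = mat.values[np.ix_(labels == 0, labels == 0)]
        between = mat.values[np.ix_(labels == 0, labels == 1)]
        assert within.max() < between.min()


class TestGromos:
    def test_five_identical_structures_one_cluster(self):
        mat = dm(np.zeros((5, 5)))
        c = gromos_cluster(mat, ClusteringParams(Algorithm.GROMOS, 1.0, 1))
        assert len(c.clusters) == 1
        assert c.clusters[0].members == [0, 1, 2, 3, 4]
        assert c.clusters[0].representative == 0

    def test_hand_enumerated_neighbour_counts(self):
        # d(A,B)=0.3 d(A,C)=0.4 d(B,C)=0.6, D at 5.0 from everyone
        values = [
            [0.0, 0.3, 0.4, 5.0],
            [0.3, 0.0, 0.6, 5.0],
            [0.4, 0.6, 0.0, 5.0],
            [5.0, 5.0, 5.0, 0.0],
        ]
        c = gromos_cluster(dm(values), ClusteringParams(Algorithm.GROMOS, 0.5, 1))
        assert [cl.members for cl in c.clusters] == [[0, 1, 2], [3]]
        assert c.clusters[0].representative == 0

    def test_members_within_cutoff_of_centre(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            mat = random_matrix(rng)
            c = gromos_cluster(mat, ClusteringParams(Algorithm.GROMOS, 0.8, 1))
            for cl in c.clusters:
                for m in cl.members:
                    assert mat.values[cl.representative, m] <= 0.8

    def test_sizes_non_increasing_in_formation_order(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            mat = random_matrix(rng)
            c = gromos_cluster(mat, ClusteringParams(Algorithm.GROMOS, 0.9, 1))
            sizes = [cl.size for cl in c.clusters]
            assert sizes == sorted(sizes, reverse=True)

    def test_min_size_moves_small_groups_to_unclustered(self):
        values = [
            [0.0, 0.3, 5.0, 5.0, 5.0],
            [0.3, 0.0, 5.0, 5.0, 5.0],
            [5.0, 5.0, 0.0, 0.2, 0.3],
            [5.0, 5.0, 0.2, 0.0, 0.25],
            [5.0, 5.0, 0.3, 0.25, 0.0],
        ]
        c = gromos_cluster(dm(values), ClusteringParams(Algorithm.GROMOS, 0.5, 3))
        assert [cl.members for cl in c.clusters] == [[2, 3, 4]]
        assert c.unclustered == [0, 1]


class TestLinkage:
    def test_hand_agglomeration_chain(self):
        values = [[0.0, 0.4, 0.8], [0.4, 0.0, 0.4], [0.8, 0.4, 0.0]]
        single = linkage_cluster(dm(values), ClusteringParams(Algorithm.SINGLE, 0.5, 1))
        complete = linkage_cluster(dm(values), ClusteringParams(Algorithm.COMPLETE, 0.5, 1))
        assert [cl.members for cl in single.clusters] == [[0, 1, 2]]
        assert [cl.members for cl in complete.clusters] == [[0, 1], [2]]

    def test_all_distant_min_size_one_gives_singletons(self):
        mat = dm(np.ones((4, 4)) * 3.0 - 3.0 * np.eye(4))
        c = linkage_cluster(mat, ClusteringParams(Algorithm.SINGLE, 1.0, 1))
        assert [cl.members for cl in c.clusters] == [[0], [1], [2], [3]]
        assert c.unclustered == []

    def test_all_distant_min_size_two_all_unclustered(self):
        mat = dm(np.ones((4, 4)) * 3.0 - 3.0 * np.eye(4))
        c = linkage_cluster(mat, ClusteringParams(Algorithm.COMPLETE, 1.0, 2))
        assert c.clusters == []
        assert c.unclustered == [0, 1, 2, 3]

    def test_single_linkage_equals_threshold_components(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            mat = random_matrix(rng)
            cutoff = 0.7
            c = linkage_cluster(mat, ClusteringParams(Algorithm.SINGLE, cutoff, 1))
            adj = mat.values <= cutoff
            n_comp, labels = cc(adj, directed=False)
            ours = {frozenset(cl.members) for cl in c.clusters}
            theirs = {
                frozenset(np.flatnonzero(labels == k).tolist()) for k in range(n_comp)
            }
            assert ours == theirs

    def test_complete_linkage_diameter_below_cutoff(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            mat = random_matrix(rng)
            c = linkage_cluster(mat, ClusteringParams(Algorithm.COMPLETE, 0.9, 1))
            for cl in c.clusters:
                sub = mat.values[np.ix_(cl.members, cl.members)]
                assert sub.max() <= 0.9

    @pytest.mark.parametrize("method,algorithm",
                             [("single", Algorithm.SINGLE), ("complete", Algorithm.COMPLETE)])
    def test_agreement_with_scipy_hierarchy(self, method, algorithm):
        rng = np.random.default_rng(17)
        for _ in range(20):
            mat = random_matrix(rng)
            cutoff = 0.8
            c = linkage_cluster(mat, ClusteringParams(algorithm, cutoff, 1))
            z = scipy_linkage(squareform(mat.values, checks=False), method=method)
            flat = fcluster(z, t=cutoff - 1e-9, criterion="distance")
            ours = {frozenset(cl.members) for cl in c.clusters}
            theirs = {
                frozenset(np.flatnonzero(flat == k).tolist())
                for k in np.unique(flat)
            }
            assert ours == theirs

    def test_representative_is_best_scoring_member(self):
        values = [[0.0, 0.3, 0.3], [0.3, 0.0, 0.3], [0.3, 0.3, 0.0]]
        scores = [-5.0, -9.0, -7.0]
        c = linkage_cluster(dm(values), ClusteringParams(Algorithm.SINGLE, 0.5, 1), scores)
        assert c.clusters[0].representative == 1
        assert c.clusters[0].representative_score == -9.0

    def test_score_fallback_is_lowest_index(self):
        values = [[0.0, 0.3], [0.3, 0.0]]
        c = linkage_cluster(dm(values), ClusteringParams(Algorithm.COMPLETE, 0.5, 1))
        assert c.clusters[0].representative == 0


class TestReport:
    def test_single_cluster_bar(self):
        mat = dm(np.zeros((5, 5)))
        c = gromos_cluster(mat, ClusteringParams(Algorithm.GROMOS, 1.0, 1),
                           scores=[-7.5, -7.0, -6.5, -6.0, -5.5])
        table, series = cluster_report(c)
        assert series == [(-7.5, 5)]
        assert table.loc[0, "size"] == 5
        assert table.loc[0, "members"].startswith("0")

    def test_empty_clustering(self):
        mat = dm(np.ones((3, 3)) * 5 - 5 * np.eye(3))
        c = linkage_cluster(mat, ClusteringParams(Algorithm.SINGLE, 1.0, 2))
        table, series = cluster_report(c)
        assert table.empty and series == []

    def test_representative_listed_first(self):
        values = [[0.0, 0.3, 0.3], [0.3, 0.0, 0.3], [0.3, 0.3, 0.0]]
        scores = [-5.0, -9.0, -7.0]
        c = linkage_cluster(dm(values), ClusteringParams(Algorithm.SINGLE, 0.5, 1), scores)
        table, _ = cluster_report(c, scores)
        assert table.loc[0, "members"].split()[0] == "1"


class TestParamsValidation:
    def test_cutoff_must_be_positive(self):
        with pytest.raises(ValueError, match="cutoff"):
            ClusteringParams(Algorithm.GROMOS, -1.0, 1)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))
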