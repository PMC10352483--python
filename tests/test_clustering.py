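"""SOM training, metaclustering, cluster profiles and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from evscope.clustering import (best_matching_units, cluster_evs,
                                enrichment_test, featurize, metacluster,
                                profile_clusters, top_markers, train_som)
from evscope.matrix import SingleEVMatrix


def _mat(rows, proteins, sample="s"):
    return SingleEVMatrix(sample, [f"{sample}_ev{i}" for i in range(len(rows))],
                          proteins, sparse.csr_matrix(np.array(rows)))


class TestFeaturize:
    def test_binary_and_count_modes(self):
        proteins = ["CDCP1", "CD9", "EPCAM"]
        m = _mat([[3, 0, 0]], proteins)
        groups = pd.Series({"s": "G"})
        Xb, meta = featurize({"s": m}, groups, mode="binary")
        Xc, _ = featurize({"s": m}, groups, mode="counts")
        np.testing.assert_array_equal(Xb, [[1, 0, 0]])
        np.testing.assert_array_equal(Xc, [[3, 0, 0]])
        assert meta.iloc[0].group == "G"

    def test_pooling_preserves_ev_count(self, clean_truth):
        X, meta = featurize(clean_truth.matrices, clean_truth.sample_groups)
        total = sum(m.n_evs for m in clean_truth.matrices.values())
        assert X.shape == (total, 113)
        assert len(meta) == total


def _two_blobs(rng, n=400, d=6):
    """Binary blobs with disjoint marker halves; any within-blob point is
    strictly closer to its own blob than to the other."""
    a = np.zeros((n, d))
    a[:, : d // 2] = 1.0
    b = np.zeros((n, d))
    b[:, d // 2:] = 1.0
    noise = rng.normal(0, 0.05, (2 * n, d))
    return np.vstack([a, b]) + noise, np.array([0] * n + [1] * n)


class TestSOM:
    def test_identical_features_collapse(self):
        X = np.ones((150, 4))
        codebook = train_som(X, 3, 3, seed=1)
        np.testing.assert_allclose(codebook, 1.0)

    def test_two_blobs_separated(self):
        rng = np.random.default_rng(21)
        X, labels = _two_blobs(rng)
        codebook = train_som(X, 4, 4, seed=2)
        bmu = best_matching_units(X, codebook)
        # every node is pure: its EVs come from a single blob
        for node in np.unique(bmu):
            assert len(np.unique(labels[bmu == node])) == 1

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(22)
        X, _ = _two_blobs(rng)
        c1 = train_som(X, 4, 4, seed=7)
        c2 = train_som(X, 4, 4, seed=7)
        np.testing.assert_array_equal(c1, c2)

    def test_requires_enough_evs(self):
        with pytest.raises(ValueError, match="at least"):
            train_som(np.ones((5, 3)), 10, 10, seed=0)

    def test_bmu_tie_breaks_to_lowest_node(self):
        codebook = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert best_matching_units(np.array([[1.0, 0.0]]), codebook)[0] == 0

    def test_prototypes_within_data_range(self):
        rng = np.random.default_rng(23)
        X = rng.random((300, 5))
        codebook = train_som(X, 4, 4, seed=3)
        assert (codebook >= X.min(axis=0) - 1e-9).all()
        assert (codebook <= X.max(axis=0) + 1e-9).all()


def brute_force_average_linkage(points, k):
    """Naive agglomeration oracle: repeatedly merge the two clusters with
    the smallest mean pairwise distance."""
    clusters = [[i] for i in range(len(points))]
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([np.linalg.norm(points[i] - points[j])
                         for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(points), dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    return labels


def _partition_sets(labels):
    return {frozenset(np.flatnonzero(labels == v)) for v in np.unique(labels)}


class TestMetacluster:
    def test_k_equals_node_count_is_identity(self):
        rng = np.random.default_rng(31)
        codebook = rng.random((6, 3))
        occupied = np.ones(6, dtype=bool)
        labels = metacluster(codebook, occupied, k=6)
        assert len(np.unique(labels)) == 6

    def test_two_blob_codebook_split(self):
        codebook = np.vstack([np.zeros((5, 4)), np.ones((5, 4))])
        codebook += np.random.default_rng(32).normal(0, 0.01, codebook.shape)
        labels = metacluster(codebook, np.ones(10, dtype=bool), k=2)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[9]

    def test_matches_brute_force_agglomeration(self):
        rng = np.random.default_rng(33)
        points = rng.random((11, 4))
        for k in (2, 3, 5):
            labels = metacluster(points, np.ones(11, dtype=bool), k=k)
            brute = brute_force_average_linkage(points, k)
            assert _partition_sets(labels) == _partition_sets(brute)

    def test_k_larger_than_occupied_rejected(self):
        codebook = np.random.default_rng(34).random((8, 3))
        occupied = np.zeros(8, dtype=bool)
        occupied[:4] = True
        with pytest.raises(ValueError, match="occupied"):
            metacluster(codebook, occupied, k=5)

    def test_unoccupied_nodes_inherit_nearest_label(self):
        codebook = np.array([[0.0, 0], [0.1, 0], [1.0, 1], [0.9, 1.0],
                             [0.05, 0.0]])
        occupied = np.array([True, True, True, True, False])
        labels = metacluster(codebook, occupied, k=2)
        assert labels[4] == labels[0]

    def test_consensus_mode_deterministic(self):
        rng = np.random.default_rng(35)
        codebook = rng.random((12, 3))
        occ = np.ones(12, dtype=bool)
        l1 = metacluster(codebook, occ, k=3, n_consensus_reps=20, seed=5)
        l2 = metacluster(codebook, occ, k=3, n_consensus_reps=20, seed=5)
        np.testing.assert_array_equal(l1, l2)


class TestPipeline:
    def test_assignment_consistency_and_determinism(self, clean_truth):
        model, assignment = cluster_evs(
            clean_truth.matrices, clean_truth.sample_groups,
            grid_w=6, grid_h=6, k=8, seed=4)
        X, _ = featurize(clean_truth.matrices, clean_truth.sample_groups)
        nodes, meta = model.assign(X)
        np.testing.assert_array_equal(nodes, assignment.node)
        np.testing.assert_array_equal(meta, assignment.metacluster)
        # every EV's metacluster equals metacluster_of_node of its BMU
        np.testing.assert_array_equal(
            assignment.metacluster,
            model.metacluster_of_node[assignment.node])
        _, again = cluster_evs(clean_truth.matrices,
                               clean_truth.sample_groups,
                               grid_w=6, grid_h=6, k=8, seed=4)
        pd.testing.assert_frame_equal(assignment, again)

    def test_labels_ordered_by_descending_size(self, clean_truth):
        _, assignment = cluster_evs(clean_truth.matrices,
                                    clean_truth.sample_groups,
                                    grid_w=6, grid_h=6, k=8, seed=4)
        sizes = assignment.metacluster.value_counts().sort_index()
        assert (sizes.diff().dropna() <= 0).all()

    def test_planted_subcluster_recovered(self, clean_truth):
        """A case-only planted subpopulation yields a metacluster that is
        nearly pure case-group and whose top markers cover the planted set."""
        model, assignment = cluster_evs(
            clean_truth.matrices, clean_truth.sample_groups,
            grid_w=8, grid_h=8, k=10, seed=1)
        X, _ = featurize(clean_truth.matrices, clean_truth.sample_groups)
        prof = profile_clusters(assignment, X,
                                list(clean_truth.panel.proteins))
        best = prof["frac_OVCA"].idxmax()
        assert prof.loc[best, "frac_OVCA"] >= 0.9
        markers = top_markers(prof.loc[best], n=10)
        assert "CDCP1" in markers


class TestProfiles:
    def test_profiles_match_brute_force(self):
        rng = np.random.default_rng(41)
        n = 60
        assignment = pd.DataFrame({
            "ev_id": [f"e{i}" for i in range(n)],
            "sample": "s",
            "group": rng.choice(["A", "B"], n),
            "node": 0,
            "metacluster": rng.integers(1, 4, n)})
        X = (rng.random((n, 3)) < 0.5).astype(float)
        prof = profile_clusters(assignment, X, ["P0", "P1", "P2"])
        for mc, row in prof.iterrows():
            members = assignment.index[assignment.metacluster == mc]
            assert row["n_evs"] == len(members)
            assert row["size_fraction"] == pytest.approx(len(members) / n)
            for g in ("A", "B"):
                assert row[f"frac_{g}"] == pytest.approx(
                    (assignment.loc[members, "group"] == g).mean())
            for j, p in enumerate(["P0", "P1", "P2"]):
                assert row[f"detfreq_{p}"] == pytest.approx(
                    X[members, j].mean())

    def test_group_composition_sums_to_one(self, clean_truth):
        _, assignment = cluster_evs(clean_truth.matrices,
                                    clean_truth.sample_groups,
                                    grid_w=6, grid_h=6, k=6, seed=2)
        X, _ = featurize(clean_truth.matrices, clean_truth.sample_groups)
        prof = profile_clusters(assignment, X,
                                list(clean_truth.panel.proteins))
        np.testing.assert_allclose(prof.frac_OVCA + prof.frac_Con, 1.0)


class TestEnrichment:
    @staticmethod
    def _profile(fracs_and_sizes, case="case"):
        rows = []
        for i, (frac, n) in enumerate(fracs_and_sizes, start=1):
            rows.append({"metacluster": i, "n_evs": n,
                         f"frac_{case}": frac})
        return pd.DataFrame(rows).set_index("metacluster")

    def test_strong_enrichment_detected(self):
        rng = np.random.default_rng(51)
        assignment = pd.DataFrame({"group": rng.choice(["case", "ctrl"],
                                                       2000)})
        prof = self._profile([(0.95, 500), (0.5, 1500)])
        res = enrichment_test(prof, assignment, "case")
        # binomial tail for 475/500 at p ~ 0.5 is astronomically small
        assert res.loc[1, "p_value"] < 1e-3
        expected = stats.binomtest(
            int(round(0.95 * 500)), 500,
            float((assignment.group == "case").mean())).pvalue
        assert res.loc[1, "p_value"] == pytest.approx(expected)

    def test_uniform_cluster_not_significant(self):
        rng = np.random.default_rng(52)
        assignment = pd.DataFrame({"group": rng.choice(["case", "ctrl"],
                                                       1000)})
        pooled = float((assignment.group == "case").mean())
        prof = self._profile([(pooled, 400)])
        res = enrichment_test(prof, assignment, "case")
        assert res.loc[1, "p_value"] > 0.5
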