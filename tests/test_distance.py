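"""Nei identity/distance, UPGMA against an independent reference
implementation, Ward linkage, and Newick round-tripping."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

import dendropy

from issrpop import (
    DistanceMatrix,
    SimulationConfig,
    euclidean_matrix,
    identity_distance_report,
    nei_distance,
    nei_identity,
    pairwise_matrix,
    simulate_dataset,
    upgma,
    ward_linkage,
    write_newick,
)
from issrpop.simulate import simulate_cluster_freqs, simulate_dominant_bands
from issrpop.trees import Tree, TreeNode
from conftest import make_matrix


class TestNeiMeasures:
    def test_identical_vectors_identity_one(self):
        p = np.array([1.0, 0.0, 0.5])
        assert nei_identity(p, p) == pytest.approx(1.0)
        assert nei_distance(1.0) == 0.0

    def test_opposite_fixation_identity_zero(self):
        x = np.ones(5)
        y = np.zeros(5)
        assert nei_identity(x, y) == pytest.approx(0.0)
        assert nei_distance(0.0) == np.inf

    def test_hand_computed_identity(self):
        px = np.array([1.0, 0.0, 0.5])
        py = np.array([1.0, 0.0, 0.9])
        jxy = np.mean([1.0, 1.0, 0.5 * 0.9 + 0.5 * 0.1])
        jx = np.mean([1.0, 1.0, 0.5])
        jy = np.mean([1.0, 1.0, 0.81 + 0.01])
        assert nei_identity(px, py) == pytest.approx(jxy / np.sqrt(jx * jy))

    def test_distance_identity_transform_scale(self):
        # GD = 0.14 corresponds to identity exp(-0.14) = 0.869
        assert nei_distance(np.exp(-0.14)) == pytest.approx(0.14)

    def test_invalid_identity_rejected(self):
        with pytest.raises(ValueError):
            nei_distance(1.5)


class TestPairwiseMatrix:
    def test_identical_individuals_zero_distance(self):
        data = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]], dtype=float)
        m = make_matrix(data)
        dist, ident = pairwise_matrix(m, "individual")
        assert dist.values[0, 1] == pytest.approx(0.0)
        assert ident[0, 1] == pytest.approx(1.0)

    def test_complete_mismatch_infinite_distance(self):
        data = np.array([[1, 1], [0, 0], [1, 0]], dtype=float)
        m = make_matrix(data)
        dist, ident = pairwise_matrix(m, "individual")
        assert ident[0, 1] == pytest.approx(0.0)
        assert dist.values[0, 1] == np.inf
        capped = dist.capped(10.0)
        assert capped.values[0, 1] == 10.0

    def test_simulated_matrix_symmetric_zero_diagonal(self, study_sim):
        m, _ = study_sim
        dist, ident = pairwise_matrix(m, "individual")
        v = dist.values
        assert v.shape == (44, 44)
        np.testing.assert_allclose(v, v.T)
        np.testing.assert_array_equal(np.diag(v), 0.0)
        np.testing.assert_allclose(
            np.where(np.isfinite(v), v, 0),
            np.where(np.isfinite(v), -np.log(np.clip(ident, 1e-300, 1)), 0),
            atol=1e-9,
        )

    def test_population_level_distances(self, study_sim):
        m, _ = study_sim
        dist, _ = pairwise_matrix(m, "population")
        assert dist.labels == m.populations
        assert np.isfinite(dist.values).all()

    def test_report_layout(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.2], [0.2, 0.0]]))
        ident = np.array([[1.0, 0.82], [0.82, 1.0]])
        rep = identity_distance_report(d, ident)
        assert rep.loc["a", "b"] == 0.82   # identity above diagonal
        assert rep.loc["b", "a"] == 0.2    # distance below diagonal


def random_distance_matrix(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 4))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix([f"u{i:02d}" for i in range(n)], d, "euclidean")


class TestUPGMA:
    def test_textbook_three_taxa(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]]),
        )
        t = upgma(d)
        assert t.root.height == pytest.approx(3.0)
        inner = [c for c in t.root.children if not c.is_leaf][0]
        assert inner.height == pytest.approx(1.0)
        assert sorted(l.name for l in inner.leaves()) == ["A", "B"]

    def test_ultrametric_input_reproduced_by_cophenetic(self):
        d = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [
                    [0.0, 2.0, 8.0, 8.0],
                    [2.0, 0.0, 8.0, 8.0],
                    [8.0, 8.0, 0.0, 4.0],
                    [8.0, 8.0, 4.0, 0.0],
                ]
            ),
        )
        t = upgma(d)
        np.testing.assert_allclose(
            t.cophenetic_matrix(d.labels), d.values, atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_average_linkage(self, seed):
        """Cross-check against SciPy's UPGMA on random 10x10 matrices."""
        d = random_distance_matrix(10, seed)
        mine = upgma(d).cophenetic_matrix(d.labels)
        Z = sch.linkage(squareform(d.values), method="average")
        ref = squareform(sch.cophenet(Z))
        np.testing.assert_allclose(mine, ref, atol=1e-9)

    def test_infinite_entries_rejected_with_guidance(self):
        v = np.array([[0.0, np.inf], [np.inf, 0.0]])
        d = DistanceMatrix(["a", "b"], v)
        with pytest.raises(ValueError, match="cap"):
            upgma(d)

    def test_deterministic_tie_break(self):
        v = np.ones((3, 3)) - np.eye(3)
        d = DistanceMatrix(["b", "a", "c"], v)
        t = upgma(d)
        first = [c for c in t.root.children if not c.is_leaf][0]
        assert sorted(l.name for l in first.leaves()) == ["a", "b"]


class TestWard:
    def test_identical_rows_merge_first_at_zero(self):
        data = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]], dtype=float)
        m = make_matrix(data)
        t = ward_linkage(euclidean_matrix(m, "individuals"))
        inner = [c for c in t.root.children if not c.is_leaf][0]
        assert inner.height == pytest.approx(0.0)
        assert sorted(l.name for l in inner.leaves()) == ["i1", "i2"]

    def test_collinear_hand_case(self):
        # points 0, 1, 3 on a line: merge (A,B) at 1, then C joins at
        # ((1+1)*3 + (1+1)*2 - 1*1)/3 = 3
        v = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        d = DistanceMatrix(["A", "B", "C"], v, "euclidean")
        t = ward_linkage(d)
        assert t.root.height == pytest.approx(3.0)
        inner = [c for c in t.root.children if not c.is_leaf][0]
        assert inner.height == pytest.approx(1.0)

    def test_leaf_order_is_permutation_of_labels(self, study_sim):
        m, _ = study_sim
        t = ward_linkage(euclidean_matrix(m, "individuals"))
        assert sorted(t.leaf_names) == sorted(m.individual_ids)


class TestNewick:
    def test_single_leaf(self):
        t = Tree(TreeNode("A", 0.0))
        assert write_newick(t) == "A;"

    def test_two_leaves_at_height_one(self):
        t = Tree(TreeNode(None, 1.0, [TreeNode("A", 0.0), TreeNode("B", 0.0)]))
        assert write_newick(t, 1) == "(A:1.0,B:1.0);"

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError):
            write_newick(None)

    def test_roundtrip_through_independent_parser(self):
        d = random_distance_matrix(44, 9)
        t = upgma(d)
        nwk = write_newick(t, precision=8)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(
            t.leaf_names
        )
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {tx.label: tx for tx in parsed.taxon_namespace}
        mine = t.cophenetic_matrix(d.labels)
        for i, a in enumerate(d.labels):
            for j, b in enumerate(d.labels):
                if i < j:
                    assert pdm.patristic_distance(
                        taxa[a], taxa[b]
                    ) == pytest.approx(mine[i, j], abs=1e-6)


class TestStructureSignal:
    def test_nei_distance_grows_with_differentiation(self):
        """Between-population Nei distance is monotone in the simulated F."""
        dists = []
        for F in (0.05, 0.1, 0.2, 0.4):
            rng = np.random.default_rng(17)
            p_anc = rng.uniform(0.1, 0.9, 400)
            pc = simulate_cluster_freqs(p_anc, [F, F], rng)
            Q = np.zeros((60, 2))
            Q[:30, 0] = 1
            Q[30:, 1] = 1
            data = simulate_dominant_bands(Q, pc, rng)
            m = make_matrix(data, pops=["X"] * 30 + ["Y"] * 30)
            d, _ = pairwise_matrix(m, "population")
            dists.append(d.values[0, 1])
        assert all(a < b for a, b in zip(dists, dists[1:]))

    def test_upgma_three_cluster_cut_recovers_truth(self):
        m, truth = simulate_dataset(SimulationConfig(seed=21))
        dist, _ = pairwise_matrix(m, "individual")
        t = upgma(dist.capped())
        cut = t.cut(3)
        true_of = {
            ind: int(truth.Q_true[i].argmax()) for i, ind in enumerate(m.individual_ids)
        }
        # majority mapping from cut clusters to true clusters
        agree = 0
        for g in set(cut.values()):
            members = [ind for ind, c in cut.items() if c == g]
            majority = max(
                set(true_of[x] for x in members),
                key=lambda lab: sum(true_of[x] == lab for x in members),
            )
            agree += sum(true_of[x] == majority for x in members)
        assert agree / len(cut) >= 0.9
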