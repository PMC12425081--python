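import io
import math

import numpy as np
import pytest
from Bio import Phylo
from scipy.cluster.hierarchy import average as scipy_average
from scipy.spatial.distance import squareform

from sigspect.cluster import (
    DistanceMatrix,
    cosine_similarity,
    distance_matrix,
    double_cluster,
    to_newick,
    tree_from_dict,
    tree_to_dict,
    upgma,
)

from oracles import brute_upgma


def random_dmat(n, rng):
    sim = rng.random((n, n))
    d = 1.0 - (sim + sim.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([f"L{i}" for i in range(n)], d)


def run_upgma(dmat, totals=None, log=None):
    if totals is None:
        totals = {i: 1.0 for i in dmat.ids}
    return upgma(dmat, totals, merge_log=log)


class TestCosine:
    def test_closed_form_values(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        v = np.array([2.0, 3.0, 1.0])
        assert cosine_similarity(v, 2 * v) == pytest.approx(1.0)
        assert cosine_similarity(
            np.array([1.0, 1.0]), np.array([1.0, 0.0])
        ) == pytest.approx(math.sqrt(2) / 2)

    def test_zero_vector_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestDistanceMatrix:
    def test_identical_and_orthogonal_rows(self):
        d = distance_matrix(np.array([[1.0, 2.0], [2.0, 4.0]]), ["a", "b"])
        np.testing.assert_allclose(d.d, 0.0, atol=1e-12)
        d = distance_matrix(np.eye(2), ["a", "b"])
        assert d.d[0, 1] == pytest.approx(1.0)

    def test_matches_pairwise_cosine_calls(self):
        rng = np.random.default_rng(0)
        m = rng.random((5, 8))
        d = distance_matrix(m, list("abcde"))
        assert np.allclose(d.d, d.d.T, atol=1e-12)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else 1 - cosine_similarity(m[i], m[j])
                assert d.d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_row_error_names_sample(self):
        with pytest.raises(ValueError, match="zilch"):
            distance_matrix(np.array([[1.0, 0.0], [0.0, 0.0]]), ["ok", "zilch"])


class TestUpgma:
    def test_two_samples_single_merge(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 0.2], [0.2, 0.0]]))
        tree = run_upgma(d, {"A": 3, "B": 4})
        assert tree.merge_distance == pytest.approx(0.2)
        assert tree.similarity == pytest.approx(0.8)
        assert tree.total_mutations == 7
        assert tree.leaf_order() == ["A", "B"]

    def test_three_samples_forced_order(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.4], [0.4, 0.4, 0.0]]),
        )
        log = []
        tree = run_upgma(d, log=log)
        assert log == [(0, 1, pytest.approx(0.1)), (0, 2, pytest.approx(0.4))]
        assert tree.merge_distance == pytest.approx(0.4)
        assert tree.leaf_order() == ["A", "B", "C"]

    def test_single_leaf(self):
        d = DistanceMatrix(["solo"], np.zeros((1, 1)))
        tree = run_upgma(d, {"solo": 5})
        assert tree.is_leaf and tree.sample_id == "solo"

    def test_totals_mismatch_is_error(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 0.2], [0.2, 0.0]]))
        with pytest.raises(ValueError, match="totals"):
            upgma(d, {"A": 1, "X": 2})

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7, 8])
    def test_merge_sequence_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(30):
            dmat = random_dmat(n, rng)
            log = []
            run_upgma(dmat, log=log)
            expected = brute_upgma(dmat.d)
            assert len(log) == len(expected) == n - 1
            for (i, j, h), (oi, oj, oh) in zip(log, expected):
                assert (i, j) == (oi, oj)
                assert h == pytest.approx(oh, abs=1e-10)

    def test_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            dmat = random_dmat(7, rng)
            log = []
            run_upgma(dmat, log=log)
            Z = scipy_average(squareform(dmat.d, checks=False))
            np.testing.assert_allclose(
                sorted(h for _, _, h in log), np.sort(Z[:, 2]), atol=1e-10
            )

    def test_heights_non_decreasing_and_totals_conserved(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 10))
            dmat = random_dmat(n, rng)
            totals = {s: float(rng.integers(1, 100)) for s in dmat.ids}
            tree = run_upgma(dmat, totals)
            assert tree.total_mutations == pytest.approx(sum(totals.values()))

            def check(node):
                if node.is_leaf:
                    return
                for child in node.children:
                    assert child.merge_distance <= node.merge_distance + 1e-12
                    check(child)
                assert node.total_mutations == pytest.approx(
                    sum(c.total_mutations for c in node.children)
                )

            check(tree)

    def test_permuting_ids_preserves_merge_heights(self):
        rng = np.random.default_rng(13)
        dmat = random_dmat(6, rng)
        log = []
        run_upgma(dmat, log=log)
        perm = rng.permutation(6)
        permuted = DistanceMatrix(
            [dmat.ids[p] for p in perm], dmat.d[np.ix_(perm, perm)]
        )
        plog = []
        run_upgma(permuted, log=plog)
        np.testing.assert_allclose(
            sorted(h for _, _, h in log),
            sorted(h for _, _, h in plog),
            atol=1e-12,
        )


class TestDoubleCluster:
    def test_identical_rows_become_adjacent(self):
        m = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 2.0], [2.0, 0.0, 2.0]])
        res = double_cluster(m, ["r0", "r1", "r2"], ["c0", "c1", "c2"])
        order = res.row_order
        assert abs(order.index("r0") - order.index("r2")) == 1

    def test_deterministic_across_runs(self):
        m = np.array([[1.0, 0.1], [0.1, 1.0]])
        first = double_cluster(m, ["a", "b"], ["x", "y"])
        second = double_cluster(m, ["a", "b"], ["x", "y"])
        assert first.row_order == second.row_order
        assert first.col_order == second.col_order

    def test_row_order_matches_independent_upgma(self):
        rng = np.random.default_rng(21)
        m = rng.random((10, 5)) + 0.01
        rows = [f"S{i}" for i in range(10)]
        cols = [f"sig{j}" for j in range(5)]
        res = double_cluster(m, rows, cols)
        tree = upgma(
            distance_matrix(m, rows), dict(zip(rows, m.sum(axis=1)))
        )
        assert res.row_order == tree.leaf_order()
        col_tree = upgma(
            distance_matrix(m.T, cols), dict(zip(cols, m.sum(axis=0)))
        )
        assert res.col_order == col_tree.leaf_order()


class TestSerialization:
    def test_newick_is_parseable_and_additive(self):
        rng = np.random.default_rng(31)
        dmat = random_dmat(6, rng)
        totals = {s: 1.0 for s in dmat.ids}
        tree = upgma(dmat, totals)
        newick = to_newick(tree)
        parsed = Phylo.read(io.StringIO(newick), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(dmat.ids)
        # root-to-leaf path length equals the root height for every leaf
        for leaf in parsed.get_terminals():
            assert parsed.distance(leaf) == pytest.approx(
                tree.merge_distance, abs=1e-10
            )

    def test_tree_json_round_trip(self):
        rng = np.random.default_rng(33)
        dmat = random_dmat(5, rng)
        totals = {s: float(i + 1) for i, s in enumerate(dmat.ids)}
        tree = upgma(dmat, totals)
        rebuilt = tree_from_dict(tree_to_dict(tree))
        assert tree_to_dict(rebuilt) == tree_to_dict(tree)
        assert rebuilt.leaf_order() == tree.leaf_order()
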