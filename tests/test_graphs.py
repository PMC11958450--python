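"""DAG representations: adjacency extraction, acyclicity, thresholding, I/O."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dagaf.graphs import (BinaryDag, WeightedAdjacency, acyclicity_value,
                          has_cycle, postprocess_structure, read_ground_truth,
                          ridge_norm_adjacency, write_dag)


def dfs_has_cycle(adj: np.ndarray) -> bool:
    """Independent cycle oracle: depth-first search with colors."""
    d = adj.shape[0]
    color = [0] * d  # 0 white, 1 grey, 2 black

    def visit(u):
        color[u] = 1
        for v in range(d):
            if adj[v, u]:  # u -> v (row = child)
                if color[v] == 1:
                    return True
                if color[v] == 0 and visit(v):
                    return True
        color[u] = 2
        return False

    return any(color[u] == 0 and visit(u) for u in range(d))


class TestRidgeNormAdjacency:
    def test_zero_weights_give_zero_matrix(self):
        blocks = [np.zeros((4, 3)) for _ in range(3)]
        assert np.array_equal(ridge_norm_adjacency(blocks).values, np.zeros((3, 3)))

    def test_single_weight_norm_is_absolute_value(self):
        blocks = [np.zeros((4, 2)) for _ in range(2)]
        blocks[0][0, 1] = -2.0  # X_1 -> X_0, latent unit 0
        A = ridge_norm_adjacency(blocks)
        assert A.values[0, 1] == pytest.approx(2.0)

    def test_column_norm_pythagorean(self):
        # oracle: sqrt(3^2 + 4^2) = 5
        blocks = [np.zeros((2, 2)) for _ in range(2)]
        blocks[0][:, 1] = (3.0, 4.0)
        assert ridge_norm_adjacency(blocks).values[0, 1] == pytest.approx(5.0)

    def test_diagonal_zeroed(self):
        blocks = [np.ones((3, 2)) for _ in range(2)]
        A = ridge_norm_adjacency(blocks)
        assert np.all(np.diag(A.values) == 0)

    def test_nonfinite_block_identified(self):
        blocks = [np.zeros((2, 2)), np.full((2, 2), np.nan)]
        with pytest.raises(ValueError, match="block 1"):
            ridge_norm_adjacency(blocks)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        blocks = [rng.normal(size=(3, 4)) for _ in range(4)]
        flipped = [b * rng.choice([-1.0, 1.0], size=b.shape) for b in blocks]
        np.testing.assert_allclose(
            ridge_norm_adjacency(blocks).values,
            ridge_norm_adjacency(flipped).values,
            atol=1e-12,
        )


class TestAcyclicityValue:
    def test_zero_matrix(self):
        assert acyclicity_value(np.zeros((5, 5))) == pytest.approx(0.0)

    def test_strictly_upper_triangular_is_acyclic(self):
        rng = np.random.default_rng(0)
        A = np.triu(rng.uniform(0.5, 3.0, size=(6, 6)), k=1)
        assert acyclicity_value(A) == pytest.approx(0.0, abs=1e-9)

    def test_two_cycle_closed_form(self):
        # tr(exp([[0,1],[1,0]])) - 2 = 2 cosh(1) - 2
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert acyclicity_value(A) == pytest.approx(2 * np.cosh(1.0) - 2, rel=1e-12)

    def test_overflow_guidance(self):
        A = np.full((3, 3), 1e3)
        np.fill_diagonal(A, 0)
        with pytest.raises(OverflowError, match="rescal"):
            acyclicity_value(A)

    def test_matches_dfs_oracle_exhaustive_d3(self):
        """h(A)=0 iff acyclic, over all 2^6 off-diagonal patterns at d=3."""
        offdiag = [(i, j) for i in range(3) for j in range(3) if i != j]
        for bits in itertools.product([0, 1], repeat=6):
            A = np.zeros((3, 3))
            for b, (i, j) in zip(bits, offdiag):
                A[i, j] = b
            h = acyclicity_value(A)
            if dfs_has_cycle(A):
                assert h > 1e-8
            else:
                assert h == pytest.approx(0.0, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_dfs_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        A = (rng.uniform(size=(8, 8)) < 0.25).astype(float)
        np.fill_diagonal(A, 0)
        h = acyclicity_value(A)
        assert (h > 1e-8) == dfs_has_cycle(A)
        assert has_cycle(A) == dfs_has_cycle(A)


class TestPostprocess:
    def test_boundary_value_drops(self):
        A_sq = np.zeros((2, 2))
        A_sq[0, 1] = 0.09  # weight exactly 0.3
        weighted, dag = postprocess_structure(A_sq, tau=0.3)
        assert weighted.values[0, 1] == pytest.approx(0.3)
        assert dag.n_edges == 0

    def test_above_threshold_kept(self):
        A_sq = np.zeros((2, 2))
        A_sq[0, 1] = 0.16
        weighted, dag = postprocess_structure(A_sq, tau=0.3)
        assert weighted.values[0, 1] == pytest.approx(0.4)
        assert dag.edges[0, 1] == 1

    def test_zero_matrix_empty_graph(self):
        _, dag = postprocess_structure(np.zeros((4, 4)))
        assert dag.n_edges == 0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            postprocess_structure(np.array([[0.0, -1.0], [0.0, 0.0]]))

    def test_raising_tau_never_adds_edges(self):
        rng = np.random.default_rng(3)
        A_sq = rng.uniform(0, 1, size=(6, 6))
        np.fill_diagonal(A_sq, 0)
        counts = []
        for tau in (0.1, 0.3, 0.5, 0.9):
            _, res = postprocess_structure(A_sq, tau=tau, enforce_acyclic=False)
            edges = res.edges if isinstance(res, BinaryDag) else res
            counts.append(int(np.sum(edges)))
        assert counts == sorted(counts, reverse=True)

    def test_cycle_repair_removes_weakest_edge(self):
        A_sq = np.zeros((2, 2))
        A_sq[0, 1] = 0.5
        A_sq[1, 0] = 0.4
        _, dag = postprocess_structure(A_sq, tau=0.3, enforce_acyclic=True)
        assert dag.edges[0, 1] == 1 and dag.edges[1, 0] == 0


class TestDagIO:
    def test_edge_list_round_trip(self, tmp_path):
        e = np.zeros((3, 3), dtype=int)
        e[1, 0] = e[2, 1] = 1  # 0->1->2
        dag = BinaryDag(e)
        p = tmp_path / "g.edges"
        write_dag(dag, p)
        assert read_ground_truth(p).edges.tolist() == e.tolist()

    def test_edge_list_contents(self, tmp_path):
        p = tmp_path / "g.edges"
        p.write_text("0\t1\n1\t2\n")
        dag = read_ground_truth(p)
        assert dag.n_edges == 2
        assert dag.edges[1, 0] == 1 and dag.edges[2, 1] == 1

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        m = np.triu((rng.uniform(size=(4, 4)) < 0.5).astype(int), k=1)
        dag = BinaryDag(m)
        p = tmp_path / "g.csv"
        write_dag(dag, p)
        assert np.array_equal(read_ground_truth(p).edges, dag.edges)

    def test_self_loop_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.edges"
        p.write_text("0\t1\n2\t2\n")
        with pytest.raises(ValueError, match="2"):
            read_ground_truth(p)

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            BinaryDag(np.array([[0, 1], [1, 0]]))

    def test_weighted_adjacency_invariants(self):
        with pytest.raises(ValueError):
            WeightedAdjacency(np.array([[0.0, -0.1], [0.0, 0.0]]))
        A = WeightedAdjacency(np.ones((3, 3)))
        assert np.all(np.diag(A.values) == 0)
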