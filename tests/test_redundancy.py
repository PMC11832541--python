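import itertools

import networkx as nx
import numpy as np
import pytest

import redunet as r
from redunet.redundancy import DensityGrid


def all_pairs_k_connected(g: nx.Graph, k: int) -> bool:
    """Brute-force oracle: every pair has >= k vertex-disjoint pathways."""
    return all(
        r.count_independent_paths(g, u, v) >= k
        for u, v in itertools.combinations(g.nodes, 2)
    )


class TestDensityGrid:
    def test_default_grid_has_19_densities(self):
        grid = DensityGrid()
        assert len(grid) == 19
        np.testing.assert_allclose(list(grid), np.arange(1, 20) * 0.05)

    def test_rejects_non_increasing_or_out_of_range(self):
        with pytest.raises(ValueError):
            DensityGrid((0.1, 0.1))
        with pytest.raises(ValueError):
            DensityGrid((0.0, 0.5))


class TestProportionalThreshold:
    def test_half_density_on_four_nodes_keeps_three_edges(self):
        corr = np.eye(4)
        vals = iter([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        for i in range(4):
            for j in range(i + 1, 4):
                corr[i, j] = corr[j, i] = next(vals)
        g = r.proportional_threshold(corr, 0.5)
        assert len(g.edges) == 3
        assert g.edges == frozenset({(0, 1), (0, 2), (0, 3)})

    def test_full_density_gives_complete_graph(self):
        corr = np.random.default_rng(0).uniform(-1, 1, (6, 6))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        g = r.proportional_threshold(corr, 1.0)
        assert len(g.edges) == 15

    def test_sparsest_density_keeps_only_the_strongest_pair(self):
        rng = np.random.default_rng(5)
        corr = rng.uniform(-0.9, 0.8, (5, 5))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        # independent oracle: sort all 10 upper-triangle entries by hand
        iu = np.triu_indices(5, k=1)
        order = np.argsort(-corr[iu])
        strongest = (iu[0][order[0]], iu[1][order[0]])
        g = r.proportional_threshold(corr, 0.2)  # round(0.2 * 10) = 2 edges
        assert len(g.edges) == 2
        assert strongest in g.edges

    def test_quota_rounds_half_away_from_zero(self):
        corr = np.random.default_rng(1).uniform(0, 1, (5, 5))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        # P = 10; 0.25 * 10 = 2.5 -> 3 edges, not banker's 2
        assert len(r.proportional_threshold(corr, 0.25).edges) == 3

    def test_density_out_of_range(self):
        with pytest.raises(ValueError):
            r.proportional_threshold(np.eye(4), 0.0)

    def test_absolute_ranking_keeps_strong_negative_edges(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = -0.95
        corr[2, 3] = corr[3, 2] = 0.4
        g_signed = r.proportional_threshold(corr, 0.2, rank_mode="signed")
        g_abs = r.proportional_threshold(corr, 0.2, rank_mode="absolute")
        assert (2, 3) in g_signed.edges and (0, 1) not in g_signed.edges
        assert (0, 1) in g_abs.edges


class TestIndependentPaths:
    def test_triangle_has_two_pathways(self):
        g = nx.cycle_graph(3)
        assert r.count_independent_paths(g, 0, 1) == 2

    def test_cut_vertex_limits_path_count(self):
        g = nx.path_graph(3)  # a - b - c
        assert r.count_independent_paths(g, 0, 2) == 1

    def test_same_node_rejected(self):
        with pytest.raises(ValueError):
            r.count_independent_paths(nx.cycle_graph(3), 1, 1)

    def test_matches_min_vertex_cut_for_nonadjacent_pairs(self):
        """Menger: path count equals the minimum vertex cut (networkx as
        the independent oracle) for non-adjacent pairs."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(30):
            g = nx.gnp_random_graph(10, 0.35, seed=int(rng.integers(2**31)))
            nodes = list(g.nodes)
            for u, v in itertools.combinations(nodes, 2):
                if g.has_edge(u, v):
                    continue
                if not nx.has_path(g, u, v):
                    assert r.count_independent_paths(g, u, v) == 0
                    continue
                cut = nx.minimum_node_cut(g, u, v)
                assert r.count_independent_paths(g, u, v) == len(cut)
                checked += 1
                if checked >= 60:
                    return
        assert checked > 0

    def test_edge_disjoint_mode_counts_edge_paths(self):
        # two triangles sharing one vertex: 2 edge-disjoint paths through
        # the hub, but only 1 vertex-disjoint
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3), (3, 4), (4, 2)])
        assert r.count_independent_paths(g, 0, 3, mode="vertex") == 1
        assert r.count_independent_paths(g, 1, 0, mode="edge") == 2


class TestKConnected:
    def test_cycle_is_biconnected(self):
        g = nx.cycle_graph(6)
        assert r.is_k_connected(g, 1)
        assert r.is_k_connected(g, 2)

    def test_star_hub_is_a_cut_vertex(self):
        g = nx.star_graph(5)
        assert r.is_k_connected(g, 1)
        assert not r.is_k_connected(g, 2)

    def test_unsupported_k(self):
        with pytest.raises(ValueError):
            r.is_k_connected(nx.cycle_graph(4), 3)

    def test_agrees_with_all_pairs_path_counts(self):
        """Fast connectivity/biconnectivity checks match the brute-force
        max-flow path-count oracle on 50 random graphs."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.7)),
                                    seed=int(rng.integers(2**31)))
            for k in (1, 2):
                assert r.is_k_connected(g, k) == all_pairs_k_connected(g, k)


class TestDensityScanAndLabels:
    def test_ring_matrix_is_redundant_at_sparsest_density(self, ring_matrix):
        grid = DensityGrid()
        assert r.min_density_k_connected(ring_matrix, grid, 1) == 0.05
        assert r.min_density_k_connected(ring_matrix, grid, 2) == 0.05
        label, d1, d2 = r.label_window(ring_matrix)
        assert (label, d1, d2) == (1, 0.05, 0.05)

    def test_star_matrix_needs_more_density_for_two_connectedness(
        self, star_matrix
    ):
        label, d1, d2 = r.label_window(star_matrix)
        assert d1 == 0.05
        assert d2 > d1
        assert label == 0

    def test_total_tie_is_deterministic(self):
        corr = np.full((8, 8), 0.5)
        np.fill_diagonal(corr, 1.0)
        first = r.label_window(corr)
        for _ in range(3):
            assert r.label_window(corr) == first

    def test_absent_one_connectedness_labels_zero(self, star_matrix):
        # a grid truncated below the star's connection density never
        # connects the graph: the ABSENT contract forces label 0
        tiny_grid = DensityGrid((0.01,))
        label, d1, d2 = r.label_window(star_matrix, tiny_grid)
        assert (label, d1, d2) == (0, None, None)

    def test_edge_sets_nest_across_the_grid(self):
        rng = np.random.default_rng(3)
        corr = rng.uniform(-1, 1, (12, 12))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        prev = frozenset()
        for d in DensityGrid():
            edges = r.proportional_threshold(corr, d).edges
            assert prev <= edges
            prev = edges

    def test_d_two_never_below_d_one_on_random_windows(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            corr = rng.uniform(-1, 1, (10, 10))
            corr = (corr + corr.T) / 2
            np.fill_diagonal(corr, 1.0)
            _, d1, d2 = r.label_window(corr)
            if d1 is not None and d2 is not None:
                assert d2 >= d1


class TestBFRScore:
    def _stack_from(self, matrices):
        mats = np.stack(matrices)
        return r.DynFCStack(
            matrices=mats,
            window_volumes=50,
            step_volumes=1,
            window_start_indices=tuple(range(len(matrices))),
        )

    def test_bfr_is_the_mean_label(self, ring_matrix, star_matrix):
        stack = self._stack_from(
            [ring_matrix, star_matrix, ring_matrix, ring_matrix]
        )
        profile = r.bfr_score([stack])
        assert profile.labels == (1, 0, 1, 1)
        assert profile.bfr == pytest.approx(0.75)

    def test_sessions_concatenate_in_order(self, ring_matrix, star_matrix):
        s1 = self._stack_from([ring_matrix, ring_matrix])
        s2 = self._stack_from([star_matrix])
        profile = r.bfr_score([s1, s2])
        assert profile.labels == (1, 1, 0)
        assert profile.n_windows == 3

    def test_two_full_sessions_give_302_windows(self):
        seq = r.StateSequence.constant(r.REDUNDANT, 4)
        stacks = [
            r.build_stack(
                r.drop_initial_volumes(
                    r.gen_timeseries(14, 204, seq, seed=s, session_id=f"ses-{s}"), 4
                )
            )
            for s in (1, 2)
        ]
        profile = r.bfr_score(stacks)
        assert profile.n_windows == 302
        assert 0.0 <= profile.bfr <= 1.0

    def test_empty_session_list_rejected(self):
        with pytest.raises(ValueError):
            r.bfr_score([])
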