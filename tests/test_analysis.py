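"""Graph metrics, motifs, attractor statistics, group tests, reference match."""

import numpy as np
import pytest

from boolense.analysis import (
    MetricsRecord,
    activity_probabilities,
    candidates_adjacency,
    compare_groups,
    count_motifs,
    graph_metrics,
    landscape_stats,
    match_matrix,
    network_adjacency,
    union_adjacency,
)
from boolense.ensemble import sample_ensemble
from boolense.network import Attractor, BooleanFunction, BooleanNetwork, GeneUniverse
from boolense.reconstruct import FunctionCandidates

from conftest import brute_force_motifs


def single_candidate_ensemble(net, seed=0, n_networks=1):
    cands = {
        f.target: FunctionCandidates(target=f.target, error=0, functions=(f,))
        for f in net.functions
    }
    return sample_ensemble(cands, net.universe, n_networks, seed=seed)


class TestGraphMetrics:
    def test_hand_example_fixed_and_isolated(self):
        u = GeneUniverse(("g1", "g2", "g3"))
        net = BooleanNetwork(
            u,
            (
                BooleanFunction.constant("g1", 0),
                BooleanFunction("g2", ("g3",), (0, 1)),
                BooleanFunction("g3", ("g2",), (0, 1)),
            ),
        )
        rec = graph_metrics(single_candidate_ensemble(net))
        assert rec.n_fixed == 1
        assert rec.n_isolated == 1  # g1: constant and unreferenced
        assert rec.mean_input == pytest.approx(2 / 3)
        assert rec.mean_functions == 1.0

    def test_all_constant_network(self):
        u = GeneUniverse(("a", "b"))
        net = BooleanNetwork(
            u, (BooleanFunction.constant("a", 0), BooleanFunction.constant("b", 1))
        )
        rec = graph_metrics(single_candidate_ensemble(net))
        assert (rec.n_fixed, rec.n_isolated, rec.mean_input) == (2, 2, 0.0)

    def test_ring_network_fully_wired(self):
        u = GeneUniverse(("a", "b", "c"))
        net = BooleanNetwork(
            u,
            (
                BooleanFunction("a", ("c",), (0, 1)),
                BooleanFunction("b", ("a",), (0, 1)),
                BooleanFunction("c", ("b",), (0, 1)),
            ),
        )
        rec = graph_metrics(single_candidate_ensemble(net))
        assert rec.n_fixed == 0 and rec.n_isolated == 0
        assert rec.mean_input == 1.0

    def test_fixed_but_referenced_gene_is_not_isolated(self):
        u = GeneUniverse(("a", "b"))
        net = BooleanNetwork(
            u,
            (
                BooleanFunction.constant("a", 1),
                BooleanFunction("b", ("a",), (0, 1)),
            ),
        )
        rec = graph_metrics(single_candidate_ensemble(net))
        assert rec.n_fixed == 1
        assert rec.n_isolated == 0


class TestMotifs:
    def test_canonical_feed_forward_loop(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[0, 2] = adj[1, 2] = 1
        assert count_motifs(adj) == (1, 0)

    def test_canonical_bifan(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 2] = adj[0, 3] = adj[1, 2] = adj[1, 3] = 1
        assert count_motifs(adj) == (0, 1)

    def test_self_loops_ignored(self):
        adj = np.eye(3, dtype=int)
        assert count_motifs(adj) == (0, 0)

    def test_complete_digraph_matches_brute_force(self):
        adj = np.ones((4, 4), dtype=int)
        assert count_motifs(adj) == brute_force_motifs(adj)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_digraphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        adj = (rng.random((n, n)) < 0.4).astype(int)
        assert count_motifs(adj) == brute_force_motifs(adj)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            count_motifs(np.zeros((2, 3)))


class TestLandscapes:
    def test_all_fixed_points(self):
        lands = [[Attractor(((0, 1),))], [Attractor(((1, 1),))]]
        assert landscape_stats(lands) == (1.0, 1.0)

    def test_swap_network_landscape(self, swap_net):
        from boolense.network import find_attractors

        atts = find_attractors(swap_net)
        mean_n, mean_len = landscape_stats([atts])
        assert mean_n == 3.0
        assert mean_len == pytest.approx(4 / 3)

    def test_mixture_is_arithmetic_mean(self, swap_net):
        from boolense.network import find_attractors

        atts = find_attractors(swap_net)
        fixed = [Attractor(((0, 0),))]
        mean_n, mean_len = landscape_stats([atts, fixed])
        assert mean_n == 2.0
        assert mean_len == pytest.approx((4 / 3 + 1.0) / 2)

    def test_missing_landscapes_excluded_with_warning(self):
        lands = [[Attractor(((1,),))], []]
        with pytest.warns(UserWarning, match="excluded"):
            mean_n, mean_len = landscape_stats(lands)
        assert (mean_n, mean_len) == (1.0, 1.0)


class TestActivity:
    def test_single_fixed_point(self):
        probs = activity_probabilities([[Attractor(((1, 0, 1),))]])
        assert probs.tolist() == [1.0, 0.0, 1.0]

    def test_pooled_fixed_point_and_cycle(self):
        # fixed point (1,0) plus 2-cycle (0,1)->(1,1): pool 3 states
        lands = [[Attractor(((1, 0),)), Attractor(((0, 1), (1, 1)))]]
        probs = activity_probabilities(lands)
        assert probs == pytest.approx([2 / 3, 2 / 3])

    def test_constant_zero_gene_has_zero_activity(self):
        lands = [[Attractor(((0, 1),)), Attractor(((0, 0),))]]
        assert activity_probabilities(lands)[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_probabilities_bounded(self, seed):
        from boolense.benchmark import random_network
        from boolense.network import find_attractors

        net = random_network(6, k_max=2, seed=seed)
        probs = activity_probabilities([find_attractors(net)])
        assert np.all(probs >= 0) and np.all(probs <= 1)

    def test_requires_attractors(self):
        with pytest.raises(ValueError):
            activity_probabilities([[]])


class TestCompareGroups:
    @staticmethod
    def records(values):
        return [
            MetricsRecord(
                n_fixed=v, n_isolated=v, mean_input=v, mean_functions=v
            )
            for v in values
        ]

    def test_identical_groups_give_p_one(self):
        a = self.records([1, 2, 3])
        with pytest.warns(UserWarning):
            out = compare_groups(self.records([2, 2, 2]), self.records([2, 2, 2]))
        assert all(p == 1.0 for _, p, _ in out.values())
        out = compare_groups(a, a)
        assert all(p > 0.9 for _, p, _ in out.values())

    def test_separated_groups_reach_exact_minimum(self):
        # complete separation with n=m=3: exact two-sided p = 2/C(6,3) = 0.1
        out = compare_groups(self.records([1, 2, 3]), self.records([10, 11, 12]))
        for _, p, _ in out.values():
            assert p == pytest.approx(0.1)

    def test_invariant_under_monotone_transform(self):
        a, b = [1.0, 2.0, 5.0, 7.0], [3.0, 8.0, 9.0, 11.0]
        p1 = compare_groups(self.records(a), self.records(b))["mean_input"][1]
        p2 = compare_groups(
            self.records([x**3 for x in a]), self.records([x**3 for x in b])
        )["mean_input"][1]
        assert p1 == pytest.approx(p2)

    def test_bonferroni_multiplies_by_metric_count(self):
        out = compare_groups(
            self.records([1, 2, 3]),
            self.records([10, 11, 12]),
            correction="bonferroni",
        )
        for _, p, padj in out.values():
            assert padj == pytest.approx(min(1.0, p * 4))

    def test_paired_signed_rank_available(self):
        out = compare_groups(
            self.records([1, 2, 3, 4, 5, 6]),
            self.records([2, 3, 4, 5, 6, 7]),
            paired=True,
        )
        assert all(0 < p <= 1 for _, p, _ in out.values())

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(self.records([1]), self.records([]))


class TestMatchMatrix:
    @pytest.fixture
    def universe(self):
        return GeneUniverse(("A", "B", "C", "D"))

    @staticmethod
    def adjacency(universe, edges):
        adj = np.zeros((len(universe), len(universe)), dtype=np.uint8)
        for i, j in edges:
            adj[universe.index[i], universe.index[j]] = 1
        return adj

    def test_direct_match(self, universe):
        adj = self.adjacency(universe, [("A", "B")])
        res = match_matrix(adj, [("A", "B")], universe)
        assert res.matrix[0, 1] == 1
        assert res.match_fraction == 1.0

    def test_single_intermediary_match(self, universe):
        adj = self.adjacency(universe, [("A", "C")])
        res = match_matrix(adj, [("A", "B"), ("B", "C")], universe)
        assert res.matrix[0, 2] == 1

    def test_two_intermediaries_is_a_mismatch(self, universe):
        adj = self.adjacency(universe, [("A", "D")])
        res = match_matrix(adj, [("A", "B"), ("C", "D")], universe)
        assert res.matrix[0, 3] == -1
        assert res.match_fraction == 0.0

    def test_non_edges_are_zero(self, universe):
        adj = self.adjacency(universe, [("A", "B")])
        res = match_matrix(adj, [("A", "B")], universe)
        assert (res.matrix == 0).sum() == 15

    def test_reference_direction_irrelevant(self, universe):
        adj = self.adjacency(universe, [("A", "B"), ("C", "A")])
        forward = match_matrix(adj, [("A", "B"), ("A", "C")], universe)
        backward = match_matrix(adj, [("B", "A"), ("C", "A")], universe)
        assert np.array_equal(forward.matrix, backward.matrix)
        assert forward.match_fraction == backward.match_fraction == 1.0

    def test_missing_genes_reported_and_count_as_mismatch(self, universe):
        adj = self.adjacency(universe, [("A", "D")])
        res = match_matrix(adj, [("A", "B")], universe)
        assert "D" in res.missing_genes
        assert res.matrix[0, 3] == -1


class TestAdjacency:
    def test_union_is_monotone_in_replicates(self):
        u = GeneUniverse(("a", "b"))
        c1 = {
            "a": FunctionCandidates("a", 0, (BooleanFunction("a", ("b",), (0, 1)),)),
            "b": FunctionCandidates("b", 0, (BooleanFunction.constant("b", 0),)),
        }
        c2 = {
            "a": FunctionCandidates("a", 0, (BooleanFunction.constant("a", 0),)),
            "b": FunctionCandidates("b", 0, (BooleanFunction("b", ("a",), (0, 1)),)),
        }
        e1 = sample_ensemble(c1, u, 1, seed=0)
        e2 = sample_ensemble(c2, u, 1, seed=0, replicate_index=2)
        one = union_adjacency([e1])
        both = union_adjacency([e1, e2])
        assert np.all(both >= one)
        assert both.sum() == 2

    def test_candidates_adjacency_unions_functions(self):
        u = GeneUniverse(("a", "b"))
        cands = {
            "a": FunctionCandidates(
                "a",
                0,
                (
                    BooleanFunction("a", ("a",), (0, 1)),
                    BooleanFunction("a", ("b",), (0, 1)),
                ),
            ),
            "b": FunctionCandidates("b", 0, (BooleanFunction.constant("b", 1),)),
        }
        adj = candidates_adjacency(cands, u)
        assert adj[0, 0] == 1 and adj[1, 0] == 1 and adj[:, 1].sum() == 0

    def test_network_adjacency_definition(self, swap_net):
        adj = network_adjacency(swap_net)
        assert adj.tolist() == [[0, 1], [1, 0]]
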