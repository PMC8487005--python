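"""Filtered best-fit: input screening, pdBF errors, candidate enumeration."""

import numpy as np
import pytest

from boolense.network import BooleanFunction, GeneUniverse
from boolense.pseudotime import TransitionPair
from boolense.reconstruct import (
    NetworkReconstructor,
    best_fit,
    build_pdbf,
    filter_inputs,
    pdbf_error,
    read_candidates,
    reconstruct_all,
    write_candidates,
)

from conftest import (
    all_state_pairs,
    brute_force_min_error,
    candidate_sets_equal,
    canonical_form,
    functions_semantically_equal,
)


def make_pairs(rows):
    """rows: list of (predecessor bits, successor bits)."""
    return [
        TransitionPair(tuple(p), tuple(s), source_cells=(f"a{i}", f"b{i}"))
        for i, (p, s) in enumerate(rows)
    ]


@pytest.fixture
def xy_universe():
    return GeneUniverse(("x", "y"))


# pairs encoding: x drives y with one conflicting observation
#   (x=0 -> y=0) x3, (x=1 -> y=1) x2, (x=1 -> y=0) x1
XY_ROWS = [
    ((0, 0), (0, 0)),
    ((0, 1), (0, 0)),
    ((0, 0), (0, 0)),
    ((1, 0), (0, 1)),
    ((1, 1), (0, 1)),
    ((1, 0), (0, 0)),
]


class TestFilterInputs:
    def test_identity_input_has_r_one(self, xy_universe):
        rows = [((0, 0), (0, 0)), ((1, 0), (0, 1)), ((0, 1), (1, 0)), ((1, 1), (1, 1))]
        res = filter_inputs(make_pairs(rows), "y", xy_universe, threshold=0.5)
        assert res.candidates[0][0] == "x"
        assert res.candidates[0][1] == pytest.approx(1.0)

    def test_inhibition_retained_via_absolute_value(self, xy_universe):
        rows = [((0, 0), (0, 1)), ((1, 0), (0, 0)), ((0, 1), (1, 1)), ((1, 1), (1, 0))]
        res = filter_inputs(make_pairs(rows), "y", xy_universe, threshold=0.5)
        assert ("x", -1.0) in [(g, round(r, 6)) for g, r in res.candidates]

    def test_zero_variance_input_excluded(self):
        u = GeneUniverse(("a", "b"))
        rows = [((1, 0), (0, 0)), ((1, 1), (0, 1)), ((1, 0), (0, 0)), ((1, 1), (0, 1))]
        res = filter_inputs(make_pairs(rows), "b", u, threshold=0.0)
        assert "a" not in res.genes

    def test_sorted_by_abs_correlation_and_truncated(self):
        rng = np.random.default_rng(0)
        u = GeneUniverse(tuple(f"g{i}" for i in range(6)))
        P = rng.integers(0, 2, (40, 6)).astype(np.uint8)
        S = np.zeros_like(P)
        S[:, 0] = P[:, 1]  # g1 drives g0 perfectly
        res = filter_inputs((P, S), "g0", u, threshold=0.0, max_candidates=3)
        assert len(res.candidates) == 3
        assert res.candidates[0][0] == "g1"
        magnitudes = [abs(r) for _, r in res.candidates]
        assert magnitudes == sorted(magnitudes, reverse=True)

    def test_needs_two_pairs_and_nonneg_threshold(self, xy_universe):
        with pytest.raises(ValueError):
            filter_inputs(make_pairs(XY_ROWS[:1]), "y", xy_universe)
        with pytest.raises(ValueError):
            filter_inputs(make_pairs(XY_ROWS), "y", xy_universe, threshold=-0.1)


class TestPdBF:
    def test_hand_tally(self, xy_universe):
        p = build_pdbf(make_pairs(XY_ROWS), "y", ("x",), xy_universe)
        assert p.counts == ((0, 3), (2, 1))
        assert p.n_observations == 6

    def test_empty_input_list_aggregates_everything(self, xy_universe):
        p = build_pdbf(make_pairs(XY_ROWS), "y", (), xy_universe)
        assert p.counts == ((2, 4),)

    def test_additivity_under_duplication(self, xy_universe):
        pairs = make_pairs(XY_ROWS)
        single = build_pdbf(pairs, "y", ("x",), xy_universe)
        double = build_pdbf(pairs + pairs, "y", ("x",), xy_universe)
        assert double.counts == tuple(
            (2 * a, 2 * b) for a, b in single.counts
        )

    def test_error_example_matches_completion_brute_force(self, xy_universe):
        p = build_pdbf(make_pairs(XY_ROWS), "y", ("x",), xy_universe)
        # brute force: both completions of the conflicting pattern
        #   y=const0: errors 2; y=x: 1 error; y=!x: 5; y=const1: 4
        assert pdbf_error(p) == 1

    def test_disjoint_patterns_are_consistent(self, xy_universe):
        rows = [((0, 0), (0, 0)), ((1, 0), (0, 1))]
        p = build_pdbf(make_pairs(rows), "y", ("x",), xy_universe)
        assert pdbf_error(p) == 0

    def test_balanced_conflicts_and_distinct_mode(self):
        u = GeneUniverse(("x", "y"))
        rows = [((0, 0), (0, 0)), ((0, 0), (0, 1)), ((1, 0), (0, 0)), ((1, 0), (0, 1))]
        p = build_pdbf(make_pairs(rows), "y", ("x",), u)
        assert pdbf_error(p, "weighted") == 2  # one misfit per balanced pattern
        assert pdbf_error(p, "distinct") == 2  # two conflicting patterns
        with pytest.raises(ValueError):
            pdbf_error(p, "exotic")


class TestBestFit:
    def test_single_input_winner_beats_constants(self, xy_universe):
        pairs = make_pairs(XY_ROWS)
        # oracle over all <=1-input functions: y=x has 1 error,
        # constants have 2 and 4, y=!x has 5
        res = best_fit(pairs, "y", ["x"], xy_universe, k_max=1)
        assert res.error == 1
        assert len(res.functions) == 1
        assert res.functions[0] == BooleanFunction("y", ("x",), (0, 1))

    def test_noise_free_and_gate_recovered(self):
        u = GeneUniverse(("a", "b", "y"))
        rows = []
        for a in (0, 1):
            for b in (0, 1):
                rows.append(((a, b, 0), (0, 0, a & b)))
        res = best_fit(make_pairs(rows), "y", ["a", "b"], u, k_max=2)
        assert res.error == 0
        target = BooleanFunction("y", ("a", "b"), (0, 0, 0, 1))
        assert any(functions_semantically_equal(f, target) for f in res.functions)

    @pytest.mark.parametrize("seed", range(6))
    def test_coin_flip_target_constant_is_minimal_when_imbalances_agree(self, seed):
        # y independent of a: splitting on a can never increase the error
        # (|d0| + |d1| >= |d0 + d1| for the per-pattern imbalances), and the
        # constant ties for minimal exactly when both imbalances share a sign
        rng = np.random.default_rng(seed)
        u = GeneUniverse(("a", "y"))
        P = np.zeros((200, 2), dtype=np.uint8)
        P[:, 0] = rng.integers(0, 2, 200)
        S = np.zeros_like(P)
        S[:, 1] = rng.integers(0, 2, 200)  # unbiased coin, independent of a
        res = best_fit((P, S), "y", ["a"], u, k_max=1)
        y = S[:, 1].astype(int)
        const_error = min(y.sum(), 200 - y.sum())
        assert res.error <= const_error
        d0 = y[P[:, 0] == 0].sum() * 2 - (P[:, 0] == 0).sum()
        d1 = y[P[:, 0] == 1].sum() * 2 - (P[:, 0] == 1).sum()
        same_sign = d0 * d1 >= 0
        assert any(f.is_constant for f in res.functions) == same_sign

    def test_unobserved_patterns_enumerate_completions(self):
        u = GeneUniverse(("a", "b", "y"))
        rows = [
            ((0, 0, 0), (0, 0, 0)),
            ((0, 1, 0), (0, 0, 1)),
            ((1, 0, 0), (0, 0, 1)),
        ]  # pattern a=1,b=1 never observed
        res = best_fit(make_pairs(rows), "y", ["a", "b"], u, k_max=2)
        two_input = [f for f in res.functions if set(f.inputs) == {"a", "b"}]
        tables = {f.table for f in two_input}
        # both completions of the missing pattern must be present
        completions = {t for t in tables}
        assert len(completions) % 2 == 0 and len(completions) >= 2

    def test_completion_cap_falls_back_to_majority_fill(self):
        u = GeneUniverse(("a", "b", "c", "y"))
        rows = [((0, 0, 0, 0), (0, 0, 0, 1)), ((1, 1, 1, 0), (0, 0, 0, 1))]
        res = best_fit(
            make_pairs(rows), "y", ["a", "b", "c"], u, k_max=3, cap=4
        )
        assert res.capped

    def test_no_pairs_degenerates_to_constant(self, xy_universe):
        res = best_fit([], "y", [], xy_universe, k_max=2)
        assert res.error == 0
        assert res.functions[0].is_constant

    def test_error_monotone_in_k_max(self):
        rng = np.random.default_rng(5)
        u = GeneUniverse(tuple(f"g{i}" for i in range(5)))
        P = rng.integers(0, 2, (40, 5)).astype(np.uint8)
        S = rng.integers(0, 2, (40, 5)).astype(np.uint8)
        errors = [
            best_fit((P, S), "g0", list(u.names), u, k_max=k).error
            for k in range(0, 4)
        ]
        assert all(e2 <= e1 for e1, e2 in zip(errors, errors[1:]))

    @pytest.mark.parametrize("seed", range(10))
    def test_minimal_error_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 5, 24
        u = GeneUniverse(tuple(f"g{i}" for i in range(n)))
        P = rng.integers(0, 2, (m, n)).astype(np.uint8)
        S = rng.integers(0, 2, (m, n)).astype(np.uint8)
        res = best_fit((P, S), "g0", list(u.names), u, k_max=2)
        oracle = brute_force_min_error(P, S[:, 0], k_max=2)
        assert res.error == oracle


class TestReconstructAll:
    def test_noise_free_network_recovery(self):
        from boolense.benchmark import random_network

        net = random_network(5, k_max=2, seed=17)
        P, S = all_state_pairs(net)
        cands = reconstruct_all(
            (P, S), net.universe, threshold=0.0, k_max=2, max_candidates=5
        )
        for f in net.functions:
            c = cands[f.target]
            assert c.error == 0
            assert any(functions_semantically_equal(g, f) for g in c.functions)

    def test_all_constant_matrix_yields_constants(self):
        u = GeneUniverse(("a", "b"))
        P = np.ones((10, 2), dtype=np.uint8)
        S = np.ones((10, 2), dtype=np.uint8)
        cands = reconstruct_all((P, S), u)
        for gene in u.names:
            assert all(f.is_constant for f in cands[gene].functions)
            assert cands[gene].functions[0].table == (1,)

    def test_impossible_threshold_forces_constants(self):
        rng = np.random.default_rng(2)
        u = GeneUniverse(("a", "b", "c"))
        P = rng.integers(0, 2, (30, 3)).astype(np.uint8)
        S = rng.integers(0, 2, (30, 3)).astype(np.uint8)
        cands = reconstruct_all((P, S), u, threshold=1.1)
        assert all(
            f.is_constant for c in cands.values() for f in c.functions
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_filter_at_zero_threshold_is_sound(self, seed):
        rng = np.random.default_rng(seed)
        u = GeneUniverse(tuple(f"g{i}" for i in range(6)))
        P = rng.integers(0, 2, (40, 6)).astype(np.uint8)
        S = rng.integers(0, 2, (40, 6)).astype(np.uint8)
        filtered = reconstruct_all((P, S), u, threshold=0.0, k_max=2, max_candidates=6)
        plain = {
            g: best_fit((P, S), g, list(u.names), u, k_max=2)
            for g in u.names
        }
        assert candidate_sets_equal(filtered, plain)


class TestSerialization:
    def test_candidates_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        u = GeneUniverse(("a", "b", "c"))
        P = rng.integers(0, 2, (30, 3)).astype(np.uint8)
        S = rng.integers(0, 2, (30, 3)).astype(np.uint8)
        sets = {
            1: reconstruct_all((P, S), u, threshold=0.0, k_max=2),
            2: reconstruct_all((P, S), u, threshold=0.5, k_max=1),
        }
        path = tmp_path / "cands.tsv"
        write_candidates(sets, path)
        back = read_candidates(path)
        assert set(back) == {1, 2}
        for rep in sets:
            assert candidate_sets_equal(sets[rep], back[rep])


class TestEstimator:
    def test_fit_predict_on_consistent_data(self):
        from boolense.benchmark import random_network

        net = random_network(6, k_max=2, seed=9)
        P, S = all_state_pairs(net)
        est = NetworkReconstructor(threshold=0.0, k_max=2, max_candidates=6)
        est.fit(P, S)
        assert est.score(P, S) == 1.0
        assert set(est.errors_.values()) == {0}

    def test_sklearn_protocol_and_validation(self):
        from sklearn.base import clone

        est = NetworkReconstructor(k_max=2)
        assert clone(est).get_params()["k_max"] == 2
        with pytest.raises(ValueError):
            est.fit(np.zeros((3, 2), dtype=np.uint8), np.zeros((4, 2), dtype=np.uint8))
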