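"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: the
best-fit oracle enumerates every truth table explicitly, the motif oracle
enumerates node tuples, and function equality is decided by evaluation
rather than by comparing the (order-dependent) stored representation.
"""

from itertools import combinations, permutations, product

import numpy as np
import pytest

from boolense.network import BooleanFunction, BooleanNetwork, GeneUniverse


@pytest.fixture
def swap_net() -> BooleanNetwork:
    """Two genes copying each other: fixed points (0,0), (1,1) and a 2-cycle."""
    u = GeneUniverse(("x1", "x2"))
    return BooleanNetwork(
        u,
        (
            BooleanFunction("x1", ("x2",), (0, 1)),
            BooleanFunction("x2", ("x1",), (0, 1)),
        ),
    )


@pytest.fixture
def not_net() -> BooleanNetwork:
    """One self-inhibiting gene: a single attractor of length 2."""
    u = GeneUniverse(("x1",))
    return BooleanNetwork(u, (BooleanFunction("x1", ("x1",), (1, 0)),))


def brute_force_min_error(P: np.ndarray, y: np.ndarray, k_max: int) -> int:
    """Minimal misclassification count over ALL input subsets and truth tables.

    Enumerates every subset of all genes with at most ``k_max`` members and,
    for each, every possible truth table; the error of a table is the
    number of pairs whose successor bit it mispredicts.
    """
    m, n = P.shape
    best = m + 1
    for k in range(0, k_max + 1):
        for subset in combinations(range(n), k):
            idx = np.zeros(m, dtype=np.int64)
            for c in subset:
                idx = (idx << 1) | P[:, c]
            tables = np.array(
                list(product((0, 1), repeat=2**k)), dtype=np.uint8
            )  # (2**2**k, 2**k)
            preds = tables[:, idx]  # (n_tables, m)
            errors = (preds != y[None, :]).sum(axis=1)
            best = min(best, int(errors.min()))
    return best


def brute_force_motifs(adj: np.ndarray) -> tuple[int, int]:
    """FFL and bi-fan counts by explicit tuple enumeration (self-loops ignored)."""
    n = adj.shape[0]
    A = adj.astype(bool).copy()
    np.fill_diagonal(A, False)
    ffl = 0
    for a, b, c in permutations(range(n), 3):
        if A[a, b] and A[a, c] and A[b, c]:
            ffl += 1
    bifan = 0
    for a, b in combinations(range(n), 2):  # regulators
        for c, d in combinations(range(n), 2):  # targets
            if len({a, b, c, d}) < 4:
                continue
            if A[a, c] and A[a, d] and A[b, c] and A[b, d]:
                bifan += 1
    return ffl, bifan


def evaluate_on_env(f: BooleanFunction, env: dict[str, int]) -> int:
    idx = 0
    for name in f.inputs:
        idx = (idx << 1) | env[name]
    return f.table[idx]


def functions_semantically_equal(f: BooleanFunction, g: BooleanFunction) -> bool:
    """True iff the functions agree on every assignment of their joint inputs."""
    names = sorted(set(f.inputs) | set(g.inputs))
    for bits in product((0, 1), repeat=len(names)):
        env = dict(zip(names, bits))
        if evaluate_on_env(f, env) != evaluate_on_env(g, env):
            return False
    return True


def canonical_form(f: BooleanFunction) -> tuple:
    """Representation invariant to input order: sorted inputs + re-indexed table."""
    names = tuple(sorted(f.inputs))
    table = []
    for bits in product((0, 1), repeat=len(names)):
        table.append(evaluate_on_env(f, dict(zip(names, bits))))
    return names, tuple(table)


def candidate_sets_equal(a, b) -> bool:
    """Gene-wise equality of candidate sets up to input reordering."""
    if set(a) != set(b):
        return False
    for gene in a:
        if a[gene].error != b[gene].error:
            return False
        ca = {canonical_form(f) for f in a[gene].functions}
        cb = {canonical_form(f) for f in b[gene].functions}
        if ca != cb:
            return False
    return True


def all_state_pairs(net: BooleanNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Every state of the network paired with its synchronous successor."""
    n = net.n
    succ = net.successor_map()
    states = np.arange(1 << n)
    P = ((states[:, None] >> (n - 1 - np.arange(n))[None, :]) & 1).astype(np.uint8)
    S = ((succ[:, None] >> (n - 1 - np.arange(n))[None, :]) & 1).astype(np.uint8)
    return P, S
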