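"""Boolean network models: states, synchronous dynamics, attractor search.

A Boolean network over ``n`` genes assigns each gene a binary activity
(0 = inactive, 1 = active) and a Boolean transition function of a subset of
the genes.  Under the synchronous update scheme every gene is updated
simultaneously, so the dynamics form a deterministic map on the ``2**n``
network states and every trajectory eventually enters a recurrent cycle of
states -- an *attractor* (a fixed point if the cycle has length 1).

Truth-table addressing convention
---------------------------------
The output column of a :class:`BooleanFunction` is indexed by reading the
input genes in their listed order with the *first* input as the most
significant bit.  For inputs ``(a, b)`` the table rows are the patterns
``a b = 00, 01, 10, 11``.  This convention is fixed so that serialized
tables are portable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneUniverse",
    "BooleanFunction",
    "BooleanNetwork",
    "Attractor",
    "evaluate_function",
    "step",
    "find_attractors",
    "basin_sizes",
    "state_space_size",
    "state_to_int",
    "int_to_state",
]

#: Largest network size for which exhaustive state-space enumeration is
#: attempted by default (2**25 states).
DEFAULT_EXHAUSTIVE_CAP = 25


@dataclass(frozen=True)
class GeneUniverse:
    """An ordered set of unique gene identifiers with name -> position lookup."""

    names: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        if not names:
            raise ValueError("gene universe must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "index", {n: i for i, n in enumerate(names)})

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def positions(self, names: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self.index[n] for n in names], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"gene {exc.args[0]!r} not in universe") from None


def _as_state(bits: Sequence[int] | np.ndarray, n: int | None = None) -> np.ndarray:
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("a network state is a 1-D binary vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("state values must be 0 or 1")
    if n is not None and arr.shape[0] != n:
        raise ValueError(f"state has length {arr.shape[0]}, expected {n}")
    return arr


@dataclass(frozen=True)
class BooleanFunction:
    """A target gene, an ordered input list, and a truth-table output column.

    ``table`` has length ``2**len(inputs)``; a constant function has no
    inputs and a single-entry table.
    """

    target: str
    inputs: tuple[str, ...]
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        inputs = tuple(self.inputs)
        table = tuple(int(b) for b in self.table)
        if len(set(inputs)) != len(inputs):
            raise ValueError("function inputs must be distinct")
        if len(table) != 2 ** len(inputs):
            raise ValueError(
                f"table length {len(table)} does not match 2**{len(inputs)} rows"
            )
        if any(b not in (0, 1) for b in table):
            raise ValueError("truth-table entries must be 0 or 1")
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "table", table)

    @property
    def is_constant(self) -> bool:
        return not self.inputs

    @property
    def arity(self) -> int:
        return len(self.inputs)

    @classmethod
    def constant(cls, target: str, value: int) -> "BooleanFunction":
        return cls(target=target, inputs=(), table=(int(value),))


def evaluate_function(
    f: BooleanFunction, state: Sequence[int] | np.ndarray, universe: GeneUniverse
) -> int:
    """Evaluate ``f`` on a network state (first input = most significant bit)."""
    s = _as_state(state, len(universe))
    idx = 0
    for name in f.inputs:
        idx = (idx << 1) | int(s[universe.index[name]])
    return f.table[idx]


@dataclass(frozen=True)
class BooleanNetwork:
    """One Boolean transition function per gene over a shared universe."""

    universe: GeneUniverse
    functions: tuple[BooleanFunction, ...]

    def __post_init__(self) -> None:
        funcs = tuple(self.functions)
        targets = [f.target for f in funcs]
        if sorted(targets) != sorted(self.universe.names):
            raise ValueError("exactly one function per universe gene is required")
        for f in funcs:
            for g in f.inputs:
                if g not in self.universe:
                    raise ValueError(f"input {g!r} of {f.target!r} not in universe")
        # store in universe order
        by_target = {f.target: f for f in funcs}
        object.__setattr__(
            self, "functions", tuple(by_target[n] for n in self.universe.names)
        )

    @property
    def n(self) -> int:
        return len(self.universe)

    def function_of(self, gene: str) -> BooleanFunction:
        return self.functions[self.universe.index[gene]]

    # -- dynamics ---------------------------------------------------------

    def step(self, state: Sequence[int] | np.ndarray) -> np.ndarray:
        """Synchronous update: every gene reads the same predecessor state."""
        s = _as_state(state, self.n)
        out = np.empty(self.n, dtype=np.uint8)
        for i, f in enumerate(self.functions):
            idx = 0
            for name in f.inputs:
                idx = (idx << 1) | int(s[self.universe.index[name]])
            out[i] = f.table[idx]
        return out

    def successor_map(self) -> np.ndarray:
        """Successor of every encoded state, vectorized over the full state space.

        States are encoded as integers with gene 0 as the most significant
        bit, so integer order coincides with lexicographic order on the bit
        vectors.  Only feasible for small ``n``.
        """
        n = self.n
        size = 1 << n
        states = np.arange(size, dtype=np.int64)
        succ = np.zeros(size, dtype=np.int64)
        for i, f in enumerate(self.functions):
            if f.is_constant:
                out = np.full(size, f.table[0], dtype=np.int64)
            else:
                idx = np.zeros(size, dtype=np.int64)
                for name in f.inputs:
                    bitpos = n - 1 - self.universe.index[name]
                    idx = (idx << 1) | ((states >> bitpos) & 1)
                out = np.asarray(f.table, dtype=np.int64)[idx]
            succ |= out << (n - 1 - i)
        return succ


def step(net: BooleanNetwork, state: Sequence[int] | np.ndarray) -> np.ndarray:
    """Apply one synchronous update of ``net`` to ``state``."""
    return net.step(state)


def state_to_int(bits: Sequence[int] | np.ndarray) -> int:
    """Encode a binary state as an integer, gene 0 = most significant bit."""
    out = 0
    for b in np.asarray(bits, dtype=np.uint8):
        out = (out << 1) | int(b)
    return out


def int_to_state(x: int, n: int) -> np.ndarray:
    return np.array([(x >> (n - 1 - i)) & 1 for i in range(n)], dtype=np.uint8)


def state_space_size(n: int) -> int:
    """Number of states of an ``n``-gene Boolean network, ``2**n`` exactly."""
    if n < 0:
        raise ValueError("network size must be non-negative")
    return 1 << n


@dataclass(frozen=True)
class Attractor:
    """A recurrent cycle of states under synchronous updating.

    ``states`` is stored in canonical rotation: the lexicographically
    smallest state leads, which makes attractors found from different start
    states directly comparable.
    """

    states: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        states = tuple(tuple(int(b) for b in s) for s in self.states)
        if not states:
            raise ValueError("an attractor has at least one state")
        if len(set(states)) != len(states):
            raise ValueError("attractor states must be distinct within the cycle")
        object.__setattr__(self, "states", _canonical_rotation(states))

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def state_matrix(self) -> np.ndarray:
        return np.array(self.states, dtype=np.uint8)


def _canonical_rotation(
    states: tuple[tuple[int, ...], ...]
) -> tuple[tuple[int, ...], ...]:
    k = min(range(len(states)), key=lambda i: states[i])
    return states[k:] + states[:k]


def _attractors_from_successor_map(succ: np.ndarray, n: int):
    """All cycles of the functional graph ``succ`` plus a state -> cycle map."""
    size = succ.shape[0]
    label = np.full(size, -1, dtype=np.int64)  # attractor id per state
    cycles: list[list[int]] = []
    for start in range(size):
        if label[start] >= 0:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        x = start
        while label[x] < 0 and x not in pos:
            pos[x] = len(path)
            path.append(x)
            x = int(succ[x])
        if label[x] >= 0:
            aid = int(label[x])
        else:
            # new cycle discovered within the current path
            cstart = pos[x]
            aid = len(cycles)
            cycles.append(path[cstart:])
        for y in path:
            label[y] = aid
    return cycles, label


def find_attractors(
    net: BooleanNetwork,
    mode: str = "exhaustive",
    n_starts: int = 1000,
    seed: int | None = None,
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> list[Attractor]:
    """Attractors of ``net`` under synchronous updating.

    ``exhaustive`` mode enumerates all ``2**n`` states and returns every
    attractor (refused above ``exhaustive_cap`` genes).  ``sampled`` mode
    follows trajectories from ``n_starts`` uniform random start states and
    returns the deduplicated attractors reached; it may under-count.
    Attractors are returned in canonical order (sorted by their canonical
    leading state).
    """
    n = net.n
    if mode == "exhaustive":
        if n > exhaustive_cap:
            raise ValueError(
                f"exhaustive search refused for n={n} > cap={exhaustive_cap}; "
                "use mode='sampled' with a start-state budget instead"
            )
        succ = net.successor_map()
        cycles, _ = _attractors_from_successor_map(succ, n)
        attractors = [
            Attractor(tuple(tuple(int_to_state(x, n)) for x in cyc)) for cyc in cycles
        ]
    elif mode == "sampled":
        if n_starts < 1:
            raise ValueError("sampled mode requires n_starts >= 1")
        if seed is None:
            raise ValueError("sampled mode requires a seed")
        rng = np.random.default_rng(seed)
        found: dict[tuple, Attractor] = {}
        for _ in range(n_starts):
            state = rng.integers(0, 2, size=n).astype(np.uint8)
            seen: dict[tuple, int] = {}
            traj: list[tuple[int, ...]] = []
            cur = tuple(int(b) for b in state)
            while cur not in seen:
                seen[cur] = len(traj)
                traj.append(cur)
                state = net.step(np.array(cur, dtype=np.uint8))
                cur = tuple(int(b) for b in state)
            att = Attractor(tuple(traj[seen[cur]:]))
            found[att.states] = att
        attractors = list(found.values())
    else:
        raise ValueError(f"unknown attractor search mode {mode!r}")
    return sorted(attractors, key=lambda a: a.states)


def basin_sizes(net: BooleanNetwork, exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP):
    """Exhaustive attractors with their basin-of-attraction sizes.

    Returns ``(attractors, sizes)`` with the same canonical ordering as
    :func:`find_attractors`; the sizes sum to ``2**n`` because every state
    leads to exactly one attractor.
    """
    n = net.n
    if n > exhaustive_cap:
        raise ValueError(f"basin computation refused for n={n} > cap={exhaustive_cap}")
    succ = net.successor_map()
    cycles, label = _attractors_from_successor_map(succ, n)
    attractors = [
        Attractor(tuple(tuple(int_to_state(x, n)) for x in cyc)) for cyc in cycles
    ]
    counts = np.bincount(label, minlength=len(cycles))
    order = sorted(range(len(attractors)), key=lambda i: attractors[i].states)
    return [attractors[i] for i in order], [int(counts[i]) for i in order]
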