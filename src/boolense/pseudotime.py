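"""Pseudo-time transition pairs from the heterogeneity of a cell population.

Instead of ordering cells along a trajectory, every cell of an individual is
treated as a potential predecessor or successor of every other cell.  With
``s`` cells there are ``s*(s-1)/2`` unordered couples and, since either cell
of a couple can act as the predecessor, ``s*(s-1)`` ordered tuples.
A reconstruction run draws a fixed number of those ordered tuples at random
(without replacement by default) and treats each as one synchronous time
step; the draw is repeated over independent replicates.

Per-replicate seeds are derived from the master seed by the documented
scheme ``seed_r = master_seed + r`` for replicate index ``r = 1..R`` --
never from global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .binarize import BinaryMatrix

__all__ = [
    "TransitionPair",
    "TupleSample",
    "count_tuples",
    "sample_tuples",
    "replicate_samples",
    "write_tuple_samples",
    "read_tuple_samples",
]


@dataclass(frozen=True)
class TransitionPair:
    """One pseudo-time step: a predecessor and a successor binary state."""

    predecessor: tuple[int, ...]
    successor: tuple[int, ...]
    source_cells: tuple[str, str] | None = None

    def __post_init__(self):
        pred = tuple(int(b) for b in self.predecessor)
        succ = tuple(int(b) for b in self.successor)
        if len(pred) != len(succ):
            raise ValueError("predecessor and successor must share the universe")
        if self.source_cells is not None and self.source_cells[0] == self.source_cells[1]:
            raise ValueError("a cell cannot be its own successor")
        object.__setattr__(self, "predecessor", pred)
        object.__setattr__(self, "successor", succ)


@dataclass(frozen=True)
class TupleSample:
    """A reproducible draw of transition pairs for one reconstruction run."""

    pairs: tuple[TransitionPair, ...]
    seed: int
    replicate_index: int = 1

    def __len__(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(predecessors, successors) as (n_pairs x n_genes) uint8 arrays."""
        pred = np.array([p.predecessor for p in self.pairs], dtype=np.uint8)
        succ = np.array([p.successor for p in self.pairs], dtype=np.uint8)
        return pred, succ


def count_tuples(s: int) -> tuple[int, int]:
    """Couples and ordered tuples formable from ``s`` cells.

    ``couples = s*(s-1)/2`` (unordered pairs of distinct cells), and each
    couple yields two ordered tuples, so ``tuples = s*(s-1)``.
    """
    if s < 2:
        raise ValueError("at least two cells are required to form tuples")
    couples = s * (s - 1) // 2
    return couples, 2 * couples


def _binary_frame(bin_matrix) -> pd.DataFrame:
    if isinstance(bin_matrix, BinaryMatrix):
        return bin_matrix.binary
    return bin_matrix


def sample_tuples(
    bin_matrix,
    n_pairs: int,
    seed: int,
    replace: bool = False,
    replicate_index: int = 1,
) -> TupleSample:
    """Draw ``n_pairs`` ordered pairs of distinct cells uniformly at random.

    Accepts a :class:`~boolense.binarize.BinaryMatrix` or a genes x cells
    0/1 DataFrame.  Self-pairs are excluded.  Without replacement (default)
    ``n_pairs`` may not exceed the total number of ordered pairs.
    """
    frame = _binary_frame(bin_matrix)
    cells = list(frame.columns)
    s = len(cells)
    if s < 2:
        raise ValueError("at least two cells are required")
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    _, total = count_tuples(s)
    rng = np.random.default_rng(seed)
    if replace:
        codes = rng.integers(0, total, size=n_pairs)
    else:
        if n_pairs > total:
            raise ValueError(
                f"cannot draw {n_pairs} distinct ordered pairs from {total} available"
            )
        codes = rng.choice(total, size=n_pairs, replace=False)
    # decode ordered-pair index: i = code // (s-1); j skips i
    i = codes // (s - 1)
    j = codes % (s - 1)
    j = j + (j >= i)
    values = frame.to_numpy(dtype=np.uint8)
    pairs = tuple(
        TransitionPair(
            predecessor=tuple(values[:, a]),
            successor=tuple(values[:, b]),
            source_cells=(cells[a], cells[b]),
        )
        for a, b in zip(i.tolist(), j.tolist())
    )
    return TupleSample(pairs=pairs, seed=seed, replicate_index=replicate_index)


def replicate_samples(
    bin_matrix,
    n_pairs: int,
    n_replicates: int,
    master_seed: int,
    replace: bool = False,
) -> list[TupleSample]:
    """Independent tuple draws for ``n_replicates`` reconstruction runs.

    Replicate ``r`` (1-based) uses seed ``master_seed + r``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [
        sample_tuples(
            bin_matrix,
            n_pairs,
            seed=master_seed + r,
            replace=replace,
            replicate_index=r,
        )
        for r in range(1, n_replicates + 1)
    ]


def write_tuple_samples(samples: Sequence[TupleSample], path) -> None:
    """TSV with columns (replicate, predecessor_cell, successor_cell)."""
    rows = []
    for sample in samples:
        for pair in sample.pairs:
            if pair.source_cells is None:
                raise ValueError("cannot serialize pairs without source cell ids")
            rows.append(
                (sample.replicate_index, pair.source_cells[0], pair.source_cells[1])
            )
    frame = pd.DataFrame(
        rows, columns=["replicate", "predecessor_cell", "successor_cell"]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_tuple_samples(path, bin_matrix) -> list[TupleSample]:
    """Replay serialized tuple draws against a binary matrix."""
    frame = _binary_frame(bin_matrix)
    table = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    values = frame.to_numpy(dtype=np.uint8)
    col_index = {c: k for k, c in enumerate(frame.columns)}
    samples = []
    for rep, group in table.groupby("replicate", sort=True):
        pairs = tuple(
            TransitionPair(
                predecessor=tuple(values[:, col_index[row.predecessor_cell]]),
                successor=tuple(values[:, col_index[row.successor_cell]]),
                source_cells=(row.predecessor_cell, row.successor_cell),
            )
            for row in group.itertuples()
        )
        samples.append(TupleSample(pairs=pairs, seed=-1, replicate_index=int(rep)))
    return samples
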