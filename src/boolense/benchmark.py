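"""Evaluation harness: random ground-truth networks, simulated series, scoring.

Random Boolean networks with scale-free in-degree topology serve as ground
truth; synchronous time series (optionally corrupted by independent bit
flips) are simulated from them, the reconstruction is run with and without
the correlation pre-filter, and edge recovery is scored as sensitivity and
specificity over all ordered gene pairs.  Runtime is reported per method
but is hardware-dependent and never part of any correctness contract.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import candidates_adjacency, network_adjacency
from .network import BooleanFunction, BooleanNetwork, GeneUniverse
from .pseudotime import TransitionPair
from .reconstruct import FunctionCandidates, reconstruct_all

__all__ = [
    "BenchmarkConfig",
    "RecoveryScore",
    "random_network",
    "simulate_series",
    "score_recovery",
    "run_benchmark",
]


@dataclass
class BenchmarkConfig:
    """Grid of the reconstruction benchmark.

    ``series_mode``: ``fixed_20`` simulates 20 time points per network,
    ``nodes_plus_10`` simulates ``n + 10`` time points.  ``noise_rate`` is
    the independent bit-flip probability applied to the observed series and
    must stay below 0.5 (beyond that the signal is inverted).
    """

    sizes: tuple[int, ...] = (20, 40, 60, 80, 100, 120, 140, 160, 180, 200)
    gamma: float = 2.5
    k_max: int = 3
    series_mode: str = "fixed_20"
    noise_rate: float = 0.0
    n_networks_per_size: int = 100
    threshold: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if any(s < 2 for s in self.sizes):
            raise ValueError("network sizes must be >= 2")
        if not (0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must be in [0, 0.5)")
        if self.series_mode not in ("fixed_20", "nodes_plus_10"):
            raise ValueError(f"unknown series mode {self.series_mode!r}")


def _has_fictitious_input(table: np.ndarray, k: int) -> bool:
    cube = table.reshape((2,) * k)
    for axis in range(k):
        if np.array_equal(
            np.take(cube, 0, axis=axis), np.take(cube, 1, axis=axis)
        ):
            return True
    return False


def random_network(
    n: int,
    k_max: int = 3,
    gamma: float = 2.5,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> BooleanNetwork:
    """Random Boolean network with truncated power-law in-degrees.

    In-degrees are drawn from ``P(k) ~ k**(-gamma)`` on ``1..k_max``,
    inputs are chosen uniformly without replacement, and truth tables are
    uniform over the tables in which every listed input is essential (a
    fictitious input would make the declared topology meaningless for
    edge-recovery scoring).
    """
    if n < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(seed)
    universe = GeneUniverse(
        tuple(names) if names is not None else tuple(f"g{i}" for i in range(n))
    )
    degrees = np.arange(1, k_max + 1, dtype=float)
    weights = degrees**-gamma
    weights /= weights.sum()
    functions = []
    for i, gene in enumerate(universe.names):
        k = int(rng.choice(np.arange(1, k_max + 1), p=weights))
        inputs = tuple(
            universe.names[j] for j in rng.choice(n, size=k, replace=False)
        )
        while True:
            table = rng.integers(0, 2, size=2**k)
            if not _has_fictitious_input(table, k):
                break
        functions.append(
            BooleanFunction(target=gene, inputs=inputs, table=tuple(int(b) for b in table))
        )
    return BooleanNetwork(universe=universe, functions=tuple(functions))


def simulate_series(
    net: BooleanNetwork,
    length: int,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> list[TransitionPair]:
    """Synchronous trajectory from a random start as consecutive pairs.

    A trajectory of ``length`` states yields ``length - 1`` transition
    pairs.  After simulation every observed bit is independently flipped
    with probability ``noise_rate`` (applied to the series, so a noisy state
    appears consistently as successor of one pair and predecessor of the
    next).
    """
    if length < 2:
        raise ValueError("a series needs at least two time points")
    if not (0 <= noise_rate < 0.5):
        raise ValueError("noise_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    states = np.zeros((length, net.n), dtype=np.uint8)
    states[0] = rng.integers(0, 2, size=net.n)
    for t in range(1, length):
        states[t] = net.step(states[t - 1])
    if noise_rate > 0:
        flips = rng.random(states.shape) < noise_rate
        states = states ^ flips.astype(np.uint8)
    return [
        TransitionPair(
            predecessor=tuple(int(b) for b in states[t]),
            successor=tuple(int(b) for b in states[t + 1]),
            source_cells=(f"t{t}", f"t{t + 1}"),
        )
        for t in range(length - 1)
    ]


@dataclass(frozen=True)
class RecoveryScore:
    """Confusion matrix of edge recovery over all ordered gene pairs."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def score_recovery(
    truth: BooleanNetwork,
    candidates: Mapping[str, FunctionCandidates],
    include_self_loops: bool = True,
) -> RecoveryScore:
    """Score predicted edges (union over candidate functions) against truth.

    All ``n**2`` ordered gene pairs are classified (self-loops included by
    default; disable to score off-diagonal pairs only).
    """
    truth_adj = network_adjacency(truth).astype(bool)
    pred_adj = candidates_adjacency(candidates, truth.universe).astype(bool)
    if not include_self_loops:
        np.fill_diagonal(truth_adj, False)
        np.fill_diagonal(pred_adj, False)
        mask = ~np.eye(truth.n, dtype=bool)
    else:
        mask = np.ones((truth.n, truth.n), dtype=bool)
    tp = int(np.sum(truth_adj & pred_adj & mask))
    fp = int(np.sum(~truth_adj & pred_adj & mask))
    fn = int(np.sum(truth_adj & ~pred_adj & mask))
    tn = int(np.sum(~truth_adj & ~pred_adj & mask))
    return RecoveryScore(tp=tp, fp=fp, tn=tn, fn=fn)


def run_benchmark(
    cfg: BenchmarkConfig,
    methods: Sequence[str] = ("plain_best_fit", "filtered_best_fit"),
) -> pd.DataFrame:
    """Run the reconstruction benchmark grid and return a tidy results table.

    ``plain_best_fit`` is the filter-free reference (threshold 0);
    ``filtered_best_fit`` applies the configured correlation threshold.
    Both consider every gene a potential input (no candidate truncation),
    so at threshold 0 the two methods coincide exactly.
    """
    known = {"plain_best_fit": 0.0, "filtered_best_fit": cfg.threshold}
    for m in methods:
        if m not in known:
            raise ValueError(f"unknown method {m!r}")
    rows = []
    for size, net_id in product(cfg.sizes, range(cfg.n_networks_per_size)):
        net_seed = cfg.seed + 1000 * size + net_id
        truth = random_network(size, k_max=cfg.k_max, gamma=cfg.gamma, seed=net_seed)
        length = 20 if cfg.series_mode == "fixed_20" else size + 10
        pairs = simulate_series(
            truth, length, noise_rate=cfg.noise_rate, seed=net_seed + 1
        )
        for method in methods:
            start = time.perf_counter()
            candidates = reconstruct_all(
                pairs,
                truth.universe,
                threshold=known[method],
                k_max=cfg.k_max,
                max_candidates=size,
            )
            runtime = time.perf_counter() - start
            score = score_recovery(truth, candidates)
            rows.append(
                {
                    "size": size,
                    "network_id": net_id,
                    "method": method,
                    "noise": cfg.noise_rate,
                    "sensitivity": score.sensitivity,
                    "specificity": score.specificity,
                    "runtime_s": runtime,
                }
            )
    return pd.DataFrame(rows)
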