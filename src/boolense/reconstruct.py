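"""Filtered Best-Fit reconstruction of Boolean functions from transition pairs.

For each target gene the pipeline first screens potential regulators by the
Pearson correlation between a candidate input's predecessor values and the
target's successor values across all transition pairs (monotone regulation
shows up as |r| bounded away from zero, with negative r for inhibition).
Inputs with |r| at or above a threshold survive.  The Best-Fit Extension
step then enumerates every subset of the surviving inputs up to ``k_max``
and scores it through its partially defined Boolean function (pdBF): each
pair contributes its input pattern to the true set T (successor 1) or the
false set F (successor 0), and the reconstruction error of the subset is

    epsilon = sum over patterns of min(count_T, count_F),

the minimal number of misclassified observations achievable by any Boolean
completion.  (An unweighted variant counting distinct conflicting patterns,
``error_mode="distinct"``, is available for comparison.)  All subsets
achieving the global minimum are kept and their truth tables filled:
patterns seen only in T become 1, only in F become 0, conflicts resolve to
the majority output (ties to 0), and unobserved patterns are enumerated
over every completion while the completion count stays within ``cap``
(majority-filled with a ``capped`` flag beyond that).  The pooled,
deduplicated functions form the gene's candidate set; a constant function
(empty input subset) always competes, so the candidate list is never empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .boolnet_io import expression_to_function, function_to_expression
from .network import BooleanFunction, GeneUniverse
from .pseudotime import TransitionPair, TupleSample

__all__ = [
    "InputFilterResult",
    "PdBF",
    "FunctionCandidates",
    "filter_inputs",
    "build_pdbf",
    "pdbf_error",
    "best_fit",
    "reconstruct_all",
    "NetworkReconstructor",
    "write_candidates",
    "read_candidates",
]

DEFAULT_THRESHOLD = 0.03  #: Pearson |r| cutoff of the input pre-filter
DEFAULT_K_MAX = 5  #: largest input-subset size searched
DEFAULT_CAP = 1024  #: completion / candidate-list budget per gene
DEFAULT_MAX_CANDIDATES = 16  #: inputs retained by the pre-filter per gene


def pairs_arrays(pairs, universe: GeneUniverse | None = None):
    """Normalize pair containers to (predecessor, successor) uint8 arrays."""
    if isinstance(pairs, TupleSample):
        return pairs.arrays()
    if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[0], np.ndarray):
        return pairs
    seq = list(pairs)
    if seq and isinstance(seq[0], TransitionPair):
        pred = np.array([p.predecessor for p in seq], dtype=np.uint8)
        succ = np.array([p.successor for p in seq], dtype=np.uint8)
        return pred, succ
    if not seq:
        n = len(universe) if universe is not None else 0
        return np.zeros((0, n), dtype=np.uint8), np.zeros((0, n), dtype=np.uint8)
    raise TypeError("pairs must be a TupleSample, TransitionPair list, or array pair")


@dataclass(frozen=True)
class InputFilterResult:
    """Correlation-screened candidate regulators for one target gene."""

    target: str
    candidates: tuple[tuple[str, float], ...]  # (gene, r), |r| descending
    threshold: float

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.candidates)


def filter_inputs(
    pairs,
    target: str,
    universe: GeneUniverse,
    threshold: float = DEFAULT_THRESHOLD,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> InputFilterResult:
    """Retain inputs whose predecessor values correlate with the target's successor.

    Pearson r is computed per potential input across all pairs; inputs with
    ``|r| >= threshold`` are kept (absolute value: inhibition is as relevant
    as activation), sorted by |r| descending and truncated to
    ``max_candidates``.  Zero-variance inputs (or a zero-variance target
    successor) have undefined r and are excluded.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    P, S = pairs_arrays(pairs, universe)
    if P.shape[0] < 2:
        raise ValueError("input filtering needs at least two transition pairs")
    y = S[:, universe.index[target]].astype(float)
    sy = y.std()
    candidates: list[tuple[str, float]] = []
    if sy > 0:
        X = P.astype(float)
        sx = X.std(axis=0)
        valid = sx > 0
        if valid.any():
            xc = X[:, valid] - X[:, valid].mean(axis=0)
            yc = y - y.mean()
            r = (xc * yc[:, None]).mean(axis=0) / (sx[valid] * sy)
            names = [universe.names[i] for i in np.flatnonzero(valid)]
            for name, rv in zip(names, r):
                if abs(rv) >= threshold:
                    candidates.append((name, float(rv)))
    candidates.sort(key=lambda t: (-abs(t[1]), universe.index[t[0]]))
    return InputFilterResult(
        target=target,
        candidates=tuple(candidates[:max_candidates]),
        threshold=threshold,
    )


@dataclass(frozen=True)
class PdBF:
    """Partially defined Boolean function: per-pattern (true, false) counts."""

    inputs: tuple[str, ...]
    counts: tuple[tuple[int, int], ...]  # indexed by pattern, length 2**k

    @property
    def k(self) -> int:
        return len(self.inputs)

    @property
    def n_observations(self) -> int:
        return sum(a + b for a, b in self.counts)


def _pattern_indices(P: np.ndarray, cols: Sequence[int]) -> np.ndarray:
    idx = np.zeros(P.shape[0], dtype=np.int64)
    for c in cols:
        idx = (idx << 1) | P[:, c]
    return idx


def build_pdbf(
    pairs, target: str, inputs: Sequence[str], universe: GeneUniverse
) -> PdBF:
    """Tally every transition pair into the pdBF of a fixed input subset."""
    inputs = tuple(inputs)
    if len(set(inputs)) != len(inputs):
        raise ValueError("pdBF inputs must be distinct")
    P, S = pairs_arrays(pairs, universe)
    cols = [universe.index[g] for g in inputs]
    y = S[:, universe.index[target]]
    idx = _pattern_indices(P, cols)
    size = 1 << len(inputs)
    cT = np.bincount(idx[y == 1], minlength=size)
    cF = np.bincount(idx[y == 0], minlength=size)
    return PdBF(inputs=inputs, counts=tuple(zip(cT.tolist(), cF.tolist())))


def pdbf_error(p: PdBF, mode: str = "weighted") -> int:
    """Best-fit error of a pdBF.

    ``weighted`` (default): sum over patterns of min(count_T, count_F) --
    the minimal number of misclassified observations under any completion.
    ``distinct``: number of patterns appearing in both T and F, the literal
    set-intersection reading.
    """
    if mode == "weighted":
        return int(sum(min(a, b) for a, b in p.counts))
    if mode == "distinct":
        return int(sum(1 for a, b in p.counts if a > 0 and b > 0))
    raise ValueError(f"unknown error mode {mode!r}")


@dataclass(frozen=True)
class FunctionCandidates:
    """All minimal-error Boolean functions reconstructed for one gene."""

    target: str
    error: int
    functions: tuple[BooleanFunction, ...]
    capped: bool = False

    def __post_init__(self):
        if not self.functions:
            raise ValueError("candidate list must be non-empty")
        if any(f.target != self.target for f in self.functions):
            raise ValueError("all candidates must share the target gene")

    def __len__(self) -> int:
        return len(self.functions)

    def input_union(self) -> set[str]:
        out: set[str] = set()
        for f in self.functions:
            out.update(f.inputs)
        return out


def _fill_tables(
    cT: np.ndarray, cF: np.ndarray, majority: int, cap: int
) -> tuple[list[tuple[int, ...]], bool]:
    """Truth-table fill rule: observed majority wins (tie 0), unobserved enumerate."""
    size = cT.shape[0]
    base = [0] * size
    unobserved = []
    for pat in range(size):
        a, b = int(cT[pat]), int(cF[pat])
        if a == 0 and b == 0:
            unobserved.append(pat)
        elif a > b:
            base[pat] = 1
        else:  # a < b, or conflict tie -> 0
            base[pat] = 0
    if not unobserved:
        return [tuple(base)], False
    if 2 ** len(unobserved) <= cap:
        tables = []
        for fill in product((0, 1), repeat=len(unobserved)):
            t = list(base)
            for pat, bit in zip(unobserved, fill):
                t[pat] = bit
            tables.append(tuple(t))
        return tables, False
    for pat in unobserved:
        base[pat] = majority
    return [tuple(base)], True


def best_fit(
    pairs,
    target: str,
    candidate_inputs: Sequence[str],
    universe: GeneUniverse,
    k_max: int = DEFAULT_K_MAX,
    cap: int = DEFAULT_CAP,
    error_mode: str = "weighted",
) -> FunctionCandidates:
    """Best-Fit Extension over all subsets of the filtered candidate inputs.

    Every subset of ``candidate_inputs`` with at most ``k_max`` members
    (including the empty subset, i.e. constant functions) is scored by its
    pdBF error; functions from all subsets achieving the global minimum are
    pooled, deduplicated and returned.
    """
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    P, S = pairs_arrays(pairs, universe)
    m = P.shape[0]
    if m == 0:
        return FunctionCandidates(
            target=target, error=0, functions=(BooleanFunction.constant(target, 0),)
        )
    y = S[:, universe.index[target]]
    n_one = int(y.sum())
    majority = 1 if n_one * 2 > m else 0
    cand = tuple(dict.fromkeys(candidate_inputs))  # dedupe, keep order
    cols = [universe.index[g] for g in cand]

    best_eps: int | None = None
    winners: list[tuple[tuple[str, ...], np.ndarray, np.ndarray]] = []
    for k in range(0, min(k_max, len(cand)) + 1):
        for subset in combinations(range(len(cand)), k):
            idx = _pattern_indices(P, [cols[i] for i in subset])
            size = 1 << k
            cT = np.bincount(idx[y == 1], minlength=size)
            cF = np.bincount(idx[y == 0], minlength=size)
            if error_mode == "weighted":
                eps = int(np.minimum(cT, cF).sum())
            else:
                eps = int(np.sum((cT > 0) & (cF > 0)))
            if best_eps is None or eps < best_eps:
                best_eps = eps
                winners = [(tuple(cand[i] for i in subset), cT, cF)]
            elif eps == best_eps:
                winners.append((tuple(cand[i] for i in subset), cT, cF))

    functions: dict[tuple, BooleanFunction] = {}
    capped = False
    for inputs, cT, cF in winners:
        tables, was_capped = _fill_tables(cT, cF, majority, cap)
        capped = capped or was_capped
        for table in tables:
            key = (inputs, table)
            if key not in functions:
                functions[key] = BooleanFunction(
                    target=target, inputs=inputs, table=table
                )
    pooled = list(functions.values())
    if len(pooled) > cap:
        pooled = pooled[:cap]
        capped = True
    return FunctionCandidates(
        target=target, error=int(best_eps), functions=tuple(pooled), capped=capped
    )


def reconstruct_all(
    sample,
    universe: GeneUniverse,
    threshold: float = DEFAULT_THRESHOLD,
    k_max: int = DEFAULT_K_MAX,
    cap: int = DEFAULT_CAP,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
    error_mode: str = "weighted",
) -> dict[str, FunctionCandidates]:
    """Filtered best-fit for every gene of the universe independently.

    Genes whose pre-filter retains no candidate input become constants at
    the majority successor value (these populate the fixed-gene metric).
    """
    P, S = pairs_arrays(sample, universe)
    out: dict[str, FunctionCandidates] = {}
    for gene in universe.names:
        filt = filter_inputs(
            (P, S), gene, universe, threshold=threshold, max_candidates=max_candidates
        )
        out[gene] = best_fit(
            (P, S),
            gene,
            filt.genes,
            universe,
            k_max=k_max,
            cap=cap,
            error_mode=error_mode,
        )
    return out


class NetworkReconstructor(BaseEstimator):
    """Scikit-learn estimator view of filtered best-fit reconstruction.

    ``fit(X, y)`` takes predecessor states ``X`` and successor states ``y``
    as (n_pairs x n_genes) binary arrays and stores the per-gene candidate
    sets; ``predict(X)`` applies one representative minimal-error function
    per gene (the first candidate) to predict successor states.
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        k_max: int = DEFAULT_K_MAX,
        cap: int = DEFAULT_CAP,
        max_candidates: int = DEFAULT_MAX_CANDIDATES,
        error_mode: str = "weighted",
        gene_names: Sequence[str] | None = None,
    ):
        self.threshold = threshold
        self.k_max = k_max
        self.cap = cap
        self.max_candidates = max_candidates
        self.error_mode = error_mode
        self.gene_names = gene_names

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.uint8)
        y = np.asarray(y, dtype=np.uint8)
        if X.shape != y.shape or X.ndim != 2:
            raise ValueError("X and y must be equal-shape (n_pairs, n_genes) arrays")
        names = (
            tuple(self.gene_names)
            if self.gene_names is not None
            else tuple(f"g{i}" for i in range(X.shape[1]))
        )
        self.universe_ = GeneUniverse(names)
        self.candidates_ = reconstruct_all(
            (X, y),
            self.universe_,
            threshold=self.threshold,
            k_max=self.k_max,
            cap=self.cap,
            max_candidates=self.max_candidates,
            error_mode=self.error_mode,
        )
        self.errors_ = {g: c.error for g, c in self.candidates_.items()}
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "candidates_")
        X = np.asarray(X, dtype=np.uint8)
        out = np.zeros_like(X)
        for j, gene in enumerate(self.universe_.names):
            f = self.candidates_[gene].functions[0]
            if f.is_constant:
                out[:, j] = f.table[0]
                continue
            cols = [self.universe_.index[g] for g in f.inputs]
            idx = _pattern_indices(X, cols)
            out[:, j] = np.asarray(f.table, dtype=np.uint8)[idx]
        return out

    def score(self, X, y):
        """Fraction of successor bits predicted correctly."""
        y = np.asarray(y, dtype=np.uint8)
        return float((self.predict(X) == y).mean())


def write_candidates(
    candidate_sets: Mapping[int, Mapping[str, FunctionCandidates]], path
) -> None:
    """Serialize candidate sets: one network-dialect rule per candidate.

    ``candidate_sets`` maps replicate index -> gene -> candidates.  Columns:
    replicate, target, epsilon, capped, factors (expression string).
    """
    rows = []
    for rep in sorted(candidate_sets):
        for gene, cands in candidate_sets[rep].items():
            for f in cands.functions:
                rows.append(
                    (rep, gene, cands.error, int(cands.capped), function_to_expression(f))
                )
    frame = pd.DataFrame(
        rows, columns=["replicate", "target", "epsilon", "capped", "factors"]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_candidates(path) -> dict[int, dict[str, FunctionCandidates]]:
    table = pd.read_csv(path, sep="\t")
    out: dict[int, dict[str, FunctionCandidates]] = {}
    for (rep, gene), group in table.groupby(["replicate", "target"], sort=True):
        funcs = tuple(
            expression_to_function(gene, expr) for expr in group["factors"]
        )
        out.setdefault(int(rep), {})[gene] = FunctionCandidates(
            target=gene,
            error=int(group["epsilon"].iloc[0]),
            functions=funcs,
            capped=bool(group["capped"].iloc[0]),
        )
    return out
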