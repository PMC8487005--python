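"""Interaction-graph metrics, motifs, attractor statistics, and group tests.

Structural readouts of a reconstructed ensemble: the number of fixed
(constant-function) genes, isolated genes (zero in- and out-degree), the
mean number of regulatory inputs, and the mean number of candidate
functions per gene.  Network motifs (feed-forward loops and bi-fans) are
counted on the interaction graph with self-loops ignored.  Dynamic
readouts summarize the synchronous attractor landscape: mean attractor
count and length per network, and per-gene activity probabilities obtained
by pooling all attractor states of a network and averaging over the
ensemble and its replicates.  Reconstructed edges can be validated against
an offline reference interaction table (a STRING-like undirected edge
list): an edge matches when the reference connects the two genes directly
or through exactly one intermediary node.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .ensemble import Ensemble
from .network import Attractor, BooleanNetwork, GeneUniverse
from .reconstruct import FunctionCandidates

__all__ = [
    "MetricsRecord",
    "MatchMatrix",
    "network_adjacency",
    "candidates_adjacency",
    "union_adjacency",
    "network_metrics",
    "graph_metrics",
    "metrics_table",
    "count_motifs",
    "landscape_stats",
    "activity_probabilities",
    "compare_groups",
    "match_matrix",
]


@dataclass
class MetricsRecord:
    """One row of ensemble readouts (structural, motif, and dynamic parts)."""

    n_fixed: float
    n_isolated: float
    mean_input: float
    mean_functions: float
    n_ffl: float | None = None
    n_bifan: float | None = None
    n_attractors: float | None = None
    mean_attractor_length: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in asdict(self).items() if v is not None}


def network_adjacency(net: BooleanNetwork) -> np.ndarray:
    """A[i, j] = 1 iff gene i appears in the regulatory function of gene j."""
    n = net.n
    adj = np.zeros((n, n), dtype=np.uint8)
    for j, f in enumerate(net.functions):
        for g in f.inputs:
            adj[net.universe.index[g], j] = 1
    return adj


def candidates_adjacency(
    candidates: Mapping[str, FunctionCandidates], universe: GeneUniverse
) -> np.ndarray:
    """Union adjacency over all candidate functions of one reconstruction."""
    n = len(universe)
    adj = np.zeros((n, n), dtype=np.uint8)
    for gene, cands in candidates.items():
        j = universe.index[gene]
        for g in cands.input_union():
            adj[universe.index[g], j] = 1
    return adj


def union_adjacency(ensembles: Sequence[Ensemble]) -> np.ndarray:
    """Union over candidate functions and replicates; monotone in replicates."""
    if not ensembles:
        raise ValueError("at least one ensemble is required")
    universe = ensembles[0].universe
    adj = np.zeros((len(universe), len(universe)), dtype=np.uint8)
    for e in ensembles:
        adj |= candidates_adjacency(e.candidates, universe)
    return adj


def network_metrics(net: BooleanNetwork) -> dict[str, float]:
    """Structural readouts of a single network."""
    adj = network_adjacency(net)
    n_fixed = sum(1 for f in net.functions if f.is_constant)
    degree = adj.sum(axis=0) + adj.sum(axis=1)
    n_isolated = int(np.sum(degree == 0))
    mean_input = float(adj.sum(axis=0).mean())
    n_ffl, n_bifan = count_motifs(adj)
    return {
        "n_fixed": float(n_fixed),
        "n_isolated": float(n_isolated),
        "mean_input": mean_input,
        "n_ffl": float(n_ffl),
        "n_bifan": float(n_bifan),
    }


def graph_metrics(ens: Ensemble) -> MetricsRecord:
    """Structural metrics averaged over an ensemble's sampled networks."""
    rows = [network_metrics(net) for net in ens.networks]
    frame = pd.DataFrame(rows)
    mean_functions = float(
        np.mean([len(ens.candidates[g]) for g in ens.universe.names])
    )
    means = frame.mean()
    return MetricsRecord(
        n_fixed=float(means["n_fixed"]),
        n_isolated=float(means["n_isolated"]),
        mean_input=float(means["mean_input"]),
        mean_functions=mean_functions,
        n_ffl=float(means["n_ffl"]),
        n_bifan=float(means["n_bifan"]),
    )


def metrics_table(ensembles: Sequence[Ensemble]) -> pd.DataFrame:
    """Tidy per-network metrics: one row per network per replicate."""
    rows = []
    for e in ensembles:
        for net_idx, net in enumerate(e.networks):
            row = {"replicate": e.replicate_index, "network": net_idx}
            row.update(network_metrics(net))
            rows.append(row)
    return pd.DataFrame(rows)


def count_motifs(adj: np.ndarray) -> tuple[int, int]:
    """Feed-forward loop and bi-fan counts of a directed adjacency matrix.

    FFL: ordered triples of distinct genes (A, B, C) with A->B, A->C, B->C.
    Bi-fan: unordered regulator pairs {A, B} and unordered target pairs
    {C, D}, all four distinct, with A->C, A->D, B->C, B->D.  Self-loops are
    ignored.
    """
    A = np.asarray(adj, dtype=np.int64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    A = A.copy()
    np.fill_diagonal(A, 0)
    # common regulators of (b, c): P[b, c] = #a with a->b and a->c
    P = A.T @ A
    n_ffl = int(np.sum(P * A))
    # bi-fans: for each unordered target pair choose 2 of the common regulators
    iu = np.triu_indices(A.shape[0], k=1)
    m = P[iu]
    n_bifan = int(np.sum(m * (m - 1) // 2))
    return n_ffl, n_bifan


def landscape_stats(
    landscapes: Sequence[Sequence[Attractor]],
) -> tuple[float, float]:
    """Mean attractor count and mean attractor length across networks.

    Each entry of ``landscapes`` is one network's attractor list.  The
    length statistic is the per-network mean attractor length averaged over
    networks.  Networks where (sampled) search found no attractor are
    excluded with a warning.
    """
    if not landscapes:
        raise ValueError("at least one network landscape is required")
    counts, lengths = [], []
    n_missing = 0
    for atts in landscapes:
        if not atts:
            n_missing += 1
            continue
        counts.append(len(atts))
        lengths.append(float(np.mean([a.length for a in atts])))
    if n_missing:
        warnings.warn(
            f"{n_missing} network(s) without detected attractors excluded",
            stacklevel=2,
        )
    if not counts:
        raise ValueError("no network has a detected attractor")
    return float(np.mean(counts)), float(np.mean(lengths))


def activity_probabilities(
    landscapes: Sequence[Sequence[Attractor]],
) -> np.ndarray:
    """Per-gene probability of being active in the attractor landscape.

    Per network, all attractor states are pooled and the fraction of states
    with the gene active is taken; the result is averaged over networks.
    Average the returned vectors over replicates for a campaign-level
    summary.
    """
    if not landscapes:
        raise ValueError("at least one network landscape is required")
    per_network = []
    for atts in landscapes:
        if not atts:
            raise ValueError("every network needs at least one attractor")
        states = np.vstack([a.state_matrix() for a in atts])
        per_network.append(states.mean(axis=0))
    return np.mean(per_network, axis=0)


def compare_groups(
    group_a,
    group_b,
    correction: str = "none",
    paired: bool = False,
) -> dict[str, tuple[float, float, float]]:
    """Rank-based per-metric comparison of two groups of metric records.

    Accepts sequences of :class:`MetricsRecord`, dicts, or DataFrames.  The
    default is the independent-samples rank-sum (Mann-Whitney U) test, with
    the paired signed-rank test behind ``paired=True``; exact p-values are
    used for small tie-free samples (the SciPy switch point), normal
    approximation otherwise.  ``correction="bonferroni"`` multiplies p by
    the number of metrics (clipped at 1).  Returns per metric
    ``(statistic, p, p_adjusted)``.  All-tied data yields p = 1 with a
    warning.
    """
    fa = _as_frame(group_a)
    fb = _as_frame(group_b)
    metrics = [c for c in fa.columns if c in fb.columns]
    if not metrics:
        raise ValueError("groups share no metric columns")
    raw: dict[str, tuple[float, float]] = {}
    for metric in metrics:
        a = fa[metric].to_numpy(dtype=float)
        b = fb[metric].to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError("both groups must be non-empty")
        if np.unique(np.concatenate([a, b])).size == 1:
            warnings.warn(f"metric {metric!r} is constant; p set to 1", stacklevel=2)
            raw[metric] = (0.0, 1.0)
            continue
        if paired:
            if a.size != b.size:
                raise ValueError("paired comparison needs equal group sizes")
            stat, p = _sstats.wilcoxon(a, b)
        else:
            stat, p = _sstats.mannwhitneyu(a, b, alternative="two-sided")
        raw[metric] = (float(stat), float(p))
    m = len(raw)
    out = {}
    for metric, (stat, p) in raw.items():
        p_adj = min(1.0, p * m) if correction == "bonferroni" else p
        out[metric] = (stat, p, p_adj)
    return out


def _as_frame(group) -> pd.DataFrame:
    if isinstance(group, pd.DataFrame):
        return group.select_dtypes(include=[np.number])
    rows = []
    for rec in group:
        if isinstance(rec, MetricsRecord):
            rows.append(rec.as_dict())
        elif isinstance(rec, Mapping):
            rows.append(dict(rec))
        else:
            raise TypeError("group entries must be MetricsRecord or mappings")
    return pd.DataFrame(rows)


@dataclass
class MatchMatrix:
    """Trinary validation of network edges against a reference edge table.

    Entry 1: the network edge is backed by a direct reference interaction or
    one with a single intermediary; -1: the edge has no such backing;
    0: no network edge at that position.
    """

    genes: tuple[str, ...]
    matrix: np.ndarray
    match_fraction: float
    missing_genes: tuple[str, ...] = ()


def match_matrix(
    adj: np.ndarray,
    reference_edges: Iterable[tuple[str, str]],
    universe: GeneUniverse,
) -> MatchMatrix:
    """Compare network edges to an undirected reference interaction list.

    The reference is treated as undirected; genes absent from the reference
    contribute no reference edges (their network edges count as mismatches)
    and are reported in ``missing_genes``.
    """
    adj = np.asarray(adj)
    n = len(universe)
    if adj.shape != (n, n):
        raise ValueError("adjacency shape does not match the universe")
    R = np.zeros((n, n), dtype=np.uint8)
    seen: set[str] = set()
    for a, b in reference_edges:
        a, b = str(a), str(b)
        for g in (a, b):
            if g in universe:
                seen.add(g)
        if a in universe and b in universe and a != b:
            ia, ib = universe.index[a], universe.index[b]
            R[ia, ib] = R[ib, ia] = 1
    two_step = (R.astype(np.int64) @ R.astype(np.int64)) > 0
    matched = (R > 0) | two_step
    M = np.zeros((n, n), dtype=np.int8)
    edge_mask = adj > 0
    M[edge_mask & matched] = 1
    M[edge_mask & ~matched] = -1
    n_edges = int(edge_mask.sum())
    fraction = float((M == 1).sum() / n_edges) if n_edges else float("nan")
    missing = tuple(g for g in universe.names if g not in seen)
    return MatchMatrix(
        genes=universe.names, matrix=M, match_fraction=fraction, missing_genes=missing
    )
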