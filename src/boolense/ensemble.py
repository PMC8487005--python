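"""Sampling concrete Boolean networks from per-gene candidate function sets.

A reconstruction run yields, for every gene, a set of equally accurate
minimal-error Boolean functions.  An *ensemble* is a population of concrete
networks obtained by drawing, per network and per gene, one candidate
function uniformly at random (with replacement across networks: two sampled
networks may coincide when candidate spaces are small).  Repeating the
procedure over replicate tuple draws yields ``n_networks * n_replicates``
networks per individual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import BooleanNetwork, GeneUniverse
from .pseudotime import TupleSample
from .reconstruct import FunctionCandidates, reconstruct_all

__all__ = ["Ensemble", "sample_ensemble", "ensemble_campaign", "write_manifest"]


@dataclass(frozen=True)
class Ensemble:
    """Concrete networks sampled from one replicate's candidate sets."""

    universe: GeneUniverse
    candidates: dict[str, FunctionCandidates]
    networks: tuple[BooleanNetwork, ...]
    choices: tuple[tuple[int, ...], ...]  # per network: candidate index per gene
    replicate_index: int
    seed: int

    def __len__(self) -> int:
        return len(self.networks)


def sample_ensemble(
    candidates: Mapping[str, FunctionCandidates],
    universe: GeneUniverse,
    n_networks: int,
    seed: int,
    replicate_index: int = 1,
) -> Ensemble:
    """Draw ``n_networks`` networks, one uniform candidate per gene each."""
    if n_networks < 1:
        raise ValueError("n_networks must be positive")
    for gene in universe.names:
        if gene not in candidates or len(candidates[gene]) == 0:
            raise ValueError(f"gene {gene!r} has no candidate functions")
    rng = np.random.default_rng(seed)
    networks = []
    choices = []
    sizes = {g: len(candidates[g]) for g in universe.names}
    for _ in range(n_networks):
        picks = tuple(int(rng.integers(0, sizes[g])) for g in universe.names)
        funcs = tuple(
            candidates[g].functions[picks[j]] for j, g in enumerate(universe.names)
        )
        networks.append(BooleanNetwork(universe=universe, functions=funcs))
        choices.append(picks)
    return Ensemble(
        universe=universe,
        candidates=dict(candidates),
        networks=tuple(networks),
        choices=tuple(choices),
        replicate_index=replicate_index,
        seed=seed,
    )


def ensemble_campaign(
    samples: Sequence[TupleSample],
    universe: GeneUniverse,
    n_networks: int,
    master_seed: int,
    **recon_params,
) -> list[Ensemble]:
    """Reconstruct and sample one ensemble per replicate tuple draw.

    Ensemble ``r`` uses sampling seed ``master_seed + r`` (1-based replicate
    index), mirroring the replicate-seed scheme of the tuple stage; the
    total network count is ``n_networks * len(samples)``.
    """
    if not samples:
        raise ValueError("at least one replicate sample is required")
    ensembles = []
    for sample in samples:
        candidates = reconstruct_all(sample, universe, **recon_params)
        ensembles.append(
            sample_ensemble(
                candidates,
                universe,
                n_networks,
                seed=master_seed + sample.replicate_index,
                replicate_index=sample.replicate_index,
            )
        )
    return ensembles


def write_manifest(ensembles: Sequence[Ensemble], path) -> None:
    """JSON manifest of per-network candidate choices, enabling exact replay."""
    payload = [
        {
            "replicate": e.replicate_index,
            "seed": e.seed,
            "genes": list(e.universe.names),
            "n_candidates": {g: len(e.candidates[g]) for g in e.universe.names},
            "choices": [list(c) for c in e.choices],
        }
        for e in ensembles
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
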