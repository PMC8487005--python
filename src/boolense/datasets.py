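"""Synthetic single-cell expression fixtures with known ground truth.

The generator emulates the two data features the pipeline depends on:

* **Bimodal per-gene expression.**  Each binary activity is mapped to a
  continuous log-expression value through a two-component Gaussian model:
  inactive cells draw from ``N(0, noise_sd)``, active cells from
  ``N(bimodal_sep, noise_sd)``.  With a separation of several standard
  deviations the step-fit binarization recovers the generating labels.

* **Cells sampled from trajectories of a known Boolean network.**  When a
  ground-truth network is supplied, cells are states collected along
  synchronous trajectories started from uniform random states.  Cell
  identifiers encode trajectory membership and step (``i<ind>_t<traj>_s<step>``)
  so consecutive cells of a trajectory form genuine transitions; the
  trajectory structure also mimics a heterogeneous snapshot of a cell
  population when pairs are drawn at random instead.

Without a ground truth, genes are independent Bernoulli activities with
per-gene active fractions drawn from [0.3, 0.7]; optionally a block of
exactly constant genes is appended to exercise the significance filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import BooleanNetwork

__all__ = ["Fixture", "generate_fixture"]


@dataclass
class Fixture:
    """Per-individual expression matrices plus the generating truth."""

    expression: dict[str, pd.DataFrame]  # individual -> genes x cells, continuous
    binary_truth: dict[str, pd.DataFrame]  # individual -> genes x cells, 0/1
    ground_truth: BooleanNetwork | None
    gene_names: tuple[str, ...]

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(self.expression)


def generate_fixture(
    n_genes: int,
    n_cells: int,
    n_individuals: int = 1,
    ground_truth: BooleanNetwork | None = None,
    bimodal_sep: float = 6.0,
    noise_sd: float = 1.0,
    trajectory_length: int = 8,
    n_constant_genes: int = 0,
    seed: int = 0,
) -> Fixture:
    """Generate per-individual expression matrices (and the binary truth).

    With a ground truth, ``n_genes`` must match the network size and cells
    are trajectory states (``trajectory_length`` states per random start,
    concatenated until ``n_cells`` cells exist).  ``n_constant_genes``
    appends genes with exactly constant expression, which cannot binarize
    significantly.
    """
    if n_genes < 2 or n_cells < 2:
        raise ValueError("need at least two genes and two cells")
    if ground_truth is not None and ground_truth.n != n_genes:
        raise ValueError(
            f"ground truth has {ground_truth.n} genes, expected {n_genes}"
        )
    rng = np.random.default_rng(seed)
    if ground_truth is not None:
        genes = list(ground_truth.universe.names)
    else:
        genes = [f"g{i}" for i in range(n_genes)]
    genes += [f"const{i}" for i in range(n_constant_genes)]

    expression: dict[str, pd.DataFrame] = {}
    binary_truth: dict[str, pd.DataFrame] = {}
    for ind_idx in range(n_individuals):
        individual = f"ind{ind_idx}"
        if ground_truth is not None:
            bits_cols = []
            cell_ids = []
            traj = 0
            while len(bits_cols) < n_cells:
                state = rng.integers(0, 2, size=n_genes).astype(np.uint8)
                for step_idx in range(trajectory_length):
                    if len(bits_cols) >= n_cells:
                        break
                    bits_cols.append(state.copy())
                    cell_ids.append(f"i{ind_idx}_t{traj}_s{step_idx}")
                    state = ground_truth.step(state)
                traj += 1
            bits = np.array(bits_cols, dtype=np.uint8).T  # genes x cells
        else:
            fractions = rng.uniform(0.3, 0.7, size=n_genes)
            bits = (rng.random((n_genes, n_cells)) < fractions[:, None]).astype(
                np.uint8
            )
            cell_ids = [f"i{ind_idx}_c{j}" for j in range(n_cells)]
        values = rng.normal(bits * bimodal_sep, noise_sd)
        if n_constant_genes:
            const_rows = np.repeat(
                rng.uniform(0.5, 2.0, size=(n_constant_genes, 1)), n_cells, axis=1
            )
            values = np.vstack([values, const_rows])
            bits = np.vstack(
                [bits, np.zeros((n_constant_genes, n_cells), dtype=np.uint8)]
            )
        expression[individual] = pd.DataFrame(values, index=genes, columns=cell_ids)
        binary_truth[individual] = pd.DataFrame(bits, index=genes, columns=cell_ids)
    return Fixture(
        expression=expression,
        binary_truth=binary_truth,
        ground_truth=ground_truth,
        gene_names=tuple(genes),
    )
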