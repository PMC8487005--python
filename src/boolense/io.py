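"""File formats: expression matrices, binary calls, edge tables, reports."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .binarize import BinaryMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "write_binary_matrix",
    "read_binary_matrix",
    "read_gene_list",
    "read_reference_edges",
]


def read_expression(
    path,
    genes_path=None,
    cells_path=None,
    gene_subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Load a genes x cells expression matrix.

    ``.tsv``/``.csv`` files carry gene names in the first column and cell
    identifiers in the header.  ``.mtx`` (MatrixMarket triplet) files need
    ``genes_path``/``cells_path`` sidecars (one identifier per line);
    sidecars default to ``<stem>.genes.txt`` / ``<stem>.cells.txt`` next to
    the matrix.  Missing values are refused, not imputed.  ``gene_subset``
    restricts rows (e.g. a pathway gene list), keeping the subset order.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        genes_path = Path(genes_path) if genes_path else path.with_suffix("").with_suffix(".genes.txt")
        cells_path = Path(cells_path) if cells_path else path.with_suffix("").with_suffix(".cells.txt")
        raw = mmread(path)
        matrix = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
        genes = read_gene_list(genes_path)
        cells = read_gene_list(cells_path)
        frame = pd.DataFrame(matrix, index=genes, columns=cells)
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, index_col=0)
        frame.index = frame.index.astype(str)
    if frame.isna().to_numpy().any():
        raise ValueError(f"{path} contains missing values; imputation is refused")
    if gene_subset is not None:
        subset = [g for g in gene_subset if g in frame.index]
        if not subset:
            raise ValueError("gene subset has no overlap with the matrix")
        frame = frame.loc[subset]
    return frame


def write_expression(frame: pd.DataFrame, path) -> None:
    """Write a genes x cells matrix as TSV/CSV or MatrixMarket with sidecars."""
    path = Path(path)
    if path.suffix == ".mtx":
        mmwrite(path, csr_matrix(frame.to_numpy()))
        genes_path = path.with_suffix("").with_suffix(".genes.txt")
        cells_path = path.with_suffix("").with_suffix(".cells.txt")
        genes_path.write_text("\n".join(map(str, frame.index)) + "\n")
        cells_path.write_text("\n".join(map(str, frame.columns)) + "\n")
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        frame.to_csv(path, sep=sep)


def write_binary_matrix(result: BinaryMatrix, calls_path, stats_path) -> None:
    """0/1 calls TSV plus the per-gene stats TSV (threshold, p, q, retained)."""
    result.binary.to_csv(calls_path, sep="\t")
    result.stats.to_csv(stats_path, sep="\t")


def read_binary_matrix(calls_path, stats_path=None) -> BinaryMatrix:
    binary = pd.read_csv(calls_path, sep="\t", index_col=0)
    binary.index = binary.index.astype(str)
    if not binary.isin([0, 1]).to_numpy().all():
        raise ValueError("binary matrix must contain only 0/1 values")
    if stats_path is not None:
        stats = pd.read_csv(stats_path, sep="\t", index_col=0)
        stats.index = stats.index.astype(str)
    else:
        stats = pd.DataFrame(
            {
                "threshold": np.nan,
                "p": np.nan,
                "q": np.nan,
                "retained": True,
            },
            index=binary.index,
        )
    return BinaryMatrix(binary=binary.astype(np.uint8), stats=stats)


def read_gene_list(path) -> list[str]:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_reference_edges(path, score_cutoff: float | None = None) -> list[tuple[str, str]]:
    """Load a reference interaction table: ``geneA<TAB>geneB[<TAB>score]``.

    Stands in for an offline export of a protein-interaction database.
    With ``score_cutoff`` set, rows whose score column falls below the
    cutoff are dropped (rows without a score are kept).
    """
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed edge line: {line!r}")
        if score_cutoff is not None and len(parts) >= 3:
            if float(parts[2]) < score_cutoff:
                continue
        edges.append((parts[0], parts[1]))
    return edges
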