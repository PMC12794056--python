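"""Pseudobulk counts-per-million aggregation of labelled single-nucleus counts.

For every (cell type, individual) pair, raw counts are summed over the
pair's cells into one pseudobulk profile and normalized to counts per
million: ``cpm[g] = 1e6 * sum_counts[g] / sum(total counts)``. Pairs with
fewer than ``min_cells`` cells are omitted and reported. Aggregation happens
on raw counts — never on per-cell CPM — so pooling two individuals'
cells and re-aggregating is count-weighted by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError


@dataclass
class LabelledCountMatrix:
    """Genes x cells raw counts with per-cell cell-type and individual labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_type_labels: list[str]
    individual_labels: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise DegenerateInputError(f"counts must be 2-D genes x cells, got {c.shape}")
        n_genes, n_cells = c.shape
        if len(self.gene_ids) != n_genes:
            raise DegenerateInputError("gene_ids length != number of rows")
        if len(self.cell_type_labels) != n_cells or len(self.individual_labels) != n_cells:
            raise DegenerateInputError("label vectors must match the number of cells")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise DegenerateInputError("counts must be non-negative integers")
        self.counts = c.astype(np.int64)


@dataclass
class PseudobulkCPM:
    """Genes x (cell type, individual) CPM matrix plus bookkeeping."""

    matrix: pd.DataFrame  # columns: MultiIndex (cell_type, individual)
    group_sizes: pd.Series  # cells per emitted pair
    dropped: list[tuple[str, str]] = field(default_factory=list)  # below min_cells
    zero_library: list[tuple[str, str]] = field(default_factory=list)


def pseudobulk_cpm(m: LabelledCountMatrix, min_cells: int = 1) -> PseudobulkCPM:
    """Sum raw counts per (cell type, individual) pair and normalize to CPM."""
    if min_cells < 1:
        raise ValueError(f"min_cells must be >= 1, got {min_cells}")
    labels = pd.MultiIndex.from_arrays(
        [m.cell_type_labels, m.individual_labels], names=["cell_type", "individual"]
    )
    cells = pd.DataFrame(m.counts.T, index=labels)
    sums = cells.groupby(level=["cell_type", "individual"], sort=True).sum()
    sizes = cells.groupby(level=["cell_type", "individual"], sort=True).size()

    keep = sizes >= min_cells
    dropped = [tuple(ix) for ix in sizes.index[~keep]]
    if not keep.any():
        raise DegenerateInputError(
            f"all {len(sizes)} (cell type, individual) pairs have < {min_cells} cells"
        )
    sums = sums[keep.to_numpy()]
    sizes = sizes[keep]

    libsize = sums.sum(axis=1)
    zero_lib = [tuple(ix) for ix in libsize.index[libsize == 0]]
    nonzero = libsize > 0
    cpm = 1e6 * sums[nonzero.to_numpy()].div(libsize[nonzero], axis=0)

    matrix = cpm.T  # genes x pairs
    matrix.index = pd.Index(m.gene_ids, name="gene")
    return PseudobulkCPM(
        matrix=matrix,
        group_sizes=sizes[nonzero],
        dropped=dropped,
        zero_library=zero_lib,
    )


def read_dense_tsv(counts_path, cell_type_col="cell_type", individual_col="individual",
                   labels_path=None) -> LabelledCountMatrix:
    """Read a small dense genes x cells TSV plus a per-cell label TSV.

    The counts file has gene ids in the first column and cell barcodes as
    the header; the labels file has one row per cell (same order or indexed
    by barcode) with cell-type and individual columns.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)
    labels = labels.reindex(counts.columns)
    if labels[cell_type_col].isna().any() or labels[individual_col].isna().any():
        raise DegenerateInputError("labels file does not cover every cell in the counts file")
    return LabelledCountMatrix(
        counts=counts.to_numpy(),
        gene_ids=[str(g) for g in counts.index],
        cell_type_labels=[str(v) for v in labels[cell_type_col]],
        individual_labels=[str(v) for v in labels[individual_col]],
    )


def read_mtx(mtx_path, genes_path, labels_path, cell_type_col="cell_type",
             individual_col="individual") -> LabelledCountMatrix:
    """Read an MTX triplet (genes x cells) with a gene list and per-cell labels."""
    from scipy.io import mmread

    counts = np.asarray(mmread(mtx_path).todense())
    gene_ids = [line.strip() for line in open(genes_path) if line.strip()]
    labels = pd.read_csv(labels_path, sep="\t")
    return LabelledCountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_type_labels=[str(v) for v in labels[cell_type_col]],
        individual_labels=[str(v) for v in labels[individual_col]],
    )
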