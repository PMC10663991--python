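"""Per-cell quality control metrics and filters.

Three standard metrics are computed per cell: the number of expressed genes,
the library size (total reads) and the percentage of reads mapped to
mitochondrial genes (symbols starting with ``mt-`` in mouse). Damaged or
dying cells leak cytoplasmic RNA and show high mitochondrial content;
droplets capturing two cells (doublets) show unusually many genes.

All three QC thresholds are applied as strict inequalities
(``min_genes < n < max_genes`` and ``mito_pct < max_mito``), i.e. a cell
sitting exactly on a threshold is removed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tenx_io import CellCounts

__all__ = ["compute_qc", "basic_filter", "qc_filter"]


def compute_qc(counts: CellCounts, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Compute per-cell QC metrics.

    Returns a DataFrame aligned with ``counts.cells`` with columns
    ``n_expressed_genes``, ``lib_size`` and ``mito_pct`` (0-100; defined as
    0 for an empty cell).
    """
    mat = counts.counts.tocsc()
    n_expressed = np.asarray((mat > 0).sum(axis=0)).ravel().astype(np.int64)
    lib_size = np.asarray(mat.sum(axis=0)).ravel().astype(np.int64)
    mito_mask = counts.genes["symbol"].str.startswith(mito_prefix).to_numpy()
    if not mito_mask.any():
        warnings.warn(
            f"no gene symbol starts with {mito_prefix!r}; mito_pct set to 0",
            stacklevel=2,
        )
        mito_reads = np.zeros_like(lib_size)
    else:
        mito_reads = np.asarray(mat[mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_pct = np.where(lib_size > 0, 100.0 * mito_reads / lib_size, 0.0)
    return pd.DataFrame(
        {
            "barcode": counts.cells["barcode"].to_numpy(),
            "sample": counts.cells["sample"].to_numpy(),
            "n_expressed_genes": n_expressed,
            "lib_size": lib_size,
            "mito_pct": mito_pct,
        }
    )


def basic_filter(
    counts: CellCounts, min_cells: int = 3, min_features: int = 200
) -> CellCounts:
    """Remove rarely expressed genes, then sparsely covered cells.

    Genes are kept iff expressed (count > 0) in at least ``min_cells``
    cells; cells are kept iff they express at least ``min_features`` of the
    *retained* genes. The gene filter runs first, matching the common
    single-cell object-construction convention.
    """
    mat = counts.counts
    gene_ncells = np.asarray((mat > 0).sum(axis=1)).ravel()
    out = counts.subset_genes(gene_ncells >= min_cells)
    cell_ngenes = np.asarray((out.counts > 0).sum(axis=0)).ravel()
    keep_cells = cell_ngenes >= min_features
    if not keep_cells.any():
        raise ValueError("basic_filter removed every cell")
    return out.subset_cells(keep_cells)


def qc_filter(
    counts: CellCounts,
    metrics: pd.DataFrame,
    min_genes: int = 500,
    max_genes: "int | dict[str, int]" = 6000,
    max_mito: float = 10.0,
    doublet_flag: "pd.Series | np.ndarray | None" = None,
) -> CellCounts:
    """Drop low-quality cells by strict thresholding of the QC metrics.

    A cell is kept iff ``min_genes < n_expressed_genes < max_genes[sample]``
    and ``mito_pct < max_mito`` and, if a doublet flag is supplied, the flag
    equals ``"singlet"``. ``max_genes`` can be a single integer or a map
    from sample name to its threshold (the upper bound is chosen per sample
    from the distribution of expressed genes).
    """
    metrics = metrics.set_index("barcode").loc[counts.cells["barcode"]]
    n = metrics["n_expressed_genes"].to_numpy()
    mito = metrics["mito_pct"].to_numpy()
    samples = counts.cells["sample"].to_numpy()
    if isinstance(max_genes, dict):
        missing = set(samples) - set(max_genes)
        if missing:
            raise ValueError(f"no max_genes entry for sample(s): {sorted(missing)}")
        upper = np.array([max_genes[s] for s in samples])
    else:
        upper = np.full(len(samples), int(max_genes))
    keep = (n > min_genes) & (n < upper) & (mito < max_mito)
    if doublet_flag is not None:
        flags = np.asarray(doublet_flag, dtype=object)
        if len(flags) != len(samples):
            raise ValueError("doublet_flag length does not match number of cells")
        keep &= flags == "singlet"
    if not keep.any():
        raise ValueError("qc_filter removed every cell")
    return counts.subset_cells(keep)
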