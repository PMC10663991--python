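"""Reading and merging 10x-style sparse count triplets.

A 10x Genomics cellranger run emits three files per sample: a MatrixMarket
coordinate matrix (genes x cells, 1-based indices on disk), a barcodes TSV
and a features/genes TSV. Indices are converted to 0-based internally; this
is the only place the on-disk convention appears.

Feature files come in two dialects: the older two-column (ensembl id,
symbol) and the newer three-column (id, symbol, type) form. Both are
accepted and any extra columns are ignored, so samples processed with
different cellranger reference builds can be mixed.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CellCounts",
    "FormatError",
    "read_mtx_triplet",
    "merge_samples",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class CellCounts:
    """Sparse nonnegative integer gene x cell matrix with metadata.

    Attributes
    ----------
    counts : scipy.sparse.csc_matrix
        genes x cells, nonnegative integers.
    genes : pandas.DataFrame
        Columns ``ensembl_id``, ``symbol`` and optionally ``entrez_id``.
        Symbols are unique after de-duplication.
    cells : pandas.DataFrame
        Columns ``barcode`` (globally unique) and ``sample``.
    """

    counts: sp.csc_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative entries in count matrix")
        dup = self.cells.duplicated(subset=["sample", "barcode"])
        if dup.any():
            raise FormatError(
                f"{int(dup.sum())} duplicate (sample, barcode) pairs"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, mask_or_idx) -> "CellCounts":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellCounts(
            self.counts[idx, :],
            self.genes.iloc[idx].reset_index(drop=True),
            self.cells.copy(),
        )

    def subset_cells(self, mask_or_idx) -> "CellCounts":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellCounts(
            self.counts[:, idx],
            self.genes.copy(),
            self.cells.iloc[idx].reset_index(drop=True),
        )


def _open_maybe_gzip(path) -> io.BufferedReader:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rb")
    return open(path, "rb")


def _read_tsv(path, n_min_cols: int = 1) -> pd.DataFrame:
    with _open_maybe_gzip(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    if df.shape[1] < n_min_cols:
        raise FormatError(
            f"{path}: expected at least {n_min_cols} columns, found {df.shape[1]}"
        )
    return df


def read_mtx_triplet(
    matrix_path,
    barcodes_path,
    features_path,
    sample_label: str,
    deduplicate_symbols: bool = True,
) -> CellCounts:
    """Read one sample's cellranger triplet into a :class:`CellCounts`.

    Barcodes are prefixed with ``sample_label + "-"`` so they stay unique
    after merging several samples. Genes with a duplicated symbol keep only
    their first occurrence (matching the usual single-cell convention of
    keying genes on symbol).
    """
    with _open_maybe_gzip(matrix_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # malformed MatrixMarket header/body
            raise FormatError(f"{matrix_path}: not a valid MatrixMarket file: {exc}")
    mat = sp.csc_matrix(mat)
    if mat.nnz and not np.issubdtype(mat.dtype, np.integer):
        if np.any(mat.data != np.round(mat.data)):
            raise FormatError(f"{matrix_path}: non-integer entries in count matrix")
        mat = mat.astype(np.int64)

    barcodes = _read_tsv(barcodes_path, 1)
    features = _read_tsv(features_path, 2)
    if mat.shape[0] != len(features):
        raise FormatError(
            f"matrix has {mat.shape[0]} rows but features file has {len(features)}"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix has {mat.shape[1]} columns but barcodes file has {len(barcodes)}"
        )

    genes = pd.DataFrame(
        {"ensembl_id": features.iloc[:, 0], "symbol": features.iloc[:, 1]}
    )
    if genes["symbol"].isna().any() or (genes["symbol"] == "").any():
        raise FormatError(f"{features_path}: empty gene symbols")
    cells = pd.DataFrame(
        {
            "barcode": sample_label + "-" + barcodes.iloc[:, 0],
            "sample": sample_label,
        }
    )
    out = CellCounts(mat, genes, cells)
    if deduplicate_symbols:
        keep = ~genes["symbol"].duplicated(keep="first").to_numpy()
        if not keep.all():
            out = out.subset_genes(keep)
    return out


def merge_samples(objects: list[CellCounts]) -> CellCounts:
    """Merge per-sample objects on the intersection of gene symbols.

    The merged gene order is the first object's order restricted to the
    symbols common to every object. Columns are concatenated in input order;
    each retained gene's per-cell counts are preserved exactly.
    """
    if not objects:
        raise ValueError("merge_samples requires at least one CellCounts")
    if len(objects) == 1:
        obj = objects[0]
        return CellCounts(obj.counts.copy(), obj.genes.copy(), obj.cells.copy())

    symbol_sets = [set(o.genes["symbol"]) for o in objects]
    common = set.intersection(*symbol_sets)
    if not common:
        for i, si in enumerate(symbol_sets):
            for j in range(i + 1, len(symbol_sets)):
                if not si & symbol_sets[j]:
                    raise ValueError(
                        f"empty gene intersection between objects {i} and {j}"
                    )
        raise ValueError("empty gene intersection across objects")

    first = objects[0]
    order = [s for s in dict.fromkeys(first.genes["symbol"]) if s in common]
    pieces = []
    for o in objects:
        # first occurrence per symbol (inputs are expected de-duplicated,
        # but brute-force against duplicates anyway)
        pos = {}
        for i, s in enumerate(o.genes["symbol"]):
            if s not in pos:
                pos[s] = i
        idx = np.array([pos[s] for s in order])
        pieces.append(o.counts[idx, :])
    counts = sp.hstack(pieces, format="csc")
    gpos = {}
    for i, s in enumerate(first.genes["symbol"]):
        if s not in gpos:
            gpos[s] = i
    genes = first.genes.iloc[[gpos[s] for s in order]].reset_index(drop=True)
    cells = pd.concat([o.cells for o in objects], ignore_index=True)
    return CellCounts(counts, genes, cells)


def write_table(rows, path) -> None:
    """Write a DataFrame (or list of dicts) as a UTF-8 TSV with header.

    Column order follows the DataFrame / first row and is therefore stable
    across runs on identical input.
    """
    if not isinstance(rows, pd.DataFrame):
        if not rows:
            raise ValueError("write_table requires non-empty rows")
        rows = pd.DataFrame(rows)
    if rows.shape[0] == 0:
        raise ValueError("write_table requires non-empty rows")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
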