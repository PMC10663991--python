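"""Pseudo-bulk construction, filtering, TMM normalization and MDS.

Single cells sharing a (sample, cluster) combination are summed into one
pseudo-bulk profile, turning a sparse cell-level matrix into a small count
matrix amenable to bulk RNA-seq statistics with replicate-level variance.
The mean pseudotime of the member cells serves as the profile's pseudotime.

Normalization follows the trimmed-mean-of-M-values (TMM) scheme: per-sample
scaling factors from a doubly trimmed, precision-weighted mean of gene-wise
log2 ratios against a reference sample, rescaled to have geometric mean 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .tenx_io import CellCounts

__all__ = [
    "PseudobulkSet",
    "aggregate",
    "sort_by_pseudotime",
    "filter_small",
    "filter_genes",
    "tmm_factors",
    "normalize",
    "log_cpm",
    "mds_leading_logfc",
    "composition_table",
]


@dataclass
class PseudobulkSet:
    """Gene x pseudo-bulk count matrix with sample metadata.

    ``samples`` carries one row per pseudo-bulk profile with columns
    ``group`` (originating biological sample / developmental stage),
    ``cluster``, ``pseudotime`` (mean of member cells), ``cell_number``,
    ``lib_size`` (column sum) and ``norm_factor`` (TMM, default 1).
    """

    counts: np.ndarray  # genes x samples, integer
    genes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match gene/sample metadata")
        if "lib_size" not in self.samples.columns:
            self.samples = self.samples.assign(lib_size=self.counts.sum(axis=0))
        if "norm_factor" not in self.samples.columns:
            self.samples = self.samples.assign(norm_factor=1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def sample_names(self) -> pd.Index:
        return self.samples.index

    def effective_lib_size(self) -> np.ndarray:
        return (
            self.samples["lib_size"].to_numpy(float)
            * self.samples["norm_factor"].to_numpy(float)
        )

    def subset_genes(self, mask_or_idx, recompute_lib_sizes: bool = False):
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        counts = self.counts[idx, :]
        samples = self.samples.copy()
        if recompute_lib_sizes:
            samples["lib_size"] = counts.sum(axis=0)
        return PseudobulkSet(counts, self.genes.iloc[idx].reset_index(drop=True), samples)

    def subset_samples(self, mask_or_idx):
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return PseudobulkSet(
            self.counts[:, idx], self.genes.copy(), self.samples.iloc[idx].copy()
        )


def aggregate(
    counts: CellCounts, annot: pd.DataFrame, pseudotime_stat: str = "mean"
) -> PseudobulkSet:
    """Sum cell counts into one profile per (sample, cluster) combination.

    ``annot`` must have columns ``barcode``, ``sample``, ``cluster``,
    ``pseudotime``; only annotated cells enter the aggregation (the count
    matrix is subset to the annotated barcodes first). Profiles are named
    ``<sample>_C<cluster>``. Every annotated cell must have finite
    pseudotime: cells unreachable on the trajectory graph carry infinite
    pseudotime and must be excluded by the caller, this function refuses
    them rather than silently dropping data.
    """
    required = {"barcode", "sample", "cluster", "pseudotime"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"annotation is missing columns: {sorted(missing)}")
    pt = annot["pseudotime"].to_numpy(float)
    n_bad = int((~np.isfinite(pt)).sum())
    if n_bad:
        raise ValueError(
            f"{n_bad} annotated cells have non-finite pseudotime; "
            "filter them out before aggregation"
        )
    bc_to_col = pd.Series(
        np.arange(len(counts.cells)), index=counts.cells["barcode"]
    )
    unknown = ~annot["barcode"].isin(bc_to_col.index)
    if unknown.any():
        raise ValueError(
            f"{int(unknown.sum())} annotated barcodes absent from the count matrix"
        )
    cols = bc_to_col.loc[annot["barcode"]].to_numpy()

    key = annot["sample"].astype(str) + "_C" + annot["cluster"].astype(str)
    # stable order of first appearance, then membership codes
    names = pd.unique(key)
    code = pd.Categorical(key, categories=names).codes

    mat = counts.counts.tocsc()[:, cols]
    indicator = sp.csr_matrix(
        (np.ones(len(code)), (np.arange(len(code)), code)),
        shape=(len(code), len(names)),
    )
    agg = np.asarray((mat @ indicator).todense()).astype(np.int64)

    if pseudotime_stat == "mean":
        pt_agg = pd.Series(pt).groupby(code).mean()
    elif pseudotime_stat == "median":
        pt_agg = pd.Series(pt).groupby(code).median()
    else:
        raise ValueError("pseudotime_stat must be 'mean' or 'median'")
    cell_number = pd.Series(1, index=range(len(code))).groupby(code).sum()
    group = annot["sample"].astype(str).groupby(code).first()
    cluster = annot["cluster"].astype(str).groupby(code).first()

    samples = pd.DataFrame(
        {
            "group": group.to_numpy(),
            "cluster": cluster.to_numpy(),
            "pseudotime": pt_agg.to_numpy(),
            "cell_number": cell_number.to_numpy(np.int64),
        },
        index=pd.Index(names, name="sample"),
    )
    return PseudobulkSet(agg, counts.genes.copy(), samples)


def sort_by_pseudotime(pb: PseudobulkSet) -> PseudobulkSet:
    """Order profiles by ascending pseudotime (stable for ties)."""
    order = np.argsort(pb.samples["pseudotime"].to_numpy(), kind="stable")
    return pb.subset_samples(order)


def filter_small(pb: PseudobulkSet, min_cells: int = 30) -> PseudobulkSet:
    """Drop pseudo-bulk profiles built from too few cells.

    Keeps profiles with ``cell_number`` strictly greater than ``min_cells``
    (so a profile with exactly 30 cells is removed at the default).
    """
    keep = pb.samples["cell_number"].to_numpy() > min_cells
    if not keep.any():
        raise ValueError("filter_small removed every pseudo-bulk sample")
    return pb.subset_samples(keep)


def filter_genes(
    pb: PseudobulkSet,
    min_count: float = 10,
    min_total: float = 15,
    group_sizes: "dict | None" = None,
    large_n: int = 10,
    min_prop: float = 0.7,
) -> PseudobulkSet:
    """Keep genes with worthwhile counts for modelling.

    A gene is kept iff its CPM exceeds ``c = min_count / median(lib_size) *
    1e6`` in at least ``k`` samples, where ``k`` is the size of the smallest
    design group (capped via ``large_n``/``min_prop`` for very large
    groups), and its total count is at least ``min_total``. Library sizes
    are recomputed on the retained genes.
    """
    lib = pb.samples["lib_size"].to_numpy(float)
    if group_sizes is None:
        group_sizes = pb.samples["group"].value_counts().to_dict()
    sizes = [v for v in group_sizes.values() if v > 0]
    min_n = min(sizes) if sizes else pb.shape[1]
    if min_n > large_n:
        min_n = large_n + (min_n - large_n) * min_prop
    median_lib = np.median(lib)
    cpm_cutoff = min_count / median_lib * 1e6
    cpm = pb.counts / lib * 1e6
    tol = 1e-14
    keep = (cpm >= cpm_cutoff).sum(axis=1) >= min_n - tol
    keep &= pb.counts.sum(axis=1) >= min_total - tol
    if not keep.any():
        warnings.warn("filter_genes kept zero genes", stacklevel=2)
    return pb.subset_genes(keep, recompute_lib_sizes=True)


def _quantile75_fraction(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    q = np.quantile(counts, 0.75, axis=0, method="linear")
    return q / lib


def tmm_factors(
    pb: PseudobulkSet,
    logratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
    ref_column: "int | None" = None,
    weighted: bool = True,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors.

    The reference is the sample whose 75th-percentile count fraction is
    closest to the mean of those fractions. For every other sample, genes
    with a zero count in either member of the pair are excluded and a
    weighted mean of the gene-wise log2 count-fraction ratios (M values) is
    taken after double trimming: ``logratio_trim`` on each tail of M and
    ``abs_expr_trim`` on each tail of average abundance (A). Weights are
    inverse asymptotic binomial variances (``weighted=False`` gives the
    plain trimmed mean, which is exactly invariant to uniform depth
    scaling; the weighted default is invariant only up to the
    count-dependent precision weights). Factors are rescaled so their
    geometric mean is 1.
    """
    counts = np.asarray(pb.counts, float)
    lib = pb.samples["lib_size"].to_numpy(float)
    if (counts.sum(axis=0) == 0).any():
        bad = list(pb.sample_names[counts.sum(axis=0) == 0])
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    if counts.shape[1] < 2:
        return np.ones(counts.shape[1])
    if ref_column is None:
        f75 = _quantile75_fraction(counts, lib)
        ref_column = int(np.argmin(np.abs(f75 - f75.mean())))

    ref = counts[:, ref_column]
    nR = lib[ref_column]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        obs = counts[:, j]
        nO = lib[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            logR = np.log2((obs / nO) / (ref / nR))
            absE = (np.log2(obs / nO) + np.log2(ref / nR)) / 2
            v = (nO - obs) / nO / obs + (nR - ref) / nR / ref
        fin = np.isfinite(logR) & np.isfinite(absE) & (absE > -1e10)
        logR, absE, v = logR[fin], absE[fin], v[fin]
        if len(logR) == 0 or np.max(np.abs(logR)) < 1e-6:
            factors[j] = 1.0
            continue
        n = len(logR)
        loL = np.floor(n * logratio_trim) + 1
        hiL = n - np.floor(n * logratio_trim)
        loS = np.floor(n * abs_expr_trim) + 1
        hiS = n - np.floor(n * abs_expr_trim)
        rR = rankdata(logR, method="average")
        rS = rankdata(absE, method="average")
        keep = (rR >= loL) & (rR <= hiL) & (rS >= loS) & (rS <= hiS)
        if not keep.any():
            factors[j] = 1.0
            continue
        if weighted:
            f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
        else:
            f = np.mean(logR[keep])
        if not np.isfinite(f):
            f = 0.0
        factors[j] = 2.0**f
    # geometric mean 1
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def normalize(pb: PseudobulkSet, **kwargs) -> PseudobulkSet:
    """Return a copy of ``pb`` with TMM ``norm_factor`` filled in."""
    out = pb.subset_samples(np.arange(pb.shape[1]))
    out.samples["norm_factor"] = tmm_factors(pb, **kwargs)
    return out


def log_cpm(pb: PseudobulkSet, prior_count: float = 2.0) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes.

    The prior count is scaled proportionally to each sample's effective
    library size (mean-prior convention), so an all-zero gene maps to the
    same value in every sample when depths are equal:
    ``log2((y + p_j) / (L_j + 2 p_j) * 1e6)`` with
    ``p_j = prior_count * L_j / mean(L)``.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    L = pb.effective_lib_size()
    pr = prior_count * L / L.mean()
    vals = np.log2((pb.counts + pr) / (L + 2 * pr) * 1e6)
    return pd.DataFrame(
        vals, index=pb.genes["symbol"].to_numpy(), columns=pb.sample_names
    )


def mds_leading_logfc(
    logcpm: pd.DataFrame, top: int = 500, ndim: int = 2
) -> pd.DataFrame:
    """Classical MDS on leading-log-fold-change distances between samples.

    The distance between two samples is the root-mean-square of the ``top``
    largest absolute log-CPM differences for that pair; coordinates come
    from Torgerson double-centring and eigendecomposition.
    """
    X = np.asarray(logcpm, float)
    G, S = X.shape
    if top > G:
        warnings.warn(f"top={top} exceeds gene count {G}; clamping", stacklevel=2)
        top = G
    D = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            d = np.abs(X[:, i] - X[:, j])
            sel = np.sort(d)[-top:]
            D[i, j] = D[j, i] = np.sqrt(np.mean(sel**2))
    J = np.eye(S) - np.ones((S, S)) / S
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:ndim]
    coords = V[:, order] * np.sqrt(np.clip(w[order], 0, None))
    return pd.DataFrame(
        coords,
        index=logcpm.columns,
        columns=[f"dim{k+1}" for k in range(ndim)],
    )


def composition_table(annot: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-by-sample cell counts and row percentages.

    Returns ``(counts, percentages)`` where rows are samples, columns are
    clusters, and percentages are ``100 * n / row_total`` rounded to 2
    decimal places — the standard cell-composition diagnostic for comparing
    cluster proportions across developmental stages.
    """
    tab = pd.crosstab(annot["sample"], annot["cluster"])
    pct = (100 * tab.div(tab.sum(axis=1), axis=0)).round(2)
    return tab, pct
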