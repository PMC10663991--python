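"""Synthetic multi-sample single-cell data with spline-shaped pseudotime
trends, for testing every pipeline stage without external downloads.

Two generators are provided. :func:`simulate_cells` emulates the structure
of a multi-stage developmental experiment: five biological samples, cells
assigned to clusters occupying overlapping windows along a single
trajectory, negative-binomial counts with per-gene baseline abundance,
planted monotone pseudotime trends for a fraction of genes, per
gene-and-sample multiplicative effects (the nuisance the design's sample
blocking removes), mitochondrial genes, planted high-mito "dead" cells and
doublets formed by summing two parent cells. :func:`simulate_pseudobulk`
generates counts directly at the pseudo-bulk level for fast statistical
tests of the NB QL engine, including a preset reproducing the pseudo-bulk
sample table of the five-stage mouse mammary-gland epithelium example
dataset.

All randomness flows through one ``numpy`` Generator seeded from the
config, so a fixed seed gives bitwise-identical output.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .tenx_io import CellCounts

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cells",
    "simulate_pseudobulk",
    "write_triplet",
    "mammary_pseudobulk_table",
    "mammary_cell_annotation",
    "MAMMARY_STAGES",
]

# ---------------------------------------------------------------------------
# Example dataset tables: mouse mammary epithelium across five developmental
# stages (embryonic E18.5 to adult), 29 sample x cluster pseudo-bulk
# profiles ordered by mean pseudotime.
# ---------------------------------------------------------------------------

MAMMARY_STAGES = ["E18.5-epi", "P5", "Pre-puberty", "Puberty", "Adult"]

_MAMMARY_TABLE = """\
sample\tlib_size\tpseudotime\tcell_number
Pre-puberty_C1\t11886898\t4.65\t1590
Adult_C1\t9285265\t4.77\t2495
P5_C1\t2680089\t6.41\t347
Puberty_C1\t3112796\t6.48\t986
E18.5-epi_C1\t8084434\t10.16\t878
E18.5-epi_C5\t5179\t15.61\t3
P5_C5\t24491\t15.61\t3
Pre-puberty_C5\t57834\t15.61\t6
Puberty_C5\t12278\t15.61\t6
Adult_C4\t204212\t19.25\t32
E18.5-epi_C4\t11725731\t19.31\t921
P5_C4\t1917228\t19.68\t120
Puberty_C4\t1860770\t19.72\t265
Pre-puberty_C4\t289370\t22.10\t23
E18.5-epi_C3\t15806768\t28.03\t2341
Puberty_C2\t5841364\t28.62\t1535
P5_C3\t3862152\t28.94\t351
E18.5-epi_C2\t167242\t29.14\t29
Adult_C2\t8320630\t29.66\t2362
P5_C2\t347365\t29.67\t47
Pre-puberty_C2\t4625160\t30.51\t482
Puberty_C3\t63722\t31.73\t20
Pre-puberty_C3\t1432336\t32.64\t64
Adult_C3\t997670\t33.99\t171
Pre-puberty_C0\t6024872\t38.90\t381
E18.5-epi_C0\t990670\t39.64\t171
Adult_C0\t27621462\t40.44\t4281
P5_C0\t3113053\t40.68\t272
Puberty_C0\t8806924\t41.09\t1894
"""


def mammary_pseudobulk_table() -> pd.DataFrame:
    """Pseudo-bulk sample table of the mammary-development example data.

    One row per (stage, cluster) pseudo-bulk profile with its library size,
    mean pseudotime and number of member cells; index is the profile name
    ``<stage>_C<cluster>``. Stages run from embryonic (E18.5) to adult.
    """
    df = pd.read_csv(StringIO(_MAMMARY_TABLE), sep="\t").set_index("sample")
    df["group"] = [name.rsplit("_C", 1)[0] for name in df.index]
    df["cluster"] = [name.rsplit("_C", 1)[1] for name in df.index]
    df["group"] = pd.Categorical(df["group"], categories=MAMMARY_STAGES)
    return df


def mammary_cell_annotation() -> pd.DataFrame:
    """Synthetic per-cell expansion of the mammary pseudo-bulk table.

    Each pseudo-bulk row is expanded into ``cell_number`` annotation rows
    (synthetic barcodes, per-cell pseudotime set to the profile mean), so
    cell-level operations — composition tables, aggregation — reproduce the
    profile-level table exactly. This is a synthetic stand-in for the real
    per-cell annotation, which requires the original GEO data.
    """
    tab = mammary_pseudobulk_table()
    rows = []
    for name, row in tab.iterrows():
        n = int(row["cell_number"])
        rows.append(
            pd.DataFrame(
                {
                    "barcode": [f"{name}-cell{i}" for i in range(n)],
                    "sample": row["group"],
                    "cluster": row["cluster"],
                    "pseudotime": row["pseudotime"],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Cell-level simulator
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-condition parameters of the cell-level simulator.

    Defaults emulate a five-stage, five-cluster single-trajectory design
    with NB noise; see the methods documentation for the reasoning behind
    each value. ``seed`` is mandatory for reproducibility.
    """

    seed: int
    n_samples: int = 5
    n_clusters: int = 5
    cells_per_cluster: int = 80
    n_genes: int = 2000
    frac_trend: float = 0.10
    effect_size: float = 2.5          # ln-scale amplitude across the trajectory
    trend_shapes: tuple = ("linear", "sigmoid", "smoothstep")
    sample_effect_sd: float = 0.2     # ln-scale per gene-and-sample effect
    cell_dispersion: float = 0.8      # NB dispersion of single-cell counts
    dispersion_sd: float = 0.4        # lognormal spread of per-gene dispersions
    lib_size_sd: float = 0.35         # lognormal cell size factors
    target_reads: float = 5000.0      # expected reads per cell
    n_mito: int = 10
    mito_fraction: float = 0.05
    dead_rate: float = 0.03
    dead_mito_fraction: float = 0.5
    doublet_rate: float = 0.05
    total_time: float = 40.0
    window_overlap: float = 0.1       # fraction of total_time clusters overlap

    def validate(self) -> None:
        rates = {
            "frac_trend": self.frac_trend,
            "mito_fraction": self.mito_fraction,
            "dead_rate": self.dead_rate,
            "doublet_rate": self.doublet_rate,
            "window_overlap": self.window_overlap,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_samples", "n_clusters", "cells_per_cluster", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_mito > self.n_genes:
            raise ValueError("n_mito cannot exceed n_genes")


@dataclass
class SimTruth:
    """Ground truth of a simulation: per-gene trend labels and generating
    parameters, per-cell trajectory state and quality flags."""

    genes: pd.DataFrame
    cells: "pd.DataFrame | None" = None


def _trend_value(shape: str, u: np.ndarray) -> np.ndarray:
    """Monotone trend shapes on u in [0, 1], centred at 0."""
    if shape == "linear":
        return u - 0.5
    if shape == "sigmoid":
        return 1.0 / (1.0 + np.exp(-10.0 * (u - 0.5))) - 0.5
    if shape == "smoothstep":
        return u * u * (3.0 - 2.0 * u) - 0.5
    raise ValueError(f"unknown trend shape {shape!r}")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi) -> np.ndarray:
    """NB(mu, phi) via the gamma-Poisson mixture (Poisson when phi ~ 0)."""
    phi = np.broadcast_to(np.asarray(phi, float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    po = phi < 1e-12
    if po.any():
        out[po] = rng.poisson(mu[po])
    nb = ~po
    if nb.any():
        lam = rng.gamma(1.0 / phi[nb], phi[nb] * mu[nb])
        out[nb] = rng.poisson(lam)
    return out


def simulate_cells(config: SimConfig):
    """Simulate a multi-sample cell x gene experiment along one trajectory.

    Returns ``(counts, annotation, truth)`` where ``annotation`` has the
    columns the aggregation step consumes (barcode, sample, cluster,
    pseudotime, doublet) and ``truth`` records planted gene trends and cell
    states. Doublet cells are literal sums of two sampled parent cells.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes

    # --- gene-level parameters
    symbols = np.array(
        [f"mt-Sim{i+1}" for i in range(config.n_mito)]
        + [f"Gene{i+1}" for i in range(G - config.n_mito)]
    )
    is_mito = np.char.startswith(symbols.astype(str), "mt-")
    rel = np.exp(rng.normal(0.0, 1.2, size=G))
    rel[is_mito] *= (
        config.mito_fraction / max(rel[is_mito].sum(), 1e-12)
        * rel[~is_mito].sum() / max(1.0 - config.mito_fraction, 1e-12)
    )
    rel = rel / rel.sum()
    base_mean = rel * config.target_reads  # expected reads/gene/cell

    n_trend = int(round(config.frac_trend * G))
    trend_idx = rng.choice(np.flatnonzero(~is_mito), size=n_trend, replace=False)
    direction = np.ones(n_trend)
    direction[1::2] = -1.0
    shapes = np.array(
        [config.trend_shapes[i % len(config.trend_shapes)] for i in range(n_trend)]
    )
    amplitude = np.zeros(G)
    amplitude[trend_idx] = direction * config.effect_size
    shape_by_gene = np.array([""] * G, dtype=object)
    shape_by_gene[trend_idx] = shapes
    trend_label = np.array(["null"] * G, dtype=object)
    trend_label[trend_idx] = np.where(direction > 0, "up", "down")

    phi_gene = config.cell_dispersion * np.exp(
        rng.normal(0.0, config.dispersion_sd, size=G)
    )
    sample_names = [f"S{i+1}" for i in range(config.n_samples)]
    sample_effect = rng.normal(
        0.0, config.sample_effect_sd, size=(G, config.n_samples)
    )

    # --- cells
    T = config.total_time
    K = config.n_clusters
    ov = config.window_overlap * T
    counts_blocks, meta = [], []
    for si, sname in enumerate(sample_names):
        for k in range(K):
            m = config.cells_per_cluster
            lo = max(0.0, k / K * T - ov)
            hi = min(T, (k + 1) / K * T + ov)
            t_cells = rng.uniform(lo, hi, size=m)
            size = np.exp(rng.normal(0.0, config.lib_size_sd, size=m))
            dead = rng.random(m) < config.dead_rate
            u = t_cells / T
            trend_term = np.zeros((G, m))
            for shp in config.trend_shapes:
                sel = shape_by_gene == shp
                if sel.any():
                    trend_term[sel] = np.outer(
                        amplitude[sel], np.ones(m)
                    ) * _trend_value(shp, u)[None, :]
            log_mu = (
                np.log(base_mean)[:, None]
                + trend_term
                + sample_effect[:, si][:, None]
            )
            mu = np.exp(log_mu) * size[None, :]
            if dead.any():
                # boost mitochondrial content of dying cells to the target
                # fraction of total reads
                mito_tot = mu[is_mito][:, dead].sum(axis=0)
                other_tot = mu[~is_mito][:, dead].sum(axis=0)
                target = config.dead_mito_fraction
                boost = target / (1 - target) * other_tot / np.maximum(
                    mito_tot, 1e-12
                )
                mu[np.ix_(is_mito, dead)] *= boost
            cnt = _nb_sample(rng, mu, phi_gene[:, None])
            counts_blocks.append(cnt)
            meta.append(
                pd.DataFrame(
                    {
                        "sample": sname,
                        "cluster": str(k),
                        "pseudotime": t_cells,
                        "dead": dead,
                    }
                )
            )
    counts = np.concatenate(counts_blocks, axis=1)
    cells = pd.concat(meta, ignore_index=True)
    cells["doublet"] = "singlet"

    # --- doublets: sums of two sampled parents
    n_cells = counts.shape[1]
    n_dbl = int(round(config.doublet_rate * n_cells))
    if n_dbl:
        p1 = rng.integers(0, n_cells, size=n_dbl)
        p2 = rng.integers(0, n_cells, size=n_dbl)
        dbl_counts = counts[:, p1] + counts[:, p2]
        dbl_cells = pd.DataFrame(
            {
                "sample": cells["sample"].to_numpy()[p1],
                "cluster": cells["cluster"].to_numpy()[p1],
                "pseudotime": (
                    cells["pseudotime"].to_numpy()[p1]
                    + cells["pseudotime"].to_numpy()[p2]
                )
                / 2.0,
                "dead": False,
                "doublet": "doublet",
            }
        )
        counts = np.concatenate([counts, dbl_counts], axis=1)
        cells = pd.concat([cells, dbl_cells], ignore_index=True)

    cells["barcode"] = [
        f"{s}-cell{i:05d}" for i, s in enumerate(cells["sample"])
    ]
    genes = pd.DataFrame(
        {
            "ensembl_id": [f"SIMG{i+1:07d}" for i in range(G)],
            "symbol": symbols,
        }
    )
    cc = CellCounts(
        sp.csc_matrix(counts),
        genes,
        cells[["barcode", "sample"]].copy(),
    )
    annot = cells[["barcode", "sample", "cluster", "pseudotime", "doublet"]].copy()
    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "symbol": symbols,
                "trend": trend_label,
                "amplitude": amplitude,
                "shape": shape_by_gene,
                "dispersion": phi_gene,
                "base_mean": base_mean,
            }
        ),
        cells=cells[
            ["barcode", "sample", "cluster", "pseudotime", "doublet", "dead"]
        ].copy(),
    )
    return cc, annot, truth


# ---------------------------------------------------------------------------
# Pseudo-bulk-level simulator
# ---------------------------------------------------------------------------

def simulate_pseudobulk(
    n_samples: int = 22,
    n_genes: int = 2000,
    pseudotime=None,
    group_labels=None,
    lib_sizes=None,
    effect_size: float = 0.0,
    frac_trend: float = 0.1,
    phi: float = 0.2,
    group_effect_sd: float = 0.0,
    trend_shape: str = "linear",
    seed: int = 0,
):
    """Generate NB pseudo-bulk counts directly, for fast engine tests.

    ``pseudotime="mammary"`` uses the 22 retained pseudotimes, stage labels
    and library sizes of the mammary example table. With
    ``effect_size=0`` the dataset is null (pure NB noise around gene
    baselines), the setting used for type-I-error checks. Returns
    ``(PseudobulkSet, SimTruth)``.
    """
    from .pseudobulk import PseudobulkSet

    rng = np.random.default_rng(seed)
    if isinstance(pseudotime, str) and pseudotime == "mammary":
        tab = mammary_pseudobulk_table()
        tab = tab[tab["cell_number"] > 30]
        t = tab["pseudotime"].to_numpy(float)
        group_labels = tab["group"].astype(str).to_numpy()
        if lib_sizes is None:
            lib_sizes = tab["lib_size"].to_numpy(float)
        names = list(tab.index)
        n_samples = len(t)
    elif pseudotime is None:
        t = np.sort(rng.uniform(0.0, 40.0, size=n_samples))
        names = [f"PB{i+1}" for i in range(n_samples)]
    else:
        t = np.asarray(pseudotime, float)
        n_samples = len(t)
        names = [f"PB{i+1}" for i in range(n_samples)]
    if lib_sizes is None:
        lib_sizes = np.exp(rng.normal(np.log(2e6), 0.4, size=n_samples))
    lib_sizes = np.asarray(lib_sizes, float)
    if group_labels is None:
        group_labels = np.array(["G1"] * n_samples)
    group_labels = np.asarray(group_labels)

    rel = np.exp(rng.normal(0.0, 1.5, size=n_genes))
    rel = rel / rel.sum()
    n_trend = int(round(frac_trend * n_genes)) if effect_size else 0
    amplitude = np.zeros(n_genes)
    trend_label = np.array(["null"] * n_genes, dtype=object)
    if n_trend:
        idx = rng.choice(n_genes, size=n_trend, replace=False)
        direction = np.ones(n_trend)
        direction[1::2] = -1.0
        amplitude[idx] = direction * effect_size
        trend_label[idx] = np.where(direction > 0, "up", "down")

    u = (t - t.min()) / max(t.max() - t.min(), 1e-12)
    f = _trend_value(trend_shape, u)
    log_mu = np.log(rel)[:, None] + amplitude[:, None] * f[None, :]
    if group_effect_sd > 0:
        levels, codes = np.unique(group_labels, return_inverse=True)
        eff = rng.normal(0.0, group_effect_sd, size=(n_genes, len(levels)))
        log_mu = log_mu + eff[:, codes]
    # rescale so each column's expected total equals its library size
    mu = np.exp(log_mu)
    mu = mu / mu.sum(axis=0, keepdims=True) * lib_sizes[None, :]
    counts = _nb_sample(rng, mu, phi)

    samples = pd.DataFrame(
        {
            "group": group_labels,
            "cluster": "0",
            "pseudotime": t,
            "cell_number": 1000,
            "lib_size": counts.sum(axis=0),
        },
        index=pd.Index(names, name="sample"),
    )
    genes = pd.DataFrame(
        {
            "ensembl_id": [f"SIMG{i+1:07d}" for i in range(n_genes)],
            "symbol": [f"Gene{i+1}" for i in range(n_genes)],
        }
    )
    pb = PseudobulkSet(counts, genes, samples)
    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "symbol": genes["symbol"],
                "trend": trend_label,
                "amplitude": amplitude,
                "dispersion": phi,
            }
        )
    )
    return pb, truth


def write_triplet(counts: CellCounts, out_dir, gzipped: bool = True) -> dict:
    """Write a CellCounts object as a 10x-style triplet.

    Emits ``matrix.mtx[.gz]``, ``barcodes.tsv[.gz]`` and
    ``features.tsv[.gz]`` under ``out_dir``; returns the three paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""
    paths = {
        "matrix": out_dir / f"matrix.mtx{suffix}",
        "barcodes": out_dir / f"barcodes.tsv{suffix}",
        "features": out_dir / f"features.tsv{suffix}",
    }
    opener = gzip.open if gzipped else open
    with opener(paths["matrix"], "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(counts.counts))
    with opener(paths["barcodes"], "wt") as fh:
        for bc in counts.cells["barcode"]:
            fh.write(f"{bc}\n")
    with opener(paths["features"], "wt") as fh:
        for _, row in counts.genes.iterrows():
            fh.write(f"{row['ensembl_id']}\t{row['symbol']}\n")
    return paths
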