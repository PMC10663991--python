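"""End-to-end orchestration from a YAML config to an output directory.

The pipeline chains: (optional) triplet reading and merging -> cell QC ->
pseudo-bulk aggregation -> small-sample and expression filtering -> TMM ->
spline design -> NB QL fit -> F-tests and trend summaries -> optional
directional enrichment. Every artifact is written as TSV/JSON so two runs
on identical inputs are byte-identical; a manifest records the seed, the
config hash and package version. The expensive QL stage is cached by a
content hash of its inputs so different coefficient sets can be re-tested
without refitting.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_qc import basic_filter, compute_qc, qc_filter
from .enrichment import directional_ora, read_gmt
from .nbql import NBQLModel, decide_tests, top_table
from .pseudobulk import (
    aggregate,
    filter_genes,
    filter_small,
    log_cpm,
    mds_leading_logfc,
    normalize,
    sort_by_pseudotime,
)
from .spline_design import (
    build_design,
    build_raw_design,
    orthonormal_time_design,
)
from .tenx_io import merge_samples, read_mtx_triplet, write_table
from .timecourse import classify_trend, fitted_curves, heatmap_matrix

__all__ = ["RunConfig", "validate_config", "run"]

log = logging.getLogger("pseudotempo")


@dataclass
class RunConfig:
    """Validated run configuration.

    ``triplets`` maps sample name -> {matrix, barcodes, features} paths;
    ``annotation`` is the per-cell TSV (barcode, sample, cluster,
    pseudotime[, doublet]). ``max_genes`` is the per-sample upper QC
    threshold map.
    """

    annotation: str
    out_dir: str
    triplets: dict = field(default_factory=dict)
    gmt_paths: list = field(default_factory=list)
    min_genes: int = 500
    max_genes: dict = field(default_factory=dict)
    max_mito: float = 10.0
    basic_min_cells: int = 3
    basic_min_features: int = 200
    min_cells: int = 30
    min_count: float = 10.0
    min_total: float = 15.0
    spline_df: int = 3
    alpha: float = 0.05
    robust: bool = True
    group_order: list = field(default_factory=list)
    seed: int = 0
    skip_cell_qc: bool = False
    n_top_heatmap: int = 20

    def __post_init__(self) -> None:
        if self.min_cells < 0:
            raise ValueError("min_cells must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.spline_df < 1:
            raise ValueError("spline_df must be >= 1")


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are rejected."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    missing = {"annotation", "out_dir"} - set(raw)
    if missing:
        raise ValueError(f"missing required config key(s): {sorted(missing)}")
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _content_hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def run(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Writes: pseudobulk counts+samples, design matrix, dispersion (BCV) and
    QL-dispersion diagnostics, full test table, trend table, fitted curves,
    MDS coordinates, heatmap matrix, enrichment tables (one per GMT) and a
    run manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_inner(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_inner(config: RunConfig, out: Path) -> Path:
    annot = pd.read_csv(config.annotation, sep="\t")
    required = {"barcode", "sample", "cluster", "pseudotime"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"annotation is missing column(s): {sorted(missing)}")

    # ---- read counts
    objs = []
    for sample, files in config.triplets.items():
        obj = read_mtx_triplet(
            files["matrix"], files["barcodes"], files["features"], sample
        )
        log.info("read sample %s: %d genes x %d cells", sample, *obj.shape)
        objs.append(obj)
    if not objs:
        raise ValueError("config.triplets is empty: nothing to analyse")
    counts = merge_samples(objs)
    log.info("merged: %d genes x %d cells", *counts.shape)

    # ---- cell QC
    if not config.skip_cell_qc:
        qc_objs = []
        for sample in pd.unique(counts.cells["sample"]):
            sub = counts.subset_cells(
                (counts.cells["sample"] == sample).to_numpy()
            )
            n0 = sub.shape
            sub = basic_filter(
                sub, config.basic_min_cells, config.basic_min_features
            )
            metrics = compute_qc(sub)
            max_genes = config.max_genes if config.max_genes else 1 << 30
            annot_idx = annot.set_index("barcode")
            flags = None
            if "doublet" in annot.columns:
                flags = (
                    annot_idx["doublet"]
                    .reindex(sub.cells["barcode"])
                    .fillna("singlet")
                    .to_numpy()
                )
            sub = qc_filter(
                sub,
                metrics,
                min_genes=config.min_genes,
                max_genes=max_genes,
                max_mito=config.max_mito,
                doublet_flag=flags,
            )
            log.info(
                "QC %s: %s -> %s (genes x cells)", sample, n0, sub.shape
            )
            qc_objs.append(sub)
        counts = merge_samples(qc_objs)
        write_table(compute_qc(counts), out / "cell_qc_metrics.tsv")

    # ---- pseudo-bulk
    keep = annot["barcode"].isin(set(counts.cells["barcode"]))
    annot_used = annot[keep & np.isfinite(annot["pseudotime"])]
    pb = aggregate(counts, annot_used)
    log.info("aggregated: %d genes x %d pseudo-bulk samples", *pb.shape)
    pb = sort_by_pseudotime(pb)
    n_before = pb.shape[1]
    pb = filter_small(pb, config.min_cells)
    log.info(
        "small-sample filter: removed %d of %d profiles",
        n_before - pb.shape[1], n_before,
    )
    g_before = pb.shape[0]
    pb = filter_genes(pb, config.min_count, config.min_total)
    log.info("gene filter: %d -> %d genes", g_before, pb.shape[0])
    pb = normalize(pb)
    write_table(
        pd.DataFrame(
            pb.counts, index=pb.genes["symbol"], columns=pb.sample_names
        ).reset_index(names="gene"),
        out / "pseudobulk_counts.tsv",
    )
    write_table(
        pb.samples.reset_index(), out / "pseudobulk_samples.tsv"
    )

    # ---- design
    t = pb.samples["pseudotime"].to_numpy(float)
    Z, basis = orthonormal_time_design(t, df=config.spline_df)
    groups = pb.samples["group"]
    if config.group_order:
        groups = pd.Series(
            pd.Categorical(groups, categories=config.group_order),
            index=groups.index,
        )
    design = build_design(Z, groups)
    design.to_tsv(out / "design.tsv")

    # ---- model fit (cached on content hash)
    cache_key = _content_hash(pb.counts, design.values)
    cache_file = out / ".cache" / f"fit_{cache_key}.pkl"
    if cache_file.exists():
        with open(cache_file, "rb") as fh:
            res = pickle.load(fh)
        log.info("loaded cached QL fit %s", cache_key)
    else:
        model = NBQLModel.from_pseudobulk(pb, design)
        res = model.fit(robust=config.robust)
        cache_file.parent.mkdir(exist_ok=True)
        with open(cache_file, "wb") as fh:
            pickle.dump(res, fh)
    log.info("common BCV: %.3f", res.common_bcv)
    write_table(
        res.dispersion.bcv_table(pb.genes["symbol"].to_numpy()),
        out / "dispersion_bcv.tsv",
    )
    write_table(res.fit.ql_dispersion_table(), out / "ql_dispersion.tsv")

    # ---- tests
    zcols = design.time_columns
    result = res.f_test(zcols)
    write_table(
        top_table(result, None).reset_index(), out / "test_results.tsv"
    )
    counts_sig = decide_tests(result, config.alpha)
    log.info("decideTests: %s", counts_sig.to_dict())

    trend = classify_trend(result)
    trend_tab = result.assign(trend=trend)
    write_table(
        top_table(trend_tab, None).reset_index(), out / "trend_table.tsv"
    )

    # ---- curves and heatmap
    raw_design = build_raw_design(
        basis, t, groups
    )
    from .nbql import ql_fit as _ql_fit  # raw-basis fit reuses dispersions

    raw_fit = _ql_fit(pb, raw_design, res.dispersion, robust=config.robust)
    ordered = top_table(trend_tab, None)
    up = ordered[ordered["trend"] == "Up"]
    down = ordered[ordered["trend"] == "Down"]
    n_curve = min(6, len(up), len(down))
    genes_for_curves = list(up.index[:n_curve]) + list(down.index[:n_curve])
    curves = fitted_curves(raw_fit, basis, t, genes_for_curves)
    write_table(curves, out / "curves.tsv")

    lcpm = log_cpm(pb)
    k = config.n_top_heatmap
    if len(up) >= 1 and len(down) >= 1:
        hm = heatmap_matrix(lcpm, list(up.index[:k]), list(down.index[:k]))
        write_table(hm.reset_index(names="gene"), out / "heatmap_matrix.tsv")

    mds = mds_leading_logfc(lcpm)
    write_table(mds.reset_index(names="sample"), out / "mds.tsv")

    # ---- enrichment
    if config.gmt_paths:
        res_z1 = res.f_test(zcols[0])
        labels = decide_tests(res_z1, config.alpha, return_labels=True)
        universe = list(result.index)
        up_list = list(labels.index[labels == "Up"])
        down_list = list(labels.index[labels == "Down"])
        for gmt in config.gmt_paths:
            sets = read_gmt(gmt)
            ora = directional_ora(up_list, down_list, universe, sets)
            name = Path(gmt).stem
            write_table(
                ora.reset_index(), out / f"enrichment_{name}.tsv"
            )

    manifest = {
        "package": "pseudotempo",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": asdict(config),
        "n_genes": int(pb.shape[0]),
        "n_pseudobulk": int(pb.shape[1]),
        "common_bcv": float(res.common_bcv),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out
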