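import numpy as np
import pandas as pd
import pytest

from pseudotempo.pseudobulk import (
    aggregate,
    composition_table,
    filter_genes,
    filter_small,
    log_cpm,
    mds_leading_logfc,
    normalize,
    sort_by_pseudotime,
    tmm_factors,
)
from pseudotempo.trajectory_sim import (
    mammary_cell_annotation,
    mammary_pseudobulk_table,
    simulate_pseudobulk,
)


def _annot(barcodes, sample, cluster, pt):
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "sample": sample,
            "cluster": cluster,
            "pseudotime": pt,
        }
    )


class TestAggregate:
    def test_arithmetic_single_group(self, make_counts_factory):
        cc = make_counts_factory([[2, 0, 5]], ["g"], "S")
        ann = _annot(cc.cells["barcode"], "S", "0", [1.0, 2.0, 3.0])
        pb = aggregate(cc, ann)
        assert list(pb.sample_names) == ["S_C0"]
        assert pb.counts[0, 0] == 7
        assert pb.samples.loc["S_C0", "pseudotime"] == pytest.approx(2.0)
        assert pb.samples.loc["S_C0", "cell_number"] == 3

    def test_conservation_two_clusters(self, make_counts_factory):
        cc = make_counts_factory([[1, 2, 3, 4], [5, 6, 7, 8]], ["a", "b"], "S")
        ann = _annot(cc.cells["barcode"], "S", ["0", "0", "1", "1"], [1, 1, 2, 2.0])
        pb = aggregate(cc, ann)
        assert pb.shape == (2, 2)
        assert pb.counts.sum() == cc.counts.sum()

    def test_matches_brute_force_groupby(self, small_sim):
        cc, annot, _ = small_sim
        pb = aggregate(cc, annot)
        dense = pd.DataFrame(
            cc.counts.toarray(),
            columns=cc.cells["barcode"],
        )
        key = (
            annot.set_index("barcode")["sample"].astype(str)
            + "_C"
            + annot.set_index("barcode")["cluster"].astype(str)
        )
        oracle = dense.T.groupby(key.loc[dense.columns].to_numpy()).sum().T
        for name in pb.sample_names:
            assert np.array_equal(
                pb.counts[:, list(pb.sample_names).index(name)],
                oracle[name].to_numpy(),
            )

    def test_refuses_non_finite_pseudotime(self, make_counts_factory):
        cc = make_counts_factory([[1, 1]], ["g"], "S")
        ann = _annot(cc.cells["barcode"], "S", "0", [1.0, np.inf])
        with pytest.raises(ValueError, match="1 annotated cells"):
            aggregate(cc, ann)

    def test_median_pseudotime_option(self, make_counts_factory):
        cc = make_counts_factory([[1, 1, 1]], ["g"], "S")
        ann = _annot(cc.cells["barcode"], "S", "0", [1.0, 2.0, 10.0])
        pb = aggregate(cc, ann, pseudotime_stat="median")
        assert pb.samples["pseudotime"].iloc[0] == 2.0


class TestFilterSmall:
    def test_mammary_table_removes_seven(self):
        tab = mammary_pseudobulk_table()
        ann = mammary_cell_annotation()
        # build a pseudobulk-like object directly from the table
        from pseudotempo.pseudobulk import PseudobulkSet

        pb = PseudobulkSet(
            np.ones((1, len(tab)), dtype=int),
            pd.DataFrame({"ensembl_id": ["x"], "symbol": ["x"]}),
            tab[["group", "cluster", "pseudotime", "cell_number"]].copy(),
        )
        out = filter_small(pb, 30)
        assert len(tab) - out.shape[1] == 7
        assert out.shape[1] == 22

    def test_exactly_30_removed(self, make_counts_factory):
        from pseudotempo.pseudobulk import PseudobulkSet

        pb = PseudobulkSet(
            np.ones((1, 2), dtype=int),
            pd.DataFrame({"ensembl_id": ["x"], "symbol": ["x"]}),
            pd.DataFrame(
                {"group": ["a", "b"], "cluster": "0",
                 "pseudotime": [1.0, 2.0], "cell_number": [30, 31]},
                index=["a_C0", "b_C0"],
            ),
        )
        out = filter_small(pb, 30)
        assert list(out.sample_names) == ["b_C0"]

    def test_zero_threshold_identity(self):
        from pseudotempo.pseudobulk import PseudobulkSet

        pb = PseudobulkSet(
            np.ones((1, 3), dtype=int),
            pd.DataFrame({"ensembl_id": ["x"], "symbol": ["x"]}),
            pd.DataFrame(
                {"group": list("abc"), "cluster": "0",
                 "pseudotime": [1.0, 2, 3], "cell_number": [1, 5, 9]},
                index=["a", "b", "c"],
            ),
        )
        assert filter_small(pb, 0).shape[1] == 3


class TestFilterGenes:
    def test_zero_gene_removed_and_threshold_kept(self):
        pb, _ = simulate_pseudobulk(n_samples=8, n_genes=50, seed=3)
        pb.counts[0, :] = 0
        pb.samples["lib_size"] = pb.counts.sum(axis=0)
        # equal-depth libraries: force lib sizes equal
        lib = int(np.median(pb.samples["lib_size"]))
        pb.samples["lib_size"] = lib
        cpm_cutoff_count = 10  # min_count at median lib -> exactly min_count
        k = 8  # one group of 8 samples
        pb.counts[1, :] = 0
        pb.counts[1, :k] = cpm_cutoff_count
        out = filter_genes(pb, min_count=10, min_total=15)
        kept = set(out.genes["symbol"])
        assert pb.genes["symbol"][0] not in kept
        assert pb.genes["symbol"][1] in kept

    def test_one_group_k_equals_n(self):
        pb, _ = simulate_pseudobulk(n_samples=5, n_genes=30, seed=4)
        out = filter_genes(pb, group_sizes={"G1": 5})
        # a gene must pass the CPM cutoff in all 5 samples
        cpm = pb.counts / pb.samples["lib_size"].to_numpy() * 1e6
        cutoff = 10 / np.median(pb.samples["lib_size"]) * 1e6
        manual = ((cpm >= cutoff).sum(axis=1) >= 5 - 1e-14) & (
            pb.counts.sum(axis=1) >= 15 - 1e-14
        )
        assert np.array_equal(
            np.isin(pb.genes["symbol"], out.genes["symbol"]), manual
        )

    def test_lib_sizes_recomputed(self):
        pb, _ = simulate_pseudobulk(n_samples=6, n_genes=40, seed=5)
        out = filter_genes(pb)
        assert np.array_equal(
            out.samples["lib_size"].to_numpy(), out.counts.sum(axis=0)
        )


def _tmm_oracle(counts, lib, logratio_trim=0.3, abs_trim=0.05):
    """Loop-level re-implementation of TMM for cross-checking."""
    counts = np.asarray(counts, float)
    G, S = counts.shape

    def quant75(j):
        col = sorted(counts[:, j])
        h = (G - 1) * 0.75
        lo = int(np.floor(h))
        hi = min(lo + 1, G - 1)
        return (col[lo] + (h - lo) * (col[hi] - col[lo])) / lib[j]

    f75 = [quant75(j) for j in range(S)]
    mean75 = sum(f75) / S
    ref = min(range(S), key=lambda j: abs(f75[j] - mean75))

    def avg_rank(vals):
        order = sorted(range(len(vals)), key=lambda i: vals[i])
        ranks = [0.0] * len(vals)
        i = 0
        while i < len(vals):
            j = i
            while j + 1 < len(vals) and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    factors = []
    for j in range(S):
        logR, absE, v = [], [], []
        for g in range(G):
            o, r = counts[g, j], counts[g, ref]
            if o > 0 and r > 0:
                logR.append(np.log2((o / lib[j]) / (r / lib[ref])))
                absE.append((np.log2(o / lib[j]) + np.log2(r / lib[ref])) / 2)
                v.append((lib[j] - o) / lib[j] / o + (lib[ref] - r) / lib[ref] / r)
        if not logR or max(abs(x) for x in logR) < 1e-6:
            factors.append(1.0)
            continue
        n = len(logR)
        loL, hiL = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        loS, hiS = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
        rR, rS = avg_rank(logR), avg_rank(absE)
        num = den = 0.0
        any_kept = False
        for i in range(n):
            if loL <= rR[i] <= hiL and loS <= rS[i] <= hiS:
                num += logR[i] / v[i]
                den += 1.0 / v[i]
                any_kept = True
        factors.append(2.0 ** (num / den) if any_kept else 1.0)
    logf = [np.log(f) for f in factors]
    gm = np.exp(sum(logf) / S)
    return np.array([f / gm for f in factors])


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 4))
        from pseudotempo.pseudobulk import PseudobulkSet

        pb = PseudobulkSet(
            counts,
            pd.DataFrame(
                {"ensembl_id": [str(i) for i in range(100)],
                 "symbol": [f"g{i}" for i in range(100)]}
            ),
            pd.DataFrame(
                {"group": list("abcd"), "cluster": "0",
                 "pseudotime": [1.0, 2, 3, 4], "cell_number": 100},
                index=list("abcd"),
            ),
        )
        assert np.allclose(tmm_factors(pb), 1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        pb, _ = simulate_pseudobulk(n_samples=6, n_genes=1000, phi=0.3, seed=8)
        pb.counts[5, 1] *= 100  # one composition outlier
        pb.samples["lib_size"] = pb.counts.sum(axis=0)
        ours = tmm_factors(pb)
        oracle = _tmm_oracle(pb.counts, pb.samples["lib_size"].to_numpy(float))
        assert np.allclose(ours, oracle, atol=1e-8)
        assert abs(np.log(ours).sum()) < 1e-10  # geometric mean 1

    def test_depth_scaling_invariance(self):
        pb, _ = simulate_pseudobulk(n_samples=5, n_genes=800, phi=0.2, seed=9)
        base = tmm_factors(pb, weighted=False)
        pb2 = pb.subset_samples(np.arange(5))
        pb2.counts = pb2.counts.copy()
        pb2.counts[:, 2] *= 2
        pb2.samples["lib_size"] = pb2.counts.sum(axis=0)
        scaled = tmm_factors(pb2, weighted=False)
        assert np.allclose(base, scaled, rtol=1e-12)
        # weighted variant: invariant up to the precision weights
        assert np.allclose(tmm_factors(pb2), tmm_factors(pb), rtol=0.03)

    def test_all_zero_sample_raises(self):
        from pseudotempo.pseudobulk import PseudobulkSet

        pb = PseudobulkSet(
            np.array([[1, 0], [2, 0]]),
            pd.DataFrame({"ensembl_id": ["a", "b"], "symbol": ["a", "b"]}),
            pd.DataFrame(
                {"group": ["x", "y"], "cluster": "0",
                 "pseudotime": [1.0, 2.0], "cell_number": 10},
                index=["x", "y"],
            ),
        )
        pb.samples["lib_size"] = [3, 1]  # avoid div-by-zero in metadata
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(pb)


class TestLogCPM:
    def test_zero_count_closed_form(self):
        from pseudotempo.pseudobulk import PseudobulkSet

        counts = np.zeros((1, 3), dtype=int)
        pb = PseudobulkSet(
            counts,
            pd.DataFrame({"ensembl_id": ["a"], "symbol": ["a"]}),
            pd.DataFrame(
                {"group": list("abc"), "cluster": "0",
                 "pseudotime": [1.0, 2, 3], "cell_number": 1,
                 "lib_size": [1_000_000] * 3, "norm_factor": 1.0},
                index=list("abc"),
            ),
        )
        vals = log_cpm(pb, prior_count=2.0).to_numpy()
        assert np.allclose(vals, np.log2(2e6 / (1e6 + 4)), atol=1e-6)
        assert vals[0, 0] == pytest.approx(1.0, abs=1e-4)

    def test_depth_invariance_and_monotonicity(self):
        pb, _ = simulate_pseudobulk(n_samples=4, n_genes=50, seed=11)
        a = log_cpm(pb)
        pb2 = pb.subset_samples(np.arange(4))
        pb2.counts = pb2.counts * 2
        pb2.samples["lib_size"] = pb2.samples["lib_size"] * 2
        b = log_cpm(pb2)
        # the mean-scaled prior count does not double with depth, so the
        # invariance is exact only as counts dominate the prior
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=0.01)
        col = a.to_numpy()[:, 0]
        order = np.argsort(pb.counts[:, 0], kind="stable")
        assert (np.diff(col[order]) >= -1e-12).all()

    def test_nonpositive_prior_rejected(self):
        pb, _ = simulate_pseudobulk(n_samples=4, n_genes=10, seed=12)
        with pytest.raises(ValueError):
            log_cpm(pb, prior_count=0)


class TestMDS:
    def test_identical_columns_distance_zero_and_symmetry(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 1, size=(200, 3))
        lc = pd.DataFrame(np.column_stack([X[:, 0], X[:, 0], X[:, 2]]),
                          columns=list("abc"))
        coords = mds_leading_logfc(lc, top=50)
        d_ab = np.linalg.norm(coords.loc["a"] - coords.loc["b"])
        assert d_ab == pytest.approx(0.0, abs=1e-6)

    def test_three_sample_eigen_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, size=(100, 3))
        lc = pd.DataFrame(X, columns=list("abc"))
        top = 20
        # oracle: explicit distance matrix + eigendecomposition
        D = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                d = np.sort(np.abs(X[:, i] - X[:, j]))[-top:]
                D[i, j] = np.sqrt((d**2).mean())
        J = np.eye(3) - 1 / 3
        B = -0.5 * J @ D**2 @ J
        w, V = np.linalg.eigh(B)
        idx = np.argsort(w)[::-1][:2]
        oracle = V[:, idx] * np.sqrt(w[idx])
        ours = mds_leading_logfc(lc, top=top).to_numpy()
        # columns defined up to sign
        for k in range(2):
            assert np.allclose(ours[:, k], oracle[:, k], atol=1e-8) or np.allclose(
                ours[:, k], -oracle[:, k], atol=1e-8
            )

    def test_top_clamped_with_warning(self):
        lc = pd.DataFrame(np.random.default_rng(3).normal(size=(10, 3)),
                          columns=list("abc"))
        with pytest.warns(UserWarning, match="clamp"):
            mds_leading_logfc(lc, top=500)


class TestOrderingAndComposition:
    def test_sort_by_pseudotime_stable_for_ties(self):
        from pseudotempo.pseudobulk import PseudobulkSet

        pb = PseudobulkSet(
            np.ones((1, 3), dtype=int),
            pd.DataFrame({"ensembl_id": ["x"], "symbol": ["x"]}),
            pd.DataFrame(
                {"group": list("abc"), "cluster": "0",
                 "pseudotime": [2.0, 1.0, 1.0], "cell_number": 5},
                index=["s1", "s2", "s3"],
            ),
        )
        out = sort_by_pseudotime(pb)
        assert list(out.sample_names) == ["s2", "s3", "s1"]

    def test_mammary_composition_percentages(self):
        ann = mammary_cell_annotation()
        counts, pct = composition_table(ann)
        assert counts.loc["E18.5-epi", "3"] == 2341
        assert pct.loc["E18.5-epi", "3"] == pytest.approx(53.90, abs=0.005)
        assert pct.loc["P5", "3"] == pytest.approx(30.79, abs=0.005)
        # percentages sum to 100 per sample
        assert np.allclose(pct.sum(axis=1), 100.0, atol=0.05)


def test_normalize_sets_factors():
    pb, _ = simulate_pseudobulk(n_samples=5, n_genes=300, seed=13)
    out = normalize(pb)
    assert (out.samples["norm_factor"] > 0).all()
    assert abs(np.log(out.samples["norm_factor"]).sum()) < 1e-10
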