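import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from pseudotempo.nbql import (
    NBQLModel,
    bh_adjust,
    decide_tests,
    estimate_dispersions,
    fit_glm,
    nb_deviance,
    nb_loglik,
    ql_f_test,
    ql_fit,
    squeeze_var,
    top_table,
)
from pseudotempo.pseudobulk import filter_genes, normalize
from pseudotempo.spline_design import build_design, orthonormal_time_design
from pseudotempo.trajectory_sim import simulate_pseudobulk


def _fit_inputs(pb):
    t = pb.samples["pseudotime"].to_numpy()
    Z, basis = orthonormal_time_design(t)
    design = build_design(Z, pb.samples["group"])
    return design


class TestGLMFit:
    def test_matches_statsmodels_poisson(self):
        """At phi ~ 0 the NB IRLS reduces to a Poisson GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 15
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        offset = np.log(rng.uniform(1e4, 1e5, size=n))
        beta_true = np.array([-6.0, 0.5])
        mu = np.exp(X @ beta_true + offset)
        y = rng.poisson(mu)[None, :]
        beta, mu_fit, dev, conv = fit_glm(y, X, offset, 0.0)
        ref = sm.GLM(
            y.ravel(), X, family=sm.families.Poisson(), offset=offset
        ).fit()
        assert np.allclose(beta.ravel(), ref.params, atol=1e-6)
        assert dev[0] == pytest.approx(ref.deviance, abs=1e-6)

    def test_deviance_nonnegative_and_nested(self):
        pb, _ = simulate_pseudobulk(n_samples=12, n_genes=100, phi=0.2, seed=1)
        design = _fit_inputs(pb)
        X = design.values
        off = np.log(pb.effective_lib_size())
        y = pb.counts.astype(float)
        _, _, dev_full, _ = fit_glm(y, X, off, 0.2)
        _, _, dev_null, _ = fit_glm(y, X[:, :1], off, 0.2)
        assert (dev_full >= -1e-8).all()
        assert (dev_null >= dev_full - 1e-6).all()


class TestDispersionEstimation:
    def test_single_gene_apl_grid_oracle(self):
        """Intercept-only, equal libraries: APL maximizer agrees with an
        explicit closed-form grid search (MLE mean = sample mean)."""
        y = np.array([[10.0, 10.0, 4.0, 16.0, 8.0, 12.0]])
        n = y.shape[1]
        lib = np.full(n, 1000.0)
        X = np.ones((n, 1))
        offset = np.log(lib)

        def apl(phi):
            mu = np.full(n, y.mean())  # intercept-only NB MLE is the mean
            ll = nb_loglik(y, mu[None, :], np.array([phi]))[0]
            w = mu / (1 + phi * mu)
            return ll - 0.5 * np.log(w.sum())

        grid = np.exp(np.linspace(np.log(1e-4), np.log(5), 4001))
        phi_oracle = grid[np.argmax([apl(p) for p in grid])]
        d = estimate_dispersions(y, X, offset=offset, n_bins=1)
        assert np.log(d.common_dispersion) == pytest.approx(
            np.log(phi_oracle), abs=1e-3
        )

    def test_common_recovery_and_poisson_limit(self):
        pb, _ = simulate_pseudobulk(n_samples=22, n_genes=600, phi=0.2, seed=2)
        d = estimate_dispersions(pb, np.ones((22, 1)))
        assert d.common_dispersion == pytest.approx(0.2, rel=0.08)
        pbp, _ = simulate_pseudobulk(n_samples=22, n_genes=400, phi=0.0, seed=3)
        dp = estimate_dispersions(pbp, np.ones((22, 1)))
        assert dp.common_dispersion < 0.01

    def test_dispersions_positive_and_trend_smooth(self):
        pb, _ = simulate_pseudobulk(n_samples=15, n_genes=400, phi=0.1, seed=4)
        design = _fit_inputs(pb)
        d = estimate_dispersions(pb, design)
        assert (d.trended_dispersion > 0).all()
        assert (d.tagwise_dispersion > 0).all()
        order = np.argsort(d.ave_log_cpm)
        # trend is a function of abundance: piecewise-monotone interpolation
        # produces no jumps larger than the overall range
        tr = np.log(d.trended_dispersion[order])
        assert np.abs(np.diff(tr)).max() <= (tr.max() - tr.min()) + 1e-12


class TestQLFit:
    def test_squeeze_reduces_spread(self):
        pb, _ = simulate_pseudobulk(n_samples=20, n_genes=500, phi=0.15, seed=5)
        design = _fit_inputs(pb)
        d = estimate_dispersions(pb, design)
        fit = ql_fit(pb, design, d, robust=True)
        ok = np.isfinite(fit.s2_raw)
        assert np.var(np.log(fit.s2_post[ok])) < np.var(
            np.log(np.maximum(fit.s2_raw[ok], 1e-10))
        )
        # squeezed value lies between raw and trend
        lo = np.minimum(fit.s2_raw[ok], fit.s2_prior[ok]) - 1e-12
        hi = np.maximum(fit.s2_raw[ok], fit.s2_prior[ok]) + 1e-12
        assert ((fit.s2_post[ok] >= lo) & (fit.s2_post[ok] <= hi)).all()

    def test_infinite_prior_df_collapses_to_trend(self):
        rng = np.random.default_rng(6)
        df = 10.0
        s0 = 1.3
        s2 = s0 * rng.chisquare(int(df), 300) / df
        # zero excess variance scenario: feed constant dispersions
        s2_const = np.full(300, 0.9)
        post, prior, dfp = squeeze_var(s2_const, df)
        assert np.isinf(dfp).all()
        assert np.allclose(post, prior)

    def test_large_count_poisson_raw_dispersion_near_one(self):
        """Poisson data with large counts: quasi-dispersion ~ 1."""
        rng = np.random.default_rng(7)
        n, G = 20, 2000
        lib = np.full(n, 1e6)
        mu = rng.uniform(200, 2000, size=G)
        y = rng.poisson(np.tile(mu[:, None], (1, n)))
        fit = ql_fit(
            y, np.ones((n, 1)), 1e-8, robust=False, lib_size=lib,
            norm_factors=np.ones(n),
        )
        assert np.nanmean(fit.s2_raw) == pytest.approx(1.0, abs=0.1)


class TestQLFTest:
    def test_intercept_rejected(self):
        pb, _ = simulate_pseudobulk(n_samples=12, n_genes=50, phi=0.1, seed=8)
        design = _fit_inputs(pb)
        fit = ql_fit(pb, design, 0.1)
        with pytest.raises(ValueError, match="intercept"):
            ql_f_test(fit, ["(Intercept)"])

    def test_constant_gene_f_zero_p_one(self):
        n = 16
        t = np.linspace(0, 10, n)
        Z, _ = orthonormal_time_design(t)
        design = build_design(Z, ["g"] * n)
        y = np.full((1, n), 50.0)
        lib = np.full(n, 1e4)
        fit = ql_fit(y, design, 0.1, lib_size=lib, robust=False)
        res = ql_f_test(fit, ["Z1", "Z2", "Z3"])
        assert res["F"].iloc[0] == pytest.approx(0.0, abs=1e-3)
        assert res["PValue"].iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_testing_three_spline_coefficients(self):
        pb, _ = simulate_pseudobulk(n_samples=14, n_genes=60, phi=0.1, seed=9)
        design = _fit_inputs(pb)
        fit = ql_fit(pb, design, 0.1)
        res = ql_f_test(fit, ["Z1", "Z2", "Z3"])
        assert {"logFC.Z1", "logFC.Z2", "logFC.Z3", "logCPM", "F",
                "PValue", "FDR"} <= set(res.columns)
        assert ((res["PValue"] > 0) & (res["PValue"] <= 1)).all()
        assert (res["FDR"] >= res["PValue"] - 1e-12).all()

    def test_median_f_monotone_in_effect_size(self):
        """A stronger planted trend never reduces the median F statistic."""
        medians = []
        for eff in (0.0, 1.0, 2.5):
            pb, truth = simulate_pseudobulk(
                n_samples=18, n_genes=200, phi=0.1, effect_size=eff,
                frac_trend=1.0 if eff else 0.0, seed=10,
            )
            design = _fit_inputs(pb)
            d = estimate_dispersions(pb, design, n_bins=1)
            fit = ql_fit(pb, design, d)
            res = ql_f_test(fit, ["Z1", "Z2", "Z3"])
            medians.append(res["F"].median())
        assert medians[0] <= medians[1] <= medians[2]

    def test_gaussian_limit_agrees_with_classical_f(self):
        """Large counts: quasi-F p-values track the OLS F-test on log-CPM."""
        from pseudotempo.pseudobulk import log_cpm

        pb, _ = simulate_pseudobulk(
            n_samples=20, n_genes=400, phi=0.02, effect_size=1.0,
            frac_trend=0.3, seed=11,
            lib_sizes=np.full(20, 5e6),
        )
        pb = normalize(pb)
        design = _fit_inputs(pb)
        d = estimate_dispersions(pb, design)
        fit = ql_fit(pb, design, d, robust=False)
        res = ql_f_test(fit, ["Z1", "Z2", "Z3"])
        X = design.values
        lc = log_cpm(pb).to_numpy()
        n, p = X.shape
        H = X @ np.linalg.solve(X.T @ X, X.T)
        X0 = np.delete(X, [1, 2, 3], axis=1)
        H0 = X0 @ np.linalg.solve(X0.T @ X0, X0.T)
        rss1 = ((lc - lc @ H.T) ** 2).sum(axis=1)
        rss0 = ((lc - lc @ H0.T) ** 2).sum(axis=1)
        f_cls = ((rss0 - rss1) / 3) / (rss1 / (n - p))
        p_cls = stats.f.sf(f_cls, 3, n - p)
        rho = stats.spearmanr(res["PValue"], p_cls).statistic
        assert rho > 0.95


class TestMultiplicity:
    def test_bh_hand_computed_examples(self):
        assert bh_adjust([0.02]) == pytest.approx([0.02])
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_adjust([0.5, 0.5, 0.5]), [0.5, 0.5, 0.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(1e-12, 1.0, allow_nan=False), min_size=1,
                 max_size=40)
    )
    def test_bh_matches_definitional_oracle(self, pvals):
        p = np.array(pvals)
        m = len(p)
        oracle = np.empty(m)
        for i in range(m):
            # adj_i = min over {j : p_j >= p_i} of min(1, m p_j / rank_j)
            candidates = []
            order = np.argsort(p, kind="stable")
            ranks = np.empty(m, int)
            ranks[order] = np.arange(1, m + 1)
            for j in range(m):
                if p[j] >= p[i] - 1e-15:
                    candidates.append(min(1.0, m * p[j] / ranks[j]))
            oracle[i] = min(candidates)
        assert np.allclose(bh_adjust(p), oracle, atol=1e-12)

    def test_decide_tests_examples(self):
        empty = pd.DataFrame(
            columns=["logFC.Z1", "logCPM", "F", "PValue", "FDR"]
        )
        counts = decide_tests(empty)
        assert counts.sum() == 0
        res = pd.DataFrame(
            {
                "logFC.Z1": [1.0, -2.0, 0.5],
                "logCPM": 1.0,
                "F": [10, 20, 1],
                "PValue": [0.001, 0.001, 1.0],
                "FDR": [0.003, 0.003, 1.0],
            },
            index=["a", "b", "c"],
        )
        counts = decide_tests(res, alpha=0.05)
        assert counts.to_dict() == {"Down": 1, "NotSig": 1, "Up": 1}
        all_ns = res.assign(PValue=1.0, FDR=1.0)
        assert decide_tests(all_ns)["NotSig"] == 3

    def test_top_table_ordering_and_stability(self):
        rng = np.random.default_rng(12)
        res = pd.DataFrame(
            {
                "logFC.Z1": rng.normal(size=8),
                "logCPM": 1.0,
                "F": [5, 9, 9, 1, 2, 2, 7, 3],
                "PValue": [0.2, 0.01, 0.01, 0.9, 0.5, 0.5, 0.05, 0.3],
                "FDR": 1.0,
            },
            index=list("hgfedcba"),
        )
        top = top_table(res, n=100)
        assert (np.diff(top["PValue"]) >= 0).all()
        # ties: larger F first, then name
        assert list(top.index[:2]) == ["f", "g"]
        shuffled = res.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(top_table(res, 5), top_table(shuffled, 5))
        assert len(top_table(res, n=100)) == 8


class TestModelAPI:
    def test_model_results_round_trip(self):
        pb, _ = simulate_pseudobulk(n_samples=14, n_genes=80, phi=0.1, seed=13)
        design = _fit_inputs(pb)
        model = NBQLModel.from_pseudobulk(pb, design)
        res = model.fit(robust=True, n_bins=1)
        tab = res.f_test(["Z1", "Z2", "Z3"])
        assert len(tab) == 80
        assert res.params.shape == (80, design.matrix.shape[1])
        text = res.summary()
        assert "common dispersion" in text and "genes: 80" in text
        # functional path gives the same table
        fit2 = ql_fit(pb, design, res.dispersion, robust=True)
        tab2 = ql_f_test(fit2, ["Z1", "Z2", "Z3"])
        pd.testing.assert_frame_equal(tab, tab2)
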