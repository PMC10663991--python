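"""Negative-binomial quasi-likelihood engine.

Counts for gene g in pseudo-bulk sample j are modelled as NB with mean
mu_gj = exp(x_j' beta_g + o_j) (log link, offset o_j = log effective
library size) and variance mu + phi mu^2, phi the NB dispersion. The
biological coefficient of variation is BCV = sqrt(phi).

Dispersion estimation maximizes the Cox-Reid adjusted profile likelihood
(APL): the NB log-likelihood at the profiled GLM fit minus half the log
determinant of the Fisher information, which corrects the downward bias of
plain profile likelihood when regression coefficients are estimated.
A single common value, a smooth abundance trend, and per-gene (tagwise)
values shrunk toward the trend by weighted-likelihood empirical Bayes are
all produced; only the trend feeds the quasi-likelihood fit, the others
serve the BCV diagnostic.

The QL layer fixes phi at the trend and captures remaining gene-specific
variability in a quasi-dispersion s^2 estimated from the residual deviance,
then squeezed toward an abundance-dependent trend by fitting a scaled-F
prior on the log dispersions (moment matching via digamma/trigamma). The
quasi-F statistic for dropping r coefficients is

    F = (drop-in-deviance / r) / s^2_posterior

referred to an F distribution on (r, residual df + prior df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.interpolate import PchipInterpolator
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "DispersionFit",
    "QLFit",
    "NBQLModel",
    "NBQLResults",
    "estimate_dispersions",
    "ql_fit",
    "ql_f_test",
    "bh_adjust",
    "decide_tests",
    "top_table",
    "ave_log_cpm",
]

LOG2 = np.log(2.0)
_PHI_MIN, _PHI_MAX = 1e-6, 10.0


# ---------------------------------------------------------------------------
# NB likelihood primitives
# ---------------------------------------------------------------------------

def nb_deviance(y, mu, phi):
    """Per-gene NB residual deviance (Poisson limit at phi ~ 0)."""
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-10)
    phi = np.broadcast_to(np.asarray(phi, float), y.shape[:1])[:, None]
    poisson = phi < 1e-10
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = special.xlogy(y, y / mu)
        # NB part
        phi_safe = np.where(poisson, 1.0, phi)
        r = 1.0 / phi_safe
        nb = term1 - (y + r) * (np.log1p(phi_safe * y) - np.log1p(phi_safe * mu))
        po = term1 - (y - mu)
    unit = np.where(poisson, po, nb)
    return 2.0 * unit.sum(axis=1)


def nb_loglik(y, mu, phi):
    """Per-gene NB log-likelihood (Poisson limit at phi ~ 0)."""
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-10)
    phi = np.broadcast_to(np.asarray(phi, float), y.shape[:1])[:, None]
    poisson = phi < 1e-10
    phi_safe = np.where(poisson, 1.0, phi)
    r = 1.0 / phi_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        nb = (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + special.xlogy(y, mu)
            - special.xlogy(y, mu + r)
            - r * np.log1p(phi_safe * mu)
        )
        po = special.xlogy(y, mu) - mu - special.gammaln(y + 1)
    ll = np.where(poisson, po, nb)
    return ll.sum(axis=1)


def fit_glm(y, X, offset, dispersion, max_iter=50, tol=1e-8):
    """Vectorized IRLS fit of per-gene NB GLMs sharing one design.

    Parameters
    ----------
    y : (G, n) counts;  X : (n, p) design;  offset : (n,) log effective
    library sizes;  dispersion : scalar or (G,) NB dispersions.

    Returns ``(beta, mu, deviance, converged)``. Divergent steps are
    line-halved; genes still diverging after ``max_iter`` are flagged.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    offset = np.asarray(offset, float)
    G, n = y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(dispersion, float), (G,)).copy()

    # init from a least-squares fit on shifted log counts
    z0 = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, p)

    def _mu(b):
        eta = b @ X.T + offset
        return np.exp(np.clip(eta, -500, 500))

    mu = _mu(beta)
    dev = nb_deviance(y, mu, phi)
    converged = np.zeros(G, bool)
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        ya, mua, phia, beta_a = y[active], mu[active], phi[active], beta[active]
        w = mua / (1.0 + phia[:, None] * mua)
        z = (beta_a @ X.T) + (ya - mua) / np.maximum(mua, 1e-10)
        XtWX = np.einsum("gn,ni,nj->gij", w, X, X) + ridge
        XtWz = np.einsum("gn,ni->gi", w * z, X)
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.einsum(
                "gij,gj->gi", np.linalg.pinv(XtWX), XtWz
            )
        step = beta_new - beta_a
        dev_old = dev[active]
        # line halving on genes whose deviance increases
        frac = np.ones(step.shape[0])
        for _half in range(15):
            cand = beta_a + frac[:, None] * step
            mu_c = _mu(cand)
            dev_c = nb_deviance(ya, mu_c, phia)
            bad = dev_c > dev_old + 1e-10
            if not bad.any():
                break
            frac[bad] *= 0.5
        beta[active] = beta_a + frac[:, None] * step
        mu[active] = _mu(beta[active])
        dev_new = nb_deviance(y[active], mu[active], phi[active])
        rel = np.abs(dev_new - dev_old) / (np.abs(dev_old) + 1.0)
        done = np.zeros(G, bool)
        done[np.flatnonzero(active)[rel < tol]] = True
        converged |= done
        dev[active] = dev_new
    return beta, mu, dev, converged


def _adjusted_profile_loglik(y, X, offset, phi):
    """Cox-Reid adjusted profile log-likelihood, per gene, at fixed phi."""
    beta, mu, dev, _ = fit_glm(y, X, offset, phi)
    ll = nb_loglik(y, mu, phi)
    phi_b = np.broadcast_to(np.asarray(phi, float), (y.shape[0],))
    w = mu / (1.0 + phi_b[:, None] * mu)
    XtWX = np.einsum("gn,ni,nj->gij", w, X, X)
    XtWX = XtWX + 1e-10 * np.eye(X.shape[1])
    sign, logdet = np.linalg.slogdet(XtWX)
    return ll - 0.5 * logdet


# ---------------------------------------------------------------------------
# Expected unit deviance correction
#
# The residual deviance of an NB GLM is not chi-square at finite counts:
# E[d] for a single observation exceeds 1 and tends to 2k(log k - psi(k))
# (k = 1/phi) in the large-mean limit, so deviance/df systematically
# overestimates the QL dispersion and makes the F-test conservative. Each
# gene's deviance is therefore divided by its mean expected unit deviance
# under the fitted model, computed exactly by summation on a (mu, phi) grid
# and interpolated.
# ---------------------------------------------------------------------------

_EXP_DEV_TABLE = None


def _unit_dev_values(y, mu, phi):
    if phi < 1e-10:
        with np.errstate(divide="ignore", invalid="ignore"):
            return 2.0 * (special.xlogy(y, y / mu) - (y - mu))
    r = 1.0 / phi
    with np.errstate(divide="ignore", invalid="ignore"):
        return 2.0 * (
            special.xlogy(y, y / mu)
            - (y + r) * (np.log1p(phi * y) - np.log1p(phi * mu))
        )


def _expected_unit_deviance_exact(mu: float, phi: float, cap: int = 30000):
    if phi < 1e-10:
        if mu > cap / 4:
            return 1.0 + 1.0 / (6.0 * mu)
        hi = int(stats.poisson.ppf(1 - 1e-13, mu)) + 5
        y = np.arange(0, hi + 1)
        pmf = stats.poisson.pmf(y, mu)
        return float(np.sum(pmf * _unit_dev_values(y.astype(float), mu, phi)))
    k = 1.0 / phi
    p = 1.0 / (1.0 + phi * mu)
    hi = int(stats.nbinom.ppf(1 - 1e-13, k, p)) + 5
    if hi > cap:
        # gamma-mixing limit: E[d] -> 2k(log k - psi(k))
        return float(2.0 * k * (np.log(k) - special.digamma(k)))
    y = np.arange(0, hi + 1)
    pmf = stats.nbinom.pmf(y, k, p)
    return float(np.sum(pmf * _unit_dev_values(y.astype(float), mu, phi)))


def _exp_dev_table():
    global _EXP_DEV_TABLE
    if _EXP_DEV_TABLE is None:
        log_mu = np.linspace(-3.0, 6.0, 37)
        log_phi = np.linspace(-6.0, 1.0, 15)
        vals = np.empty((len(log_mu), len(log_phi)))
        for i, lm in enumerate(log_mu):
            for j, lp in enumerate(log_phi):
                vals[i, j] = _expected_unit_deviance_exact(10.0**lm, 10.0**lp)
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (log_mu, log_phi), vals, method="linear", bounds_error=False,
            fill_value=None,
        )
        _EXP_DEV_TABLE = (interp, log_mu, log_phi)
    return _EXP_DEV_TABLE


def expected_unit_deviance(mu, phi):
    """Mean of the NB unit deviance under NB(mu, phi), interpolated from an
    exact table on a log-log grid."""
    interp, log_mu, log_phi = _exp_dev_table()
    mu = np.asarray(mu, float)
    phi_b = np.broadcast_to(np.asarray(phi, float), mu.shape)
    lm = np.clip(np.log10(np.maximum(mu, 1e-300)), log_mu[0], log_mu[-1])
    lp = np.clip(np.log10(np.maximum(phi_b, 1e-300)), log_phi[0], log_phi[-1])
    pts = np.stack([lm.ravel(), lp.ravel()], axis=1)
    return interp(pts).reshape(mu.shape)


def ave_log_cpm(counts, eff_lib, prior_count: float = 2.0) -> np.ndarray:
    """Average abundance of each gene in log2 counts-per-million."""
    counts = np.asarray(counts, float)
    eff_lib = np.asarray(eff_lib, float)
    S = counts.shape[1]
    total = counts.sum(axis=1)
    return np.log2(
        (total + 2.0 * prior_count)
        / (eff_lib.sum() + 4.0 * prior_count)
        * 1e6
    )


# ---------------------------------------------------------------------------
# NB dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionFit:
    """Common, trended and tagwise NB dispersion estimates."""

    common_dispersion: float
    trended_dispersion: np.ndarray
    tagwise_dispersion: np.ndarray
    ave_log_cpm: np.ndarray
    trend_fn: object = field(default=None, repr=False)

    def bcv_table(self, gene_names=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "ave_log_cpm": self.ave_log_cpm,
                "common_bcv": np.sqrt(self.common_dispersion),
                "trended_bcv": np.sqrt(self.trended_dispersion),
                "tagwise_bcv": np.sqrt(self.tagwise_dispersion),
            }
        )
        if gene_names is not None:
            df.insert(0, "gene", np.asarray(gene_names))
        return df


class _DispersionTrend:
    """Picklable dispersion-vs-abundance trend (PCHIP in log phi, clamped
    flat outside the fitted abundance range; constant when degenerate)."""

    def __init__(self, centers=None, log_phis=None, constant=None):
        self.centers = None if centers is None else np.asarray(centers, float)
        self.log_phis = None if log_phis is None else np.asarray(log_phis, float)
        self.constant = constant
        self._interp = None
        if self.centers is not None and len(self.centers) >= 2:
            self._interp = PchipInterpolator(
                self.centers, self.log_phis, extrapolate=False
            )

    def __call__(self, abundance):
        a = np.asarray(abundance, float)
        if self._interp is None:
            return np.full(np.shape(a), self.constant)
        out = self._interp(np.clip(a, self.centers[0], self.centers[-1]))
        return np.exp(out)

    def __getstate__(self):
        return {
            "centers": self.centers,
            "log_phis": self.log_phis,
            "constant": self.constant,
        }

    def __setstate__(self, state):
        self.__init__(**state)


def _maximize_apl(y, X, offset, lo=_PHI_MIN, hi=_PHI_MAX, xatol=1e-6):
    """1-D maximization of summed APL over log-dispersion."""

    def neg(lp):
        return -float(_adjusted_profile_loglik(y, X, offset, np.exp(lp)).sum())

    res = optimize.minimize_scalar(
        neg, bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": xatol},
    )
    return float(np.exp(res.x))


def estimate_dispersions(
    counts,
    design,
    offset=None,
    lib_size=None,
    norm_factors=None,
    n_bins: "int | None" = None,
    prior_df: float = 20.0,
    grid_points: int = 15,
    grid_range: tuple[float, float] = (-6.0, 6.0),
) -> DispersionFit:
    """Estimate common, trended and tagwise NB dispersions by Cox-Reid APL.

    ``counts`` may be a :class:`~pseudotempo.pseudobulk.PseudobulkSet` (its
    design-relevant metadata supplies the offsets) or a plain (G, n) array
    with ``offset``/``lib_size`` given explicitly.

    The trend is built by maximizing the summed APL within abundance bins
    and interpolating the bin maxima with a monotone (PCHIP) cubic in
    ave-log-CPM; tagwise values maximize each gene's APL plus
    ``prior_df/df_residual`` times a locally shared APL (moving average
    over abundance-sorted neighbours), evaluated on a log2 grid of
    multipliers of the trend.
    """
    y, X, offset = _resolve_inputs(counts, design, offset, lib_size, norm_factors)
    G, n = y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not of full column rank")

    eff_lib = np.exp(offset)
    alc = ave_log_cpm(y, eff_lib)
    expressed = y.sum(axis=1) > 0
    ye = y[expressed]

    common = _maximize_apl(ye, X, offset)

    # ---- trended: per-abundance-bin APL maxima, monotone interpolation
    alc_e = alc[expressed]
    Ge = ye.shape[0]
    if n_bins is None:
        n_bins = int(np.clip(Ge // 150, 1, 20))
    if n_bins >= 2 and len(np.unique(alc_e)) >= n_bins:
        qs = np.quantile(alc_e, np.linspace(0, 1, n_bins + 1))
        qs[0] -= 1e-9
        which = np.clip(np.searchsorted(qs, alc_e, side="right") - 1, 0, n_bins - 1)
        centers, phis = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.sum() < 5:
                continue
            centers.append(np.median(alc_e[sel]))
            phis.append(_maximize_apl(ye[sel], X, offset, xatol=1e-4))
        centers = np.asarray(centers)
        phis = np.asarray(phis)
        order = np.argsort(centers)
        centers, phis = centers[order], phis[order]
        if len(centers) >= 2:
            trend_fn = _DispersionTrend(centers, np.log(phis))
        else:
            trend_fn = _DispersionTrend(constant=common)
    else:
        trend_fn = _DispersionTrend(constant=common)

    trended = np.asarray(trend_fn(alc), float)
    trended = np.clip(trended, _PHI_MIN, _PHI_MAX)

    # ---- tagwise: weighted-likelihood EB on a grid of trend multipliers
    df_resid = max(n - p, 1)
    prior_n = prior_df / df_resid
    mults = np.exp(np.linspace(grid_range[0], grid_range[1], grid_points) * LOG2 / 2)
    apl = np.empty((Ge, grid_points))
    trend_e = trended[expressed]
    for k, m in enumerate(mults):
        apl[:, k] = _adjusted_profile_loglik(ye, X, offset, trend_e * m)
    order = np.argsort(alc_e, kind="stable")
    window = max(2, int(round(0.05 * Ge)))
    ma = np.empty_like(apl)
    csum = np.cumsum(apl[order], axis=0)
    for i in range(Ge):
        lo_i = max(0, i - window)
        hi_i = min(Ge - 1, i + window)
        tot = csum[hi_i] - (csum[lo_i - 1] if lo_i > 0 else 0.0)
        ma[order[i]] = tot / (hi_i - lo_i + 1)
    score = apl + prior_n * ma
    best = np.argmax(score, axis=1)
    log_m = np.log(mults)
    tag_log_m = log_m[best].copy()
    interior = (best > 0) & (best < grid_points - 1)
    if interior.any():
        i = np.flatnonzero(interior)
        b = best[i]
        y0 = score[i, b - 1]
        y1 = score[i, b]
        y2 = score[i, b + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        h = log_m[1] - log_m[0]
        tag_log_m[i] = log_m[b] + shift * h
    tagwise_e = np.clip(trend_e * np.exp(tag_log_m), _PHI_MIN, _PHI_MAX)
    tagwise = trended.copy()
    tagwise[expressed] = tagwise_e

    return DispersionFit(
        common_dispersion=common,
        trended_dispersion=trended,
        tagwise_dispersion=tagwise,
        ave_log_cpm=alc,
        trend_fn=trend_fn,
    )


def _resolve_inputs(counts, design, offset, lib_size, norm_factors):
    from .pseudobulk import PseudobulkSet  # local import to avoid cycle
    from .spline_design import TimecourseDesign

    if isinstance(design, TimecourseDesign):
        X = design.values
    elif isinstance(design, pd.DataFrame):
        X = design.to_numpy(float)
    else:
        X = np.asarray(design, float)
    if isinstance(counts, PseudobulkSet):
        y = np.asarray(counts.counts, float)
        if offset is None:
            offset = np.log(counts.effective_lib_size())
    else:
        y = np.asarray(counts, float)
        if offset is None:
            if lib_size is None:
                lib_size = y.sum(axis=0)
            nf = np.ones(y.shape[1]) if norm_factors is None else np.asarray(norm_factors)
            offset = np.log(np.asarray(lib_size, float) * nf)
    return y, X, np.asarray(offset, float)


# ---------------------------------------------------------------------------
# Quasi-likelihood fit and empirical-Bayes squeeze
# ---------------------------------------------------------------------------

def _trigamma_inverse(x):
    """Solve trigamma(y) = x for y (vectorized Newton iteration)."""
    x = np.atleast_1d(np.asarray(x, float))
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / np.maximum(y, 1e-8)) < 1e-10:
            break
    return y


def squeeze_var(
    s2,
    df,
    covariate=None,
    robust: bool = False,
    winsor: tuple[float, float] = (0.05, 0.95),
    lowess_frac: float = 0.4,
):
    """Empirical-Bayes moderation of sample variances via a scaled-F prior.

    Moment-matches log s^2 to the log of a scaled F distribution: the prior
    df d0 solves trigamma(d0/2) = var(log s^2) - trigamma(df/2) and the
    abundance trend of the prior value comes from a lowess fit of the
    bias-corrected log dispersions on the covariate. Returns
    ``(s2_post, s2_prior, df_prior)`` where df_prior is per-gene when
    ``robust`` (outliers receive a smaller prior df, protecting them from
    over-shrinkage).
    """
    s2 = np.asarray(s2, float)
    df = np.broadcast_to(np.asarray(df, float), s2.shape).astype(float)
    G = len(s2)
    ok = (df > 0) & np.isfinite(s2)
    s2_floor = np.maximum(s2, 1e-10)
    z = np.log(s2_floor)
    dg = special.digamma(df[ok] / 2.0)
    e = np.full(G, np.nan)
    e[ok] = z[ok] - dg + np.log(df[ok] / 2.0)

    if covariate is not None and ok.sum() >= 10:
        cov = np.asarray(covariate, float)
        sm = lowess(e[ok], cov[ok], frac=lowess_frac, return_sorted=True)
        emean = np.interp(cov, sm[:, 0], sm[:, 1])
    else:
        emean = np.full(G, np.nanmean(e))
    resid = e - emean

    rfit = resid[ok]
    if robust:
        lo_q, hi_q = np.quantile(rfit, winsor)
        rwin = np.clip(rfit, lo_q, hi_q)
        # consistency factor: winsorizing shrinks the variance even without
        # outliers; rescale using the clamped-normal second moment
        zlo, zhi = stats.norm.ppf(winsor)
        phi_lo, phi_hi = stats.norm.pdf([zlo, zhi])
        cdf_lo, cdf_hi = stats.norm.cdf([zlo, zhi])
        m1 = (phi_lo - phi_hi) + zlo * cdf_lo + zhi * (1 - cdf_hi)
        m2 = (
            (cdf_hi - cdf_lo) + zlo * phi_lo - zhi * phi_hi
            + zlo**2 * cdf_lo + zhi**2 * (1 - cdf_hi)
        )
        consistency = max(m2 - m1**2, 1e-3)
        evar = (np.var(rwin, ddof=1) / consistency) if len(rwin) > 1 else 0.0
    else:
        evar = np.var(rfit, ddof=1) if len(rfit) > 1 else 0.0
    tri_df = np.mean(special.polygamma(1, df[ok] / 2.0))
    vt = evar - tri_df
    if vt > 0:
        df_prior_scalar = float(2.0 * _trigamma_inverse(vt)[0])
    else:
        df_prior_scalar = np.inf
        # observed log-dispersions are under-dispersed relative to a
        # chi-square on the nominal df: moment-match an effective residual
        # df so the bias correction of the prior trend stays calibrated
        if evar > 0:
            mean_df = float(np.mean(df[ok]))
            df_eff = float(2.0 * _trigamma_inverse(evar)[0])
            delta = (
                special.digamma(mean_df / 2.0) - np.log(mean_df / 2.0)
            ) - (special.digamma(df_eff / 2.0) - np.log(df_eff / 2.0))
            emean = emean + delta

    if np.isfinite(df_prior_scalar):
        s2_prior = np.exp(
            emean + special.digamma(df_prior_scalar / 2.0)
            - np.log(df_prior_scalar / 2.0)
        )
    else:
        s2_prior = np.exp(emean)

    df_prior = np.full(G, df_prior_scalar)
    if robust and np.isfinite(df_prior_scalar):
        hi_lim = np.quantile(rfit, winsor[1])
        excess = np.clip(resid - hi_lim, 0.0, None)
        excess[~np.isfinite(excess)] = 0.0
        df_prior = df_prior_scalar * np.exp(-excess)
        df_prior = np.maximum(df_prior, 1.0)

    with np.errstate(invalid="ignore"):
        s2_post = np.where(
            np.isfinite(df_prior),
            (df_prior * s2_prior + df * s2_floor) / (df_prior + df),
            s2_prior,
        )
    s2_post = np.where(ok, s2_post, s2_prior)
    return s2_post, s2_prior, df_prior


@dataclass
class QLFit:
    """Per-gene NB GLM fit with quasi-likelihood dispersions."""

    coefficients: np.ndarray      # (G, p), natural-log scale
    fitted: np.ndarray            # (G, n)
    deviance: np.ndarray          # (G,)
    df_residual: np.ndarray       # (G,)
    s2_raw: np.ndarray
    s2_post: np.ndarray
    s2_prior: np.ndarray
    df_prior: np.ndarray
    dispersion: np.ndarray        # trended NB dispersion used in the fit
    design: np.ndarray = field(repr=False)
    design_names: list = field(default_factory=list)
    offset: np.ndarray = field(default=None, repr=False)
    ave_log_cpm: np.ndarray = field(default=None, repr=False)
    gene_names: np.ndarray = field(default=None, repr=False)
    counts: np.ndarray = field(default=None, repr=False)

    def ql_dispersion_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "ave_log_cpm": self.ave_log_cpm,
                "raw": self.s2_raw,
                "trend": self.s2_prior,
                "squeezed": self.s2_post,
            }
        )
        if self.gene_names is not None:
            df.insert(0, "gene", self.gene_names)
        return df


def ql_fit(
    counts,
    design,
    disp: "DispersionFit | np.ndarray | float",
    robust: bool = True,
    offset=None,
    lib_size=None,
    norm_factors=None,
    gene_names=None,
) -> QLFit:
    """Fit per-gene NB GLMs at the trended dispersion and squeeze the QL
    dispersions toward their abundance trend."""
    y, X, offset = _resolve_inputs(counts, design, offset, lib_size, norm_factors)
    from .pseudobulk import PseudobulkSet
    from .spline_design import TimecourseDesign

    names = None
    if isinstance(design, TimecourseDesign):
        names = list(design.matrix.columns)
    elif isinstance(design, pd.DataFrame):
        names = list(design.columns)
    if names is None:
        names = [f"coef{k}" for k in range(X.shape[1])]
    if gene_names is None and isinstance(counts, PseudobulkSet):
        gene_names = counts.genes["symbol"].to_numpy()

    G, n = y.shape
    p = X.shape[1]
    if isinstance(disp, DispersionFit):
        phi = np.asarray(disp.trended_dispersion, float)
        alc = disp.ave_log_cpm
    else:
        phi = np.broadcast_to(np.asarray(disp, float), (G,)).astype(float)
        alc = ave_log_cpm(y, np.exp(offset))

    beta, mu, dev, converged = fit_glm(y, X, offset, phi)
    if not converged.all():
        warnings.warn(
            f"{int((~converged).sum())} gene fits did not fully converge",
            stacklevel=2,
        )
    # residual df, discounting samples whose fitted value is effectively
    # zero (they contribute no information to the deviance)
    n_zero = (mu < 1e-4).sum(axis=1)
    df_resid = np.maximum(n - p - n_zero, 0).astype(float)
    # deviance calibrated by its expected unit value under the fitted model
    # (finite-count NB deviances run above chi-square expectation)
    cbar = expected_unit_deviance(mu, phi[:, None]).mean(axis=1)
    cbar = np.maximum(cbar, 1e-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2_raw = np.where(
            df_resid > 0, dev / cbar / np.maximum(df_resid, 1), np.nan
        )
    s2_post, s2_prior, df_prior = squeeze_var(
        s2_raw, df_resid, covariate=alc, robust=robust
    )
    return QLFit(
        coefficients=beta,
        fitted=mu,
        deviance=dev,
        df_residual=df_resid,
        s2_raw=s2_raw,
        s2_post=s2_post,
        s2_prior=s2_prior,
        df_prior=df_prior,
        dispersion=phi,
        design=X,
        design_names=names,
        offset=offset,
        ave_log_cpm=alc,
        gene_names=gene_names,
        counts=y,
    )


# ---------------------------------------------------------------------------
# Testing and multiplicity control
# ---------------------------------------------------------------------------

def _coef_indices(fit: QLFit, coefs) -> np.ndarray:
    if np.isscalar(coefs) or isinstance(coefs, str):
        coefs = [coefs]
    idx = []
    for c in coefs:
        if isinstance(c, str):
            if c not in fit.design_names:
                raise ValueError(f"unknown coefficient {c!r}")
            idx.append(fit.design_names.index(c))
        else:
            idx.append(int(c))
    idx = np.asarray(idx)
    if (idx == 0).any() or ("(Intercept)" in fit.design_names and
                            any(fit.design_names[i] == "(Intercept)" for i in idx)):
        raise ValueError("cannot test the intercept")
    if (idx < 0).any() or (idx >= fit.design.shape[1]).any():
        raise ValueError("coefficient index out of range")
    return idx


def ql_f_test(fit: QLFit, coefs) -> pd.DataFrame:
    """Quasi-likelihood F-test for dropping the given coefficients.

    Returns a DataFrame with the tested coefficients in log2 units
    (``logFC.<name>``), average abundance, F statistic, PValue and
    Benjamini-Hochberg FDR, indexed by gene.
    """
    idx = _coef_indices(fit, coefs)
    r = len(idx)
    keep = np.setdiff1d(np.arange(fit.design.shape[1]), idx)
    X0 = fit.design[:, keep]
    _, _, dev0, _ = fit_glm(fit.counts, X0, fit.offset, fit.dispersion)
    num = np.maximum(dev0 - fit.deviance, 0.0) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / fit.s2_post
    F = np.where(np.isfinite(F), F, 0.0)
    df2 = fit.df_residual + np.minimum(fit.df_prior, 1e8)
    pvals = stats.f.sf(F, r, np.maximum(df2, 1e-8))
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    cols = {}
    for i in idx:
        cols[f"logFC.{fit.design_names[i]}"] = fit.coefficients[:, i] / LOG2
    cols["logCPM"] = fit.ave_log_cpm
    cols["F"] = F
    cols["PValue"] = pvals
    cols["FDR"] = bh_adjust(pvals)
    index = (
        pd.Index(fit.gene_names, name="gene")
        if fit.gene_names is not None
        else pd.RangeIndex(len(F), name="gene")
    )
    return pd.DataFrame(cols, index=index)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def decide_tests(result: pd.DataFrame, alpha: float = 0.05,
                 return_labels: bool = False):
    """Classify genes at the FDR threshold.

    With a single tested coefficient the significant genes are split by
    coefficient sign into Up/Down; with several, they are labelled Sig.
    Returns a Series of counts by default, or per-gene labels with
    ``return_labels=True``.
    """
    lfc_cols = [c for c in result.columns if c.startswith("logFC.")]
    sig = result["FDR"].to_numpy() < alpha if len(result) else np.array([], bool)
    if len(lfc_cols) == 1 and len(result):
        sign_up = result[lfc_cols[0]].to_numpy() > 0
        labels = np.where(sig, np.where(sign_up, "Up", "Down"), "NotSig")
        cats = ["Down", "NotSig", "Up"]
    else:
        labels = np.where(sig, "Sig", "NotSig") if len(result) else np.array([])
        cats = ["NotSig", "Sig"]
    labels = pd.Series(labels, index=result.index, name="decision")
    if return_labels:
        return labels
    counts = labels.value_counts().reindex(cats, fill_value=0)
    counts.name = "n"
    return counts


def top_table(result: pd.DataFrame, n: "int | None" = 10) -> pd.DataFrame:
    """Rows sorted by ascending PValue; ties broken by larger F, then gene
    name — a deterministic ordering."""
    df = result.copy()
    df["_name"] = df.index.astype(str)
    df = df.sort_values(
        ["PValue", "F", "_name"], ascending=[True, False, True], kind="stable"
    ).drop(columns="_name")
    if n is not None:
        df = df.head(n)
    return df


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------

class NBQLModel:
    """NB quasi-likelihood time-course model for pseudo-bulk counts.

    Parameters
    ----------
    counts : PseudobulkSet or (G, n) array
    design : TimecourseDesign, DataFrame or (n, p) array
    lib_size, norm_factors : optional explicit library sizes / TMM factors
        when ``counts`` is a plain array.

    Examples
    --------
    >>> model = NBQLModel.from_pseudobulk(pb, design)   # doctest: +SKIP
    >>> res = model.fit(robust=True)                    # doctest: +SKIP
    >>> res.f_test(["Z1", "Z2", "Z3"]).head()           # doctest: +SKIP
    """

    def __init__(self, counts, design, lib_size=None, norm_factors=None,
                 gene_names=None):
        self.counts = counts
        self.design = design
        self.lib_size = lib_size
        self.norm_factors = norm_factors
        self.gene_names = gene_names

    @classmethod
    def from_pseudobulk(cls, pb, design) -> "NBQLModel":
        return cls(pb, design, gene_names=pb.genes["symbol"].to_numpy())

    def fit(self, robust: bool = True,
            dispersion: "DispersionFit | None" = None,
            **disp_kwargs) -> "NBQLResults":
        if dispersion is None:
            dispersion = estimate_dispersions(
                self.counts, self.design,
                lib_size=self.lib_size, norm_factors=self.norm_factors,
                **disp_kwargs,
            )
        fit = ql_fit(
            self.counts, self.design, dispersion, robust=robust,
            lib_size=self.lib_size, norm_factors=self.norm_factors,
            gene_names=self.gene_names,
        )
        return NBQLResults(self, dispersion, fit)


class NBQLResults:
    """Fitted NB QL model: dispersions, coefficients and tests."""

    def __init__(self, model: NBQLModel, dispersion: DispersionFit, fit: QLFit):
        self.model = model
        self.dispersion = dispersion
        self.fit = fit

    # statsmodels-style attribute access
    @property
    def params(self) -> np.ndarray:
        return self.fit.coefficients

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.fit.fitted

    @property
    def common_bcv(self) -> float:
        return float(np.sqrt(self.dispersion.common_dispersion))

    def f_test(self, coefs) -> pd.DataFrame:
        return ql_f_test(self.fit, coefs)

    def decide(self, coefs, alpha: float = 0.05, return_labels=False):
        return decide_tests(self.f_test(coefs), alpha, return_labels)

    def summary(self) -> str:
        G, n = self.fit.counts.shape
        p = self.fit.design.shape[1]
        dfp = self.fit.df_prior
        dfp_txt = (
            "Inf" if not np.isfinite(dfp).any()
            else f"{np.nanmedian(dfp[np.isfinite(dfp)]):.2f}"
        )
        lines = [
            "NB quasi-likelihood time-course fit",
            "=" * 44,
            f"genes: {G}    samples: {n}    coefficients: {p}",
            f"common dispersion: {self.dispersion.common_dispersion:.4f}"
            f"  (BCV {self.common_bcv:.3f})",
            f"trended dispersion range: "
            f"[{self.dispersion.trended_dispersion.min():.4f}, "
            f"{self.dispersion.trended_dispersion.max():.4f}]",
            f"QL dispersion (squeezed) median: "
            f"{np.nanmedian(self.fit.s2_post):.3f}",
            f"prior df (median): {dfp_txt}",
            f"residual df: {int(np.max(self.fit.df_residual))} (max per gene)",
        ]
        return "\n".join(lines)
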