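"""Post-test summaries: trend direction, fitted curves, heatmap matrix and
gene-set average trends.

The sign of the Z1 coefficient (the orthonormalized linear-pseudotime
covariate) classifies each gene's overall direction along pseudotime.
Fitted expression curves are predicted from the raw-basis fit
([1, X, group dummies]) on a grid of 100 evenly spaced pseudotimes: the
group effects are averaged (with the reference group contributing zero)
and the linear predictor converted to a population-level log2 CPM via
(eta + ln 1e6)/ln 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .nbql import LOG2, QLFit
from .spline_design import NaturalSplineBasis

__all__ = [
    "classify_trend",
    "fitted_curves",
    "heatmap_matrix",
    "geneset_average_trend",
]


def classify_trend(result: pd.DataFrame, coef: str = "logFC.Z1") -> pd.Series:
    """Label each tested gene Up (coefficient > 0) or Down (<= 0)."""
    if coef not in result.columns:
        raise ValueError(f"result has no column {coef!r}")
    vals = result[coef].to_numpy()
    return pd.Series(
        np.where(vals > 0, "Up", "Down"), index=result.index, name="trend"
    )


def fitted_curves(
    raw_fit: QLFit,
    basis: NaturalSplineBasis,
    pseudotime,
    genes,
    n_points: int = 100,
) -> pd.DataFrame:
    """Predicted log2-CPM expression curves along pseudotime.

    ``raw_fit`` must be a QL fit on the raw-basis design
    [(Intercept), X1..Xdf, group dummies]. For each requested gene the
    linear predictor on the grid is

        intercept + mean(0, group effects) + X(new) @ spline coefficients

    and the curve is reported as (eta + ln 1e6)/ln 2, i.e. log2 CPM without
    a library-size offset (population-level CPM convention).

    Returns a long DataFrame with columns ``gene``, ``pseudotime``,
    ``log2_cpm``; the grid spans [min, max] of the observed pseudotimes.
    """
    t = np.asarray(pseudotime, float)
    grid = np.linspace(t.min(), t.max(), n_points)
    X_new = basis.evaluate(grid)
    df = basis.df
    names = raw_fit.design_names
    x_cols = [i for i, nm in enumerate(names) if nm.startswith("X")]
    if len(x_cols) != df:
        raise ValueError("raw_fit design does not contain the spline columns X1..Xdf")
    group_cols = [
        i
        for i, nm in enumerate(names)
        if i != 0 and i not in x_cols
    ]
    if raw_fit.gene_names is None:
        raise ValueError("raw_fit carries no gene names")
    name_to_row = {g: i for i, g in enumerate(raw_fit.gene_names)}
    rows = []
    for g in genes:
        if g not in name_to_row:
            raise KeyError(f"gene {g!r} absent from fit")
        beta = raw_fit.coefficients[name_to_row[g]]
        avg_intercept = beta[0] + np.mean(
            np.concatenate([[0.0], beta[group_cols]])
        )
        eta = avg_intercept + X_new @ beta[x_cols]
        log2cpm = (eta + np.log(1e6)) / LOG2
        rows.append(
            pd.DataFrame({"gene": g, "pseudotime": grid, "log2_cpm": log2cpm})
        )
    return pd.concat(rows, ignore_index=True)


def heatmap_matrix(
    logcpm: pd.DataFrame,
    up_genes,
    down_genes,
    sample_order=None,
) -> pd.DataFrame:
    """Row-standardized expression of the top up/down genes.

    Rows are the up genes followed by the down genes; columns are samples
    (in ascending-pseudotime order if ``sample_order`` is given). Each row
    is centred to mean 0 and scaled to SD 1 (denominator n-1). Constant
    rows cannot be standardized and are rejected.
    """
    genes = list(up_genes) + list(down_genes)
    missing = [g for g in genes if g not in logcpm.index]
    if missing:
        raise KeyError(f"genes absent from log-CPM matrix: {missing[:5]}")
    z = logcpm.loc[genes]
    if sample_order is not None:
        z = z[list(sample_order)]
    vals = z.to_numpy(float)
    sd = vals.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = [genes[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant expression rows cannot be standardized: {bad[:5]}")
    out = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(out, index=z.index, columns=z.columns)


def geneset_average_trend(
    logcpm: pd.DataFrame,
    gene_set,
    pseudotime,
    span: float = 2.0 / 3.0,
) -> pd.DataFrame:
    """Average log-CPM of a gene set per sample, with a lowess smooth.

    Members absent from the matrix are ignored. Returns a DataFrame with
    columns ``pseudotime``, ``mean_log_cpm`` and ``smooth`` ordered by
    pseudotime — the pathway-level trend diagnostic.
    """
    members = [g for g in gene_set if g in logcpm.index]
    if not members:
        raise ValueError("no gene-set member present in the log-CPM matrix")
    t = np.asarray(pseudotime, float)
    avg = logcpm.loc[members].to_numpy(float).mean(axis=0)
    order = np.argsort(t, kind="stable")
    sm = lowess(avg[order], t[order], frac=span, return_sorted=True)
    smooth = np.interp(t, sm[:, 0], sm[:, 1])
    return pd.DataFrame(
        {
            "sample": logcpm.columns,
            "pseudotime": t,
            "mean_log_cpm": avg,
            "smooth": smooth,
        }
    ).sort_values("pseudotime", kind="stable", ignore_index=True)
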