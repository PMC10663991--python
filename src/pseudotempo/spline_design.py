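"""Pseudotime spline design: natural cubic basis, QR re-parametrization,
sample blocking.

Gene expression is modelled as a smooth function of pseudotime via a
natural cubic spline with ``df`` basis functions (default 3). The raw basis
columns have no individual interpretation, so the design is re-parametrized:
the columns of ``A = [1, t, X]`` are orthonormalized in order
(Gram-Schmidt, equivalently QR with a positive-diagonal sign convention)
and the intercept direction dropped. The first resulting covariate is then
exactly the centred, normalized pseudotime,

    Z1 = (t - mean t) / ||t - mean t||,

so its coefficient measures the linear trend along pseudotime, while Z2,
Z3... capture orthogonal curvature. Because the natural-spline space plus
an intercept already contains every linear function, A has rank df+1 (not
df+2); the trailing dependent direction is discarded during
orthonormalization.

Knot placement: for df basis functions, df-1 internal knots at equally
spaced quantiles of the observed pseudotimes (linear-interpolation quantile
definition) and boundary knots at the min/max. Evaluation outside the
boundary knots extrapolates linearly (the natural constraint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "NaturalSplineBasis",
    "TimecourseDesign",
    "natural_spline_basis",
    "orthonormal_time_design",
    "build_design",
    "build_raw_design",
]


@dataclass
class NaturalSplineBasis:
    """Natural cubic spline basis evaluated at the training pseudotimes.

    The construction matches the classical natural-spline recipe: a cubic
    B-spline basis on the augmented knot vector, the intercept column
    dropped, then projection onto the null space of the second-derivative
    constraints at the two boundary knots.
    """

    df: int
    internal_knots: np.ndarray
    boundary_knots: tuple[float, float]
    X: np.ndarray = field(repr=False)
    _aug_knots: np.ndarray = field(repr=False)
    _projector: np.ndarray = field(repr=False)

    def evaluate(self, new_t) -> np.ndarray:
        """Evaluate the basis at new pseudotimes (linear extrapolation
        beyond the boundary knots)."""
        x = np.atleast_1d(np.asarray(new_t, float))
        lo, hi = self.boundary_knots
        nb = len(self._aug_knots) - 4
        B = np.zeros((len(x), nb))
        inside = (x >= lo) & (x <= hi)
        if inside.any():
            B[inside] = BSpline.design_matrix(
                x[inside], self._aug_knots, 3
            ).toarray()
        for bnd, out in ((lo, x < lo), (hi, x > hi)):
            if out.any():
                for j in range(nb):
                    c = np.zeros(nb)
                    c[j] = 1.0
                    spj = BSpline(self._aug_knots, c, 3)
                    B[out, j] = spj(bnd) + spj.derivative(1)(bnd) * (x[out] - bnd)
        return B[:, 1:] @ self._projector


def natural_spline_basis(t, df: int = 3) -> NaturalSplineBasis:
    """Build a natural cubic spline basis with df columns (no intercept)."""
    t = np.asarray(t, float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if len(np.unique(t)) < df + 1:
        raise ValueError(
            f"need at least {df + 1} distinct pseudotimes for df={df}"
        )
    n_internal = df - 1
    probs = np.linspace(0, 1, n_internal + 2)[1:-1]
    internal = np.quantile(t, probs, method="linear") if n_internal else np.array([])
    lo, hi = float(t.min()), float(t.max())
    aug = np.sort(
        np.concatenate([np.repeat(lo, 4), internal, np.repeat(hi, 4)])
    )
    nb = len(aug) - 4
    # second-derivative constraints at the boundary knots
    C = np.zeros((2, nb))
    for j in range(nb):
        c = np.zeros(nb)
        c[j] = 1.0
        spj = BSpline(aug, c, 3)
        C[0, j] = spj.derivative(2)(lo)
        C[1, j] = spj.derivative(2)(hi)
    # drop the intercept column BEFORE projecting onto the constraint null
    # space (order matters for the exact basis values)
    C1 = C[:, 1:]
    Q, _ = np.linalg.qr(C1.T, mode="complete")
    projector = Q[:, 2:]
    basis = NaturalSplineBasis(
        df=df,
        internal_knots=np.asarray(internal, float),
        boundary_knots=(lo, hi),
        X=np.empty((0, df)),
        _aug_knots=aug,
        _projector=projector,
    )
    basis.X = basis.evaluate(t)
    return basis


def _gram_schmidt(A: np.ndarray, tol: float = 1e-9) -> tuple[np.ndarray, int]:
    """Orthonormalize columns in order, dropping dependent ones.

    Equivalent to QR with the sign convention that the R diagonal is
    positive, which removes implementation-dependent sign flips.
    """
    Qcols: list[np.ndarray] = []
    for k in range(A.shape[1]):
        v = A[:, k].astype(float).copy()
        norm0 = np.linalg.norm(v)
        for q in Qcols:
            v -= (q @ A[:, k]) * q
        # second pass for numerical stability (modified Gram-Schmidt twice)
        for q in Qcols:
            v -= (q @ v) * q
        nv = np.linalg.norm(v)
        if norm0 > 0 and nv > tol * norm0:
            Qcols.append(v / nv)
    Q = np.column_stack(Qcols) if Qcols else np.empty((A.shape[0], 0))
    return Q, Q.shape[1]


def orthonormal_time_design(t, df: int = 3, basis: "NaturalSplineBasis | None" = None):
    """Orthonormalized pseudotime covariates Z1..Zdf.

    Forms ``A = [1, t, X]`` with X the natural-spline basis, orthonormalizes
    the columns in order and drops the intercept direction. Returns
    ``(Z, basis)`` where Z is n x df with Z1 equal to the centred,
    normalized pseudotime exactly.
    """
    t = np.asarray(t, float)
    if basis is None:
        basis = natural_spline_basis(t, df=df)
    A = np.column_stack([np.ones_like(t), t, basis.evaluate(t)])
    Q, rank = _gram_schmidt(A)
    if rank < basis.df + 1:
        raise ValueError(
            f"design [1, t, X] has rank {rank}; need {basis.df + 1} to form "
            f"{basis.df} orthonormal time covariates"
        )
    Z = Q[:, 1 : basis.df + 1]
    return Z, basis


@dataclass
class TimecourseDesign:
    """Full design [intercept | Z1..Zdf | group treatment contrasts]."""

    matrix: pd.DataFrame
    time_columns: list[str]
    group_columns: list[str]
    reference_group: str

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(float)

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index=False)


def _group_dummies(group_labels, reference_group=None):
    labels = pd.Series(group_labels).astype(str)
    if isinstance(group_labels, pd.Series) and isinstance(
        group_labels.dtype, pd.CategoricalDtype
    ):
        levels = [str(level) for level in group_labels.cat.categories]
    else:
        levels = list(pd.unique(labels))
    if reference_group is not None:
        reference_group = str(reference_group)
        if reference_group not in levels:
            raise ValueError(f"reference group {reference_group!r} not among levels")
        levels = [reference_group] + [g for g in levels if g != reference_group]
    counts = labels.value_counts()
    empty = [g for g in levels if counts.get(g, 0) == 0]
    if empty:
        raise ValueError(f"group level(s) with zero members: {empty}")
    ref = levels[0]
    cols = {g: (labels == g).astype(float).to_numpy() for g in levels[1:]}
    return cols, ref


def build_design(Z: np.ndarray, group_labels, reference_group=None) -> TimecourseDesign:
    """Assemble [(Intercept), Z1..Zdf, non-reference group indicators].

    The reference group (first factor level, the earliest developmental
    stage by convention) is absorbed into the intercept via treatment
    contrasts.
    """
    Z = np.asarray(Z, float)
    n, df = Z.shape
    data = {"(Intercept)": np.ones(n)}
    zcols = [f"Z{k+1}" for k in range(df)]
    for k, name in enumerate(zcols):
        data[name] = Z[:, k]
    dummies, ref = _group_dummies(group_labels, reference_group)
    for g, col in dummies.items():
        data[g] = col
    mat = pd.DataFrame(data)
    if np.linalg.matrix_rank(mat.to_numpy()) < mat.shape[1]:
        raise ValueError("full design matrix is rank deficient")
    return TimecourseDesign(
        matrix=mat,
        time_columns=zcols,
        group_columns=list(dummies),
        reference_group=ref,
    )


def build_raw_design(
    basis: NaturalSplineBasis, t, group_labels, reference_group=None
) -> TimecourseDesign:
    """Raw-basis design [(Intercept), X1..Xdf, group indicators].

    Spans the same column space as the orthonormalized design but keeps the
    spline coefficients directly usable for curve prediction at new
    pseudotimes.
    """
    X = basis.evaluate(np.asarray(t, float))
    n, df = X.shape
    data = {"(Intercept)": np.ones(n)}
    xcols = [f"X{k+1}" for k in range(df)]
    for k, name in enumerate(xcols):
        data[name] = X[:, k]
    dummies, ref = _group_dummies(group_labels, reference_group)
    for g, col in dummies.items():
        data[g] = col
    mat = pd.DataFrame(data)
    return TimecourseDesign(
        matrix=mat,
        time_columns=xcols,
        group_columns=list(dummies),
        reference_group=ref,
    )
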