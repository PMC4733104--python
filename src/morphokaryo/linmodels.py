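"""Multivariate linear-model machinery shared by the statistical modules.

Design-matrix construction with named columns, least-squares fits, Wilks'
Lambda with Rao's F approximation, and residual randomization (RRPP) for
comparing nested multivariate models.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "design_intercept",
    "design_continuous",
    "design_factor",
    "design_interaction",
    "DesignMatrix",
    "check_full_rank",
    "fit_ols",
    "wilks_lambda",
    "rao_f",
    "rrpp_compare",
]


class DesignMatrix:
    """A design matrix with column names, buildable by concatenation."""

    def __init__(self, columns: np.ndarray, names: list[str]):
        columns = np.asarray(columns, dtype=float)
        if columns.ndim != 2 or columns.shape[1] != len(names):
            raise ValueError("column count does not match names")
        self.x = columns
        self.names = list(names)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def hstack(self, other: "DesignMatrix") -> "DesignMatrix":
        return DesignMatrix(np.hstack([self.x, other.x]), self.names + other.names)


def design_intercept(n: int) -> DesignMatrix:
    return DesignMatrix(np.ones((n, 1)), ["intercept"])


def design_continuous(values, name: str) -> DesignMatrix:
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    return DesignMatrix(v, [name])


def design_factor(labels, name: str, drop_first: bool = True) -> DesignMatrix:
    """Treatment-coded dummies for a categorical factor."""
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    keep = levels[1:] if drop_first else levels
    cols = np.column_stack([(labels == lv).astype(float) for lv in keep]) if keep else \
        np.empty((len(labels), 0))
    return DesignMatrix(cols, [f"{name}[{lv}]" for lv in keep])


def design_interaction(a: DesignMatrix, b: DesignMatrix) -> DesignMatrix:
    cols, names = [], []
    for i, ni in enumerate(a.names):
        for j, nj in enumerate(b.names):
            cols.append(a.x[:, i] * b.x[:, j])
            names.append(f"{ni}:{nj}")
    return DesignMatrix(np.column_stack(cols), names)


def check_full_rank(design: DesignMatrix, tol: float = 1e-8) -> None:
    """Raise on collinear designs, naming the aliased columns."""
    from scipy.linalg import qr

    if design.x.shape[1] == 0:
        return
    _, r, piv = qr(design.x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    thresh = tol * max(diag.max(), 1.0)
    rank = int(np.sum(diag > thresh))
    if rank < design.x.shape[1]:
        aliased = [design.names[p] for p in piv[rank:]]
        raise ValueError(f"collinear design matrix; aliased columns: {aliased}")


def fit_ols(y: np.ndarray, x: np.ndarray):
    """Least squares fit; returns (coefficients, fitted, residuals)."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    return beta, fitted, y - fitted


def wilks_lambda(e: np.ndarray, h: np.ndarray) -> float:
    """Wilks' Lambda = det(E) / det(E + H) via slogdet for stability."""
    s_e, ld_e = np.linalg.slogdet(e)
    s_eh, ld_eh = np.linalg.slogdet(e + h)
    if s_e <= 0 or s_eh <= 0:
        raise np.linalg.LinAlgError("singular error matrix in Wilks' Lambda")
    return float(np.exp(ld_e - ld_eh))


def rao_f(lmbda: float, p: int, q: int, v: int):
    """Rao's F approximation for Wilks' Lambda.

    p: number of response variables; q: hypothesis degrees of freedom;
    v: error degrees of freedom.  Returns (F, df1, df2, p_value).
    """
    if p * p + q * q - 5 > 0:
        s = np.sqrt((p * p * q * q - 4) / (p * p + q * q - 5))
    else:
        s = 1.0
    df1 = p * q
    df2 = s * (v - (p - q + 1) / 2) - (p * q - 2) / 2
    if df2 <= 0:
        raise ValueError(
            f"error degrees of freedom too small for Rao's F (p={p}, q={q}, v={v})"
        )
    lam_s = lmbda ** (1.0 / s)
    f = (1 - lam_s) / lam_s * (df2 / df1)
    pval = float(stats.f.sf(f, df1, df2))
    return float(f), int(df1), float(df2), pval


def _sse(y: np.ndarray, q: np.ndarray) -> float:
    """Residual sum of squares (trace) after projecting onto span(Q)."""
    return float(np.sum(y * y) - np.sum((q.T @ y) ** 2))


def rrpp_compare(
    y: np.ndarray,
    x_full: DesignMatrix,
    x_reduced: DesignMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
):
    """Residual randomization test of a full vs nested reduced model.

    The observed statistic is the multivariate (trace-based) F for the extra
    term(s).  The null distribution randomizes reduced-model residuals,
    adds them back to the reduced-model fitted values, and refits both
    models.  Returns (F, Z, p, df), with Z the position of the observed F in
    the permuted distribution in standard-deviation units and the p-value
    including the observed statistic in the null set.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    check_full_rank(x_full)
    full_names = set(x_full.names)
    if not set(x_reduced.names) <= full_names:
        raise ValueError("reduced model is not nested in the full model")
    df_f = np.linalg.matrix_rank(x_full.x)
    df_r = np.linalg.matrix_rank(x_reduced.x)
    if df_f <= df_r:
        raise ValueError("full model adds no estimable terms beyond the reduced model")
    if n <= df_f:
        raise ValueError("more parameters than specimens")
    q_f = np.linalg.qr(x_full.x)[0]
    q_r = np.linalg.qr(x_reduced.x)[0]

    _, fitted_r, resid_r = fit_ols(y, x_reduced.x)

    def f_stat(yy: np.ndarray) -> float:
        sse_f = _sse(yy, q_f)
        sse_r = _sse(yy, q_r)
        return ((sse_r - sse_f) / (df_f - df_r)) / (sse_f / (n - df_f))

    f_obs = f_stat(y)
    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        f_perm[b] = f_stat(fitted_r + resid_r[perm])
    p = (np.sum(f_perm >= f_obs) + 1) / (n_perm + 1)
    sd = f_perm.std(ddof=1)
    z = (f_obs - f_perm.mean()) / sd if sd > 0 else np.nan
    return f_obs, float(z), float(p), (int(df_f - df_r), int(n - df_f))
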