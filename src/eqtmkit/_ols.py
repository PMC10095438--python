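"""Vectorized ordinary-least-squares across many response vectors.

Both the per-CpG methylation test and the per-gene expression test regress
thousands of responses on the same design matrix, so the normal equations are
solved once and reused.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["check_full_rank", "ols_coef_t_p"]


def check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise ValueError naming collinear columns if X is rank-deficient."""
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full relative rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or names}"
        )


def ols_coef_t_p(
    X: np.ndarray, Y: np.ndarray, coef_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit Y[i] ~ X for every row i of Y; test one coefficient.

    Parameters
    ----------
    X : (n_samples, p) design matrix, full rank, intercept included.
    Y : (n_responses, n_samples) response matrix.
    coef_index : column of X whose coefficient is tested (two-sided t).

    Returns
    -------
    coef, t, p, degenerate : arrays of length n_responses.  ``degenerate``
    marks responses with (numerically) zero residual variance, whose t and p
    are NaN.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    if Y.shape[1] != n:
        raise ValueError(f"Y has {Y.shape[1]} samples, X has {n}")
    if n <= p:
        raise ValueError(f"need more samples ({n}) than parameters ({p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = xtx_inv @ X.T                      # (p, n)
    B = Y @ proj.T                            # (m, p)
    resid = Y - B @ X.T
    dof = n - p
    rss = np.einsum("ij,ij->i", resid, resid)
    # scale-aware zero-variance cutoff
    scale = np.maximum(np.einsum("ij,ij->i", Y, Y), 1.0)
    degenerate = rss <= scale * 1e-24
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * xtx_inv[coef_index, coef_index])
    coef = B[:, coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    pval = 2.0 * stats.t.sf(np.abs(t), dof)
    t = np.where(degenerate, np.nan, t)
    pval = np.where(degenerate, np.nan, pval)
    return coef, t, pval, degenerate
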