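"""RNA-seq count handling: filtering, normalization, differential expression.

The differential-expression step is a log-linear OLS surrogate for a
negative-binomial model: normalized counts are log2(x+1)-transformed and
regressed on [intercept, group, covariates] per gene.  At whole-cohort
sample sizes this provides the property that matters downstream — nominal
type-I error control — without dispersion shrinkage machinery.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from ._ols import check_full_rank, ols_coef_t_p
from .methylation import DesignSpec, bh_fdr, build_design

logger = logging.getLogger(__name__)


def filter_expressed(counts: pd.DataFrame, min_nonzero_frac: float = 0.90) -> pd.DataFrame:
    """Keep genes with a non-zero count in at least ``min_nonzero_frac`` of samples.

    The threshold is ceil(min_nonzero_frac · n_samples), so a gene exactly at
    the boundary is kept.  Row order is preserved.
    """
    n = counts.shape[1]
    need = math.ceil(min_nonzero_frac * n)
    keep = (counts > 0).sum(axis=1) >= need
    return counts.loc[keep]


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Ratios are taken against the per-gene geometric mean over genes with
    all-nonzero counts.  If no such gene exists, total-count scaling is used
    instead (logged).
    """
    X = counts.to_numpy(dtype=float)
    all_nonzero = (X > 0).all(axis=1)
    if all_nonzero.any():
        logX = np.log(X[all_nonzero])
        log_geo = logX.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logX - log_geo, axis=0))
    else:
        logger.warning("no gene with all-nonzero counts; total-count scaling")
        totals = X.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total count")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    sf = pd.Series(factors, index=counts.columns, name="size_factor")
    return counts / sf, sf


def log_transform(normalized: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1)."""
    if (normalized.to_numpy() < 0).any():
        raise ValueError("negative values in normalized matrix")
    return np.log2(normalized + 1.0)


def de_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    design: DesignSpec = DesignSpec(),
) -> pd.DataFrame:
    """Per-gene differential expression between groups, covariate-adjusted.

    Counts are size-factor normalized and log2(x+1)-transformed, then each
    gene is fit by OLS on [intercept, group, covariates]; the group
    coefficient is the adjusted log2 fold change (case vs control).  BH FDR
    across all genes.  Sorted by p-value.
    """
    norm, _ = normalize_counts(counts)
    Y = log_transform(norm)
    samples = samples.loc[counts.columns]
    X, _names = build_design(samples, design)
    coef, t, p, degen = ols_coef_t_p(X, Y.to_numpy(), coef_index=1)
    if degen.any():
        logger.warning("%d genes with zero residual variance flagged", degen.sum())
    out = pd.DataFrame(
        {
            "log2_fold_change": coef,
            "t_stat": t,
            "p_value": p,
            "fdr": bh_fdr(p),
            "degenerate": degen,
        },
        index=counts.index.rename("gene_id"),
    )
    return out.sort_values("p_value", kind="stable")


def residualize(log_expr: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Remove covariate effects per gene; keep the gene mean.

    ``covariates`` is a samples × covariates numeric frame (group must NOT
    be among them: the group signal is what network analysis should keep).
    OLS residuals against [intercept, covariates] with the gene mean added
    back, so the result stays on the expression scale.
    """
    C = covariates.loc[log_expr.columns].to_numpy(dtype=float)
    X = np.column_stack([np.ones(C.shape[0]), C])
    check_full_rank(X, ["intercept", *covariates.columns])
    Y = log_expr.to_numpy(dtype=float)
    beta_hat = np.linalg.lstsq(X, Y.T, rcond=None)[0]
    resid = Y - (X @ beta_hat).T
    resid += Y.mean(axis=1, keepdims=True)
    return pd.DataFrame(resid, index=log_expr.index, columns=log_expr.columns)
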