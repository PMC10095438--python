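"""Per-CpG differential methylation and cell-composition utilities.

Implements the EWAS stage of the pipeline: a covariate-adjusted linear model
per CpG with Benjamini-Hochberg FDR, the beta/M-value transform, promoter
annotation (5'UTR, first exon, or 1500 bp upstream of the TSS), and a
reference-based constrained-projection estimate of blood cell-type fractions
(Houseman-style deconvolution, simplified).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.stats.multitest import multipletests

from ._ols import check_full_rank, ols_coef_t_p

logger = logging.getLogger(__name__)

#: canonical blood cell types, in reference-column order
CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")

#: gene-region feature vocabulary for CpG annotation
FEATURES = ("TSS1500", "5UTR", "1stExon", "Body", "3UTR", "IGR")

_EPS = 1e-6


@dataclass(frozen=True)
class DesignSpec:
    """Model specification for the per-CpG test.

    ``response_scale`` is "beta" (default: normalized β values) or "m_value".
    ``covariates`` is an ordered subset of {"age", "sex", "cell_fractions"};
    the group indicator (case=1) is always included.  Only five of the six
    cell fractions enter the design: the fractions sum to one, so the sixth
    (granulocytes, the reference type) is dropped to keep the design full
    rank.
    """

    response_scale: str = "beta"
    covariates: tuple[str, ...] = ("age", "sex", "cell_fractions")

    def __post_init__(self) -> None:
        if self.response_scale not in ("beta", "m_value"):
            raise ValueError(f"unknown response scale {self.response_scale!r}")
        allowed = {"age", "sex", "cell_fractions"}
        bad = set(self.covariates) - allowed
        if bad:
            raise ValueError(f"unknown covariates {sorted(bad)}")


def beta_to_m(beta: np.ndarray | float) -> np.ndarray | float:
    """Logit2 transform: M = log2(β / (1 − β)), with ε-clipping at 1e-6."""
    b = np.clip(np.asarray(beta, dtype=float), _EPS, 1.0 - _EPS)
    out = np.log2(b / (1.0 - b))
    return float(out) if np.isscalar(beta) else out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    NaN entries propagate as NaN and are excluded from the denominator.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if p[ok].min() < 0 or p[ok].max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def build_design(samples: pd.DataFrame, design: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Construct the design matrix [intercept, group, covariates...]."""
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    cols.append((samples["group"].to_numpy() == "case").astype(float))
    names.append("group")
    for cov in design.covariates:
        if cov == "age":
            cols.append(samples["age"].to_numpy(dtype=float))
            names.append("age")
        elif cov == "sex":
            cols.append((samples["sex"].to_numpy() == "M").astype(float))
            names.append("sex_male")
        elif cov == "cell_fractions":
            for ct in CELL_TYPES[:-1]:  # drop Gran: fractions sum to 1
                cols.append(samples[f"cf_{ct}"].to_numpy(dtype=float))
                names.append(f"cf_{ct}")
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise ValueError("missing values in design columns")
    check_full_rank(X, names)
    return X, names


def fit_dmps(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    design: DesignSpec = DesignSpec(),
) -> pd.DataFrame:
    """Per-CpG covariate-adjusted linear model for the group effect.

    For every CpG, ordinary least squares of the response (β values, or
    M values if requested) on [intercept, group, covariates]; the reported
    ``delta_beta`` is always the adjusted group coefficient on the β scale,
    so direction labels stay interpretable as case-minus-control methylation
    differences.  Two-sided t p-values are BH-adjusted across all tested
    CpGs; CpGs with zero residual variance get NaN p, are flagged, and are
    excluded from the FDR denominator.

    Returns a DataFrame indexed by cpg_id with columns delta_beta, t_stat,
    p_value, fdr, direction, degenerate, sorted by p-value.
    """
    samples = samples.loc[beta.columns]
    X, _names = build_design(samples, design)
    Y_beta = beta.to_numpy(dtype=float)
    if design.response_scale == "m_value":
        Y = beta_to_m(Y_beta)
    else:
        Y = Y_beta
    coef, t, p, degen = ols_coef_t_p(X, Y, coef_index=1)
    if design.response_scale == "m_value":
        delta_beta = ols_coef_t_p(X, Y_beta, coef_index=1)[0]
    else:
        delta_beta = coef
    if degen.any():
        logger.warning("%d CpGs with zero residual variance flagged", degen.sum())
    out = pd.DataFrame(
        {
            "delta_beta": delta_beta,
            "t_stat": t,
            "p_value": p,
            "fdr": bh_fdr(p),
            "direction": np.where(delta_beta > 0, "hyper", "hypo"),
            "degenerate": degen,
        },
        index=beta.index.rename("cpg_id"),
    )
    return out.sort_values("p_value", kind="stable")


def annotate_promoter(cpg: pd.Series, gene: pd.Series, window: int = 1500) -> bool:
    """True iff the CpG falls in the gene's promoter.

    Promoter means: annotated feature 5UTR or 1stExon, position inside the
    first-exon interval, or position within ``window`` bp upstream of the
    TSS on the strand-oriented upstream side.
    """
    if cpg["chrom"] != gene["chrom"]:
        raise ValueError("CpG and gene are on different chromosomes")
    strand = gene["strand"]
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand {strand!r} for gene {gene.name}")
    if cpg.get("feature") in ("5UTR", "1stExon"):
        return True
    pos = int(cpg["pos"])
    tss = int(gene["tss"])
    if int(gene["first_exon_start"]) <= pos <= int(gene["first_exon_end"]):
        return True
    if strand == "+":
        return tss - window <= pos <= tss - 1
    return tss + 1 <= pos <= tss + window


def annotate_promoters(
    annotation: pd.DataFrame, gene_models: pd.DataFrame
) -> pd.Series:
    """Vector form of :func:`annotate_promoter` over an annotation table."""
    flags = pd.Series(False, index=annotation.index)
    for cpg_id, row in annotation.iterrows():
        gene = row.get("gene", "")
        if not gene or gene not in gene_models.index:
            continue
        flags.loc[cpg_id] = annotate_promoter(row, gene_models.loc[gene])
    return flags


def estimate_cell_fractions(
    bulk_beta: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Constrained projection of bulk methylation onto cell-type profiles.

    Each sample's marker-CpG β profile is least-squares projected onto the
    reference cell-type profiles subject to fractions ≥ 0 and Σ ≤ 1
    (quadratic program, deterministic).  Rows of ``reference`` are marker
    CpGs, columns are cell types.

    Returns a samples × cell-types DataFrame of fractions.
    """
    markers = reference.index
    missing = markers.difference(bulk_beta.index)
    if len(missing):
        raise ValueError(f"bulk matrix is missing marker CpGs: {list(missing[:5])}")
    R = reference.to_numpy(dtype=float)
    if R.shape[0] < R.shape[1]:
        raise ValueError("need at least as many marker CpGs as cell types")
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValueError("reference profile matrix is rank deficient")
    B = bulk_beta.loc[markers].to_numpy(dtype=float)
    k = R.shape[1]
    out = np.empty((B.shape[1], k))
    for s in range(B.shape[1]):
        b = B[:, s]
        f, _ = optimize.nnls(R, b)
        if f.sum() > 1.0 + 1e-12:
            # sum constraint active: refine with an SLSQP quadratic program
            res = optimize.minimize(
                lambda x: 0.5 * np.sum((R @ x - b) ** 2),
                x0=np.full(k, 1.0 / k),
                jac=lambda x: R.T @ (R @ x - b),
                bounds=[(0.0, 1.0)] * k,
                constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(),
                              "jac": lambda x: -np.ones(k)}],
                method="SLSQP",
                options={"maxiter": 500, "ftol": 1e-14},
            )
            f = np.clip(res.x, 0.0, None)
        out[s] = f
    return pd.DataFrame(out, index=bulk_beta.columns, columns=reference.columns)
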