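"""Signed co-expression network, module detection, eigengenes, and ORA.

A WGCNA-style workflow: pairwise Pearson correlation raised to a soft
threshold gives a signed adjacency, topological overlap (TOM) turns shared
neighborhoods into a similarity, average-linkage clustering of 1 − TOM with
a fixed-height cut yields modules, each summarized by its eigengene (first
principal component of the standardized member submatrix).  Gene-set
overrepresentation of a module is tested with the hypergeometric upper tail
against a user-supplied background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .methylation import bh_fdr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    """Soft threshold and module-cut parameters.

    ``soft_power`` is the exponent applied to co-expression similarity
    (default 6, the conventional choice for signed networks);
    ``cut_height`` is the dissimilarity (1 − TOM) at which the
    average-linkage dendrogram is cut; clusters smaller than
    ``min_module_size`` are relabelled 0 (unassigned / "grey").
    ``variant`` selects the signed ((1+r)/2)^β or signed-hybrid
    (max(r,0)^β) adjacency.
    """

    soft_power: float = 6.0
    min_module_size: int = 10
    cut_height: float = 0.9
    variant: str = "signed"

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0.0 <= self.cut_height <= 1.0:
            raise ValueError("cut_height must lie in [0, 1]")
        if self.variant not in ("signed", "signed_hybrid"):
            raise ValueError(f"unknown adjacency variant {self.variant!r}")


def signed_adjacency(
    expr: pd.DataFrame, soft_power: float = 6.0, variant: str = "signed"
) -> pd.DataFrame:
    """aᵢⱼ = ((1 + cor(i,j)) / 2)^β (signed) over a gene × sample matrix."""
    X = expr.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0][:5])
        raise ValueError(f"zero-variance genes: {bad}")
    cor = np.corrcoef(X)
    cor = np.clip(cor, -1.0, 1.0)
    if variant == "signed":
        adj = ((1.0 + cor) / 2.0) ** soft_power
    elif variant == "signed_hybrid":
        adj = np.where(cor > 0, cor, 0.0) ** soft_power
    else:
        raise ValueError(f"unknown adjacency variant {variant!r}")
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOMᵢⱼ = (Σ_u aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ)+1−aᵢⱼ).

    The sum runs over u ∉ {i, j}; k is the connectivity (row sum minus the
    unit diagonal); the diagonal is 1.
    """
    A = adjacency.to_numpy(dtype=float)
    k = A.sum(axis=1) - 1.0
    shared = A @ A - 2.0 * A  # removes the u == i and u == j terms (diag 1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + A) / denom
    tom = np.where(denom <= 0, 1.0, tom)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom: pd.DataFrame, config: NetworkConfig = NetworkConfig()) -> pd.Series:
    """Average-linkage clustering of 1 − TOM with a flat cut.

    Clusters smaller than ``min_module_size`` become label 0 (unassigned);
    remaining modules are renumbered 1, 2, ... by decreasing size.
    """
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0  # enforce exact symmetry for squareform
    Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=config.cut_height, criterion="distance")
    labels = np.zeros(len(raw), dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = sizes[sizes >= config.min_module_size]
    # order by size descending, ties by first occurrence for determinism
    order = sorted(kept.index, key=lambda c: (-kept[c], int(np.argmax(raw == c))))
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    return pd.Series(labels, index=tom.index, name="module")


def module_eigengene(expr: pd.DataFrame, members) -> pd.Series:
    """First principal component of the z-scored member submatrix.

    Scaled to unit variance; the sign is fixed so the mean Pearson
    correlation with member genes is positive.  Zero-variance members are
    dropped with a warning.
    """
    sub = expr.loc[list(members)].to_numpy(dtype=float)
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        logger.warning("dropping %d zero-variance module members", (sd == 0).sum())
        sub = sub[sd > 0]
        sd = sd[sd > 0]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 non-degenerate members")
    Z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _u, _s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    eig = eig / eig.std(ddof=1)
    cors = [np.corrcoef(eig, g)[0, 1] for g in Z]
    if np.mean(cors) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns, name="eigengene")


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Eigengene per assigned module (label > 0); columns ME1, ME2, ..."""
    out = {}
    for mod in sorted(set(labels) - {0}):
        out[f"ME{mod}"] = module_eigengene(expr, labels.index[labels == mod])
    return pd.DataFrame(out, index=expr.columns)


def module_trait_correlation(eigengenes: pd.DataFrame, trait) -> pd.DataFrame:
    """Pearson r of each eigengene with a trait (e.g. case=1 / control=0).

    p-values from the two-sided t distribution on n − 2 degrees of freedom.
    """
    t = np.asarray(trait, dtype=float)
    if np.std(t) == 0:
        raise ValueError("trait is constant")
    rows = {}
    for name, col in eigengenes.items():
        x = col.to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"eigengene {name} is constant")
        r, p = stats.pearsonr(x, t)
        rows[name] = {"r": r, "p_value": p}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("module")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: tab-separated term id, description, member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def ora_hypergeometric(
    query, background, gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``query`` in each gene set.

    The population is the background; each set is intersected with the
    background before testing (sets disjoint from the background are skipped
    with a warning).  p = P(X ≥ overlap); BH FDR across tested sets.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    q = set(query)
    if not q <= bg:
        raise ValueError("query genes must be a subset of the background")
    rows = []
    for term, genes in gene_sets.items():
        inset = set(genes) & bg
        if not inset:
            logger.warning("gene set %s disjoint from background; skipped", term)
            continue
        overlap = len(q & inset)
        M, K, N = len(bg), len(inset), len(q)
        p = float(stats.hypergeom.sf(overlap - 1, M, K, N))
        rows.append(
            {
                "term_id": term,
                "term_size": K,
                "overlap": overlap,
                "expected": N * K / M,
                "p_value": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_size", "overlap", "expected", "p_value", "fdr"],
            index=pd.Index([], name="term_id"),
        )
    out = pd.DataFrame(rows).set_index("term_id")
    out["fdr"] = bh_fdr(out["p_value"])
    return out.sort_values("p_value", kind="stable")
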