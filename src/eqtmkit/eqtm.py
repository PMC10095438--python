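"""The eQTM engine: DMR median methylation vs log gene expression.

For every cis pair of a differentially methylated region and its annotated
gene, the per-sample median β over member CpGs is correlated (Pearson) with
the log2-transformed normalized counts of the gene.  Uncertainty comes from
a percentile bootstrap over samples (default 100,000 replicates); the
p-value comes from a resampling null that permutes the expression vector
against the methylation vector.  Group-specific correlations decompose the
combined coefficient into case and control components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import de_test, filter_expressed, log_transform, normalize_counts
from .methylation import DesignSpec

logger = logging.getLogger(__name__)

#: region-level feature vocabulary (result-table style)
DMR_FEATURES = ("Promoter", "1st exon", "Gene body", "Intergenic")


@dataclass(frozen=True)
class EqtmConfig:
    """Knobs of the eQTM stage.

    ``n_boot`` bootstrap replicates for the 95% percentile CI (100,000 by
    default), ``n_perm`` permutations for the resampling p-value,
    ``sig_threshold`` the nominal significance cut (0.05, unadjusted — a BH
    q-value is reported as an extra column), ``nearest_tss_window`` the
    maximal distance for matching intergenic regions to a TSS,
    ``min_nonzero_frac`` the expressed-gene filter applied to counts.
    """

    n_boot: int = 100_000
    n_perm: int = 10_000
    ci_level: float = 0.95
    sig_threshold: float = 0.05
    nearest_tss_window: int = 100_000
    min_nonzero_frac: float = 0.90
    seed: int = 0
    design: DesignSpec = field(default_factory=DesignSpec)


def dmr_median_methylation(beta: pd.DataFrame, member_cpgs) -> pd.Series:
    """Per-sample median β over the region's member CpGs."""
    members = list(member_cpgs)
    missing = [c for c in members if c not in beta.index]
    if missing:
        raise ValueError(f"member CpGs missing from beta matrix: {missing[:5]}")
    return beta.loc[members].median(axis=0)


def eqtm_correlation(medians, log_expr) -> float:
    """Pearson correlation between region medians and log expression."""
    x = np.asarray(medians, dtype=float)
    y = np.asarray(log_expr, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input vector")
    return float(np.corrcoef(x, y)[0, 1])


def _batched_pearson(xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r for paired (m, n) matrices; NaN where degenerate."""
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.einsum("ij,ij->i", xc, xc))
    sy = np.sqrt(np.einsum("ij,ij->i", yc, yc))
    denom = sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("ij,ij->i", xc, yc) / denom
    r[denom == 0] = np.nan
    return r


def bootstrap_ci(
    medians,
    log_expr,
    n_boot: int = 100_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    _max_rounds: int = 10,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the Pearson correlation.

    Sample indices are resampled with replacement (paired); replicates where
    either resampled vector is constant are redrawn for a bounded number of
    rounds, then dropped with a warning.  More than 50% degenerate
    replicates is an error.
    """
    x = np.asarray(medians, dtype=float)
    y = np.asarray(log_expr, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    reps = np.empty(n_boot)
    reps.fill(np.nan)
    need = np.arange(n_boot)
    for _ in range(_max_rounds):
        if need.size == 0:
            break
        idx = rng.integers(0, n, size=(need.size, n))
        r = _batched_pearson(x[idx], y[idx])
        reps[need] = r
        need = need[np.isnan(r)]
    valid = reps[~np.isnan(reps)]
    n_bad = n_boot - valid.size
    if n_bad:
        logger.warning("dropping %d degenerate bootstrap replicates", n_bad)
    if valid.size < n_boot / 2:
        raise ValueError("more than half of bootstrap replicates degenerate")
    lo, hi = np.quantile(valid, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def resampling_pvalue(
    medians,
    log_expr,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided resampling p-value for the Pearson correlation.

    The null is built by permuting the expression vector against the
    methylation vector; p = (1 + #{|r_perm| ≥ |r_obs|}) / (n_perm + 1), so p
    is never exactly zero.
    """
    x = np.asarray(medians, dtype=float)
    y = np.asarray(log_expr, dtype=float)
    r_obs = eqtm_correlation(x, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(y, (n_perm, y.size)), axis=1)
    r_perm = _batched_pearson(np.broadcast_to(x, (n_perm, x.size)).copy(), perms)
    # tiny slack keeps exact ties (e.g. the identity permutation) counted
    hits = np.count_nonzero(np.abs(r_perm) >= abs(r_obs) - 1e-12)
    return float((1 + hits) / (n_perm + 1))


def group_correlations(medians, log_expr, groups) -> tuple[float, float]:
    """Pearson correlation within cases and within controls separately.

    Groups with fewer than 3 samples or constant vectors yield NaN (logged).
    """
    x = np.asarray(medians, dtype=float)
    y = np.asarray(log_expr, dtype=float)
    g = np.asarray(groups)
    out = []
    for label in ("case", "control"):
        mask = g == label
        if mask.sum() < 3 or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
            logger.warning("group %r too small or constant; correlation NaN", label)
            out.append(float("nan"))
        else:
            out.append(float(np.corrcoef(x[mask], y[mask])[0, 1]))
    return out[0], out[1]


def match_cis(
    dmrs: pd.DataFrame,
    gene_models: pd.DataFrame,
    expressed,
    nearest_tss_window: int = 100_000,
) -> tuple[list[tuple[str, str, bool]], list[dict]]:
    """Pair each DMR with its annotated, expressed gene(s).

    Returns (pairs, drop_log).  Each pair is (region_id, gene_id,
    matched_by_proximity).  DMRs annotated to multiple genes fan out to one
    pair per expressed gene.  Unannotated (intergenic) regions are matched
    to the nearest TSS on the same chromosome within
    ``nearest_tss_window`` bp, flagged.  Regions whose genes are all
    unexpressed, or with no gene in range, go to the drop log.
    """
    expressed = set(expressed)
    pairs: list[tuple[str, str, bool]] = []
    drop_log: list[dict] = []
    for region_id, row in dmrs.iterrows():
        genes = [g for g in str(row.get("genes", "") or "").split(",") if g]
        if genes:
            for g in genes:
                if g in expressed:
                    pairs.append((region_id, g, False))
                else:
                    drop_log.append(
                        {"region_id": region_id, "gene_id": g, "reason": "not expressed"}
                    )
            continue
        # intergenic: nearest expressed TSS on the same chromosome
        center = (int(row["start"]) + int(row["end"])) // 2
        cand = gene_models[gene_models["chrom"] == row["chrom"]]
        cand = cand[cand.index.isin(expressed)]
        if len(cand):
            dist = (cand["tss"].astype(int) - center).abs()
            g = dist.idxmin()
            if dist.loc[g] <= nearest_tss_window:
                pairs.append((region_id, g, True))
                continue
        drop_log.append(
            {"region_id": region_id, "gene_id": "", "reason": "no gene in range"}
        )
    return pairs, drop_log


def _dmr_feature(
    member_cpgs, annotation: pd.DataFrame, gene_models: pd.DataFrame, gene_id: str
) -> str:
    """Region-level feature label from member-CpG annotations.

    Priority: promoter evidence (TSS1500/5'UTR annotation or position inside
    the upstream window) > first exon > gene body > intergenic.
    """
    feats = set()
    for cpg in member_cpgs:
        if cpg in annotation.index:
            feats.add(annotation.loc[cpg, "feature"])
    if feats & {"TSS1500", "5UTR"}:
        return "Promoter"
    if "1stExon" in feats:
        return "1st exon"
    if feats & {"Body", "3UTR"}:
        return "Gene body"
    return "Intergenic"


def classify_expression_direction(effect: float, raw_diff: float) -> str:
    """Overexpression/Underexpression from the adjusted group effect.

    An exactly zero adjusted effect falls back to the sign of the raw
    case-minus-control mean difference; a zero there too yields "none".
    """
    val = effect if effect != 0 else raw_diff
    if val > 0:
        return "Overexpression"
    if val < 0:
        return "Underexpression"
    return "none"


def run_eqtm_analysis(
    beta: pd.DataFrame,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    dmrs: pd.DataFrame,
    gene_models: pd.DataFrame,
    annotation: pd.DataFrame,
    config: EqtmConfig = EqtmConfig(),
) -> pd.DataFrame:
    """Full per-pair eQTM pipeline.

    Median β per region → Pearson r vs log2 normalized counts → bootstrap
    CI → resampling p → group-specific r → feature/direction labels.
    Deterministic given ``config.seed``.  Returns a DataFrame sorted by
    p-value with one row per (region, gene) pair.
    """
    cols = [
        "gene_id", "r", "ci_low", "ci_high", "p_value", "q_value",
        "r_case", "r_control", "n_cpgs", "dmr_feature", "dmr_direction",
        "expression_direction", "significant", "matched_by_proximity",
    ]
    if len(dmrs) == 0:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="region_id"))
    kept = filter_expressed(counts, config.min_nonzero_frac)
    norm, _ = normalize_counts(kept)
    log_expr = log_transform(norm)
    de = de_test(kept, samples, config.design)
    groups = samples.loc[beta.columns, "group"].to_numpy()
    case_mask = groups == "case"
    pairs, drop_log = match_cis(
        dmrs, gene_models, set(kept.index), config.nearest_tss_window
    )
    for entry in drop_log:
        logger.info(
            "dropped pair %s/%s: %s",
            entry["region_id"], entry["gene_id"], entry["reason"],
        )
    rng = np.random.default_rng(config.seed)
    rows = []
    for region_id, gene_id, by_prox in pairs:
        region = dmrs.loc[region_id]
        members = region["member_cpgs"].split(",")
        med = dmr_median_methylation(beta, members).to_numpy()
        y = log_expr.loc[gene_id].to_numpy()
        try:
            r = eqtm_correlation(med, y)
        except ValueError as exc:
            logger.warning("pair %s/%s skipped: %s", region_id, gene_id, exc)
            continue
        lo, hi = bootstrap_ci(med, y, config.n_boot, config.ci_level, rng)
        p = resampling_pvalue(med, y, config.n_perm, rng)
        r_case, r_control = group_correlations(med, y, groups)
        effect = de.loc[gene_id, "log2_fold_change"] if gene_id in de.index else 0.0
        raw_diff = float(y[case_mask].mean() - y[~case_mask].mean())
        rows.append(
            {
                "region_id": region_id,
                "gene_id": gene_id,
                "r": r,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": p,
                "r_case": r_case,
                "r_control": r_control,
                "n_cpgs": int(region["n_cpgs"]),
                "dmr_feature": _dmr_feature(members, annotation, gene_models, gene_id),
                "dmr_direction": "Hyper-methylated"
                if region["mean_delta_beta"] > 0
                else "Hypo-methylated",
                "expression_direction": classify_expression_direction(effect, raw_diff),
                "matched_by_proximity": by_prox,
            }
        )
    if not rows:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="region_id"))
    out = pd.DataFrame(rows).set_index("region_id")
    from .methylation import bh_fdr

    out["q_value"] = bh_fdr(out["p_value"])
    out["significant"] = out["p_value"] < config.sig_threshold
    return out[cols].sort_values("p_value", kind="stable")
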