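"""Differentially methylated region (DMR) calling and Stouffer combination.

A DMR is a maximal run of at least ``min_cpgs`` consecutively significant
CpGs (FDR below the configured threshold) in which each successive pair of
members lies within ``max_gap`` nucleotides and no non-significant panel CpG
intervenes.  Regions are ranked by Stouffer's coefficient (SC), the combined
p-value from summing per-CpG z-scores and renormalizing by sqrt(n); the
per-CpG two-sided p-values are converted one-sidedly using the sign of the
methylation difference, so that members of opposing direction cancel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

logger = logging.getLogger(__name__)

_P_EPS = 1e-15


def stouffer_combine(pvalues) -> tuple[float, float]:
    """Combine one-sided p-values: Z = Σ Φ⁻¹(1−pᵢ) / √n, p = 1 − Φ(Z).

    p-values at 0 or 1 are ε-clipped (and a warning logged), since the
    normal quantile diverges there.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ((p <= 0) | (p >= 1)).any():
        logger.warning("p-values at 0 or 1 clipped to [%g, %g]", _P_EPS, 1 - _P_EPS)
        p = np.clip(p, _P_EPS, 1 - _P_EPS)
    z = ndtri(1.0 - p)
    Z = z.sum() / np.sqrt(p.size)
    return float(Z), float(ndtr(-Z))


def _signed_stouffer(p_two_sided: np.ndarray, signs: np.ndarray) -> tuple[float, float]:
    """Directional Stouffer on two-sided p-values.

    Each CpG contributes z = sign(Δβ) · Φ⁻¹(1 − p/2); the combined p is
    two-sided on |Z| so hypo- and hypermethylated regions are on the same
    scale and mixed-direction members cancel.
    """
    p = np.clip(p_two_sided, _P_EPS, 1 - _P_EPS)
    z = signs * ndtri(1.0 - p / 2.0)
    Z = z.sum() / np.sqrt(p.size)
    return float(Z), float(2.0 * ndtr(-abs(Z)))


def call_dmrs(
    dmps: pd.DataFrame,
    annotation: pd.DataFrame,
    fdr_threshold: float = 0.05,
    max_gap: int = 1000,
    min_cpgs: int = 2,
) -> pd.DataFrame:
    """Segment FDR-significant CpGs into DMRs.

    Per chromosome, CpGs are scanned in position order; maximal runs of
    consecutively significant CpGs are emitted when (a) every successive
    significant pair is at most ``max_gap`` bp apart, (b) no non-significant
    panel CpG lies between members, and (c) the run has at least
    ``min_cpgs`` members.  Region direction is the sign of the mean member
    delta_beta; mixed-sign regions are flagged.

    Returns a DataFrame indexed by region id "chrom:start-end" with columns
    chrom, start, end (1-based inclusive positions of the first/last member
    CpG), n_cpgs, member_cpgs (comma-joined), genes (comma-joined unique
    member annotations), mean_delta_beta, direction, mixed_direction,
    stouffer_z, stouffer_p; sorted by stouffer_p.
    """
    missing = dmps.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"CpGs missing from annotation: {list(missing[:5])}")
    ann = annotation.loc[dmps.index]
    tab = dmps.assign(chrom=ann["chrom"], pos=ann["pos"].astype(int))
    if "gene" in ann.columns:
        tab["gene"] = ann["gene"]
    records = []
    for chrom, sub in tab.groupby("chrom", sort=True):
        # stable sort keeps input order for duplicated positions
        dup = sub["pos"].duplicated()
        if dup.any():
            logger.warning("%s: %d duplicated CpG positions", chrom, dup.sum())
        sub = sub.sort_values("pos", kind="stable")
        sig = (sub["fdr"] < fdr_threshold).to_numpy()
        pos = sub["pos"].to_numpy()
        run: list[int] = []
        for i in range(len(sub)):
            if sig[i] and (not run or pos[i] - pos[run[-1]] <= max_gap):
                run.append(i)
                continue
            if len(run) >= min_cpgs:
                records.append(_make_region(sub.iloc[run], chrom))
            run = [i] if sig[i] else []
        if len(run) >= min_cpgs:
            records.append(_make_region(sub.iloc[run], chrom))
    cols = [
        "chrom", "start", "end", "n_cpgs", "member_cpgs", "genes",
        "mean_delta_beta", "direction", "mixed_direction",
        "stouffer_z", "stouffer_p",
    ]
    if not records:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="region_id"))
    out = pd.DataFrame(records).set_index("region_id")
    return out[cols].sort_values("stouffer_p", kind="stable")


def _make_region(members: pd.DataFrame, chrom: str) -> dict:
    delta = members["delta_beta"].to_numpy()
    signs = np.sign(delta)
    z, p = _signed_stouffer(members["p_value"].to_numpy(), signs)
    mean_delta = float(delta.mean())
    genes = []
    if "gene" in members.columns:
        genes = [g for g in pd.unique(members["gene"]) if isinstance(g, str) and g]
    start = int(members["pos"].iloc[0])
    end = int(members["pos"].iloc[-1])
    mixed = bool(len(set(signs[signs != 0])) > 1)
    if mixed:
        logger.warning("region %s:%d-%d has mixed-direction members", chrom, start, end)
    return {
        "region_id": f"{chrom}:{start}-{end}",
        "chrom": chrom,
        "start": start,
        "end": end,
        "n_cpgs": int(len(members)),
        "member_cpgs": ",".join(members.index),
        "genes": ",".join(genes),
        "mean_delta_beta": mean_delta,
        "direction": "hyper" if mean_delta > 0 else "hypo",
        "mixed_direction": mixed,
        "stouffer_z": z,
        "stouffer_p": p,
    }


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive region coordinates → 0-based half-open BED."""
    return pd.DataFrame(
        {
            "chrom": dmrs["chrom"].to_numpy(),
            "start": dmrs["start"].to_numpy() - 1,
            "end": dmrs["end"].to_numpy(),
            "name": dmrs.index.to_numpy(),
        }
    )


def bed_to_intervals(bed: pd.DataFrame) -> pd.DataFrame:
    """0-based half-open BED → 1-based inclusive coordinates."""
    return pd.DataFrame(
        {
            "chrom": bed["chrom"].to_numpy(),
            "start": bed["start"].to_numpy() + 1,
            "end": bed["end"].to_numpy(),
        }
    )
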