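"""Seeded synthetic cohorts with planted methylation and expression effects.

The generator emulates the statistical structure of a whole-blood
case/control methylation + RNA-seq study at desk scale: a default panel of
20,000 CpGs over 6 chromosomes and 2,000 genes for 12 cases vs 51 controls.
β values are drawn on the logit (M-value) scale — baseline + group shift +
cell-fraction confound + noise — and inverse-logit mapped, which keeps them
in (0, 1) by construction.  Counts are negative binomial with variance
μ + φμ²; for planted eQTM genes the log mean is linearly coupled to the
planted region's per-sample median β with a coefficient solved to hit a
target Pearson correlation.  A single global seed expands to independent
per-stream seeds (layout, β, cell fractions, counts, metadata) so adding a
stream never perturbs another.

Every planted effect is recorded in a :class:`SyntheticTruth` registry used
as ground truth by recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .methylation import CELL_TYPES

_CHROM_LENGTH = 10_000_000
_MIN_CPG_GAP = 20


@dataclass(frozen=True)
class DMRSpec:
    """One planted differentially methylated region.

    ``delta_beta`` is the signed mean β shift in cases; ``max_gap`` bounds
    the intra-region CpG spacing; ``feature`` fixes the gene-region
    annotation of member CpGs (TSS1500, 5UTR, 1stExon, Body).
    """

    n_cpgs: int = 3
    delta_beta: float = -0.15
    max_gap: int = 500
    feature: str = "TSS1500"


@dataclass(frozen=True)
class EqtmSpec:
    """A planted methylation-expression coupling.

    ``rho`` is the target Pearson correlation between the linked region's
    median β and the gene's log counts; ``gene_id`` links to a panel gene
    (auto-assigned when None).  Spec i couples to planted region i.
    """

    rho: float = -0.4
    gene_id: str | None = None


@dataclass(frozen=True)
class CoexprSpec:
    """A planted co-expression block driven by a shared latent factor.

    ``group_shift`` moves the factor mean in cases (units of factor SD),
    making the block's eigengene trait-associated when nonzero.
    """

    n_genes: int = 60
    within_cor: float = 0.6
    group_shift: float = 0.0


def _default_dmr_specs() -> tuple[DMRSpec, ...]:
    # six expression-coupled regions (five hypo-, one hypermethylated, with
    # promoter / first-exon / gene-body placements) plus two uncoupled ones
    return (
        DMRSpec(3, -0.15, 500, "TSS1500"),
        DMRSpec(4, -0.15, 500, "TSS1500"),
        DMRSpec(2, -0.15, 500, "1stExon"),
        DMRSpec(5, -0.15, 500, "Body"),
        DMRSpec(4, +0.15, 500, "TSS1500"),
        DMRSpec(3, -0.15, 500, "TSS1500"),
        DMRSpec(3, +0.15, 500, "Body"),
        DMRSpec(2, -0.15, 500, "TSS1500"),
    )


def _default_eqtm_specs() -> tuple[EqtmSpec, ...]:
    # five negative couplings and one positive, magnitudes typical of
    # whole-blood cis effects
    return (
        EqtmSpec(-0.44),
        EqtmSpec(-0.38),
        EqtmSpec(-0.34),
        EqtmSpec(-0.32),
        EqtmSpec(+0.29),
        EqtmSpec(-0.28),
    )


def _default_coexpr_specs() -> tuple[CoexprSpec, ...]:
    return (CoexprSpec(60, 0.6, 0.0), CoexprSpec(60, 0.6, -2.5))


@dataclass(frozen=True)
class SimConfig:
    """Cohort generator configuration; defaults are the study conditions."""

    n_cases: int = 12
    n_controls: int = 51
    n_cpgs: int = 20_000
    n_genes: int = 2_000
    n_chromosomes: int = 6
    planted_dmr_specs: tuple[DMRSpec, ...] = field(default_factory=_default_dmr_specs)
    planted_eqtm_specs: tuple[EqtmSpec, ...] = field(default_factory=_default_eqtm_specs)
    planted_coexpr_specs: tuple[CoexprSpec, ...] = field(
        default_factory=_default_coexpr_specs
    )
    nb_dispersion: float = 0.15
    beta_noise_sd: float = 0.15
    cell_fraction_alpha: tuple[float, ...] = (6.0, 9.0, 3.0, 3.0, 6.0, 33.0)
    #: multiplicative Dirichlet-α shift for cases (group-linked composition)
    case_cell_shift: tuple[float, ...] = (1.0, 0.85, 1.0, 1.0, 1.0, 1.25)
    #: fraction of background CpGs carrying a cell-composition effect
    cell_confound_frac: float = 0.3
    #: SD of the logit-scale coefficient on the standardized granulocyte fraction
    cell_confound_sd: float = 0.3
    #: case/control mean and SD of age in years
    age_case: tuple[float, float] = (6.95, 3.68)
    age_control: tuple[float, float] = (13.20, 2.94)
    #: probability of male sex per group
    male_frac_case: float = 7 / 12
    male_frac_control: float = 33 / 51
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        if len(self.cell_fraction_alpha) != len(CELL_TYPES):
            raise ValueError(f"cell_fraction_alpha must have {len(CELL_TYPES)} entries")
        if len(self.planted_eqtm_specs) > len(self.planted_dmr_specs):
            raise ValueError("every planted eQTM needs a planted region to couple to")
        n_planted = sum(s.n_cpgs for s in self.planted_dmr_specs)
        if n_planted > self.n_cpgs:
            raise ValueError("planted regions exceed the CpG panel size")
        per_chrom = -(-self.n_cpgs // self.n_chromosomes)
        if per_chrom * _MIN_CPG_GAP * 4 > _CHROM_LENGTH:
            raise ValueError("CpG panel too dense for the chromosome length")
        for s in self.planted_dmr_specs:
            if s.n_cpgs < 2:
                raise ValueError("planted regions need at least 2 CpGs")
            if not -0.35 <= s.delta_beta <= 0.35:
                raise ValueError(
                    "planted |delta_beta| must be <= 0.35 to keep β in [0, 1] "
                    "from mid-range baselines"
                )
            if s.max_gap < _MIN_CPG_GAP:
                raise ValueError("max_gap too small for distinct positions")
        for s in self.planted_eqtm_specs:
            if not -0.95 <= s.rho <= 0.95:
                raise ValueError(
                    f"target correlation {s.rho} not achievable given count noise"
                )
            if s.gene_id is not None and not _gene_in_panel(s.gene_id, self.n_genes):
                raise ValueError(f"linked gene {s.gene_id!r} not in the gene panel")
        if sum(s.n_genes for s in self.planted_coexpr_specs) + len(
            self.planted_eqtm_specs
        ) > self.n_genes:
            raise ValueError("planted gene effects exceed the gene panel size")


def _gene_in_panel(gene_id: str, n_genes: int) -> bool:
    if not gene_id.startswith("G"):
        return False
    try:
        k = int(gene_id[1:])
    except ValueError:
        return False
    return 1 <= k <= n_genes


@dataclass
class SyntheticTruth:
    """Registry of planted effects (ground truth for recovery tests)."""

    dmr_regions: list[dict]      # chrom, start, end, cpg_ids, delta_beta, gene
    eqtm_pairs: list[dict]       # region_key, gene_id, rho
    coexpr_modules: list[dict]   # gene_ids, within_cor, group_shift
    null_cpg_ids: list[str]
    null_gene_ids: list[str]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**d)


@dataclass
class Cohort:
    """One generated dataset: all matrices, tables, and the truth registry."""

    beta: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame
    cpg_annotation: pd.DataFrame
    gene_models: pd.DataFrame
    truth: SyntheticTruth


def _sample_table(
    config: SimConfig, rng: np.random.Generator, rng_frac: np.random.Generator
) -> pd.DataFrame:
    n = config.n_cases + config.n_controls
    ids = [f"S{i + 1:03d}" for i in range(n)]
    group = ["case"] * config.n_cases + ["control"] * config.n_controls
    age = np.concatenate(
        [
            rng.normal(*config.age_case, size=config.n_cases),
            rng.normal(*config.age_control, size=config.n_controls),
        ]
    ).clip(min=1.0)
    sex = np.concatenate(
        [
            rng.random(config.n_cases) < config.male_frac_case,
            rng.random(config.n_controls) < config.male_frac_control,
        ]
    )
    alpha = np.asarray(config.cell_fraction_alpha)
    shift = np.asarray(config.case_cell_shift)
    fracs = np.vstack(
        [
            rng_frac.dirichlet(alpha * shift, size=config.n_cases),
            rng_frac.dirichlet(alpha, size=config.n_controls),
        ]
    )
    tab = pd.DataFrame(
        {"group": group, "age": np.round(age, 2), "sex": np.where(sex, "M", "F")},
        index=pd.Index(ids, name="sample_id"),
    )
    for j, ct in enumerate(CELL_TYPES):
        tab[f"cf_{ct}"] = fracs[:, j]
    return tab


def _gene_models(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(config.n_genes):
        chrom = f"chr{i % config.n_chromosomes + 1}"
        tss = int(rng.integers(50_000, _CHROM_LENGTH - 150_000))
        strand = "+" if rng.random() < 0.5 else "-"
        ex_len = int(rng.integers(100, 400))
        length = int(rng.integers(5_000, 100_000))
        if strand == "+":
            fe = (tss, tss + ex_len)
            span = (tss, tss + length)
        else:
            fe = (tss - ex_len, tss)
            span = (tss - length, tss)
        rows.append(
            {
                "gene_id": f"G{i + 1:04d}",
                "chrom": chrom,
                "start": span[0],
                "end": span[1],
                "strand": strand,
                "tss": tss,
                "first_exon_start": fe[0],
                "first_exon_end": fe[1],
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _place_region(
    spec: DMRSpec, gene: pd.Series, rng: np.random.Generator
) -> np.ndarray:
    """Member positions for a planted region, anchored per its feature."""
    gaps = rng.integers(_MIN_CPG_GAP, spec.max_gap + 1, size=spec.n_cpgs - 1)
    span = int(gaps.sum())
    tss, strand = int(gene["tss"]), gene["strand"]
    if spec.feature == "TSS1500":
        # inside the 1500 bp upstream window
        if strand == "+":
            anchor = tss - 1500 + int(rng.integers(0, max(1, 1400 - span)))
        else:
            anchor = tss + 100 + int(rng.integers(0, max(1, 1300 - span)))
    elif spec.feature in ("5UTR", "1stExon"):
        anchor = int(gene["first_exon_start"])
    else:  # Body
        lo = min(int(gene["start"]), int(gene["end"])) + 2_000
        anchor = lo + int(rng.integers(0, 2_000))
    return anchor + np.concatenate([[0], np.cumsum(gaps)])


def _nearest_feature(pos: int, gene: pd.Series) -> str:
    tss = int(gene["tss"])
    strand = gene["strand"]
    if int(gene["first_exon_start"]) <= pos <= int(gene["first_exon_end"]):
        return "1stExon"
    upstream = (
        tss - 1500 <= pos <= tss - 1 if strand == "+" else tss + 1 <= pos <= tss + 1500
    )
    if upstream:
        return "TSS1500"
    lo, hi = sorted((int(gene["start"]), int(gene["end"])))
    if lo <= pos <= hi:
        return "Body"
    return "IGR"


def _cpg_panel(
    config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[dict]]:
    """CpG annotation table plus planted-region registry (ids unresolved)."""
    planted_rows = []
    regions: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in
                                                  (f"chr{i+1}" for i in range(config.n_chromosomes))}
    gene_ids = list(genes.index)
    used_genes: set[str] = set()
    for ridx, spec in enumerate(config.planted_dmr_specs):
        eq = (
            config.planted_eqtm_specs[ridx]
            if ridx < len(config.planted_eqtm_specs)
            else None
        )
        fixed_gene = eq is not None and eq.gene_id is not None
        placed = False
        # a gene's feasible anchor window can be blocked by an earlier
        # region on a dense panel; auto-assigned genes are re-drawn
        for _gene_attempt in range(50):
            if fixed_gene:
                gene_id = eq.gene_id
            else:
                free = [g for g in gene_ids if g not in used_genes]
                if not free:
                    break
                gene_id = free[int(rng.integers(0, len(free)))]
            gene = genes.loc[gene_id]
            chrom = gene["chrom"]
            for _attempt in range(100):
                pos = _place_region(spec, gene, rng)
                lo, hi = int(pos[0]) - 2_000, int(pos[-1]) + 2_000
                if all(hi < a or lo > b for a, b in occupied[chrom]):
                    placed = True
                    break
            used_genes.add(gene_id)
            if placed or fixed_gene:
                break
        if not placed:
            raise ValueError(f"could not place planted region {ridx} without overlap")
        occupied[chrom].append((lo, hi))
        for p in pos:
            planted_rows.append(
                {"chrom": chrom, "pos": int(p), "gene": gene_id,
                 "feature": spec.feature, "region": ridx}
            )
        regions.append(
            {"chrom": chrom, "positions": [int(p) for p in pos],
             "delta_beta": spec.delta_beta, "gene": gene_id,
             "rho": None if eq is None else eq.rho}
        )
    # background CpGs, uniform over chromosomes, away from planted spans
    n_bg = config.n_cpgs - len(planted_rows)
    per_chrom = np.full(config.n_chromosomes, n_bg // config.n_chromosomes)
    per_chrom[: n_bg % config.n_chromosomes] += 1
    bg_rows = []
    gene_by_chrom = {c: sub for c, sub in genes.groupby("chrom", sort=False)}
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        need = int(per_chrom[ci])
        taken: set[int] = set()
        spans = occupied[chrom]
        sub = gene_by_chrom.get(chrom)
        tss_arr = sub["tss"].to_numpy() if sub is not None else np.array([])
        while len(taken) < need:
            cand = rng.integers(1_000, _CHROM_LENGTH, size=(need - len(taken)) * 2)
            for p in cand:
                p = int(p)
                if p in taken or any(a <= p <= b for a, b in spans):
                    continue
                taken.add(p)
                if len(taken) == need:
                    break
        for p in sorted(taken):
            gene_id, feature = "", "IGR"
            if len(tss_arr):
                j = int(np.argmin(np.abs(tss_arr - p)))
                g = sub.iloc[j]
                if abs(int(g["tss"]) - p) <= 60_000:
                    feature = _nearest_feature(p, g)
                    gene_id = g.name if feature != "IGR" else ""
            bg_rows.append({"chrom": chrom, "pos": p, "gene": gene_id,
                            "feature": feature, "region": -1})
    ann = pd.DataFrame(planted_rows + bg_rows)
    ann = ann.sort_values(
        ["chrom", "pos"],
        key=lambda s: s.str.replace("chr", "").astype(int) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)
    ann.index = pd.Index(
        [f"cg{i + 1:08d}" for i in range(len(ann))], name="cpg_id"
    )
    # resolve member CpG ids per planted region
    for ridx, reg in enumerate(regions):
        mask = (ann["region"] == ridx)
        members = ann.index[mask][np.argsort(ann.loc[mask, "pos"].to_numpy())]
        reg["cpg_ids"] = list(members)
        reg["start"] = int(ann.loc[mask, "pos"].min())
        reg["end"] = int(ann.loc[mask, "pos"].max())
    return ann, regions


def _beta_matrix(
    config: SimConfig,
    ann: pd.DataFrame,
    regions: list[dict],
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_cpg, n_samp = len(ann), len(samples)
    case = (samples["group"] == "case").to_numpy().astype(float)
    gran = samples["cf_Gran"].to_numpy()
    z_gran = (gran - gran.mean()) / gran.std()
    baseline = rng.normal(0.0, 1.3, size=n_cpg)
    planted_mask = (ann["region"].to_numpy() >= 0)
    # planted members get mid-range baselines so the shift stays in bounds
    b0_planted = rng.uniform(0.35, 0.60, size=planted_mask.sum())
    baseline[planted_mask] = logit(b0_planted)
    shift = np.zeros(n_cpg)
    region_idx = ann["region"].to_numpy()
    for ridx, reg in enumerate(regions):
        mask = region_idx == ridx
        b0 = expit(baseline[mask])
        b1 = np.clip(b0 + reg["delta_beta"], 1e-3, 1 - 1e-3)
        shift[mask] = logit(b1) - logit(b0)
    confound = np.zeros(n_cpg)
    bg_idx = np.flatnonzero(~planted_mask)
    n_conf = int(round(config.cell_confound_frac * bg_idx.size))
    conf_idx = rng.choice(bg_idx, size=n_conf, replace=False)
    confound[conf_idx] = rng.normal(0.0, config.cell_confound_sd, size=n_conf)
    noise = rng.normal(0.0, config.beta_noise_sd, size=(n_cpg, n_samp))
    logits = (
        baseline[:, None]
        + shift[:, None] * case[None, :]
        + confound[:, None] * z_gran[None, :]
        + noise
    )
    return pd.DataFrame(
        np.clip(expit(logits), 0.0, 1.0), index=ann.index, columns=samples.index
    )


def _log_count_noise_sd(mu: float, phi: float) -> float:
    """Delta-method SD of ln(C+1) for C ~ NB(mean μ, var μ + φμ²)."""
    var = (mu / (mu + 1.0)) ** 2 * (1.0 / mu + phi)
    return float(np.sqrt(var))


def _implied_corr(a: float, base_log_mu: np.ndarray, x: np.ndarray, phi: float) -> float:
    """Model-implied Pearson corr(x, log(C+1)) when log μ gains a·x.

    Uses second-order delta approximations for the mean and variance of
    ln(C+1) under NB noise, capturing log-curvature and the μ-dependence of
    the noise (heteroscedasticity).
    """
    mu = np.exp(base_log_mu + a * x)
    var_c = mu + phi * mu**2
    m = np.log1p(mu) - var_c / (2.0 * (1.0 + mu) ** 2)
    v = (mu / (1.0 + mu)) ** 2 * (1.0 / mu + phi)
    cov = np.cov(x, m, ddof=1)[0, 1]
    denom = np.sqrt(np.var(x, ddof=1) * (np.var(m, ddof=1) + v.mean()))
    return float(cov / denom)


def _solve_coupling(
    base_log_mu: np.ndarray, x: np.ndarray, rho: float, phi: float
) -> float:
    """Coefficient a with implied corr(x, log counts) equal to the target ρ."""
    from scipy.optimize import brentq

    if rho == 0:
        return 0.0
    hi = 1.0
    sign = np.sign(rho)
    for _ in range(30):
        if sign * _implied_corr(sign * hi, base_log_mu, x, phi) >= abs(rho):
            break
        hi *= 1.5
    else:
        raise ValueError(f"target correlation {rho} not achievable given noise settings")
    lo, hi = (0.0, hi) if sign > 0 else (-hi, 0.0)
    return float(
        brentq(lambda a: _implied_corr(a, base_log_mu, x, phi) - rho, lo, hi, xtol=1e-10)
    )


def _count_matrix(
    config: SimConfig,
    beta: pd.DataFrame,
    regions: list[dict],
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[dict], list[dict]]:
    n_genes, n_samp = len(genes), len(samples)
    case = (samples["group"] == "case").to_numpy().astype(float)
    base = rng.normal(np.log(300.0), 0.8, size=n_genes)
    lib = rng.normal(0.0, 0.15, size=n_samp)
    log_mu = base[:, None] + lib[None, :]
    gene_pos = {g: i for i, g in enumerate(genes.index)}
    eqtm_genes = {reg["gene"] for reg in regions if reg["rho"] is not None}
    # planted co-expression blocks on genes not used by eQTM couplings
    free = [g for g in genes.index if g not in eqtm_genes]
    coexpr_truth = []
    cursor = 0
    for spec in config.planted_coexpr_specs:
        members = free[cursor : cursor + spec.n_genes]
        cursor += spec.n_genes
        factor = rng.normal(0.0, 1.0, size=n_samp) + spec.group_shift * case
        rows = [gene_pos[g] for g in members]
        for i in rows:
            sd = _log_count_noise_sd(float(np.exp(base[i])), config.nb_dispersion)
            loading = np.sqrt(spec.within_cor / (1.0 - spec.within_cor)) * sd
            log_mu[i] += loading * factor
        coexpr_truth.append(
            {"gene_ids": list(members), "within_cor": spec.within_cor,
             "group_shift": spec.group_shift}
        )
    # eQTM couplings: inject the region's standardized median β
    eqtm_truth = []
    for reg in regions:
        if reg["rho"] is None:
            continue
        rho = reg["rho"]
        med = beta.loc[reg["cpg_ids"]].median(axis=0).to_numpy()
        x = (med - med.mean()) / med.std()
        i = gene_pos[reg["gene"]]
        a = _solve_coupling(log_mu[i], x, rho, config.nb_dispersion)
        log_mu[i] += a * x
        eqtm_truth.append(
            {
                "region_key": f"{reg['chrom']}:{reg['start']}-{reg['end']}",
                "gene_id": reg["gene"],
                "rho": rho,
            }
        )
    mu = np.exp(log_mu)
    phi = config.nb_dispersion
    if phi > 0:
        size = 1.0 / phi
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)
    return (
        pd.DataFrame(counts, index=genes.index, columns=samples.index),
        eqtm_truth,
        coexpr_truth,
    )


def generate_cohort(config: SimConfig = SimConfig()) -> Cohort:
    """Generate one synthetic cohort; identical config+seed gives identical output."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_layout, rng_beta, rng_frac, rng_counts, rng_meta = (
        np.random.default_rng(s) for s in streams
    )
    # metadata and cell fractions from their own streams
    samples = _sample_table(config, rng_meta, rng_frac)
    genes = _gene_models(config, rng_layout)
    ann, regions = _cpg_panel(config, genes, rng_layout)
    beta = _beta_matrix(config, ann, regions, samples, rng_beta)
    counts, eqtm_truth, coexpr_truth = _count_matrix(
        config, beta, regions, genes, samples, rng_counts
    )
    planted_cpgs = {c for reg in regions for c in reg["cpg_ids"]}
    effect_genes = {p["gene_id"] for p in eqtm_truth}
    for m in coexpr_truth:
        effect_genes |= set(m["gene_ids"])
    truth = SyntheticTruth(
        dmr_regions=[
            {
                "region_key": f"{r['chrom']}:{r['start']}-{r['end']}",
                "chrom": r["chrom"],
                "start": r["start"],
                "end": r["end"],
                "cpg_ids": r["cpg_ids"],
                "delta_beta": r["delta_beta"],
                "gene": r["gene"],
            }
            for r in regions
        ],
        eqtm_pairs=eqtm_truth,
        coexpr_modules=coexpr_truth,
        null_cpg_ids=[c for c in ann.index if c not in planted_cpgs],
        null_gene_ids=[g for g in genes.index if g not in effect_genes],
    )
    annotation = ann.drop(columns=["region"])
    return Cohort(beta, counts, samples, annotation, genes, truth)
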