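# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Study design assumed

A two-group (case/control) cohort with, per sample: a CpG-by-sample β-value
matrix (methylation fractions in [0, 1], 450K-array-like), a gene-by-sample
raw count matrix (whole-blood RNA-seq), age, sex, and six blood cell-type
fractions.  Defaults throughout correspond to a small unbalanced design of
12 cases vs 51 controls.

## Differential methylation

Per CpG, ordinary least squares of the β value on
`[intercept, group, age, sex, 5 cell fractions]`, with a two-sided t test
on the group coefficient and BH FDR across the panel.

* **Response scale.**  β values by default; the M-value
  (`M = log2(β/(1−β))`, ε-clipped at 1e-6) is available via
  `DesignSpec(response_scale="m_value")`.  Even under the M-value response,
  the reported `delta_beta` is the group coefficient from the β-scale fit,
  so effect sizes and hypo/hyper labels remain methylation differences.
* **No empirical-Bayes moderation.**  A moderated-t shrinkage
  constant would be arbitrary here and changes little at n = 63; the plain
  OLS t is exact under the model and matches the normal-equations oracle to
  1e-9 in tests.
* **Cell fractions.**  Only five of the six fractions enter the design: the
  six sum to one, so the sixth (granulocytes, the most abundant type, used
  as the reference) would make the design rank-deficient.
* **Degenerate CpGs.**  Zero residual variance (all values identical within
  numerical tolerance) yields NaN t and p; such CpGs are flagged, logged,
  and excluded from the FDR denominator rather than being assigned an
  arbitrary p.

Cell fractions themselves are estimated by constrained projection: each
bulk marker-CpG profile is least-squares projected onto reference cell-type
profiles subject to fractions ≥ 0 and Σ ≤ 1 (NNLS, refined by an SLSQP
quadratic program when the sum constraint activates).  This is the
reference-based deconvolution idea with a simple quadratic program in place
of the original quadratic-programming-with-equality variants; it is exact
on constructed mixtures to 1e-6 and idempotent on its own reconstructions.

## DMR calling

A DMR is a maximal run of consecutively significant CpGs (FDR below the
threshold; 0.05 for genome-wide reporting, 0.1 for eQTM candidate
selection) such that each successive pair of members is ≤ 1000 nt apart
and **no non-significant panel CpG lies between members** — the stricter
reading of "consecutively significant", under which an intervening null CpG
breaks a run.  Runs need ≥ 2 members.  Kernel-smoothed region statistics
are deliberately not reproduced; the two-CpG/1000-nt rule is the operative
definition, and the caller is verified against an exhaustive
window-enumeration oracle on random panels.

Region evidence is combined by Stouffer's method.  The primitive
`stouffer_combine` is the textbook one-sided form
`Z = Σ Φ⁻¹(1−pᵢ)/√n`, `p = 1−Φ(Z)`.  For regions, the two-sided per-CpG
p-values are converted one-sidedly using the sign of the methylation
difference, `zᵢ = sign(Δβᵢ)·Φ⁻¹(1−pᵢ/2)`, and the combined p is two-sided
on |Z| — members of opposing direction cancel, and hypo- and
hypermethylated regions rank on one scale.  Mixed-sign regions are allowed
but flagged.  p-values at 0 or 1 are clipped to 1e-15 and logged.

Coordinates are 1-based inclusive positions of the first and last member
CpG (`chrom:start-end`); BED export converts to 0-based half-open and the
conversion is tested in both directions.  Position ties resolve by stable
input order and are logged.

## Expression

* **Filter:** genes with a non-zero count in at least ⌈0.9·n⌉ samples (the
  boundary is inclusive).
* **Normalization:** median-of-ratios size factors over genes with
  all-nonzero counts, rescaled to geometric mean 1; total-count scaling is
  the logged fallback when no gene is all-nonzero.
* **Transform:** `log2(x+1)` (base 2 with pseudocount 1).
* **Differential expression** is a log-linear OLS on the same design as the
  methylation model.  This is a deliberate surrogate for a negative-binomial
  model with dispersion shrinkage: at these sample sizes the property that
  matters downstream — type-I error control under the null — is provided by
  OLS on log counts, which the null simulations confirm (median 0 FDR<0.05
  discoveries over 20 null cohorts at 12 vs 51).  Effect-size estimates for
  strongly discrete low-count genes would be less efficient than an NB fit;
  that trade-off is accepted and documented.
* **Residualization** for the network stage removes age, sex and the five
  cell fractions per gene (never the group indicator — the group signal is
  what module–trait analysis should retain) and re-adds the gene mean.
* Whether counts should be normalized before the eQTM log transform is an
  open interpretive question; the default normalizes (and the same matrix
  feeds DE and eQTM), with raw counts available by skipping
  `normalize_counts`.

## Co-expression network

Signed adjacency `aᵢⱼ = ((1+cor)/2)^β` with default soft power β = 6 (the
conventional signed-network default; β is a config knob, as is the
signed-hybrid `max(r,0)^β` variant).  TOM:

    TOMᵢⱼ = (Σ_{u≠i,j} aᵢᵤaᵤⱼ + aᵢⱼ) / (min(kᵢ,kⱼ) + 1 − aᵢⱼ)

Modules come from average-linkage clustering of 1 − TOM with a **fixed cut
height** (default 0.9) and minimum module size (default 10); clusters below
the minimum are label 0 ("grey"/unassigned), and surviving modules are
renumbered by decreasing size.  A dynamic tree cut would adapt the height
per branch; the fixed cut is simpler, deterministic, order-invariant (up to
renaming), and sufficient to recover planted blocks with Rand ≥ 0.95, which
is what the pipeline's validation requires.

The module eigengene is the first principal component of the per-gene
z-scored member submatrix, scaled to unit variance (SD with one delta
degree of freedom) and signed so its mean correlation with members is
positive (a stated convention; other tools align to mean expression
instead).  Module–trait association is a Pearson correlation with the
binary group coding and a two-sided t p-value on n−2 df.

ORA is the hypergeometric upper tail `P(X ≥ overlap)` with the supplied
background as population, each set intersected with the background first,
BH across sets.  Gene-set semantics (GO ancestry, term similarity) are out
of scope; sets come from a plain GMT file.

## eQTM engine

For each (DMR, gene) cis pair where the gene survives the expression
filter:

1. per-sample **median** β over member CpGs (midpoint mean for even
   counts);
2. Pearson r against the gene's log2 normalized counts over all samples —
   the combined-cohort r is the primary statistic; group-specific r values
   are descriptive (NaN with a log entry for groups with < 3 samples or
   constant vectors, and no group-difference test is performed);
3. **95% percentile bootstrap CI**, default 100,000 paired resamples of
   sample indices; replicates where either resampled vector is constant are
   redrawn a bounded number of times then dropped with a warning, and > 50%
   degenerate replicates is an error;
4. **resampling p-value**: the expression vector is permuted against the
   methylation vector (exchangeability-exact under the null of no
   association), `p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1)`, default
   n_perm = 10,000 — the add-one estimator keeps p > 0, and exact ties
   (e.g. a drawn identity permutation) count as hits via a 1e-12 slack;
5. labels: region direction from the sign of the mean member Δβ;
   region feature by priority promoter (TSS1500/5'UTR evidence) → 1st
   exon → gene body → intergenic; expression direction from the sign of
   the covariate-adjusted group effect on log expression, falling back to
   the raw mean difference at an exact zero ("none" if both are zero).

Significance is the unadjusted p < 0.05 (mirroring common practice for
small candidate sets selected upstream); a BH q-value column is reported
alongside.  Multi-gene DMRs fan out to one record per gene; unexpressed or
out-of-range pairs go to a drop log.  Intergenic DMRs may be matched to the
nearest TSS within 100 kb (flagged `matched_by_proximity`).

**Calibration facts** (recomputed by `scripts/acceptance.py`): the
permutation p-value is uniform under the null (type-I ≈ 0.05 at α = 0.05
over 1000 null datasets, n = 63).  The percentile bootstrap CI covers
ρ = 0.5 at n = 63 in ≈ 94% of datasets rather than the nominal 95% — a
known small-n property of percentile intervals for correlations, not an
implementation artifact: on identical data the interval matches the
reference implementation in `scipy.stats.bootstrap(method="percentile")`
replicate-for-replicate in coverage.  Users needing closer-to-nominal
coverage at small n should prefer larger cohorts; the interval choice
itself is kept deliberately simple and auditable.

## Synthetic cohorts

The generator produces, from a single seed, a complete dataset with the
statistical structure the analysis assumes.  The global seed expands into
independent streams (layout, β, cell fractions, counts, metadata) so adding
one stream never perturbs another; identical config + seed gives
byte-identical outputs.

* **Panel.**  Default 20,000 CpGs on 6 synthetic 10-Mb chromosomes and
  2,000 genes — a desk-scale stand-in for a 450K array and a filtered
  whole-blood transcriptome.  CpGs are annotated to the nearest gene
  (within 60 kb) with a gene-region feature derived from their position
  (upstream window, first exon, body) or IGR otherwise.
* **β values** are drawn on the logit (M-value) scale: per-CpG baseline
  `N(0, 1.3)` (mid-weighted; real arrays are more bimodal — see
  limitations), plus a group shift for planted-region members, plus a
  cell-composition term, plus `N(0, 0.15)` noise, then inverse-logit — β
  stays in (0, 1) by construction.  The noise level corresponds to a
  β-scale residual SD of ≈ 0.035 at mid-range CpGs, in the range of
  whole-blood array replicate variability; it makes the planted
  Δβ = 0.15 a clearly detectable effect at n = 63, which is the role
  planted regions play in recovery tests.
* **Planted DMRs** place members with gaps in [20, 500] nt anchored to a
  chosen gene according to the requested feature; the case shift is solved
  on the logit scale so the mean β difference equals the requested Δβ at
  the region's baseline.  Defaults plant eight regions (five hypo- and one
  hypermethylated expression-coupled regions with promoter/first-exon/body
  placements, plus two uncoupled ones).
* **Cell fractions** are Dirichlet with a whole-blood-like mean
  (granulocytes ≈ 55%); cases' concentration is shifted (granulocytes
  ×1.25, CD4 ×0.85) so composition confounds the group comparison, and 30%
  of background CpGs carry a `N(0, 0.3)` logit-scale coefficient on the
  standardized granulocyte fraction.  An unadjusted EWAS on such a cohort
  shows genomic inflation that the adjusted model removes — the property
  the covariate design exists for.
* **Counts** are negative binomial with `Var = μ + φμ²` (default
  φ = 0.15), per-gene baselines `exp(N(ln 300, 0.8))` and lognormal
  library-size factors.  For planted eQTM genes the log mean gains
  `a · z(median β of the linked region)`, with `a` found by root-solving
  the model-implied correlation (second-order delta approximations for the
  mean and variance of `log(C+1)` under NB noise, capturing curvature and
  heteroscedasticity) so the realized Pearson correlation targets the
  requested ρ; the realized mean r is within 0.05 of ρ at n = 500.
  Targets |ρ| > 0.95 are rejected as unattainable under the noise model.
  Planted co-expression blocks share a latent factor with loading set from
  the requested within-block correlation; a nonzero group shift on the
  factor (default −2.5 factor-SD in the second default block, chosen once
  so the module is reliably trait-associated after residualization on
  group-correlated cell fractions) makes its eigengene track the
  phenotype.
* **Metadata** defaults mirror a realistic severe-case pediatric design:
  case ages `N(6.95, 3.68²)`, control ages `N(13.20, 2.94²)`, male
  probabilities 7/12 and 33/51.
* **Truth registry** (JSON) records every planted region, coupling, and
  block plus the null CpG/gene id lists, and is what recovery tests score
  against.

**What the generator does not emulate:** array probe chemistry and its
type-I/type-II β distributions (the baseline is unimodal rather than
bimodal, so FDR behaviour at the extremes of the β scale is untested),
probe cross-reactivity and polymorphisms, spatial correlation of
methylation beyond planted regions, gene-length and GC effects on counts,
batch structure, and any trans (distal) coupling.  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every artifact of real array/RNA-seq data.

## Problem sizes used in validation

Recovery and calibration runs use scaled panels chosen to make the suite
quick while keeping the study's sample design (12 + 51) intact: permutation
type-I error and bootstrap coverage use 1000 simulated datasets each
(n_perm = 999, n_boot = 2000); eQTM power uses 200 cohort seeds with a
300-CpG/60-gene panel; DMR sensitivity uses 20 full-scale cohorts;
trait-module detection uses 50 seeds at 300 genes; the expression null uses
20 cohorts at 2,000 genes.  Bootstrap defaults stay at 100,000 replicates
for analysis runs; validation uses 2,000, which changes CI endpoints by
far less than their sampling variability.

## Known limitations

* The DE surrogate is not an NB model; its fold-change estimates for
  low-count genes are noisier than shrinkage estimators would give.
* The fixed-height module cut can split or merge modules that an adaptive
  cut would resolve; `cut_height` and `min_module_size` are the knobs.
* Percentile bootstrap CIs undercover by ≈ 1 point at n ≈ 63 (see above).
* The promoter definition (5'UTR, first exon, 1500 bp upstream of the TSS)
  is a fixed convention; enhancer-mediated coupling is out of scope.
* Group-specific correlations are descriptive; the pipeline deliberately
  performs no case/control correlation-difference test.
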