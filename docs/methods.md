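# Methods

This note documents the models, estimators and numerical choices behind
`dualscreen`, what the synthetic data does and does not emulate, and the
design decisions taken where the underlying experimental practice leaves the
analysis under-specified.

## The experimental design being modeled

Both screen arms perturb the same guide library: ~100 target genes with four
unique sgRNAs each, plus safe-targeting controls (cut a neutral locus; the
null background for gene scoring) and non-targeting controls. Cells are
transduced at MOI ≤ 0.3 and drug-selected, so the analyzed population carries
at least one integration and is mostly single-guide.

* **Sorted-bin (flow) arm.** The phenotype is the protein level of an early
  differentiation reporter (KRT10-like). Cells are FACS-gated into low /
  medium / high reporter bins; guide abundance per bin is measured by
  UMI-deduplicated amplicon sequencing. A knockout that blocks
  differentiation leaves its cells reporter-low: its guides enrich in the low
  bin and deplete from the high bin.
* **Perturb-seq arm.** The phenotype is the position of a cell's
  transcriptome along a differentiation trajectory. Knockouts that block
  differentiation hold their cells at early pseudotime.

## Synthetic data generator (`simdata`)

The generator is the package's ground-truth instrument: every planted effect
is recorded so downstream stages can be scored for recovery.

**Latent state.** Each cell draws a differentiation time t ~ Uniform(0,1).
A knockout of gene g shifts it to clip(t + δ_g, 0, 1); δ_g < 0 means cells
fail to progress (mass accumulates near t = 0, a truncation rather than a
pure shift). Defaults plant no effects; study-style runs plant δ = −0.3.

**Guide capture.** Integrations per cell follow a *zero-truncated*
Poisson(MOI): drug selection removes untransduced cells, and the truncated
distribution is what the observed multiplet fraction (≈ 14.3% at MOI 0.3)
refers to. Captured guide UMIs are 1 + Poisson(14) per integrated guide, so
the detection threshold (3 UMIs) essentially never misses a real integration;
ambient contamination is not modeled.

**Flow arm.** The reporter is a logistic function of t (span 4 log-units,
midpoint 0.6, steepness 8) plus the knockout's direct reporter effect and
Gaussian noise (sd 0.5). Only single-integration cells are binned (multiples
are rare at this MOI and a real sorter cannot deconvolve them). The three
configured quantiles (default 0.2, 0.5, 0.865) cut the reporter distribution
into four contiguous gates: low, medium, a broad un-gated remainder that
stands in for the *unsorted* pool, and a high gate taking the top ~13.5% —
the benchmark fraction of reporter-high cells in a differentiated culture.
This remainder reading (rather than a uniform subsample) keeps the four bins
an exact partition of the sorted population, which the count bookkeeping
relies on; its cost is that the simulated unsorted pool is mildly
reporter-biased, which the high-vs-rest / low-vs-rest comparisons tolerate.
Guide UMI counts per bin are multinomial over the guides carried by the
bin's cells, at a depth proportional to bin size, totalling `flow_depth`
per replicate.

**Perturb-seq arm.** Gene relative abundances are lognormal(0, 1). Thirty
progenitor-program genes fall and thirty differentiation-program genes rise
logistically in t (floor 0.05, midpoint 0.5, steepness 8) — the named 3+3
marker panels used for orientation are the first members of each set; a
trajectory recoverable from correlation distances needs a realistically
sized dynamic program, not just six genes. Target genes are expressed flat
and knocked down ×0.3 in cells carrying their guides (so knockout efficiency
is checkable). Mitochondrial genes hold ~2.5% of reads on average with
lognormal per-cell load variation (sd 0.25 log-units), putting a realistic
minority of cells over the 5% QC gate. Counts are negative binomial via a
Gamma-Poisson mixture, var = μ + 0.3 μ², at lognormal per-cell depth around
2,000 UMIs.

**Not emulated:** ambient RNA, doublets by collision, batch effects,
cell-cycle structure, read-level errors, guide-efficiency variation.
Passing recovery tests therefore demonstrates the statistical machinery is
correct and calibrated under the assumed generative model, not robustness to
those artifacts.

## Flow-arm scoring (`guideio`, `flowscreen`)

* **UMI counting** deduplicates by exact 9-nt UMI match per guide;
  collapsing near-duplicate UMIs is deliberately not attempted. Unknown
  guides and malformed UMIs go to a rejection log rather than aborting.
* **Representation QC**: coverage (fraction of designed guides observed),
  Gini coefficient by the mean-absolute-difference formula, and the 90/10
  percentile count ratio (∞ when the 10th percentile is zero).
* **Normalization** uses median-of-ratios size factors over guides nonzero
  in all samples, falling back to total-count scaling when fewer than
  min(100, n_guides) such guides exist.
* **α-RRA**: guides ranked by LFC per replicate (average ranks across
  replicates, ties averaged, renormalized to (0,1]); a gene's ρ is the
  minimum Beta order-statistic CDF over guides ranked inside the top α
  (default 0.25). The permutation p draws gene-sized rank sets without
  replacement from the safe-targeting guide ranks (all ranks when fewer
  than 20 controls are present), sharing the null distribution across genes
  of equal size; p = (1 + #{ρ* ≤ ρ}) / (n_perm + 1), so the smallest
  achievable value is 1/(n_perm+1).
* **ψP**: Fisher's χ²₄ combination of the low-enrichment+high-depletion pair
  (pro-differentiation direction) and of the mirrored pair. The smaller of
  the two is reported with its direction (called at ψP ≤ 0.05, configurable).
  ψP is a ranking score, not a calibrated error rate: the two comparisons
  share background bins. The *beta score* is the median high-vs-rest guide
  LFC — an effect-size proxy named after the convention of labeling
  gene-level screen effects "beta".

## Perturb-seq preprocessing (`cellprep`)

Filters follow the screen's stated gates with these boundary semantics:
mitochondrial fraction strictly < 0.05, total UMIs ≥ 200 ("RNAs" read as
total UMIs, not detected genes), exactly one detected guide (≥ 3 capture
UMIs). Normalization is log1p of counts scaled per cell to the median
total — a deliberately simple monotone transform; the trajectory's
correlation distances are insensitive to the choice among monotone
variance-stabilizers at this fidelity, and the function is swappable.
Variable features are ranked by dispersion (variance/mean) z-scored within
20 equal-frequency mean bins, ties broken by gene id for determinism.

## Trajectory (`trajectory`)

Classical (Torgerson) MDS on 1 − Pearson distances: double-center the
squared-distance matrix, eigendecompose, keep the top-k (default 10)
non-negative eigenpairs; eigenvalues below 10⁻¹² of the leading one are
treated as rank deficit; each axis's sign is fixed by its largest-magnitude
loading. The principal curve initializes from the first MDS coordinate,
then iterates: order cells by arc-length projection, smooth each coordinate
against the order with a centered rolling mean over 10% of cells, thin to
100 nodes, re-project onto the piecewise-linear curve. Convergence is
declared when mean projection-foot displacement falls below 10⁻⁴ of the
curve span (max 100 iterations; the best iterate is returned flagged if not
converged — near the fixed point the ordering of near-tied cells can
oscillate harmlessly). Pseudotime is arc length min-max rescaled to [0,1];
cells projecting beyond the curve ends tie at 0 or 1. Orientation flips the
curve iff mean progenitor-marker expression correlates positively with
pseudotime. On simulated data (1,000 cells, default noise) pseudotime
attains Spearman ≥ 0.9 against the true latent time.

## Phenotyping statistics (`perturbstats`)

* **Shift test**: one-sided Mann-Whitney (target cells earlier) against all
  other single-guide cells; exact enumeration when n₁+n₂ ≤ 20 without ties,
  otherwise normal approximation with tie and continuity corrections. The
  signed Z is the standardized U (negative = target earlier). One-sided p's
  are BH-adjusted across genes; a two-sided version (doubled one-sided,
  capped at 1) is adjusted separately for use in classification, where
  either direction must be detectable.
* **Density profiles**: Gaussian KDE evaluated at 40 evenly spaced points on
  [0,1] (pseudotime's codomain; the evaluation range is fixed rather than
  data-driven so profiles are comparable across genes). Bandwidth defaults
  to Scott's rule and is recorded; an explicit bandwidth supports degenerate
  samples. The implementation is the plain Gaussian-sum evaluation and
  matches the reference `scipy.stats.gaussian_kde` to 10⁻⁸ at equal
  bandwidth.
* **Windowed enrichment**: for each of the 31 stride-1 windows of 10 grid
  points, one-sided Mann-Whitney between the 10 target and 10 reference
  density values, in both directions. The reference profile uses *all*
  cells, including the target's own. These p-values compare smooth,
  autocorrelated curves and are **not calibrated**; they localize where
  along pseudotime a target's cells concentrate. An alternative
  cell-pooling reading — hypergeometric enrichment of the target's cell
  count within each window's pseudotime interval
  (`windowed_enrichment_cells`) — is provided but not used by the default
  pipeline; no fidelity claim is made for either reading over the other.
* **Classification**: pro-differentiation requires (i) some window among
  the first 10 (low pseudotime) enriched at α = 0.05, (ii) shift Z < 0, and
  (iii) BH-adjusted two-sided shift p < α; pro-progenitor mirrors this in
  the last 10 windows. Requirement (iii) exists because the window test
  alone — even sign-gated by Z — flagged ~75% of null genes in calibration
  simulations (the windows' MW inputs are 10 points of one smooth curve
  each); conjoining the calibrated shift test restores the null call rate
  to < 5% while planted effects (δ = −0.3, ≥ 45 cells/target) remain
  recovered at ~100%.

## Integration (`integrate`)

Mean of within-arm ranks (beta score ascending; shift Z ascending), so the
pro-differentiation direction ranks low. Mean ranks are used instead of a
p-value combination because ψP and the shift p are dependent and differently
calibrated. The cross-arm Spearman correlation of beta score vs shift Z is
reported; the concordance flag requires matching non-null direction calls.

## Problem sizes used in validation

Simulation-backed tests run at sizes chosen so the dense cell-cell distance
matrix and the 20-seed sweeps stay cheap: the recovery sweep uses 50 target
genes (5 planted at δ = −0.3, reporter effect −1.5), 24 safe + 16
non-targeting controls, and 3,500 cells (≈ 45–50 single-guide cells per
target after QC) over 20 seeds; the flow-only recovery uses 10 genes, 2,000
cells and 100,000 UMIs per replicate over 20 seeds; RRA calibration uses
1,000 null genes × 4 guides with 1,000 permutations. At these sizes the
planted targets are recovered in all arms in ≥ 90% of seeds with the null
direction-call rate well under 5%.

## Known limitations

* Single, unbranched trajectories only; no graph-based pseudotime.
* The window statistic inherits the anticalibration described above; treat
  window p-values as descriptive localization, not inference.
* ψP is a dependent-evidence combination; rank by it, don't threshold it as
  an FDR.
* The shift-test background ("all other single-guide cells") is contaminated
  by true hits; with many strong perturbations concentrated at one end of
  pseudotime, null genes acquire a small opposite-direction bias. The
  classification conjunction absorbs this at the simulated effect densities
  (5 planted of 50 genes), but screens where a large fraction of targets are
  real hits would need a control-cell background instead.
* Exact UMI deduplication only; sequencing errors inflate UMI counts
  slightly rather than being collapsed.
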