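# Methods

## Scope and shape

`ppbc` is a library of composable analysis stages for parity-stratified
breast cancer transcriptomics. Each stage is a plain function over pandas
containers (genes × samples matrices, sample-indexed metadata, long-format
clonotype tables); `examples/` shows each one end to end. There is no
command-line wrapper: the functions plus the example scripts are the
interface.

## Differential expression

Counts are normalized to CPM; genes are kept when CPM exceeds a threshold
(default 0.05) in at least `min_samples_per_group` (default 3) samples of
*every* group. The two-group test is Welch's t on log2(CPM + 1) with
Benjamini–Hochberg adjustment (statsmodels). This is intentionally not a
count-model (dispersion-shrinkage) method: the downstream consumers need
a ranked signature and an FDR-controlled gene list, and the Welch test's
type-I error is verified by simulation to sit at its nominal level on
negative-binomial data at n = 10/group. Consequently, gene lists from
shrinkage-based tools will agree only approximately, especially for
low-count genes.

Fold changes are log2 ratios of pseudocounted (pc = 1) group-mean CPM.
Genes whose test is degenerate (zero variance and zero difference) are
reported with stat 0, p 1.

Sample clustering z-scores each gene across samples (ddof = 1; sd = 0
rows set to 0), then applies average-linkage clustering on Euclidean
distances (scipy). Columns are sorted lexicographically beforehand so
equal-height merges resolve deterministically.

## Gene set enrichment

The enrichment score is the weighted KS running-sum statistic with hit
weight |s|^p (p = 1 by default). Ties in the ranking are broken
lexicographically by gene symbol. The permutation null defaults to
`gene_set` mode — random same-size gene sets drawn from the signature —
because phenotype permutation is underpowered at the cohort sizes this
analysis targets (n ≈ 16); phenotype mode is available and refuses to run
with fewer than 3 samples per group. `p_nominal` is the fraction of
same-sign permuted ES at least as extreme; NES divides the ES by the mean
|ES| of same-sign permutations and is reported missing when no
permutation lands on that sign. Across a collection, BH FDR is applied
within each ES sign class. Permutations use an O(k) evaluation on hit
positions, verified in tests against the full running-sum profile.

Single-sample gene set scores are the mean per-gene z-score across
samples over member genes. The mean-z convention is the simplest
reproducible choice; ssGSEA-style rank weighting is a noted alternative,
not implemented. Constant genes contribute 0.

## Regulon activity and the composite score

Expression is rank-transformed per sample to standard-normal quantiles
z = Φ⁻¹((rank − 0.5)/N), ties mid-ranked; activity is the weighted
two-tail sum A = Σ w·m·z / √(Σ w²) over targets (mode m ∈ [−1, 1],
likelihood w ∈ (0, 1], minimum 10 targets present by default). This
preserves the properties the composite depends on — sign, confidence
weighting, rank basis, monotone-transform invariance — without the
three-tail interaction terms of full inference-engine implementations,
which is a documented divergence from them. Master-regulator ranking
applies the same weighted sum to a group-contrast t-statistic signature
with a gene-label permutation p value.

The composite postpartum score is P = A_exhaustion + A_E2F1 − A_TP53 −
A_ESR1. The immune-exhaustion component is a gene set, scored by the same
operation with m = +1, w = 1. Both raw and z-standardized combinations
are available (`standardize=`); raw is the default and is what the
acceptance script uses.

## Repertoire diversity

Frequencies f_k are counts over the sample total after summing duplicate
(sample, key) rows. H = −Σ f_k ln f_k; normalized entropy H/ln n;
clonality C = 1 − H/ln n. For n = 1 the formula is 0/0; the
distributional limit C = 1 (normalized entropy 0) is used. The Gini index
uses the mean-absolute-difference definition, computed via sorted
cumulative sums and tested against an O(n²) pairwise oracle. Clonal-space
occupancy bins repertoire mass by clone frequency with default edges
(0, 10⁻⁵, 10⁻⁴, 10⁻³, 10⁻², 1], labelled rare → hyperexpanded;
edges are configurable.

Note an asymmetry: splitting a clone always increases H but can *raise*
clonality, because ln n grows with richness; the tests assert only the
entropy direction.

## Subtype and recurrence scores

Nearest-centroid subtyping correlates each sample's profile over the
50-gene intrinsic-subtype panel with five centroids using Spearman
correlation (robust to platform scale and monotone transforms); ties are
assigned to the lexicographically first subtype and flagged. The packaged
centroid table is **synthetic**: it spans the published 50 panel gene
symbols with constructed values reproducing the qualitative
luminal/HER2/basal/proliferation structure, because the published numeric
centroids are not redistributable here. Real centroids in the same layout
can be passed directly; results with the synthetic panel demonstrate the
machinery, not clinical concordance.

The recurrence score normalizes each of 16 target genes by subtracting
the per-sample mean of 5 reference genes and adding 10, then applies the
published group formulas (GRB7 group 0.9·GRB7 + 0.1·ERBB2 floored at 8;
ER group (0.8·ESR1 + 1.2·PGR + BCL2 + SCUBE2)/4; proliferation mean of 5
floored at 6.5; invasion mean of 2) and coefficients (+0.47, −0.34,
+1.04, +0.10, +0.05 CD68, −0.08 GSTM1, −0.07 BAG1), with
RS = 20(RS_u − 6.7) clipped to [0, 100]. The expression scale fed in is
the caller's choice (log2-like by default) and is recorded in the output;
the reference normalization makes the score shift-invariant but not
scale-invariant.

## Survival

The log-rank test accumulates O − E with hypergeometric variance over
pooled event times (event-time ties handled in one risk-set step);
p is two-tailed from χ²(1). The primary hazard ratio is the O/E form
(O_A/E_A)/(O_B/E_B) with CI exp(±1.96·√(1/E_A + 1/E_B)) — the convention
of common survival-plotting software — not a fitted Cox coefficient; a
lifelines Cox fit is available via `include_cox=True` as a secondary
estimate, and is left off by default both for speed and because it is
unstable under near-separation. Kaplan–Meier estimation delegates to
lifelines. Median splits send ties at the median to "lo"; follow-up
truncation (default 180 months = 15 years) censors later times at the
horizon and is idempotent.

## Cohort merging

Probe-level matrices are collapsed to genes by arithmetic mean; the gene
space is the intersection across studies (no imputation). Each gene is
centered and unit-scaled within each study before concatenation. This
removes additive and multiplicative batch effects exactly — the
no-shrinkage limit of empirical-Bayes batch correction — but also removes
genuine cross-study location differences, so absolute expression
comparisons across studies are not meaningful after merging; rank- and
split-based analyses are. The age filter defaults to ≤ 45 years with a
strict-< option, both logged, since both conventions appear in cohort
definitions.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with one RNG stream per artifact section (counts, clonotypes, survival,
layout) spawned from a single master seed.

- **Counts**: NB(mean, size), shared size `nb_dispersion` = 10; per-gene
  baselines log-normal (log-mean 4, log-sd 1.5, natural log); library
  sizes log-normal around 10⁶ with CV 0.2 so CPM ≠ raw counts. Five
  planted blocks of `targets_per_regulon` genes — cell-cycle, immunity
  and exhaustion programs up in the postpartum group by
  `program_effect_log2fc` (default 2), ESR1-like and TP53-like regulon
  targets down by the same amount — plus null TF regulons over the
  remaining genes. Because expected column sums are fixed at the drawn
  library size, CPM is compositional: planting shifts on a minority of
  genes compresses observed fold changes by ~0.1–0.2 log2 units, which
  the recovery tolerances (±0.3) absorb.
- **Clonotypes**: each repertoire draws 5000 reads from a Zipf law over
  its group's clone ranks; richness per group from `n_clones_per_group`
  (default 150 vs 400) and the postpartum tail exponent is
  `clone_alpha × 1.25` (default 1.2 → 1.5), giving the postpartum group
  higher richness but lower normalized entropy. The expected sampled Gini
  at α = 1.5 over 1000 clones is pinned against an independent 10⁶-draw
  Monte-Carlo value (0.8928).
- **Survival**: event times exponential with hazard λ₀·exp(β·score),
  λ₀ = 0.01/month, β = ln 2 per unit score, administrative censoring at
  180 months. Note that when the score is the raw composite (several
  units of spread), β = ln 2 produces a very strong, near-separating
  effect — appropriate for qualitative recovery checks, not for effect
  calibration.

What the simulations do *not* emulate: FFPE degradation artifacts,
gene–gene correlation beyond the planted blocks, realistic V(D)J
sequence structure, platform-specific microarray noise, or informative
censoring. Passing recovery tests therefore demonstrates the pipeline's
correctness and statistical calibration on its assumed generative model,
not performance on archival clinical data.

## Problem sizes in the checked runs

The test suite and the acceptance script use: n = 20/group × 2000 genes
for differential-expression and regulon recovery; n = 100/group × 1500
genes for the full composite-to-survival chain; 200 replicates × 1000
permutations for the enrichment null calibration; n = 500/group for the
HR = 2 recovery and 200 replicates of n = 60/group for the log-rank null
calibration. These sizes give stable Monte-Carlo estimates (calibration
fractions move by well under their acceptance bands across seeds) while
keeping the full run in the tens of seconds.
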