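# ppbc — postpartum breast cancer signature pipeline

Breast cancer diagnosed within a few years of childbirth (postpartum
breast cancer, PPBC) carries a markedly worse prognosis than
age/stage/subtype-matched disease in nulliparous women (NPBC), yet the
two look identical in the clinic. This package implements, as a tested
and reusable library, the transcriptomic analysis chain by which that
distinction can be drawn from bulk RNA-seq of ER+ young-women's breast
cancer — and by which a composite transcription-factor-regulon signature
of the postpartum state can be used to stratify survival in larger
cohorts. A synthetic-data generator with planted effects makes every
stage runnable and testable entirely offline.

## What it computes

- **`ppbc.preprocess`** — CPM normalization, the "CPM > 0.05 in ≥ 3
  samples of every group" expression filter, two-group differential
  expression (Welch's t on log2(CPM+1), Benjamini–Hochberg FDR), and
  z-score / Euclidean / average-linkage sample clustering.
- **`ppbc.enrichment`** — weighted Kolmogorov–Smirnov gene set
  enrichment: for a signature ranked by a per-gene statistic, member
  genes add |s|^p (normalized), non-members subtract 1/(N−N_h); the ES is
  the signed maximum of the running sum, with permutation p values and
  NES = ES / mean |ES_perm| of the same sign. Single-sample gene set
  scores (cell-cycle, immune-infiltrate) are the mean per-gene z-score.
- **`ppbc.regulon`** — single-sample TF regulon activity
  A = Σ w·m·z / √(Σ w²) on rank-normal quantile scores, master-regulator
  ranking against a contrast signature, and the composite score
  **P = A_exhaustion + A_E2F1 − A_TP53 − A_ESR1**.
- **`ppbc.tcr`** — TCR repertoire diversity: richness, Shannon entropy
  H = −Σ f_k ln f_k, clonality C = 1 − H/ln n, Gini index, clonal-space
  occupancy bins.
- **`ppbc.subtypes`** — nearest-centroid intrinsic subtyping (Spearman
  correlation against a 50-gene centroid panel; a synthetic stand-in
  panel is packaged, any panel can be supplied) and the pseudo 21-gene
  recurrence score with the published group weights, floors and
  RS = 20(RS_u − 6.7) scaling.
- **`ppbc.survival`** — Kaplan–Meier curves, the Mantel–Cox log-rank
  test with O/E hazard ratio HR = (O_A/E_A)/(O_B/E_B), median-split
  stratification and 15-year follow-up truncation.
- **`ppbc.cohort`** — multi-study microarray merging: probe→gene
  averaging, per-study location-scale standardization, age/outcome/ER
  cohort filters.
- **`ppbc.simulate`** — the synthetic cohort generator (negative-binomial
  counts with planted programs, Zipf clonotype tables, exponential
  proportional-hazards survival).

## Worked example

```python
import numpy as np, ppbc

out = ppbc.simulate_cohort(ppbc.SimConfig(n_samples_per_group=100, n_genes=1500, seed=6))
expr = np.log2(ppbc.compute_cpm(out.counts) + 1)

named = {r.tf: r for r in out.regulons}
exhaustion = ppbc.Regulon.from_gene_set(
    next(g for g in out.gene_sets if g.name == "EXHAUSTION"))
scores = ppbc.activity_table(expr, [named["E2F1"], named["ESR1"], named["TP53"], exhaustion])
composite = ppbc.ppbc_composite(scores)
meta = ppbc.simulate_survival(composite, ppbc.SimConfig(seed=8))
result, split, km_hi, km_lo = ppbc.stratified_survival(composite, meta)
print(result.hr, result.p)
```

prints

```
median split: {'lo': 100, 'hi': 100}
log-rank chi2=245.39  p=2.63e-55
O/E hazard ratio hi vs lo: 5.47  (95% CI 3.73-8.02)
```

i.e. samples in the high half of the composite postpartum score die
substantially faster (HR ≫ 1) — the planted proportional-hazards effect
is recovered through the whole scoring-splitting-testing chain. The
scripts in `examples/` walk through each capability the same way
(differential expression + GSEA, the composite signature, repertoire
diversity, subtyping and cohort merging) and print what the numbers mean.

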