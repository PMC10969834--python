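# circlex

Analysis pipeline for a **circular reprogramming** experiment: neural
stem cells (NSCs) derived from embryonic stem cells are reprogrammed to
induced pluripotency and re-differentiated into the same NSC type, and
the two isogenic NSC populations (ESC-NSC vs iPSC-NSC) are compared at
the transcriptome and DNA-methylome level. Because the somatic lineage
travels through pluripotency and back, any difference isolates
reprogramming-associated change from somatic epigenetic memory. The
package is aimed at computational biologists who want a tested,
seedable implementation of this comparison — and a synthetic-data
generator that reproduces its statistical structure, so every stage is
verifiable without access to the original arrays.

## What it computes

- **Surrogate-variable-adjusted differential expression.** Per gene g,
  OLS of log2 expression on [1, origin, SV₁…SV_q], two-sided t test on
  the origin coefficient, Benjamini–Hochberg across genes
  (adjusted p < 0.01), and a 2-fold filter (|log2FC| ≥ 1). Surrogate
  variables are the leading right singular vectors of the
  design-residualized matrix that survive a permutation
  (parallel-analysis) threshold — they absorb batch and background
  structure without modeling it explicitly.
- **Chromosome / gene-set / imprinted-gene enrichment.** One-sided
  hypergeometric upper tail P(X ≥ k) with N = measured features,
  K = features in the category, n = query size; BH across categories;
  separate tests of the up/down (hyper/hypo) subsets.
- **Delta-beta differential methylation.** A CpG is called when the
  difference of group-mean beta values satisfies |Δβ| > 0.2
  (iPSC-derived minus ESC-derived; hyper = positive).
- **Positional scan and co-localization.** 10 Mb windows sliding in
  1 Mb steps; per window a one-sided binomial test of k hits among m
  features against the chromosome-wide hit rate, BH across windows;
  enriched expression and methylation windows that overlap are merged
  into co-localized regions.
- **Pluripotency and neurality scores.** NMF (k = 8, multiplicative
  updates, deterministic SVD-based init) on a labeled reference cohort;
  components ranked by AUROC for the target class; a ridge logistic
  head with **non-negative coefficients** (projected gradient on the
  convex objective); new samples projected onto the basis by
  non-negative least squares and scored as w·h + b on the logit scale.
- **Clustering / PCA / separation.** UPGMA on distance 1 − Pearson r,
  Newick export; centered SVD PCA over all / autosomal / chrX features;
  mean-silhouette separation summaries.
- **Synthetic data.** A seeded generator planting the study's
  structure: two genetic backgrounds, batch effects, an X-specific
  upregulation clustered in 10 Mb regions, X CpGs splitting from
  beta ≈ 0.5 to 0.8/0.2, and a pluripotent/brain/other reference
  cohort, with all ground truth returned.

## Worked example

```python
import numpy as np
import circlex as cx

cfg = cx.SyntheticConfig(seed=1)
ann = cx.generate_annotation(cfg)
expr, truth = cx.generate_expression(cfg, ann)

nsc = expr.subset_samples(expr.metadata.index[expr.metadata.lineage == "NSC"])
labels = nsc.metadata["origin"]
design = np.column_stack([np.ones(len(labels)), (labels == "iPSC-NSC").astype(float)])
svs = cx.estimate_surrogate_variables(nsc, design, seed=42)
de = cx.test_differential_expression(nsc, labels, svs,
                                     reference="ESC-NSC", treatment="iPSC-NSC")
sig, fold = cx.filter_significant(de, alpha=0.01, fold_change=2.0)
enr = cx.chromosome_enrichment(sig, ann.genes, directions=de.loc[sig, "direction"])
print(len(sig), len(fold), enr.loc["chrX", "p"])
```

prints

```
60 27 1.373709078894627e-81
```

60 genes pass BH < 0.01 and 27 of them deviate ≥ 2-fold; the planted
effect is 60 X genes, and the chrX hypergeometric p of ~1e-81 reflects
that essentially the whole significant set sits on the X chromosome —
the qualitative signature of X-specific reprogramming escape (a handful
of counts shift with the surrogate-variable seed). The same objects
flow on into the scan and co-localization:

```python
gx = ann.genes[ann.genes.chromosome == "chrX"]
win = cx.window_scan(gx.loc[gx.index.intersection(sig), "position"],
                     gx["position"], "chrX")
print(int(win.enriched.sum()))   # 33 enriched 10 Mb windows over the planted clusters
```

Or run everything from the shell:

```bash
circlex run --seed 1 --outdir out/   # full pipeline, summary.json + TSV/BED/Newick
circlex simulate --seed 1 --outdir data/
circlex de --expr data/expression.tsv --meta data/samples.tsv --annot data/genes.tsv -o de.tsv
```

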