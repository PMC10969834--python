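# Methods

## The analysis this package implements

`circlex` analyses a "circular" reprogramming design: neural stem cells
(NSCs) derived from embryonic stem cells (ESC-NSCs) are reprogrammed to
induced pluripotency and re-differentiated into the same NSC type
(iPSC-NSCs). Because the somatic lineage is propagated through
pluripotency and back, differences between the two NSC populations
cannot be attributed to heterologous somatic memory; they isolate
reprogramming-associated change. The biological expectation, which the
synthetic generator encodes, is that autosomal expression and
methylation are reinstalled almost perfectly while a clustered subset of
X-chromosomal genes escapes: they are upregulated in iPSC-derived cells,
and X CpGs that sit at an intermediate methylation level (beta ≈ 0.5,
the signature of one methylated and one unmethylated allele under X
inactivation) split to hyper- (≈0.8) or hypomethylated (≈0.2) states.

## Synthetic study design

The generator is the package's definition of the study conditions; all
downstream calibration and recovery checks run against it.

Sample layout (defaults): 2 genetic backgrounds x {1 parental ESC line,
1 iPSC line, 1 ESC-NSC line, 3 iPSC-NSC lines} x 3 replicates = 36
samples, of which 24 are NSCs (6 ESC-NSC vs 18 iPSC-NSC). Three
iPSC-derived NSC lines per parental line in biological triplicate
mirrors the published panel's proportions; replicate r is assigned to
experiment batch r mod 3. Methylation is generated for the NSC samples.

Expression model per gene g, sample i (log2 scale):

    y_gi = mu_g + bg_g*background_i + batch_g*batch_i + lin_g*lineage_i
           + delta * 1[i iPSC-derived AND g affected-X] + eps_gi

with mu_g ~ N(7, 1.5), per-gene coefficients bg_g ~ N(0, 0.7),
batch_g ~ N(0, 0.5), lin_g ~ N(0, 1.0), residual sd 0.25 and
delta = 1.0 log2 units on 12% of the 500 X genes. Per-gene random
coefficients (rather than shared shifts) give the heterogeneous
confounding that surrogate-variable analysis is designed to remove.
Integer coding of batch (0,1,2) is deliberate and simple; one side
effect is that batches 1 and 2 share an effect direction, so
correlation-based clustering tends to split batch 0 from the rest
before splitting backgrounds — both structures are present, as in the
study's dendrograms.

The affected X genes are confined to 3 disjoint 10 Mb intervals on a
155 Mb chromosome; unaffected X genes are placed on the complement so
the intervals are clean ground truth. Differentially methylated X CpGs
(10% of 1000) sit at beta 0.5 in ESC-NSCs and 0.8/0.2 (half each) in
iPSC-NSCs; 80% of them are placed inside the first two expression
clusters, creating the co-localization ground truth. Beta values are
Gaussian noise (sd 0.05) around the group mean, clipped to [0, 1] — a
deliberate simplification over a Beta distribution that matches the
|delta-beta| calling rule exactly. Non-DM CpGs draw a baseline from
{0.1, 0.5, 0.9}.

What the generator does **not** emulate: probe-level microarray
artifacts, intensity-dependent variance, probe cross-hybridization,
Infinium type-I/II chemistry differences, cell-composition mixtures,
correlated co-expression modules, or line-specific (as opposed to
background/batch) effects. Passing recovery tests therefore demonstrates
that the statistical machinery is correct and calibrated under the
declared generative model, not that it is robust to every artifact of
real arrays.

The magnitude of the X upregulation is not published; 1.0 log2 units is
a testability choice exposed in the config. The scale (10,500 genes,
20,000 CpGs) keeps the full pipeline under ~10 s on one CPU while
retaining genome-scale multiple-testing behavior.

## Differential expression with surrogate variables

The primary comparison regresses each gene on [intercept, origin] plus
surrogate variables and tests the origin coefficient with a two-sided t
test (residual df = n - p), Benjamini-Hochberg corrected across genes.
With no surrogate variables the procedure reduces exactly to the
equal-variance two-sample t test, which is the oracle used in tests.
Reported log2 fold changes are raw group-mean differences (iPSC-derived
minus ESC-derived); "2-fold" means |log2FC| >= 1. Thresholds are strict
inequalities (adjusted p < 0.01). Zero-variance genes get t = 0, p = 1
and a flag rather than NaNs.

Surrogate variables use the two-step construction: residualize the
primary design per gene, eigen-decompose the residual sample-by-sample
Gram matrix, and retain leading components whose variance fraction
exceeds the 95th percentile of the matching component from 20
permutation null datasets (each built by independently permuting every
gene's raw values and re-residualizing on the design — permuting the
residuals directly and not re-residualizing biases the null, because
permutation restores the rank lost to the design projection). Retention
stops at the first failing component. This is parallel analysis, chosen
over iteratively re-weighted SVA because the acceptance property is
batch recovery, not equivalence to a particular package; the number of
surrogate variables is data-driven (auto) by default.

Calibration under the null (all planted effects zero): type-I rate at
p < 0.05 within [0.04, 0.06] over >10^4 gene tests, zero surrogate
variables in ~95% of pure-noise datasets, and non-significant chrX
enrichment in >=90% of seeds.

Pairwise per-line comparisons (one iPSC-NSC line's triplicate vs the
matched ESC-NSC triplicate) use the plain equal-variance t test with BH
at 0.05 and report a chrX hypergeometric p per pair. Note a power
limitation of the default conditions: at 3v3 (df 4), residual sd 0.25
plus batch variance, no gene can reach BH-adjusted 0.05 among 10,500
tests at a 1.0 log2 effect, so per-pair significant sets are empty on
default synthetic data; the operation is validated on constructed
positive controls with larger effects. The pooled comparison (6 vs 18
with surrogate adjustment) is the powered analysis.

## Enrichment

All enrichment is the one-sided hypergeometric upper tail
P(X >= k | N, K, n) against the universe of *measured* features (never a
genome-wide count). Chromosome enrichment is computed per chromosome
with BH across the 23 categories, overall and separately for the
up/down (or hyper/hypo) subsets — the directional split uses the full
universe with the directional subset as query. Gene-set overlap (GMT
input) and imprinted-gene enrichment (one gene counts once regardless
of its number of DM CpGs; CpGs map to their nearest annotated gene) are
the same primitive. The implementation is verified against exhaustive
enumeration of all draws for every valid parameter tuple with N <= 12
(agreement to 1e-12) and against exact rational binomial-coefficient
sums for larger cases.

## Differential methylation

Delta-beta is the difference of group-mean beta values (iPSC-derived
minus ESC-derived; means over available replicates, with CpGs flagged if
a group is entirely missing). A CpG is called when |delta-beta| is
strictly greater than 0.2. No variance-based per-CpG test is applied —
the threshold criterion is the method. At the default noise level
(sd 0.05, 6 vs 18 replicates) a planted |delta-beta| of 0.3 is ~10
standard errors past the threshold, giving sensitivity ~100% and a
false-call rate indistinguishable from zero (the threshold is ~8 se
under the null).

## Positional scan and co-localization

A 10 Mb window slides in 1 Mb steps along the chromosome (1-based
half-open; a final clipped window covers the tail). Per window, the k
hit features of the m located there are tested against the
chromosome-wide hit rate with the one-sided binomial tail, BH across
windows; a window is enriched when adjusted p < 0.05 and k >= 3 (the
minimum guards against sparse-window artifacts). The published figures'
local-enrichment curves come from an unspecified estimator, so this
transparent scan is the package's stand-in; window and step are flags.
Co-localization pairs every overlapping (expression, methylation)
enriched window and merges connected components into regions; BED
export converts to 0-based half-open coordinates.

## Tissue scores

Both the pluripotency and the neurality score use the same
construction on a labeled reference cohort (defaults 98 pluripotent, 34
brain, 200 other — the published reference's proportions at reduced
scale): NMF with k = 8 components (multiplicative updates on the
Frobenius objective, deterministic NNDSVD-style initialization, the
objective sequence recorded and checked non-increasing), AUROC ranking
of components for the target class (midrank ties; equals Mann-Whitney
pair counting), and a ridge-penalized logistic head with coefficients
constrained non-negative (projected gradient from w = 0, b = log-odds;
the objective is strictly convex so the optimum is unique, and the
constraint reproduces "positive coefficients only"; with small ridge
this is margin-maximizing on separable data). "Margin maximization" in
the source description has no published optimizer, so the convex
surrogate is the package's choice. New samples are shifted by the
recorded reference minimum, floored at zero, projected onto the basis
by non-negative least squares, and scored on the logit scale. Basis
genes missing from an input raise a warning and the projection uses the
intersection. The reference generator draws samples as non-negative
mixtures of k gene signatures with class-specific mixing means;
"NSC-like" samples mix the pluripotent and brain signatures and land
between the class medians on both score axes.

## Clustering, PCA, separation

Hierarchical clustering uses distance 1 - Pearson r (not 1 - |r|;
anticorrelated profiles are dissimilar) with UPGMA average linkage;
columns are sorted by sample id first so ties break deterministically,
and height inversions (possible under average linkage on this
semi-metric) are flagged rather than forbidden. PCA centers features
(no unit-variance scaling, the microarray convention), uses SVD, and
fixes component signs by the largest-magnitude loading. The separation
score is the mean silhouette (Euclidean) of a labeling in PCA space;
the pipeline uses three components because the design has exactly three
sample-level axes (batch, background, origin) — with two components the
origin signal, which lives on X PC3 behind batch and background, is
invisible. Singleton classes are excluded with a warning.

On default synthetic data the qualitative published pattern reproduces:
the X-gene PCA separates ESC-NSC from iPSC-NSC better than the
autosomal PCA does, autosomal space separates genetic backgrounds, the
methylation X-CpG dendrogram splits perfectly by origin while the
autosomal one does not, and the chrX group-mean correlation is lower
than the autosomal one in both modalities.

## Pipeline, seeding, determinism

`run_pipeline` derives independent named substreams from one root seed
(NumPy SeedSequence; all derived seeds < 2^31), so any stage's draw is
stable under changes elsewhere. Identical (config, seed) produce
byte-identical JSON summaries, and a run can be reproduced from its
written manifest. The score stage trains on an 80/20 split of the
reference cohort and reports held-out AUROCs; it scores reference
samples (held-out plus NSC-like mixtures) rather than the simulated
microarray samples, because the two generators use disjoint gene
universes.

## Problem sizes

Defaults per run: 10,500 genes x 36 samples, 20,000 CpGs x 24 samples,
146 scan windows per modality, reference 2,000 genes x 332 samples plus
30 mixtures. A full pipeline run takes a few seconds on one CPU; the
complete test suite (including twenty 20-seed calibration/recovery
loops) runs in well under a minute.

## Known limitations

- The delta-beta rule has no replicate-variance guard; with very few
  replicates and higher noise than the default its false-call rate
  rises quickly.
- The window scan's binomial null treats features as independent; for
  strongly clumped annotations the BH-adjusted p-values are
  approximate.
- The non-negative logistic head is fit on NMF mixing weights whose
  scale is data-dependent; weights are not comparable across models
  trained on different references.
- Score projection floors shifted intensities at zero, which biases
  projections of samples far below the reference minimum.
- PluriTest's novelty score and its published reference/weights are out
  of scope; both axes here are the in-repo construction.
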