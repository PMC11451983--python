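# Methods

This note documents the models, procedures and numerical choices behind the
package: what each stage computes, which parameters matter, what the synthetic
cohorts emulate, and where the design was genuinely open.

## The two coexpression modalities

Coexpression between a gene pair is estimated in two complementary views of
the same multi-tissue expression matrix.

*System level* ("TPM modality"): association is computed on quantile-
normalized log10(TPM + 1) values pooled across all tissue clusters. Between-
tissue differences in mean expression contribute fully, so a pair whose
expression rises and falls together across the body scores highly even if the
two genes are uncorrelated within any single tissue.

*Tissue level* ("z-score modality"): each gene is standardized within each
tissue cluster, z = (x − m)/s with m the cluster mean and s the cluster sample
standard deviation (s = 0 maps to z = 0, flagged). Only within-tissue
covariation survives; this is the view classical coexpression databases take.
The z-score modality is invariant to adding any per-cluster constant to a
gene; the TPM modality is deliberately not.

## Association metrics

Three metrics are computed per subsample:

- **Pearson** and **Spearman** (average ranks on ties) correlation; a constant
  gene receives zeros off-diagonal and a warning.
- A **modified G-statistic** for non-linear and mutually exclusive patterns.
  Each gene is independently discretized into low/mid/high: values strictly
  below the 0.2 percentile or above the 99.8 percentile are trimmed; k-means
  (k = 3) runs on the rest, initialized at the deterministic centroids
  [0.2-percentile, median, 99.8-percentile]. The primary optimizer is a 1-D
  Hartigan–Wong pass limited to 1,000 sweeps; on non-convergence a Lloyd
  refinement with up to 10,000 iterations takes over. Codes are ordered by
  centroid. For a pair, samples trimmed in *either* gene are excluded
  (trimming is defined per gene, so exclusion is pairwise rather than
  listwise), a 3×3 contingency table is formed, E is the product of marginals
  over the total, and G = 2 Σ O·ln(O/E) with empty cells contributing zero.
  Because tiny expected counts inflate G, E is floored before the log: cells
  with O > 4 floor at 1, others at 0.5. The direction of that mapping is not
  uniquely determined by its verbal description; both directions are
  implemented and this default is documented here. Cell-wise post-hoc
  p-values come from standardized residuals (O − E)/√(E(1 − r)(1 − c))
  against a standard normal, using the unfloored E.

Under independence the G null behaves like χ² with 4 degrees of freedom; the
flooring changes only cells with tiny E and leaves the null essentially
untouched (both properties are tested).

## Subsample design and minimum aggregation

Tissue clusters differ enormously in size, so each repetition draws a fixed
70 samples per cluster without replacement (~80% of the smallest cluster at
full scale); 20 repetitions are drawn by default. The reported value per pair
is the **minimum across repetitions**: for signed correlations, the value of
smallest absolute magnitude with its sign preserved — a pessimistic estimate
biased toward zero that guards against single-draw artifacts. The raw signed
minimum is available as an option (`signed_min=True`). Pairs whose sign flips
across repetitions are flagged. Repetition r draws from the child stream
(base_seed, spawn_key r) of a NumPy SeedSequence, so designs are reproducible
and extendable. One design is shared by all metrics within a fit, and
discretization centroids are re-fitted per repetition on the subsample (a
fit-once mode is not provided; per-repetition fitting matches the sampling
logic of the design).

Default full-scale inventory: 2 modalities × 20 repetitions × 3 metrics
per-repetition matrices (120), plus 2 modalities × 7 covariate strata (14),
plus 3 × 2 minima (6) — 140 matrices.

## Covariate strata

Seven strata: sex (male/female), age (<50, 50–59 inclusive on both ends —
"less than 50" and "more than 59" leave the closed middle interval — and
>59), and ischemia time split low/high by 1-D 2-means with centroids
initialized at the minimum and maximum observed times. Each stratum gets one
Pearson matrix per modality from a single subsample per cluster (clusters
empty in a stratum are dropped with a warning).

## Preprocessing

1. **Gene filter**: keep genes at ≥ 0.1 TPM in at least 20% of samples, with
   the count rounded *up* (16,651 samples → 3,331). 
2. **Tissue-specific rescue**: a failed gene returns if its maximum per-tissue
   mean TPM exceeds 5 *and* its maximum per-tissue fraction of samples at
   ≥ 1 TPM exceeds 66%. The two maxima may come from different tissues by
   default; whether they must coincide is ambiguous in the verbal rule, so a
   strict same-tissue mode is exposed (`rescue_same_tissue`).
3. **log10(TPM + 1)**, then **quantile normalization**: each sample's sorted
   values are replaced by the mean of sorted values across samples; ties get
   the mean of the reference values their positions span. Within-sample rank
   order is preserved.
4. **Serial ComBat**: parametric empirical-Bayes location/scale batch
   adjustment, run for the extraction batch and then the sequencing batch,
   preserving tissue, sex and age as model covariates. Samples with a missing
   batch, or in a batch with fewer than two samples, are first pooled into a
   single placeholder level per batch variable. The implementation is written
   here from first principles (per-gene standardization against the full
   model fit, normal prior on batch means, inverse-gamma prior on batch
   variances with moment-matched hyperparameters, fixed-point iteration to
   1e-4); it reproduces the Bioconductor `sva::ComBat` reference to ~1e-8 on
   test problems, which the suite verifies through Rscript. A batch variable
   perfectly confounded with a preserved covariate is an error. Note that EB
   shrinkage intentionally does *not* force post-correction batch means to
   equality gene-by-gene; exact removal happens only when the prior is
   degenerate (all genes sharing one shift), which is how the exact-removal
   test is constructed.

## Tissue-cluster purification

Stage one operates in PC space. Genes are standardized (constant genes
dropped with a warning) and PCs are retained sequentially: PC_i stays if its
explained-variance share of the current residual exceeds the maximum of 100
first-PC shares computed after independently permuting every gene's values
(a sequential Buja–Eyuboglu-style test; the acceptance rule — max, or 95th
percentile — is configurable because the verbal description names only the
permutation count). A kNN graph (Euclidean distance in PC space, union-
symmetrized, edge weight = Jaccard index of the endpoints' neighbour sets,
self excluded) is clustered by Louvain for each k in a sweep (1–100 by
default; tests and desk-scale runs use coarser sweeps). Each tissue is
matched to its best (k, cluster) by the purity score P = (I/T)(I/C), the
product of the cluster's recall and precision for the tissue; P = 1 exactly
at set identity. At the labelled tissue's best k: samples in a cluster with
no dominant tissue (max P < `p_min`, default 0.5) are flagged MIXED; samples
outside the tissue's best cluster whose own cluster is dominated by another
tissue are flagged DIVERGENT. Tissues whose best clusters coincide (both
purities ≥ `mix_threshold`, default 0.25) are merged, transitively with a
warning for chains. `p_min` and `mix_threshold` are this package's own
defaults — the procedure's description fixes the intent, not the numbers —
and both are exposed in the config.

Stage two embeds the retained samples by exact (theta = 0) 2-D t-SNE
(perplexity 30, learning rate 200, 1,000 iterations, no input PCA or
rescaling; at desk scale a smaller learning rate separates small cohorts more
reliably and is configurable). Per cluster a medoid is computed as the
coordinate-wise median after dropping boxplot outliers (outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR]) in either dimension (clusters of size < 4 skip
the trim with a warning). Each sample's membership is predicted by majority
vote among its k nearest embedded neighbours, k = size of the cluster whose
medoid is nearest (ties toward the larger cluster); a sample whose predicted
cluster differs from its assigned one is flagged TSNE_OUTLIER, and vote ties
keep the sample — removal is deliberately conservative. Manual exclusions are
only ever read from an explicit list, never inferred.

All statuses are mutually exclusive and counts are conserved:
n_input = n_kept + n_flagged.

## Validation statistics

- **Enrichment counts**: for a gene's ranking by |coexpression| (ties broken
  by gene id), the top and bottom 5% (the bottom being the associations
  *closest to zero*) are tested for over-representation against each pathway
  by the hypergeometric upper tail P(X ≥ overlap) on the shared gene
  universe; the statistic reported is the number of pathways with p < 0.05.
- **Network AUROC**: edges of a probabilistic functional network with
  p > 0.8 are positives (0.995 is exposed as an alternative threshold, since
  both appear in common benchmark variants); an equal-sized seeded draw from
  edges with p < 0.005 are negatives; the ROC is traced over 1,000 operating
  thresholds on |coexpression| and the area is computed exactly from the rank
  statistic, making it invariant to any odd strictly monotone transform of
  the values.
- **Top-n overlap / median rank** between two rankings over a shared
  universe; identical rankings give overlap n and median rank (n + 1)/2.
- **D-score**: for a gene ordering with per-gene ChIP-peak flags,
  D = Σ_i |O_i − E_i| / (N·P/2) where O_i is the cumulative peak count,
  E_i = i·P/N the uniform expectation, N the genes ranked, P the peak
  carriers — the deviation area as a fraction of the triangle area. The
  peak-first ordering maximizes D (verified exhaustively at small N); random
  orderings give D ≈ 1/√N by the hypergeometric-bridge scaling, reported as a
  seeded permutation null (default 100 permutations).

## Synthetic cohorts

`cogtex.synthetic` generates seeded GTEx-like cohorts on the log10(TPM + 1)
scale: per-gene tissue means (baseline N(1.2, 0.4), tissue spread sd 0.6), a
10% fraction of tissue-specific genes (high in one tissue, near zero
elsewhere), Gaussian within-tissue residuals (sd 0.25), two nested batch
variables with gene-specific additive shifts on the log scale (sd 0.12 —
multiplicative in TPM; chosen so the batch signal is detectable but smaller
than tissue structure), donor covariates (sex and age per donor, bimodal
ischemia times per sample so a two-cluster split is well defined), and values
exponentiated back to TPM with clipping at zero.

Planted pairs realize the canonical scenarios. SYS_ONLY shares one tissue-
mean profile between the genes with independent residuals; TISSUE_ONLY
orthogonalizes the two mean profiles and correlates the residuals (identical
varying profiles would plant a system-level signal too — that is the BOTH
scenario); XOR gives complementary on/off tissue sets with tissue-varying
"on" levels so the scatter is L-shaped; NONLINEAR links the second gene to
the first through a monotone-saturating response; TISSUE_EXCEPTION is linear
except one offset tissue; NULL leaves both genes untouched. Mean profiles of
planted pairs are shifted at least three residual standard deviations above
zero — otherwise joint clipping at the TPM floor induces a spurious
within-tissue correlation for shared-profile pairs. Injected artifacts come
in two kinds: *mixed* samples are re-drawn from the 50/50 average of one
tissue pair's profiles (a shared intermediate state, as co-clustering mixed
samples occupy), and *divergent* samples keep their expression but receive a
wrong tissue label.

What the generator does **not** emulate: the empirical mean–variance trend of
real RNA-seq, correlated gene modules beyond the planted pairs, donor-level
expression effects, and single-cell structure. Passing tests therefore
demonstrate that the machinery recovers the signals it is pointed at under
realistic noise, not that real-tissue estimates are correct.

With few tissues, two genes' *mean profiles* can correlate by chance
(sd ≈ 1/√(T−1) across T tissues), so system-level null correlations do not
vanish with sample size; this mirrors the real situation and is why the
planted-scenario checks are formulated as ranks against the cohort-wide
background rather than absolute thresholds, with medians across several
planted pairs (a pair with no within-tissue signal has an exchangeable —
hence roughly uniform — rank in the z modality; single-pair assertions
against a rank cutoff would be noise-driven).

## Problem sizes for the property suites

The benchmark harnesses (`cogtex.benchmarks`) run the full chain at sizes a
single core handles in minutes: scenario recovery uses 12 tissues × 60
samples, 100 genes, 3 pairs per scenario, 10 repetitions of 50 samples per
cluster; outlier recovery pools counts over three cohorts of 6 tissues × 40
samples with 5 mixed + 5 divergent injections each; the merge benchmark lays
47 tissue labels over 42 well-separated expression states. These are the
package's chosen desk-scale study conditions, documented here so results are
interpretable; the full-scale defaults (70 × 20, k = 1..100, 100
permutations) remain the configured operating point.

## Known limitations

- The Louvain resolution interacts with k: small clusters can split at small
  k; the purity sweep absorbs this, but a single-k run is not reliable.
- Exact t-SNE is O(n²) per iteration and is the slowest stage at scale;
  approximate (Barnes–Hut) embedding is not implemented.
- Mixed samples whose own label matches one parent tissue and that embed
  inside that parent's cluster are geometrically indistinguishable from mild
  within-cluster outliers and can survive purification.
- The G-statistic matrix is computed pair-by-pair in Python; at the full
  33k-gene scale it would need the blocked/streamed path and substantial
  compute.
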