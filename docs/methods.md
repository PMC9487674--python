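# Methods

## The generative model

`simulate_dataset` draws multi-subject, two-condition UMI-like counts from
a three-level hierarchy:

1. **Genes.** Baseline log mean β₀g ~ Uniform[−4, 2] (natural log; exp(β₀)
   is the per-cell mean count, spanning ~0.02–7). A configured number of DE
   genes receive a log2 fold change with magnitude ~ Uniform[0.5, 2.0] and
   random sign, applied to condition B only; all other genes have logFC 0.
2. **Samples.** Each sample s contributes, per gene, a multiplicative
   subject effect u_gs ~ Gamma(shape θ_s, scale 1/θ_s), so E[u] = 1 and
   Var[u] = 1/θ_s. θ_s = 0.1 is severe between-subject variation
   (CV ≈ 3), θ_s = 100 makes subjects nearly exchangeable. The number of
   cells per sample is Poisson(avg) for balanced designs or negative
   binomial with size 2 (markedly skewed allocations) for imbalanced ones.
3. **Cells.** Counts are NB with mean μ = exp(β₀g)·u_gs·2^(x_s·logFC_g) and
   variance μ(1 + φ_c μ) (quadratic parametrization; φ_c ∈ 0.05–0.5 in the
   benchmark grid), sampled as a Gamma–Poisson mixture.

All cells share unit sequencing depth — there is no library-size term in
the generative model; observed library sizes vary only through counting
noise. The simulator is deterministic given its config (including seed);
grid and protocol seeds derive from one master seed by stable hashing
(`numpy.random.SeedSequence` of (master, index)), so any dataset can be
regenerated in isolation.

The interpretation of "sample overdispersion" as a Gamma shape on a
mean-one multiplicative effect is a documented convention of this package:
it spans the intended spectrum (0.1 = strong, 100 = negligible subject
variation) with a single positive parameter.

### Differential-state categories

`simulate_category_dataset` extends the model with a per-gene two-component
scheme on the log2-mean scale — a low component at b and a high component
at b + gap (default gap = 3 × cluster_logfc):

| category | condition A | condition B |
| --- | --- | --- |
| EE | unimodal low | unimodal low |
| EP | 50/50 low/high | 50/50 low/high |
| DE | unimodal low | shifted by ±cluster_logfc |
| DP | mixture (p_low, p_high) = (0.3, 0.7) | reversed (0.7, 0.3) |
| DM | unimodal low | unimodal high |
| DB | unimodal at the midpoint | 50/50 low/high |

Each cell draws its mixture component independently. Category counts are
exact (largest-remainder allocation), default fractions 2.5% for each of
DE/DP/DM/DB (10% DS in total). Subject effects and cell-level NB noise are
identical to the DE generator.

### Imbalance

`subsample_imbalance` assigns evenly spaced retention proportions between
0.20 and 1 (one per sample), permutes them randomly across samples, and
keeps ⌊p·n⌋ cells (at least one) per sample without replacement.

## What the simulator does and does not emulate

It reproduces the features that drive the methodological question: nested
subject/cell variance, overdispersed counts, sparse low-mean genes,
unequal cell allocations, and distributional (not just mean) differences.
It does **not** model library-size variation between cells, batch effects,
doublets or ambient RNA, gene–gene correlation, or multi-cell-type
structure. Conclusions from passing tests therefore concern the relative
behavior of test families under subject-level correlation — not absolute
error rates on any real dataset.

## Test families

All methods run behind `run_method(data, name)`, which applies the
family's gene filter, normalization and aggregation before testing and
maps results back to the full gene universe (missing p-values for filtered
genes). Per-method filters: all-zero genes for the rank/logistic/hurdle
and pseudobulk methods; expressed in < 3 cells for the count GLMs;
expressed in < 20 cells plus samples with < 10 cells for the mixed model.

* **wilcoxon** — two-sided rank-sum on log-normalized values
  (ln(1 + 10⁴·count/libsize)); exact null distribution for total n ≤ 25
  without ties, otherwise normal approximation with tie and continuity
  correction. Effects are Seurat-convention log2 fold changes of expm1
  means with pseudocount 1.
* **lr / poisson / negbinom** — per-gene likelihood-ratio tests (df 1) of
  the group term: logistic regression of group membership on expression;
  Poisson and NB2 GLMs of counts with log library-size offset (NB
  dispersion by maximum likelihood from a method-of-moments start, Poisson
  fallback when it collapses to zero).
* **hurdle** — two-part model on log-normalized values: logistic detection
  part plus Gaussian part on positive values; per-part LRT chi-squares and
  degrees of freedom are summed into one combined p-value. Without latent
  covariates the detection part uses the closed-form group-rate MLE.
* **latent variants** (`*_latent`) — subject identities enter as
  fixed-effect dummy columns and the group term is tested given them.
  Because condition is constant within subject, the group indicator lies in
  the span of the dummies: the LRT is identically zero and every p-value is
  1. This degenerate behavior is intentional — it is exactly what happens
  when a latent-variable test is asked to condition away the design — and
  the code detects the collinearity up front instead of fitting singular
  models. With genuinely non-confounded covariates (e.g. batch) the same
  functions perform real conditional tests.
* **lmm** — Gaussian random intercept per subject on log-normalized
  values. The likelihood profiles out the fixed effects and residual
  variance, leaving a one-dimensional optimization over the variance ratio
  λ = σ²_subject/σ²_resid (bounded search on log λ plus the λ = 0
  boundary); REML for variance reporting, ML fits for the χ²(1)
  likelihood-ratio test of condition. Estimates agree with statsmodels
  MixedLM to < 1e-4 on test fixtures. Singular fits (λ → 0) fall back to
  the ordinary two-sample t-test.
* **pb_modt_{sum,mean}** — moderated t on pseudobulks: sum aggregation is
  normalized TMM + CPM(prior 0.5) + log2; mean aggregation averages
  log-normalized values. Gene variances are shrunk to
  (d₀s₀² + d_g s²_g)/(d₀ + d_g), with (d₀, s₀²) estimated by matching the
  moments of log s² to the scaled-F sampling law (trigamma inversion by
  Newton steps); infinite d₀ (common variance) arises when observed spread
  does not exceed the sampling spread.
* **pb_nbglm_{tmm,mor}** — per-gene NB GLM on sum pseudobulks with TMM- or
  median-of-ratios offsets; gene dispersion is a weighted average of the
  method-of-moments estimate and a lowess trend over log abundance (prior
  weight equivalent to 10 samples); Wald test on the group coefficient,
  Poisson family when the dispersion is zero.
* **pb_rots_{sum,mean}** — statistic |mean_A − mean_B|/(a₁ + a₂·s) with s
  the pooled standard error; (a₁, a₂) ∈ {0, 0.01, 0.1, 0.25, 0.5, 1} ×
  {0, 1} and the top-list size k ∈ {5, 10, 25, 50} (clipped to half the
  gene count) are chosen to maximize the Z-score of observed top-k overlap
  between group-preserving bootstrap pairs against label-permuted pairs
  (default 100 pairs, reduced from the reference default of 500 for desk
  scale); p-values by pooled permutation of the selected statistic.

These are structural analogues of the families found in the bulk and
single-cell toolkits (limma, edgeR, DESeq2, ROTS, MAST, Seurat, lme4-based
mixed models), not numeric clones: the model class, normalization and test
match; the dispersion/shrinkage estimators are simplified. Voom precision
weights and NB mixed models are out of scope.

## Evaluation conventions

* Genes are intersected across methods **before** BH adjustment; AUROC
  uses −p as score with midranks for ties.
* Precision and F1 are *undefined* (NaN), not zero, when a method calls no
  positives; such entries are excluded from aggregate medians.
* MCC is NaN when any marginal of the confusion matrix is empty.
* Average overlap is computed on pseudobulk-normalized values; it is
  symmetric and invariant under common monotone increasing transforms.

## Protocols

* **Grid benchmark** — simulate each config, run all methods on the same
  counts, intersect genes, BH, score. Method failures are logged per
  dataset and yield NaN rows rather than aborting the grid.
* **Mock comparison** — 30 random *balanced* splits of single-condition
  samples into two mock groups (the larger group takes the extra sample for
  odd counts); reported per repetition: significant genes / common genes.
  Balanced splits avoid degenerate 1-vs-(n−1) draws, which the protocol
  statement leaves open.
* **Reproducibility** — 50 balanced + 50 imbalanced replicate subsets (per
  condition, replicate count uniform on {4, …, available − 1}; imbalanced
  subsets additionally cell-subsampled over 0.20–1), Spearman correlation
  of nominal p-values over shared genes for all C(100, 2) = 4950 pairs per
  method. Constant p-value vectors (the latent LR case) give missing
  correlations.
* **Discordance profile** — per method, genes split into TP/FP/TN/FN at BH
  0.05; per gene: average overlap of pseudobulk values between conditions,
  |log2((mean_A + 1)/(mean_B + 1))| on pseudobulk means, mean pseudobulk
  and mean single-cell-normalized expression.

## Numerical choices and degenerate inputs

* NB sampling uses the Gamma–Poisson construction (exact for the quadratic
  NB law, vectorizes over the full gene × cell block).
* Rank-sum σ = 0 (all values tied) gives p = 1; zero-variance genes under
  the moderated t get p = 1 when the mean difference is 0.
* TMM: reference column by upper-quartile proximity to the mean upper
  quartile, trims 30% (M) and 5% (A), precision weights from the binomial
  delta method, factors rescaled to product 1. Columns that are scalar
  multiples get composition factors of exactly 1 — depth lives in the
  library sizes.
* GLM fits that fail to converge yield missing p-values and a debug log,
  never an exception escaping a gene loop.
* Ties in all rankings break by stable gene order.

## Problem sizes in the shipped analyses

The test suite and the acceptance script run everything at desk scale,
chosen so each claim is estimated from real calls: calibration targets use
the stated 2000-gene / 14-sample / ~200-cell and 2000-gene / 12-sample /
~300-cell designs; comparative claims use 16–20 datasets of 400–800 genes
with 40–120 cells per sample. The pseudoreplication comparison uses
θ_s = 10: strong enough to inflate the naive test's call count roughly
sevenfold, mild enough that the pseudobulk side still makes calls (at
θ_s ≤ 0.5 with 5 samples per group the pseudobulk test calls nothing, and
its precision would be decided by single genes). The 16-config ordering
grid spans both ends of each varied parameter list, mirroring how the full
1280-config factorial spans its ranges.

## Known limitations

* One mixed model (Gaussian random intercept) represents the mixed family;
  count-scale mixed models are not implemented.
* The mean-aggregation path averages over all cells of a sample, including
  zeros.
* ROTS p-values come from pooled permutations, which are granular for very
  small sample counts (≥ 3 per group required).
* The latent variants are informative only when the latent covariates do
  not fully encode the design (see above); with subject dummies in a
  subject-constant design their p-values are identically 1 by
  construction.
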