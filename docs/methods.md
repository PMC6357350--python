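# Methods

## The problem and the pipeline

A disease signature is usually defined by differential expression
between tumors and matched adjacent normal tissue. When a cohort has no
adjacent normals, healthy-donor reference tissue can substitute — but
only if the right reference tissue is chosen. `refnorm` automates that
choice: it embeds expression profiles into a feature space, ranks
candidate tissue sites by correlation with the tumor cohort, selects a
reference set, and derives the signature against it. The package's claim
to correctness is operational: on synthetic compendia with known ground
truth, the selected references must recover the tissue of origin and
yield signatures concordant with the adjacent-normal benchmark.

Pipeline order (fixed, asserted in the run manifest): tumor purity
filter → tumor PC1 outlier filter → feature-space construction →
candidate correlation → reference selection → reference PC1 outlier
filter → RUV normalization → differential expression → signature →
optional concordance.

## Synthetic compendium generator

Counts for gene *g*, sample *s* are negative binomial with
mean `lib_s · 2^(b_g + tissue[g, site(s)] + batch[g, study(s)] + tumor_shift_g)`
and variance `μ + φμ²`.

* Baseline log₂-means `b_g ~ Normal(3, 2)` — a log-normal over the count
  scale, so a minority of genes dominates variance as in real RNA-seq.
* **Sites** (default 10, two of them a correlated "proximal" pair):
  each site independently marks 10% of genes with shifts
  `Normal(0, 1.5)`. The proximal pair shares its marked gene set with
  shift correlation 0.8, emulating anatomically adjacent sites
  (kidney vs kidney cortex). The panel width matters: with too few
  sites, a random reference draw is mostly origin-adjacent tissue and
  the random-selection baseline becomes meaninglessly strong; ten sites
  is the smallest panel at which random selection behaves like the
  diverse-compendium case. Tissue shifts of sd 1.5 log₂ units reflect
  that tissue-specific genes differ by multiples, not fractions, of a
  fold change.
* **Studies**: two reference studies plus the tumor study, each with
  per-gene batch shifts `Normal(0, 0.3)`; the tumor study's batch shift
  is shared by tumors and adjacent normals, creating the cross-study
  confound the normalization stages must handle.
* **Tumors**: 20 samples, purity `Uniform(0.5, 1)`; 20 matched adjacent
  normals. 300 DE genes with signed magnitudes
  `|log₂FC| ~ Uniform(1, 3)` (mean 2), drawn from genes with baseline
  mean count ≥ 5 — a fold change on an undetectable gene produces no
  observable signal, so including such genes would make the ground
  truth ill-posed. Heterogeneous magnitudes matter for the concordance
  metric: with a constant magnitude, the rank correlation over consensus
  genes degenerates to rank correlation of estimation noise within the
  up and down groups and is capped near 0.75 regardless of method
  quality.
* Library-size factors log-normal (sd 0.2); gene lengths
  `Uniform(500, 10000)` bp for TPM conversion; dispersion φ = 0.1.
* Bit-reproducible for a fixed seed.

What the generator does **not** emulate: isoform structure, GC bias,
gene-gene correlation beyond the shared shift structure, purity-driven
expression mixtures (purity is metadata only), and the long tail of
rare tissue subtypes. Passing tests therefore demonstrate the machinery
is correct and calibrated under NB noise with additive log-scale tissue
and batch structure — not that real compendia meet those assumptions.

## Preprocessing

Counts → TPM (gene lengths required) → log₂(TPM+1). The correlation and
embedding path additionally keeps only genes with ≥ 10 counts in ≥ 25%
of samples (the same convention the DE engine uses) and drops
zero-variance genes. Without the abundance filter, the variance ranking
is dominated by the log-scale sampling noise of barely detected genes
and carries no tissue information.

## Feature spaces

* **Top-varying genes** — genes ranked by variance across the tumor
  cohort (ties broken lexicographically), default K = 5000 (saturates at
  the gene count on small data); features are the expression sub-vector.
* **PCA** — 64 components of per-gene-centered log₂(TPM+1).
* **Autoencoder** — input → hidden(512) → bottleneck(64) → hidden →
  output; leaky-ReLU (slope 0.2), batch normalization and dropout (0.2)
  between layers; Adam at learning rate 2·10⁻⁴, batch 128, 100 epochs,
  80/20 split stratified by site. Implemented in numpy; training is
  bit-reproducible for a fixed seed. Inputs are TPM, internally
  log₂(x+1)-transformed and min-max scaled per gene to [0,1] (an MSE
  objective on raw TPM is dominated by a few genes); the scaling
  constants ship with the model. The hidden width is not fixed by the
  architecture description; 512 is the default and everything (depth,
  width, bottleneck, dropout, slope) is configurable for sensitivity
  exploration.

Desk-scale defaults (`refnorm.benchmarks`): the synthetic compendium has
~320 normal samples, so the full-scale training schedule (sized for a
~19k-sample compendium) is rescaled to keep the optimizer step budget:
hidden 128, batch 32, 150 epochs, learning rate 10⁻³
(`SMALL_AE_PARAMS`). Two further choices proved necessary at this scale
and are the package's defaults:

* **Train on normals only** (`ae_train_on="normals"`). With tumors at
  ~13% of the training set, the bottleneck spends capacity on the
  tumor-specific displacement (disease axis plus study batch) and site
  geometry degrades measurably; on normals only, tumors are projected
  onto the normal-tissue manifold at encode time. At compendium scale,
  where any one cohort is <1% of samples, the distinction vanishes,
  which is why training on everything works there.
* **High-variance-gene input** (`ae_input_k=500`): the autoencoder
  encodes the top-varying genes of its training cohort rather than all
  genes. With few samples and full-gene input, the encoder occasionally
  mapped the tumor cohort's (out-of-distribution) displacement onto an
  unrelated site's direction, producing a confident misranking even
  though the origin site still won in the encoder's own input space.
  Restricting the input to high-variance genes — the standard embedding
  practice in single-cell analysis — concentrates tissue signal and
  eliminated the failure mode across all tested replicates.

## Correlation and selection

Per-candidate score = mean over tumors of the profile-wise correlation
(median available via `aggregate`). Defaults: Spearman in gene space
(robust to dynamic range), Pearson in PCA/autoencoder space. For the
compact embeddings each feature dimension is z-scored across the pooled
tumor + candidate samples before correlating: bottleneck dimensions
carry arbitrary scales and offsets, and without standardization the
constant offsets dominate the correlation. Gene space is left on its
native log₂(TPM+1) scale. Site statistic = median of candidate scores,
descending, ties lexicographic; the normalized column divides by the top
site's median.

Selection strategies: `top_site` (all members of the top-ranked site);
`pct25_within_site` (top-site members with correlation ≥ the site's 25th
percentile, inclusive); `top50_any_site` (the 50 best candidates
regardless of site, site recorded as NA; all of them when fewer than 50
exist); `random50` (seeded uniform draw without replacement — the
baseline, conventionally averaged over three seeds); `manual` (a named
site). The tissue-of-origin verdict compares the top-ranked site with a
curated mapping of primary and acceptable proximal sites; a proximal hit
is reported as its own category, not an error, since anatomically
adjacent sites are legitimate reference tissue.

## RUV normalization

On `Y = log(counts+1)`: center the control-gene rows, take the SVD of
the control submatrix, set `W` (samples × k) to the top-k right singular
vectors scaled by singular values, estimate per-gene loadings by least
squares of centered Y on W, and subtract `W·α`; normalized counts are
`round(exp(·) − 1)` floored at zero. `k = 0` is the exact identity.
Control genes default to the 1000 least-DE genes from a first-pass test
(`choose_empirical_controls`). The first pass uses a mid-p variant of
the NB test: with a discrete test statistic, p-values pile at 1 for
low-count genes and the control set would be biased toward weak
expression; mid-p de-discretizes the ranking. k defaults to 1 and is
configurable — which factors real data need is dataset-specific.

## Differential expression

Self-contained NB empirical-Bayes test:

1. Median-of-ratios size factors (library-size fallback when fewer than
   10 genes are always-expressed).
2. Abundance filter: ≥ 10 counts in ≥ 25% of samples.
3. Per-gene method-of-moments dispersion pooled within groups; a
   parametric trend `φ(μ) = a + b/μ` fitted across genes; gene-wise
   estimates shrunk toward the trend with prior weight 10 df.
4. Exact-style conditional test: group sums of normalized counts are
   treated as NB (sum of n samples with mean μ and dispersion φ has mean
   nμ and dispersion φ/n); conditional on the total, the two-sided
   p-value sums all splits at most as probable as the one observed
   (Poisson/binomial limit when φ → 0). The enumeration window spans
   ±10 conditional standard deviations (+50), wide enough that the
   excluded mass is negligible at double precision.
5. log₂FC = log₂ of (group mean + 0.5) ratio; BH adjustment.

Bit-compatibility with any particular R package is not promised;
the contract is calibration, verified by simulation: type-I error within
[0.04, 0.06] on a ≥ 30k-gene global null, empirical FDR ≤ 0.10 at
padj < 0.05, and median |log₂FC| error ≤ 0.3 under spiked effects
(20 vs 20, φ = 0.1).

Signature thresholds are strict inequalities: |log₂FC| > 1 **and**
adjusted p < 0.001; a gene at exactly either boundary is excluded.

## Concordance

Consensus = genes significant in both signatures with equal direction
(symmetric). ρ = Spearman over consensus genes' fold changes; fewer than
3 consensus genes is reported as undefined, never imputed as zero.
Overlap significance = upper-tail hypergeometric on membership, with the
universe = genes tested in both comparisons. The method comparison table
averages the random baseline over its seeds and flags methods that beat
it.

## Problem sizes for the built-in benchmarks

Chosen so a full validation runs in minutes on one CPU: 20 replicate
compendia for tissue-of-origin recovery (default effects) plus 8 under
heavy batch effects (sd 0.8) for the margin comparison; 50 000 genes at
10 vs 10 for the null calibration; 10 000 genes / 500 spiked at 20 vs 20;
2000 genes / 40 samples for RUV recovery; one compendium with a
three-seed random baseline for the end-to-end concordance.

## Known limitations

* The exact-style test on group sums discards within-group library-size
  imbalance beyond the size factors; severe imbalance would call for a
  GLM with offsets (not implemented; the two-group contrast is the
  scope).
* RUV's rounding back to integer counts loses sub-count precision; the
  k = 0 identity and factor-recovery tests bound the effect.
* The autoencoder is sensitive to architecture and scale, as the
  sensitivity analysis hooks acknowledge; the desk-scale defaults here
  are validated only for compendium-like synthetic data.
* Identifier mapping between gene namespaces is out of scope: one
  namespace per run.
* Purity is consumed as metadata, never computed.
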