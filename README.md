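# refnorm

**Reference-normal tissue selection and disease signatures for bulk RNA-seq tumor cohorts.**

Many tumor cohorts lack matched adjacent-normal tissue, which blocks the
standard route to a disease signature (differential expression of tumor
vs matched normal). `refnorm` implements a computational substitute:
given a multi-study expression compendium of healthy reference tissues
(GTEx-style), it identifies the tumor cohort's tissue of origin by
correlation in a learned feature space, selects a reference-normal set,
and derives the disease signature against those references — then
quantifies how well that signature agrees with the adjacent-normal
benchmark when one exists.

## Method

For a tumor cohort *T* and candidate normals *C* over a common gene set:

1. **QC** — keep tumors with purity > 0.7 (purity supplied as metadata);
   remove samples with |z| > 3 on the first principal component of
   standardized log₂(TPM+1) profiles. The PC1 filter is applied again to
   the selected references.
2. **Feature spaces** — three embeddings of an expression profile:
   the top-*K* varying genes across the tumor cohort (K = 5000),
   the top 64 principal components, or the 64-unit bottleneck of a
   symmetric autoencoder (input → hidden → 64 → hidden → output; leaky
   ReLU, batch normalization, dropout; Adam on MSE; 80/20 train/test
   split; batch 128, 100 epochs, learning rate 2·10⁻⁴).
3. **Site ranking** — each candidate *c* is scored by the mean of its
   correlations r(c, t) to the tumors in feature space; sites are ranked
   by the median candidate score.
4. **Selection strategies** — top site (all its members); top-site
   members at or above the site's 25th correlation percentile; the 50
   highest-correlated candidates from any site; 50 at random (baseline);
   or a manually named site.
5. **Signature** — RUV normalization (k nuisance factors estimated from
   empirical least-DE control genes), negative-binomial differential
   expression (median-of-ratios size factors, trended empirical-Bayes
   dispersion shrinkage, exact-style conditional test), Benjamini-
   Hochberg adjustment; the signature is the signed gene set with
   |log₂FC| > 1 and adjusted p < 0.001.
6. **Concordance** — consensus genes (significant in both signatures
   with the same direction), Spearman ρ of log₂ fold changes over the
   consensus, and the hypergeometric significance of the overlap.

A synthetic-compendium generator with known ground truth (tissue shifts,
study batch effects, NB dispersion, true DE genes) makes every stage
testable end to end; see `docs/methods.md` for the generative model and
all numerical choices.

## Worked example

```python
from refnorm import RunConfig, SimulationConfig, simulate_compendium
from refnorm.benchmarks import SMALL_AE_PARAMS
from refnorm.pipeline import run_pipeline

counts, meta, truth = simulate_compendium(SimulationConfig(seed=1))
config = RunConfig(feature_space="autoencoder",
                   autoencoder=dict(SMALL_AE_PARAMS, seed=1),
                   method="top_site", outdir="run")
res = run_pipeline(config, counts=counts, meta=meta,
                   gene_lengths=truth.gene_lengths)
print(res.ranking.table.head(3).round(3))
```

prints

```
             site  median_correlation  normalized  n_candidates
0           liver               0.867       1.000            30
1  liver_proximal               0.726       0.838            30
2          kidney              -0.043      -0.050            30
```

The tumor cohort (simulated from liver) correlates with the liver site
at 0.867 in autoencoder space, with the anatomically proximal site a
clear second and every unrelated site far behind — the margin that makes
the tissue-of-origin call reliable. Running the signature stage against
the 30 selected liver references recovers 241 of 300 simulated disease
genes at 0.92 precision, and the fold-change concordance with the
matched adjacent-normal signature is ρ = 0.942 versus 0.927 for the
random-selection baseline (`examples/04`, `examples/05`).

The `examples/` directory has one short script per capability:
simulation, embedding comparison, site ranking and selection, signature
derivation, and the strategy benchmark. A thin CLI mirrors the pipeline
(`refnorm simulate|embed|select|signature|evaluate|run`).

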