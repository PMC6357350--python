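"""Derive a disease signature from selected reference normals.

Runs RUV normalization and negative-binomial differential expression for
tumors vs the autoencoder-selected reference set, thresholds the result
into a signed signature (|log2FC| > 1, adjusted p < 0.001), and checks it
against the simulation's known DE genes.
"""

from refnorm import RunConfig, SimulationConfig, simulate_compendium
from refnorm.benchmarks import SMALL_AE_PARAMS
from refnorm.pipeline import run_pipeline

counts, meta, truth = simulate_compendium(SimulationConfig(seed=1))
config = RunConfig(
    feature_space="autoencoder",
    autoencoder=dict(SMALL_AE_PARAMS, seed=1),
    method="top_site",
    outdir="scratch/example_signature",
)
res = run_pipeline(config, counts=counts, meta=meta, gene_lengths=truth.gene_lengths)

sig = res.signature
true_de = set(truth.de_genes["gene_id"])
hits = sig.genes & true_de
print(f"genes tested: {len(res.de.table)}")
print(f"signature size: {len(sig.table)} (|log2FC| > {sig.lfc_min}, padj < {sig.alpha})")
print(f"true DE genes recovered: {len(hits)}/{len(true_de)}")
print(f"signature precision: {len(hits) / len(sig.genes):.2f}")
print("\ntop 5 by |log2FC|:")
top = sig.table.reindex(sig.table["log2fc"].abs().sort_values(ascending=False).index)
print(top.head(5).round(2).to_string(index=False))
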