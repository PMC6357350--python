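"""Fit the three expression embeddings and compare how they separate sites.

Trains the top-varying-genes subset, a 64-component PCA, and the
bottleneck autoencoder on one compendium, then reports the silhouette of
site labels in each space — higher means tissue sites form tighter, more
separated clusters.
"""

import numpy as np
from sklearn.metrics import silhouette_score

from refnorm import (
    AutoencoderParams,
    SimulationConfig,
    encode,
    fit_pca_embedding,
    select_top_varying_genes,
    simulate_compendium,
    train_autoencoder,
)
from refnorm.benchmarks import AE_INPUT_K, SMALL_AE_PARAMS
from refnorm.pipeline import prepare_expression

counts, meta, truth = simulate_compendium(SimulationConfig(seed=1))
tpm, logm = prepare_expression(counts, truth.gene_lengths)
normals = list(meta.of_type("reference_normal")["sample_id"])
sites = meta.table.set_index("sample_id")["site"].reindex(normals).to_numpy()

vg = select_top_varying_genes(logm, normals, k=1000)
pca = fit_pca_embedding(logm, n_components=64)
hv = select_top_varying_genes(logm, normals, k=AE_INPUT_K)
ae, curve = train_autoencoder(
    tpm.subset_genes(list(hv.arrays["selected"])).subset_samples(normals),
    AutoencoderParams(**SMALL_AE_PARAMS, seed=1),
    site_labels=sites,
)
print(f"autoencoder: final train MSE {curve.train[-1]:.4f}, held-out MSE {curve.test[-1]:.4f}")

for name, model, source in [("varying_genes", vg, logm), ("pca", pca, logm), ("autoencoder", ae, tpm)]:
    feats = encode(model, source.subset_samples(normals)).to_numpy()
    score = silhouette_score(feats, sites)
    print(f"{name:14s} dim={model.dim:5d} site silhouette = {score:+.3f}")
print("\nHigher silhouette = cleaner tissue clusters in that feature space.")
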