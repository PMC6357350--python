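"""Seeded synthetic study conditions for validating the whole pipeline.

Each function simulates data with known ground truth, runs the package's
own machinery, and returns the measured quantities: tissue-of-origin
recovery across replicate compendia, DE test calibration under a global
null and under spiked fold changes, RUV nuisance-factor recovery, and
end-to-end signature concordance against the matched adjacent-normal
benchmark (with the random-selection baseline).  These are the quantities
the package's acceptance checks report.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import evaluation, features, selection
from . import signature as sig
from .io import CountMatrix
from .pipeline import RunConfig, prepare_expression, run_pipeline
from .simulate import SimulationConfig, simulate_compendium

#: Autoencoder settings scaled to the ~150-sample synthetic compendium: a
#: few thousand optimizer steps to convergence (the full-scale defaults
#: assume a compendium of ~19k samples).
SMALL_AE_PARAMS = dict(hidden=128, epochs=150, batch_size=32, learning_rate=1e-3)

#: Autoencoder input restricted to the top-varying genes of the training
#: cohort (high-variance-gene selection before embedding).
AE_INPUT_K = 500

#: Curated mapping for the synthetic liver cancer: the correlated
#: "liver_proximal" site plays the role of an anatomically proximal site.
EXPECTED_SITES = {
    "synthetic_liver_cancer": {"primary": ["liver"], "proximal": ["liver_proximal"]}
}


def _rank_for_space(counts, meta, lengths, space, seed):
    """Site ranking for one compendium under one feature space."""
    tpm, logm = prepare_expression(counts, lengths)
    tumors = list(meta.of_type("tumor")["sample_id"])
    cands = list(meta.of_type("reference_normal")["sample_id"])
    if space == "autoencoder":
        normals = [s for s in tpm.sample_ids if s not in set(tumors)]
        hv = features.select_top_varying_genes(logm, normals, k=AE_INPUT_K)
        train = tpm.subset_genes(list(hv.arrays["selected"])).subset_samples(normals)
        sites = meta.table.set_index("sample_id")["site"].reindex(normals).to_numpy()
        model, _ = features.train_autoencoder(
            train, features.AutoencoderParams(**SMALL_AE_PARAMS, seed=seed), site_labels=sites
        )
        source, kind = tpm, "pearson"
    else:
        model = features.select_top_varying_genes(logm, tumors, k=1000)
        source, kind = logm, "spearman"
    ct = selection.correlate_candidates(
        features.encode(model, source.subset_samples(tumors)),
        features.encode(model, source.subset_samples(cands)),
        kind=kind,
        feature_space=space,
        meta=meta,
    )
    return selection.rank_sites(ct, meta)


def tissue_recovery_benchmark(
    n_replicates: int = 20, seed: int = 0, batch_effect_sd: float | None = None
) -> pd.DataFrame:
    """Replicate compendia -> per-replicate origin-site verdict and margins.

    For each replicate the autoencoder-space and varying-genes-space site
    rankings are computed; the verdict applies the origin-or-proximal
    acceptance rule, and the margin is the top site's median correlation
    minus the runner-up's.
    """
    rows = []
    for i in range(n_replicates):
        rep_seed = seed + i
        cfg = SimulationConfig(seed=rep_seed)
        if batch_effect_sd is not None:
            cfg = replace(cfg, batch_effect_sd=batch_effect_sd)
        counts, meta, truth = simulate_compendium(cfg)
        row = {"replicate": i, "seed": rep_seed}
        for space in ("autoencoder", "varying_genes"):
            ranking = _rank_for_space(counts, meta, truth.gene_lengths, space, rep_seed)
            verdict, top = selection.call_tissue_of_origin(
                ranking, EXPECTED_SITES, "synthetic_liver_cancer"
            )
            med = ranking.table["median_correlation"]
            row[f"{space}_verdict"] = verdict
            row[f"{space}_top"] = top
            row[f"{space}_margin"] = float(med.iloc[0] - med.iloc[1]) if len(med) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _nb_counts(rng, mu, phi, size):
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


def de_null_calibration(
    n_genes: int = 50_000, n_per_group: int = 10, phi: float = 0.1, seed: int = 0
) -> dict:
    """Global-null NB simulation: fraction of raw p below 0.05 and 0.01."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(3.0, 1.5, n_genes))
    counts = _nb_counts(rng, mu[:, None], phi, (n_genes, 2 * n_per_group))
    ids = [f"s{i}" for i in range(2 * n_per_group)]
    cm = CountMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)], columns=ids)
    )
    groups = pd.Series(["tumor"] * n_per_group + ["ref"] * n_per_group, index=ids)
    de = sig.differential_expression(cm, groups)
    p = de.table["pvalue"].to_numpy()
    return {
        "n_tests": int(len(p)),
        "type1_at_05": float((p < 0.05).mean()),
        "type1_at_01": float((p < 0.01).mean()),
    }


def de_spiked_benchmark(
    n_genes: int = 10_000,
    n_de: int = 500,
    log2fc: float = 2.0,
    n_per_group: int = 20,
    phi: float = 0.1,
    seed: int = 0,
) -> dict:
    """Spiked simulation: FDR at padj<0.05 and median |log2FC| error."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(3.0, 1.5, n_genes))
    lfc = np.zeros(n_genes)
    de_idx = rng.choice(n_genes, n_de, replace=False)
    lfc[de_idx] = rng.choice([-log2fc, log2fc], n_de)
    a = _nb_counts(rng, (mu * 2.0**lfc)[:, None], phi, (n_genes, n_per_group))
    b = _nb_counts(rng, mu[:, None], phi, (n_genes, n_per_group))
    ids = [f"s{i}" for i in range(2 * n_per_group)]
    cm = CountMatrix(
        pd.DataFrame(np.hstack([a, b]), index=[f"g{i}" for i in range(n_genes)], columns=ids)
    )
    groups = pd.Series(["tumor"] * n_per_group + ["ref"] * n_per_group, index=ids)
    de = sig.differential_expression(cm, groups)
    t = de.table.set_index("gene_id")
    true_de = {f"g{i}" for i in de_idx}
    tested_de = [g for g in t.index if g in true_de]
    err = t.loc[tested_de, "log2fc"].to_numpy() - lfc[[int(g[1:]) for g in tested_de]]
    calls = set(t.index[t["padj"] < 0.05])
    fdr = len(calls - true_de) / max(len(calls), 1)
    return {
        "n_tested": int(len(t)),
        "fdr_at_padj05": float(fdr),
        "median_abs_lfc_error": float(np.median(np.abs(err))),
        "power_at_padj05": float(len(calls & true_de) / max(len(tested_de), 1)),
    }


def ruv_recovery_benchmark(n_genes: int = 2000, n_samples: int = 40, seed: int = 0) -> dict:
    """Rank-1 contamination: |r| between the estimated and true factor."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(3.0, 1.5, n_genes))
    factor = rng.normal(0.0, 1.0, n_samples)
    loadings = rng.normal(0.0, 0.5, n_genes)
    counts = rng.poisson(np.exp(np.log(mu)[:, None] + loadings[:, None] * factor[None, :]))
    cm = CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )
    )
    fit = sig.ruv_fit(cm, [f"g{i}" for i in range(200)], k=1)
    r = float(np.corrcoef(fit.W[:, 0], factor)[0, 1])
    return {"abs_r": abs(r)}


def concordance_benchmark(seed: int = 0, n_baseline_seeds: int = 3) -> dict:
    """End-to-end: autoencoder-selected references vs matched adjacent normals.

    Runs the full pipeline with autoencoder top-site selection, then the
    random-50 baseline with ``n_baseline_seeds`` seeds, on one default
    compendium.  Reports the concordance rho of each and the fraction of
    true DE genes covered by the consensus set.
    """
    cfg = SimulationConfig(seed=seed)
    counts, meta, truth = simulate_compendium(cfg)
    base = RunConfig(
        feature_space="autoencoder",
        autoencoder=dict(SMALL_AE_PARAMS, seed=seed),
        method="top_site",
    )
    res = run_pipeline(
        base, counts=counts, meta=meta, gene_lengths=truth.gene_lengths, write_outputs=False
    )
    consensus = evaluation.consensus_signature(res.signature, res.benchmark_signature)
    true_de = set(truth.de_genes["gene_id"])
    coverage = len(set(consensus["gene_id"]) & true_de) / len(true_de)

    baseline_rhos = []
    for i in range(n_baseline_seeds):
        rand_cfg = replace(
            base, feature_space="varying_genes", method="random50", selection_seed=seed + 1 + i
        )
        rand_res = run_pipeline(
            rand_cfg, counts=counts, meta=meta, gene_lengths=truth.gene_lengths, write_outputs=False
        )
        baseline_rhos.append(rand_res.concordance.rho)
    return {
        "rho_autoencoder_top_site": float(res.concordance.rho),
        "rho_random50_mean": float(np.mean(baseline_rhos)),
        "baseline_rhos": [float(r) for r in baseline_rhos],
        "n_consensus": int(res.concordance.n_consensus),
        "true_de_coverage": float(coverage),
        "overlap_log10p": float(np.log10(max(res.concordance.overlap_p, 1e-300))),
    }
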