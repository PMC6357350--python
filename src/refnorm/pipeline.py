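"""End-to-end pipeline: QC -> feature space -> reference selection ->
second outlier pass -> RUV normalization -> differential expression ->
signature -> optional concordance against a matched adjacent-normal
benchmark.

The stage order is fixed and recorded in the run manifest; every stage
logs sample/gene counts in and out so the filter accounting is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluation, features, qc, selection, signature as sig
from .io import (
    CountMatrix,
    SampleTable,
    counts_to_tpm,
    drop_zero_variance_genes,
    filter_low_expression,
    log_transform,
    read_count_matrix,
    read_gene_lengths,
    read_sample_table,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "purity_filter",
    "tumor_outlier_filter",
    "feature_space",
    "correlation",
    "reference_selection",
    "reference_outlier_filter",
    "ruv_normalization",
    "differential_expression",
    "signature",
    "concordance",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    counts_path: str | None = None
    metadata_path: str | None = None
    gene_lengths_path: str | None = None
    outdir: str = "refnorm_run"
    # qc
    purity_threshold: float = 0.7
    pc1_z: float = 3.0
    # feature space
    feature_space: str = "autoencoder"  # varying_genes | pca | autoencoder
    k_varying: int = 5000
    pca_dim: int = 64
    autoencoder: dict = field(default_factory=dict)  # AutoencoderParams overrides
    ae_train_on: str = "normals"  # "normals" (default) or "all" samples
    ae_input_k: int | None = 500  # restrict AE input to top-k varying genes (None = all)
    # selection
    method: str = "top_site"
    correlation_kind: str | None = None  # default depends on feature space
    n_select: int = 50
    percentile: float = 25.0
    manual_site: str | None = None
    selection_seed: int = 0
    # signature
    ruv_k: int = 1
    n_controls: int = 1000
    lfc_min: float = 1.0
    alpha: float = 0.001
    # evaluation
    compare_to_adjacent: bool = True

    def validate(self) -> None:
        if not 0 <= self.purity_threshold <= 1:
            raise PipelineError("config", f"purity_threshold outside [0,1]: {self.purity_threshold}")
        if self.feature_space not in ("varying_genes", "pca", "autoencoder"):
            raise PipelineError("config", f"unknown feature space {self.feature_space!r}")
        if self.method not in selection.METHODS:
            raise PipelineError("config", f"unknown selection method {self.method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for key, val in raw.items():
            if isinstance(val, dict) and key not in ("autoencoder",):
                flat.update(val)
            else:
                flat[key] = val
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in flat.items() if k in known})

    def default_correlation_kind(self) -> str:
        if self.correlation_kind:
            return self.correlation_kind
        # rank correlation in gene space; product-moment on compact embeddings
        return "spearman" if self.feature_space == "varying_genes" else "pearson"


@dataclass
class RunResult:
    config: RunConfig
    qc_tumor: qc.QCReport
    correlation: selection.CorrelationTable
    ranking: selection.SiteRanking
    reference: selection.ReferenceSet
    qc_reference: qc.QCReport | None
    de: sig.DETable
    signature: sig.Signature
    benchmark_de: sig.DETable | None = None
    benchmark_signature: sig.Signature | None = None
    concordance: evaluation.ConcordanceReport | None = None
    embedding: features.EmbeddingModel | None = None
    outdir: Path | None = None


def prepare_expression(counts: CountMatrix, gene_lengths: dict):
    """Shared preprocessing for the correlation path: abundance filter,
    TPM conversion, log2(x+1), zero-variance drop.  Returns (tpm, logm)."""
    expressed = filter_low_expression(counts)
    tpm = counts_to_tpm(expressed, gene_lengths)
    return tpm, drop_zero_variance_genes(log_transform(tpm))


def qc_tumor_cohort(
    logm: CountMatrix, meta: SampleTable, purity_threshold: float = 0.7, pc1_z: float = 3.0
) -> qc.QCReport:
    """Purity filter then PC1 outlier filter on the tumor cohort."""
    tumor_ids = list(meta.of_type("tumor")["sample_id"])
    purity_rep = qc.filter_by_purity(meta.subset(tumor_ids), threshold=purity_threshold)
    if len(purity_rep.kept) < 3:
        raise PipelineError(
            "tumor_outlier_filter", f"only {len(purity_rep.kept)} tumors after purity filter"
        )
    out_rep = qc.remove_pc1_outliers(logm.subset_samples(purity_rep.kept), z_threshold=pc1_z)
    return qc.QCReport(
        kept=out_rep.kept,
        removed_purity=purity_rep.removed_purity,
        removed_outlier=out_rep.removed_outlier,
        pc1_scores=out_rep.pc1_scores,
    )


def _build_embedding(
    config: RunConfig,
    log_m: CountMatrix,
    tpm_m: CountMatrix,
    tumor_ids: list[str],
    meta: SampleTable,
):
    if config.feature_space == "varying_genes":
        return features.select_top_varying_genes(log_m, tumor_ids, k=config.k_varying), None
    if config.feature_space == "pca":
        return features.fit_pca_embedding(log_m, n_components=config.pca_dim), None
    params = features.AutoencoderParams(**config.autoencoder)
    # Default: learn the normal-tissue manifold only; tumors are projected
    # onto it at encode time.  Training on all samples is configurable.
    if config.ae_train_on == "normals":
        types = meta.table.set_index("sample_id")["sample_type"]
        train_ids = [s for s in tpm_m.sample_ids if types.get(s) != "tumor"]
        train_m = tpm_m.subset_samples(train_ids)
    else:
        train_m = tpm_m
    if config.ae_input_k:
        # concentrate tissue signal: encode only the top-varying genes of
        # the training cohort (high-variance-gene selection before embedding)
        hv = features.select_top_varying_genes(log_m, train_m.sample_ids, k=config.ae_input_k)
        genes = [g for g in hv.arrays["selected"] if g in train_m.values.index]
        train_m = train_m.subset_genes(genes)
    sites = meta.table.set_index("sample_id")["site"].reindex(train_m.sample_ids)
    model, curve = features.train_autoencoder(train_m, params, site_labels=sites.to_numpy())
    return model, curve


def run_pipeline(
    config: RunConfig,
    counts: CountMatrix | None = None,
    meta: SampleTable | None = None,
    gene_lengths: dict | None = None,
    write_outputs: bool = True,
) -> RunResult:
    """Execute the full workflow; inputs may be paths (in config) or objects."""
    config.validate()
    if counts is None:
        counts = read_count_matrix(config.counts_path, unit="raw_count")
    if meta is None:
        meta = read_sample_table(config.metadata_path)
    if gene_lengths is None:
        gene_lengths = read_gene_lengths(config.gene_lengths_path)

    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "config": asdict(config)}

    def stage(name: str, **counts_io):
        manifest["stages"].append({"name": name, **counts_io})
        logger.info("stage %s: %s", name, counts_io)

    # correlation/embedding path works on well-detected genes only; the DE
    # stage keeps the full count matrix and applies its own abundance filter
    tpm, logm = prepare_expression(counts, gene_lengths)

    # 1-2. tumor purity filter then PC1 outlier filter -----------------------
    tumor_ids = list(meta.of_type("tumor")["sample_id"])
    qc_tumor = qc_tumor_cohort(logm, meta, config.purity_threshold, config.pc1_z)
    tumors_kept = qc_tumor.kept
    stage("purity_filter", n_in=len(tumor_ids), n_out=len(tumor_ids) - len(qc_tumor.removed_purity))
    stage("tumor_outlier_filter", n_out=len(tumors_kept))

    # 3. feature space -------------------------------------------------------
    model, curve = _build_embedding(config, logm, tpm, tumors_kept, meta)
    stage("feature_space", kind=config.feature_space, dim=model.dim)

    # 4. correlation ---------------------------------------------------------
    candidate_ids = list(meta.of_type("reference_normal")["sample_id"])
    if not candidate_ids:
        raise PipelineError("correlation", "no reference_normal candidates in metadata")
    unit = features.EmbeddingModel.INPUT_UNIT[model.kind]
    source = logm if unit == "log2_tpm_plus1" else tpm
    tumor_feats = features.encode(model, source.subset_samples(tumors_kept))
    cand_feats = features.encode(model, source.subset_samples(candidate_ids))
    kind = config.default_correlation_kind()
    ct = selection.correlate_candidates(
        tumor_feats, cand_feats, kind=kind, feature_space=config.feature_space, meta=meta
    )
    ranking = selection.rank_sites(ct, meta)
    stage("correlation", n_candidates=len(candidate_ids), kind=kind)

    # 5. reference selection -------------------------------------------------
    ref = selection.select_reference(
        ct,
        meta,
        config.method,
        n=config.n_select,
        percentile=config.percentile,
        manual_site=config.manual_site,
        seed=config.selection_seed,
    )
    stage("reference_selection", method=config.method, n_selected=len(ref.sample_ids))

    # 6. second outlier pass on the selected references ----------------------
    qc_reference = None
    ref_ids = ref.sample_ids
    if len(ref_ids) >= 3:
        qc_reference = qc.remove_pc1_outliers(
            logm.subset_samples(ref_ids), z_threshold=config.pc1_z
        )
        ref_ids = qc_reference.kept
    else:
        logger.warning("reference set too small for outlier filtering (%d)", len(ref_ids))
    stage("reference_outlier_filter", n_out=len(ref_ids))

    # 7-9. RUV -> DE -> signature -------------------------------------------
    de, signature_, ruv = _signature_for(config, counts, tumors_kept, ref_ids, "reference")
    stage("ruv_normalization", k=config.ruv_k, n_controls=config.n_controls)
    stage("differential_expression", n_tested=len(de.table))
    stage("signature", n_genes=len(signature_.table))

    # 10. optional concordance against matched adjacent normals --------------
    benchmark_de = benchmark_sig = report = None
    adjacent_ids = list(meta.of_type("adjacent_normal")["sample_id"])
    if config.compare_to_adjacent and len(adjacent_ids) >= 2:
        benchmark_de, benchmark_sig, _ = _signature_for(
            config, counts, tumors_kept, adjacent_ids, "adjacent_normal"
        )
        consensus = evaluation.consensus_signature(signature_, benchmark_sig)
        rho, rho_p = evaluation.fold_change_concordance(consensus, de, benchmark_de)
        universe = len(set(de.table["gene_id"]) & set(benchmark_de.table["gene_id"]))
        overlap_p = evaluation.overlap_significance(signature_, benchmark_sig, universe)
        report = evaluation.ConcordanceReport(
            method=config.method,
            cancer=meta.of_type("tumor")["site"].iloc[0] if len(tumor_ids) else "NA",
            n_consensus=len(consensus),
            rho=rho,
            rho_p=rho_p,
            overlap_p=overlap_p,
        )
        stage("concordance", n_consensus=len(consensus), rho=rho)

    result = RunResult(
        config=config,
        qc_tumor=qc_tumor,
        correlation=ct,
        ranking=ranking,
        reference=ref,
        qc_reference=qc_reference,
        de=de,
        signature=signature_,
        benchmark_de=benchmark_de,
        benchmark_signature=benchmark_sig,
        concordance=report,
        embedding=model,
        outdir=outdir if write_outputs else None,
    )
    if write_outputs:
        _write_run(result, curve, manifest, outdir)
    return result


def _signature_for(config: RunConfig, counts, tumor_ids, normal_ids, label):
    """RUV-normalize and test tumors against one normal cohort."""
    ids = list(tumor_ids) + list(normal_ids)
    sub = counts.subset_samples(ids)
    groups = pd.Series(
        ["tumor"] * len(tumor_ids) + [label] * len(normal_ids), index=ids
    )
    ruv = None
    if config.ruv_k > 0:
        n_ctrl = min(config.n_controls, sub.n_genes)
        controls = sig.choose_empirical_controls(sub, groups, n_controls=n_ctrl)
        ruv = sig.ruv_fit(sub, controls, k=config.ruv_k)
    de = sig.differential_expression(sub, groups, normalization=ruv)
    signature_ = sig.derive_signature(de, lfc_min=config.lfc_min, alpha=config.alpha)
    return de, signature_, ruv


def _write_run(result: RunResult, curve, manifest: dict, outdir: Path) -> None:
    result.qc_tumor.write(outdir / "qc_tumor.tsv")
    if result.qc_reference is not None:
        result.qc_reference.write(outdir / "qc_reference.tsv")
    result.correlation.write(outdir / "correlation.tsv")
    result.ranking.write(outdir / "site_ranking.tsv")
    result.reference.write(outdir / "reference_set.tsv")
    result.de.write(outdir / "de_table.tsv")
    result.signature.write(outdir / "signature.tsv")
    if result.embedding is not None:
        result.embedding.save(outdir / "embedding_model.npz")
    if curve is not None:
        curve.write(outdir / "training_curve.tsv")
    if result.benchmark_de is not None:
        result.benchmark_de.write(outdir / "benchmark_de_table.tsv")
        result.benchmark_signature.write(outdir / "benchmark_signature.tsv")
    if result.concordance is not None:
        pd.DataFrame([result.concordance.to_row()]).to_csv(
            outdir / "concordance.tsv", sep="\t", index=False, na_rep="NA"
        )
    observed = [s["name"] for s in manifest["stages"]]
    expected = [s for s in STAGE_ORDER if s in observed]
    if observed != expected:
        raise PipelineError("manifest", f"stage order violated: {observed}")
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
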