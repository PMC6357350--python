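"""Synthetic bulk RNA-seq compendium with known ground truth.

Emulates the structure of a multi-study expression compendium: several
tissue sites, several studies with per-study batch effects, a tumor cohort
(plus matched adjacent normals) with a known set of differentially
expressed genes, negative-binomial count noise and variable library sizes.
Because tissue identity, batch factors and DE genes are all known, every
downstream stage (embedding, site ranking, reference selection, RUV,
differential expression, concordance) can be tested without external data.

Generative model per gene g, sample s::

    log2 mean  = b_g + tissue_shift[g, site(s)] + batch_shift[g, study(s)]
                     + tumor_shift[g] * 1{s is tumor}
    mu         = libsize_factor_s * 2 ** (log2 mean)
    count      ~ NB(mean = mu, variance = mu + phi * mu**2)

Baseline log2-means b_g are Normal(3, 2) — i.e. a log-normal over the
count scale — so a minority of genes dominates variance, mimicking the
dynamic range of real RNA-seq.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import CountMatrix, SampleTable, write_count_matrix, write_gene_lengths, write_sample_table


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic compendium.

    ``samples_per_site_per_study`` maps ``(site, study)`` to a
    reference-normal sample count; sites/studies absent from the mapping
    get ``default_samples_per_cell`` samples.
    """

    n_genes: int = 2000
    sites: Sequence[str] = (
        "liver",
        "liver_proximal",
        "lung",
        "kidney",
        "bladder",
        "colon",
        "stomach",
        "pancreas",
        "brain",
        "skin",
    )
    studies: Sequence[str] = ("GTEX-SYN", "REFDB-SYN")
    samples_per_site_per_study: Mapping[tuple[str, str], int] = field(default_factory=dict)
    default_samples_per_cell: int = 15
    n_tumor: int = 20
    n_adjacent_normal: int = 20
    tumor_site: str = "liver"
    tumor_study: str = "TCGA-SYN"
    frac_tissue_genes: float = 0.10
    tissue_effect_sd: float = 1.5
    batch_effect_sd: float = 0.3
    n_de_genes: int = 300
    de_log2fc: float = 2.0
    de_log2fc_spread: float = 1.0  # |log2FC| ~ Uniform(de_log2fc +/- spread)
    de_min_baseline: float = 5.0  # DE genes drawn from genes with mean count >= this
    dispersion: float = 0.1
    libsize_log_sd: float = 0.2
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    proximal_pairs: Sequence[tuple[str, str]] = (("liver", "liver_proximal"),)
    proximal_correlation: float = 0.8
    gene_length_range: tuple[float, float] = (500.0, 10000.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise SimulationConfigError("n_genes must be positive")
        if not self.sites:
            raise SimulationConfigError("at least one site required")
        if self.tumor_site not in self.sites:
            raise SimulationConfigError(
                f"tumor_site {self.tumor_site!r} not in sites {list(self.sites)}"
            )
        if not 0 < self.frac_tissue_genes < 1:
            raise SimulationConfigError("frac_tissue_genes must lie in (0, 1)")
        if self.dispersion < 0:
            raise SimulationConfigError("dispersion must be >= 0")
        if self.n_de_genes > self.n_genes:
            raise SimulationConfigError("n_de_genes exceeds n_genes")
        for site, other in self.proximal_pairs:
            if site not in self.sites or other not in self.sites:
                raise SimulationConfigError(f"proximal pair ({site}, {other}) not in sites")
        if any(sd < 0 for sd in (self.tissue_effect_sd, self.batch_effect_sd, self.libsize_log_sd)):
            raise SimulationConfigError("effect standard deviations must be >= 0")

    def n_reference(self, site: str, study: str) -> int:
        return int(self.samples_per_site_per_study.get((site, study), self.default_samples_per_cell))


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must recover."""

    tissue_gene_shifts: pd.DataFrame  # genes x sites, log2
    batch_shifts: pd.DataFrame  # genes x studies, log2
    de_genes: pd.DataFrame  # gene_id, direction, log2fc
    site_of_origin: pd.Series  # tumor sample_id -> site
    gene_lengths: dict[str, float]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tissue_gene_shifts.to_csv(outdir / "tissue_shifts.tsv", sep="\t", index_label="gene_id")
        self.batch_shifts.to_csv(outdir / "batch_shifts.tsv", sep="\t", index_label="gene_id")
        self.de_genes.to_csv(outdir / "de_genes.tsv", sep="\t", index=False)
        with open(outdir / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(
                {"site_of_origin": {k: str(v) for k, v in self.site_of_origin.items()}}, fh
            )


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Counts with mean mu and variance mu + phi mu^2 (Poisson when phi=0)."""
    if phi == 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    # NB as Gamma-Poisson mixture: lambda ~ Gamma(r, mu/r), count ~ Poisson(lambda)
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def simulate_compendium(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleTable, GroundTruth]:
    """Generate (counts, metadata, ground truth) for one synthetic compendium.

    Deterministic: same config (including seed) yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(G)]
    sites = list(config.sites)
    studies = list(config.studies)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=G)

    # Tissue-specific log2 shifts: each site independently marks a fraction
    # of genes; proximal pairs share the marked set and get correlated values.
    tissue = np.zeros((G, len(sites)))
    paired = {s for pair in config.proximal_pairs for s in pair}
    for j, site in enumerate(sites):
        if site in paired and any(site == b for _, b in config.proximal_pairs):
            continue  # second member handled with its partner below
        mask = rng.random(G) < config.frac_tissue_genes
        tissue[mask, j] = rng.normal(0.0, config.tissue_effect_sd, size=mask.sum())
        for a, b in config.proximal_pairs:
            if a == site:
                jb = sites.index(b)
                rho = config.proximal_correlation
                noise = rng.normal(0.0, config.tissue_effect_sd, size=mask.sum())
                tissue[mask, jb] = rho * tissue[mask, j] + np.sqrt(1 - rho**2) * noise

    batch = np.zeros((G, len(studies) + 1))
    all_studies = studies + [config.tumor_study]
    for j in range(len(all_studies)):
        batch[:, j] = rng.normal(0.0, config.batch_effect_sd, size=G)

    # Tumor DE genes: half up, half down at +/- de_log2fc.  Drawn from genes
    # expressed above a minimal baseline so every true DE gene carries signal
    # (a fold change on an expected count near zero is unobservable).
    eligible = np.flatnonzero(2.0**baseline >= config.de_min_baseline)
    if len(eligible) < config.n_de_genes:
        eligible = np.arange(G)
    de_idx = rng.choice(eligible, size=config.n_de_genes, replace=False)
    de_sign = np.where(rng.random(config.n_de_genes) < 0.5, 1.0, -1.0)
    spread = min(config.de_log2fc_spread, config.de_log2fc)  # keep |lfc| > 0
    de_mag = (
        rng.uniform(config.de_log2fc - spread, config.de_log2fc + spread, config.n_de_genes)
        if spread > 0
        else np.full(config.n_de_genes, config.de_log2fc)
    )
    tumor_shift = np.zeros(G)
    tumor_shift[de_idx] = de_sign * de_mag

    # Assemble samples: reference normals per (site, study), then tumors and
    # matched adjacent normals at the tumor site in the tumor study.
    records = []
    log2_means = []
    for site in sites:
        for study in studies:
            n = config.n_reference(site, study)
            for i in range(n):
                records.append(
                    {
                        "sample_id": f"{study}.{site}.{i:03d}",
                        "study": study,
                        "site": site,
                        "sample_type": "reference_normal",
                        "purity": np.nan,
                    }
                )
                log2_means.append(
                    baseline + tissue[:, sites.index(site)] + batch[:, studies.index(study)]
                )
    j_tumor_study = len(studies)
    j_tsite = sites.index(config.tumor_site)
    purities = rng.uniform(0.5, 1.0, size=config.n_tumor)
    for i in range(config.n_tumor):
        records.append(
            {
                "sample_id": f"{config.tumor_study}.tumor.{i:03d}",
                "study": config.tumor_study,
                "site": config.tumor_site,
                "sample_type": "tumor",
                "purity": purities[i],
            }
        )
        log2_means.append(baseline + tissue[:, j_tsite] + batch[:, j_tumor_study] + tumor_shift)
    for i in range(config.n_adjacent_normal):
        records.append(
            {
                "sample_id": f"{config.tumor_study}.adjnorm.{i:03d}",
                "study": config.tumor_study,
                "site": config.tumor_site,
                "sample_type": "adjacent_normal",
                "purity": np.nan,
            }
        )
        log2_means.append(baseline + tissue[:, j_tsite] + batch[:, j_tumor_study])

    meta = pd.DataFrame.from_records(records)
    n_samples = len(meta)
    lib = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n_samples))
    mu = np.power(2.0, np.column_stack(log2_means)) * lib[None, :]
    counts = _nb_sample(rng, mu, config.dispersion)

    lengths = rng.uniform(*config.gene_length_range, size=G)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=meta["sample_id"].tolist()),
        unit="raw_count",
    )
    truth = GroundTruth(
        tissue_gene_shifts=pd.DataFrame(tissue, index=gene_ids, columns=sites),
        batch_shifts=pd.DataFrame(batch, index=gene_ids, columns=all_studies),
        de_genes=pd.DataFrame(
            {
                "gene_id": [gene_ids[i] for i in de_idx],
                "direction": np.where(de_sign > 0, "up", "down"),
                "log2fc": de_sign * de_mag,
            }
        ),
        site_of_origin=pd.Series(
            config.tumor_site,
            index=[f"{config.tumor_study}.tumor.{i:03d}" for i in range(config.n_tumor)],
            name="site_of_origin",
        ),
        gene_lengths=dict(zip(gene_ids, lengths)),
    )
    return cm, SampleTable(meta), truth


def write_compendium(
    counts: CountMatrix, meta: SampleTable, truth: GroundTruth, outdir: str | Path
) -> None:
    """Write the simulator output in the pipeline's TSV exchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_matrix(counts, outdir / "counts.tsv")
    write_sample_table(meta, outdir / "metadata.tsv")
    write_gene_lengths(truth.gene_lengths, outdir / "gene_lengths.tsv")
    truth.save(outdir / "ground_truth")
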