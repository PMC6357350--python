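"""Concordance between two disease signatures.

A reference-derived signature is judged against the benchmark signature
from matched adjacent normals by three quantities:

* the consensus gene set — genes significant in both signatures with the
  same fold-change direction;
* the Spearman rank correlation of log2 fold changes over the consensus
  genes (the headline agreement statistic);
* the one-sided hypergeometric significance of the signature overlap
  (membership only; directionality is the consensus set's job).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, spearmanr

from .signature import DETable, Signature


class EvaluationError(ValueError):
    pass


@dataclass
class ConcordanceReport:
    method: str
    cancer: str
    n_consensus: int
    rho: float | None  # None when consensus < 3 (undefined, not zero)
    rho_p: float | None
    overlap_p: float

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "cancer": self.cancer,
            "n_consensus": self.n_consensus,
            "rho": self.rho,
            "rho_p": self.rho_p,
            "overlap_p": self.overlap_p,
        }


def consensus_signature(sig_a: Signature, sig_b: Signature) -> pd.DataFrame:
    """Genes present in both signatures with the same direction.

    Symmetric in its arguments; returns a frame with gene_id and direction.
    """
    dir_a = sig_a.direction_of()
    dir_b = sig_b.direction_of()
    shared = sorted(set(dir_a.index) & set(dir_b.index))
    agree = [g for g in shared if dir_a[g] == dir_b[g]]
    return pd.DataFrame({"gene_id": agree, "direction": [dir_a[g] for g in agree]})


def fold_change_concordance(
    consensus: pd.DataFrame | list[str], de_a: DETable, de_b: DETable
) -> tuple[float | None, float | None]:
    """Spearman rho of log2 fold changes over the consensus genes.

    With fewer than 3 consensus genes the correlation is undefined and
    (None, None) is returned rather than an imputed zero.
    """
    genes = list(consensus["gene_id"]) if isinstance(consensus, pd.DataFrame) else list(consensus)
    if len(genes) < 3:
        return None, None
    fa = de_a.table.set_index("gene_id")["log2fc"].reindex(genes)
    fb = de_b.table.set_index("gene_id")["log2fc"].reindex(genes)
    if fa.isna().any() or fb.isna().any():
        raise EvaluationError("consensus genes missing from a DE table")
    rho, p = spearmanr(fa.to_numpy(), fb.to_numpy())
    return float(rho), float(p)


def overlap_significance(sig_a: Signature, sig_b: Signature, universe_size: int) -> float:
    """Upper-tail hypergeometric p of the signature membership overlap."""
    a, b = sig_a.genes, sig_b.genes
    if len(a) > universe_size or len(b) > universe_size:
        raise EvaluationError("signature larger than the gene universe")
    overlap = len(a & b)
    if overlap > min(len(a), len(b)):
        raise EvaluationError("overlap exceeds smaller signature (impossible input)")
    # P(X >= overlap), X ~ Hypergeom(universe, |A|, |B|)
    return float(hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))


def benchmark_methods(
    runs: list[tuple[str, ConcordanceReport]], baseline_method: str = "random50"
) -> pd.DataFrame:
    """Tabulate per-method concordance with the random baseline averaged.

    ``runs`` holds (method, report) pairs; the random baseline must be
    present (typically once per seed, >= 3 seeds) and is averaged into a
    single row.  Methods whose rho exceeds the averaged baseline are
    flagged.
    """
    rows = [rep.to_row() for _, rep in runs]
    df = pd.DataFrame(rows)
    if baseline_method not in set(df["method"]):
        raise EvaluationError(f"missing baseline method {baseline_method!r}")
    base = df[df["method"] == baseline_method]
    base_rho = base["rho"].astype(float).mean()
    others = df[df["method"] != baseline_method]
    summary = (
        others.groupby(["method", "cancer"], as_index=False)
        .agg({"n_consensus": "mean", "rho": "mean", "rho_p": "mean", "overlap_p": "mean"})
    )
    baseline_row = pd.DataFrame(
        [
            {
                "method": f"{baseline_method}_ave",
                "cancer": base["cancer"].iloc[0],
                "n_consensus": base["n_consensus"].mean(),
                "rho": base_rho,
                "rho_p": base["rho_p"].astype(float).mean(),
                "overlap_p": base["overlap_p"].mean(),
            }
        ]
    )
    out = pd.concat([summary, baseline_row], ignore_index=True)
    out["beats_baseline"] = out["rho"] > base_rho
    out.loc[out["method"] == f"{baseline_method}_ave", "beats_baseline"] = False
    return out


def write_comparison(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
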