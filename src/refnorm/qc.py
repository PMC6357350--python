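"""Sample-level quality control.

Two filters, applied to the tumor cohort before reference selection and
again to the chosen reference samples:

* purity filter — keep tumors whose purity (supplied as metadata) is
  strictly greater than a threshold (default 0.7);
* PC1 outlier filter — standardize genes, project samples onto the first
  principal component, and drop samples whose PC1 score has an absolute
  z-score above a threshold (default 3), in a single pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleTable

logger = logging.getLogger(__name__)


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    """Partition of the input samples into kept / removed, with PC1 audit."""

    kept: list[str]
    removed_purity: list[str] = field(default_factory=list)
    removed_outlier: list[str] = field(default_factory=list)
    pc1_scores: pd.DataFrame | None = None  # sample_id, pc1_score, pc1_z

    def __post_init__(self) -> None:
        groups = [set(self.kept), set(self.removed_purity), set(self.removed_outlier)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise QCError("kept/removed sets overlap")

    def write(self, path: str | Path) -> None:
        rows = []
        scores = (
            self.pc1_scores.set_index("sample_id")
            if self.pc1_scores is not None
            else pd.DataFrame()
        )
        for status, ids in [
            ("kept", self.kept),
            ("removed_purity", self.removed_purity),
            ("removed_outlier", self.removed_outlier),
        ]:
            for s in ids:
                row = {"sample_id": s, "status": status}
                if s in scores.index:
                    row["pc1_score"] = scores.loc[s, "pc1_score"]
                    row["pc1_z"] = scores.loc[s, "pc1_z"]
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def filter_by_purity(
    samples: SampleTable, threshold: float = 0.7, strict_missing: bool = False
) -> QCReport:
    """Keep tumors with purity strictly greater than ``threshold``.

    Non-tumor samples pass through untouched.  Tumors with missing purity
    are kept with a warning by default; ``strict_missing=True`` drops them.
    """
    if not 0 <= threshold <= 1:
        raise QCError(f"purity threshold must lie in [0, 1], got {threshold}")
    kept, removed = [], []
    for _, row in samples.table.iterrows():
        if row["sample_type"] != "tumor":
            kept.append(row["sample_id"])
            continue
        purity = row["purity"]
        if pd.isna(purity):
            if strict_missing:
                removed.append(row["sample_id"])
            else:
                logger.warning("tumor %s has no purity; kept", row["sample_id"])
                kept.append(row["sample_id"])
        elif purity > threshold:
            kept.append(row["sample_id"])
        else:
            removed.append(row["sample_id"])
    return QCReport(kept=kept, removed_purity=removed)


def remove_pc1_outliers(m: CountMatrix, z_threshold: float = 3.0) -> QCReport:
    """Drop samples with |z| > ``z_threshold`` on the first principal component.

    Genes are standardized to mean 0 / sd 1 across samples before the PCA;
    the z-score uses the mean and sd of the PC1 score distribution itself.
    Single pass: the PC is not re-fitted after removal.  If all scores are
    identical (sd 0) no sample is removed.
    """
    if m.n_samples < 3:
        raise QCError(f"PC1 outlier calling needs >= 3 samples, got {m.n_samples}")
    X = m.values.to_numpy(dtype=float).T  # samples x genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep_genes = sd > 0
    ids = np.asarray(m.sample_ids)
    if not keep_genes.any():  # every gene constant: no spread, no outliers
        return QCReport(
            kept=list(ids),
            pc1_scores=pd.DataFrame(
                {"sample_id": ids, "pc1_score": 0.0, "pc1_z": 0.0}
            ),
        )
    Xs = (X[:, keep_genes] - mu[keep_genes]) / sd[keep_genes]
    # first right singular vector of the centered standardized matrix
    Xc = Xs - Xs.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt[0]
    ssd = scores.std()
    if ssd == 0:
        z = np.zeros_like(scores)
    else:
        z = (scores - scores.mean()) / ssd
    out = np.abs(z) > z_threshold
    ids = np.asarray(m.sample_ids)
    report = QCReport(
        kept=list(ids[~out]),
        removed_outlier=list(ids[out]),
        pc1_scores=pd.DataFrame({"sample_id": ids, "pc1_score": scores, "pc1_z": z}),
    )
    if out.any():
        logger.info("PC1 outlier filter removed %d sample(s): %s", out.sum(), list(ids[out]))
    return report
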