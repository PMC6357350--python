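"""Tumor-to-normal correlation, site ranking and reference selection.

Each candidate reference-normal sample is scored by the mean (or median)
of its pairwise correlations to the tumor cohort in a chosen feature
space.  Sites are ranked by the median candidate score; a reference set
is then selected by one of five strategies:

* ``top_site``          — every candidate from the top-ranked site;
* ``pct25_within_site`` — top-site candidates at or above the 25th
  percentile of that site's score distribution;
* ``top50_any_site``    — the 50 highest-scoring candidates regardless of
  site (site recorded as ``NA``);
* ``random50``          — 50 candidates drawn uniformly without
  replacement (seeded baseline);
* ``manual``            — every candidate from an analyst-specified site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import SampleTable

logger = logging.getLogger(__name__)

METHODS = ("top_site", "pct25_within_site", "top50_any_site", "random50", "manual")


class SelectionError(ValueError):
    pass


@dataclass
class CorrelationTable:
    """Per-candidate mean correlation to the tumor cohort."""

    table: pd.DataFrame  # sample_id, site, correlation
    feature_space: str
    correlation_kind: str

    def __post_init__(self) -> None:
        corr = self.table["correlation"].dropna()
        if ((corr < -1 - 1e-12) | (corr > 1 + 1e-12)).any():
            raise SelectionError("correlation outside [-1, 1]")
        if self.table["sample_id"].duplicated().any():
            raise SelectionError("duplicate candidate in correlation table")

    def write(self, path: str | Path) -> None:
        out = self.table.assign(
            feature_space=self.feature_space, correlation_kind=self.correlation_kind
        )
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class SiteRanking:
    """Sites ordered by median candidate correlation (descending)."""

    table: pd.DataFrame  # site, median_correlation, normalized, n_candidates

    @property
    def top_site(self) -> str:
        return self.table.iloc[0]["site"]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ReferenceSet:
    method: str
    sample_ids: list[str]
    site: str  # "NA" for cross-site methods
    correlations: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    seed: int | None = None

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "method": self.method,
                "site": self.site,
                "correlation": [self.correlations.get(s, np.nan) for s in self.sample_ids],
            }
        ).to_csv(path, sep="\t", index=False, na_rep="NA")


def _row_correlations(A: np.ndarray, B: np.ndarray, kind: str) -> np.ndarray:
    """Pairwise correlation between rows of A (n x d) and rows of B (m x d)."""
    if kind == "spearman":
        A = rankdata(A, axis=1)
        B = rankdata(B, axis=1)
    elif kind != "pearson":
        raise SelectionError(f"unknown correlation kind {kind!r}")
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (A @ B.T) / np.outer(na, nb)
    C[na == 0, :] = np.nan
    C[:, nb == 0] = np.nan
    return C


def correlate_candidates(
    tumors: pd.DataFrame,
    candidates: pd.DataFrame,
    kind: str = "spearman",
    feature_space: str = "varying_genes",
    meta: SampleTable | None = None,
    aggregate: str = "mean",
    standardize: bool | None = None,
) -> CorrelationTable:
    """Score each candidate by its mean correlation to the tumor cohort.

    ``tumors`` and ``candidates`` are samples x features frames from
    :func:`refnorm.features.encode`.  For compact embeddings (PCA,
    autoencoder) each feature dimension is z-scored across the pooled
    tumor + candidate samples before correlating — embedding dimensions
    carry arbitrary scales and offsets, so a profile-wise correlation is
    only meaningful on a common scale; gene-space features already share
    the log2(TPM+1) scale and are used as-is.  ``standardize`` overrides
    this default.  Zero-variance feature vectors yield undefined
    correlations; those pairs are excluded from the mean with a warning.
    """
    if tumors.shape[1] != candidates.shape[1]:
        raise SelectionError("tumor and candidate feature dimensionality differ")
    if tumors.shape[1] < 3:
        raise SelectionError("need >= 3 features for a meaningful correlation")
    T = tumors.to_numpy(dtype=float)
    K = candidates.to_numpy(dtype=float)
    if standardize is None:
        standardize = feature_space in ("pca", "autoencoder")
    if standardize:
        pooled = np.vstack([T, K])
        mu = pooled.mean(axis=0)
        sd = pooled.std(axis=0)
        sd[sd == 0] = 1.0
        T = (T - mu) / sd
        K = (K - mu) / sd
    C = _row_correlations(K, T, kind)  # candidates x tumors
    if np.isnan(C).any():
        logger.warning(
            "%d candidate/tumor pair(s) had zero-variance features; excluded from mean",
            int(np.isnan(C).sum()),
        )
    agg = np.nanmean if aggregate == "mean" else np.nanmedian
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows stay NaN
        scores = agg(C, axis=1)
    table = pd.DataFrame({"sample_id": candidates.index, "correlation": scores})
    if meta is not None:
        table["site"] = table["sample_id"].map(meta.site_of())
    else:
        table["site"] = "NA"
    return CorrelationTable(
        table=table[["sample_id", "site", "correlation"]],
        feature_space=feature_space,
        correlation_kind=kind,
    )


def rank_sites(ct: CorrelationTable, meta: SampleTable | None = None) -> SiteRanking:
    """Order sites by the median of their candidates' correlations.

    Also emits each site's median normalized by the top site's median,
    for cross-feature-space comparison.  Ties break by site label.
    """
    table = ct.table.copy()
    if meta is not None:
        table["site"] = table["sample_id"].map(meta.site_of())
    if table["site"].isna().any():
        missing = table.loc[table["site"].isna(), "sample_id"].tolist()
        raise SelectionError(f"candidates without a site label: {missing[:5]}")
    stats = (
        table.groupby("site")["correlation"]
        .agg(median_correlation="median", n_candidates="count")
        .reset_index()
    )
    stats = stats.sort_values(
        ["median_correlation", "site"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    top = stats["median_correlation"].iloc[0]
    stats["normalized"] = stats["median_correlation"] / top if top != 0 else np.nan
    return SiteRanking(table=stats[["site", "median_correlation", "normalized", "n_candidates"]])


def select_reference(
    ct: CorrelationTable,
    meta: SampleTable,
    method: str,
    n: int = 50,
    percentile: float = 25.0,
    manual_site: str | None = None,
    seed: int | None = None,
) -> ReferenceSet:
    """Select a reference-normal set by one of the five strategies."""
    if method not in METHODS:
        raise SelectionError(f"unknown method {method!r}; expected one of {METHODS}")
    table = ct.table.copy()
    table["site"] = table["sample_id"].map(meta.site_of())
    if table.empty:
        raise SelectionError("empty candidate pool")
    corr = table.set_index("sample_id")["correlation"]

    if method in ("top_site", "pct25_within_site"):
        ranking = rank_sites(ct, meta)
        site = ranking.top_site
        at_site = table[table["site"] == site]
        if method == "pct25_within_site":
            cutoff = np.percentile(at_site["correlation"].to_numpy(), percentile)
            at_site = at_site[at_site["correlation"] >= cutoff]
        ids = sorted(at_site["sample_id"])
        return ReferenceSet(method=method, sample_ids=ids, site=site, correlations=corr)
    if method == "top50_any_site":
        ordered = table.sort_values(
            ["correlation", "sample_id"], ascending=[False, True], kind="mergesort"
        )
        ids = ordered["sample_id"].head(n).tolist()
        return ReferenceSet(method=method, sample_ids=ids, site="NA", correlations=corr)
    if method == "random50":
        if seed is None:
            raise SelectionError("random50 requires a seed")
        rng = np.random.default_rng(seed)
        pool = sorted(table["sample_id"])
        k = min(n, len(pool))
        ids = sorted(rng.choice(pool, size=k, replace=False))
        return ReferenceSet(
            method=method, sample_ids=ids, site="NA", correlations=corr, seed=seed
        )
    # manual
    if manual_site is None or manual_site not in set(table["site"]):
        raise SelectionError(
            f"manual_site {manual_site!r} not among candidate sites "
            f"{sorted(set(table['site'].dropna()))}"
        )
    ids = sorted(table.loc[table["site"] == manual_site, "sample_id"])
    return ReferenceSet(method="manual", sample_ids=ids, site=manual_site, correlations=corr)


def call_tissue_of_origin(
    ranking: SiteRanking, expected: dict, cancer: str
) -> tuple[str, str]:
    """Classify the top-ranked site against a curated cancer -> site mapping.

    ``expected`` maps cancer label to ``{"primary": [...], "proximal": [...]}``.
    Returns ``(verdict, top_site)`` with verdict in
    {correct, proximal_correct, incorrect}.
    """
    if cancer not in expected:
        raise SelectionError(f"cancer {cancer!r} absent from expected-site mapping")
    entry = expected[cancer]
    top = ranking.top_site
    if top in set(entry.get("primary", [])):
        return "correct", top
    if top in set(entry.get("proximal", [])):
        return "proximal_correct", top
    return "incorrect", top
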