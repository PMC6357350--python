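"""RUV normalization, negative-binomial differential expression, and
disease-signature thresholding.

The DE engine is a self-contained negative-binomial empirical-Bayes test:

1. library-size normalization by median-of-ratios size factors;
2. per-gene method-of-moments dispersion, shrunk toward a mean-dependent
   trend phi(mu) = a + b/mu by empirical-Bayes weighting;
3. an exact-style conditional test of mean equality between the two
   groups, computed on group sums of normalized counts (the two-sided
   p-value sums all conditional outcomes at most as probable as the one
   observed);
4. Benjamini-Hochberg adjustment across the tested genes.

Unwanted variation is removed beforehand (optionally) by a
control-gene factor analysis: the top singular vectors of the centered
log-counts of a control-gene set estimate nuisance factors W, whose
contribution is regressed out of every gene.

A signature is the signed gene set with |log2FC| strictly above
``lfc_min`` (default 1) and adjusted p strictly below ``alpha``
(default 0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom

from .io import CountMatrix

logger = logging.getLogger(__name__)


class SignatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values: monotone, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise SignatureError("p must be a 1-d vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise SignatureError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# RUV (remove unwanted variation, control-gene flavor)
# ---------------------------------------------------------------------------

@dataclass
class RUVFit:
    """Estimated nuisance factors W (samples x k) and gene loadings alpha."""

    k: int
    controls: list[str]
    W: np.ndarray  # samples x k
    alpha: np.ndarray  # k x genes
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)


def ruv_fit(counts: CountMatrix, controls: set[str] | list[str], k: int) -> RUVFit:
    """Estimate k unwanted factors from control genes.

    On Y = log(counts + 1): the control-gene rows are centered and their
    singular value decomposition taken; W is the top-k right singular
    vectors scaled by singular values, and alpha is the least-squares
    regression of every (centered) gene on W.
    """
    if k < 0:
        raise SignatureError("k must be >= 0")
    if k >= counts.n_samples and k > 0:
        raise SignatureError(f"k ({k}) must be < n_samples ({counts.n_samples})")
    controls = sorted(set(controls))
    if k > 0 and not controls:
        raise SignatureError("control gene set empty with k > 0")
    missing = set(controls) - set(counts.gene_ids)
    if missing:
        raise SignatureError(f"control genes absent from matrix: {sorted(missing)[:5]}")
    if k == 0:
        return RUVFit(
            k=0,
            controls=controls,
            W=np.zeros((counts.n_samples, 0)),
            alpha=np.zeros((0, counts.n_genes)),
            gene_ids=list(counts.gene_ids),
            sample_ids=list(counts.sample_ids),
        )
    Y = np.log(counts.values.to_numpy(dtype=float) + 1.0)  # genes x samples
    ctrl_idx = counts.values.index.get_indexer(controls)
    Z = Y[ctrl_idx, :]
    Zc = Z - Z.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Zc, full_matrices=False)
    W = (vt[:k, :] * s[:k, None]).T  # samples x k
    Yc = Y - Y.mean(axis=1, keepdims=True)
    alpha, *_ = np.linalg.lstsq(W, Yc.T, rcond=None)  # k x genes
    return RUVFit(
        k=k,
        controls=controls,
        W=W,
        alpha=alpha,
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
    )


def ruv_normalize(fit: RUVFit, counts: CountMatrix) -> CountMatrix:
    """Remove the fitted W·alpha term and map back to integer counts.

    k = 0 returns the input counts exactly.  Normalized log counts are
    exponentiated, shifted back by the pseudocount, rounded and floored
    at zero.
    """
    if fit.k == 0:
        return counts
    if list(counts.sample_ids) != fit.sample_ids or list(counts.gene_ids) != fit.gene_ids:
        raise SignatureError("counts do not match the RUV fit's gene/sample universe")
    Y = np.log(counts.values.to_numpy(dtype=float) + 1.0)
    norm = Y - (fit.W @ fit.alpha).T
    vals = np.maximum(np.rint(np.exp(norm) - 1.0), 0.0)
    return CountMatrix(
        pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns),
        unit="raw_count",
    )


def choose_empirical_controls(
    counts: CountMatrix, groups: pd.Series, n_controls: int = 1000
) -> list[str]:
    """Least-DE genes by a first-pass test, used as empirical RUV controls.

    Genes are ranked by the p-value of an unnormalized first-pass DE test,
    largest p first; the top ``n_controls`` are returned.
    """
    if n_controls > counts.n_genes:
        raise SignatureError(
            f"n_controls ({n_controls}) exceeds gene count ({counts.n_genes})"
        )
    # mid-p first pass: a discrete p piles ties at 1 on low-count genes,
    # which would bias the control set toward weak expression
    de = differential_expression(counts, groups, normalization=None, min_count=0, midp=True)
    ranked = de.table.sort_values(["pvalue", "gene_id"], ascending=[False, True], kind="mergesort")
    return ranked["gene_id"].head(n_controls).tolist()


# ---------------------------------------------------------------------------
# Negative-binomial differential expression
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """Per-gene log2 fold change (tumor vs reference), p, BH-adjusted p."""

    table: pd.DataFrame  # gene_id, base_mean, log2fc, pvalue, padj

    def __post_init__(self) -> None:
        t = self.table
        if ((t["pvalue"] < 0) | (t["pvalue"] > 1)).any():
            raise SignatureError("p-value outside [0, 1]")
        if (t["padj"] + 1e-12 < t["pvalue"]).any():
            raise SignatureError("adjusted p below raw p")

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "DETable":
        return cls(pd.read_csv(path, sep="\t"))


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors (genes x samples input)."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    finite = np.isfinite(logc).all(axis=1)
    if finite.sum() >= 10:
        logref = logc[finite].mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc[finite] - logref, axis=0))
    else:  # too few always-expressed genes: fall back to library-size ratios
        lib = counts.sum(axis=0).astype(float)
        sf = lib / np.exp(np.mean(np.log(np.maximum(lib, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))


def _dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit phi(mu) = a + b/mu to the per-gene moment estimates.

    Weighted least squares on genes with usable estimates; coefficients
    floored at zero so the trend stays a valid dispersion.
    """
    ok = (mean > 0) & np.isfinite(disp)
    if ok.sum() < 10:
        common = float(np.nanmedian(np.where(ok, disp, np.nan))) if ok.any() else 0.1
        return np.full_like(mean, max(common, 1e-8))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    y = disp[ok]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = max(coef[0], 1e-8), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a + b / np.maximum(mean, 1e-8)
    return trend


def _moment_dispersions(y: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-group method-of-moments dispersion per gene."""
    means, excess = [], []
    for idx in (idx_a, idx_b):
        sub = y[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        means.append(mu * len(idx))
        excess.append((var - mu) * (len(idx) - 1))
    mu_all = y[:, np.concatenate([idx_a, idx_b])].mean(axis=1)
    # pool the (var - mu) excess over groups, weight by within-group df
    df = (len(idx_a) - 1) + (len(idx_b) - 1)
    pooled_excess = (excess[0] + excess[1]) / df
    mu_sq = (means[0] / len(idx_a)) ** 2 * (len(idx_a) - 1) / df + (
        means[1] / len(idx_b)
    ) ** 2 * (len(idx_b) - 1) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mu_sq > 0, pooled_excess / mu_sq, np.nan)
    disp = np.clip(disp, 0.0, 10.0)
    return mu_all, disp


def _exact_nb_pvalue(
    sum_a: float, n_a: int, sum_b: float, n_b: int, phi: float, midp: bool = False
) -> float:
    """Two-sided conditional NB test of equal per-sample means.

    The group sums are treated as NB with mean n*mu and dispersion phi/n.
    Conditional on the total, the p-value sums the probabilities of all
    splits at most as probable as the observed one (double-tail style).
    ``midp`` subtracts half the observed outcome's probability, which
    de-discretizes the null distribution (used for control-gene ranking,
    not for inference).
    """
    ya = int(round(sum_a))
    yb = int(round(sum_b))
    total = ya + yb
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    mean_a, mean_b = n_a * mu, n_b * mu
    phi_a, phi_b = phi / n_a, phi / n_b
    if phi <= 1e-10:
        # Poisson limit: conditional distribution is Binomial(total, n_a/(n_a+n_b))
        from scipy.stats import binom

        w = n_a / (n_a + n_b)
        logp = binom.logpmf(np.arange(total + 1), total, w)
        obs = logp[ya]
        mass = logp[logp <= obs + 1e-10]
        p = np.exp(logsumexp(mass) - logsumexp(logp))
        if midp:
            p -= 0.5 * np.exp(obs - logsumexp(logp))
        return float(min(1.0, p))
    r_a, r_b = 1.0 / phi_a, 1.0 / phi_b
    p_a = r_a / (r_a + mean_a)
    p_b = r_b / (r_b + mean_b)
    # enumeration window around the conditional mode, wide enough that the
    # excluded mass is negligible
    var_a = mean_a + phi_a * mean_a**2
    var_b = mean_b + phi_b * mean_b**2
    cvar = var_a * var_b / (var_a + var_b)
    center = total * n_a / (n_a + n_b)
    half = 10.0 * np.sqrt(cvar) + 50.0
    lo = max(0, int(center - half))
    hi = min(total, int(center + half))
    ya_grid = np.arange(lo, hi + 1)
    logp = nbinom.logpmf(ya_grid, r_a, p_a) + nbinom.logpmf(total - ya_grid, r_b, p_b)
    if ya < lo or ya > hi:
        return 0.0 if hi > lo else 1.0
    obs = logp[ya - lo]
    denom = logsumexp(logp)
    mass = logp[logp <= obs + 1e-10]
    p = np.exp(logsumexp(mass) - denom)
    if midp:
        p -= 0.5 * np.exp(obs - denom)
    return float(min(1.0, p))


def differential_expression(
    counts: CountMatrix,
    groups: pd.Series,
    normalization: RUVFit | None = None,
    min_count: int = 10,
    min_fraction: float = 0.25,
    prior_count: float = 0.5,
    prior_df: float = 10.0,
    midp: bool = False,
) -> DETable:
    """Two-group NB differential expression (tumor vs reference).

    ``groups`` maps sample_id to ``tumor`` or a reference label; log2 fold
    changes are tumor over reference.  Genes with fewer than ``min_count``
    counts in at least ``min_fraction`` of samples are excluded before
    testing.
    """
    if counts.unit != "raw_count":
        raise SignatureError(f"differential expression expects raw counts, got {counts.unit}")
    groups = groups.reindex(counts.sample_ids)
    if groups.isna().any():
        raise SignatureError("every sample needs a group label")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise SignatureError(f"exactly two groups required, got {list(levels)}")
    # tumor group is the numerator when present
    if "tumor" in set(levels):
        lev_a = "tumor"
        lev_b = [l for l in levels if l != "tumor"][0]
    else:
        lev_a, lev_b = sorted(levels)
    idx_a = np.flatnonzero((groups == lev_a).to_numpy())
    idx_b = np.flatnonzero((groups == lev_b).to_numpy())
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise SignatureError("each group needs >= 2 samples")

    if normalization is not None and normalization.k > 0:
        counts = ruv_normalize(normalization, counts)
    raw = counts.values.to_numpy(dtype=float)
    if raw.sum() == 0:
        raise SignatureError("all-zero count matrix")

    keep = (raw >= min_count).mean(axis=1) >= min_fraction if min_count > 0 else np.ones(
        raw.shape[0], dtype=bool
    )
    genes = np.asarray(counts.gene_ids)[keep]
    sub = raw[keep]

    sf = _size_factors(raw)
    y = sub / sf[None, :]

    mu_all, disp_raw = _moment_dispersions(y, idx_a, idx_b)
    trend = _dispersion_trend(mu_all, disp_raw)
    df_gene = len(idx_a) + len(idx_b) - 2
    disp_ok = np.where(np.isfinite(disp_raw), disp_raw, trend)
    phi = (df_gene * disp_ok + prior_df * trend) / (df_gene + prior_df)
    phi = np.clip(phi, 1e-8, 10.0)

    sum_a = y[:, idx_a].sum(axis=1)
    sum_b = y[:, idx_b].sum(axis=1)
    n_a, n_b = len(idx_a), len(idx_b)
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    log2fc = np.log2(mean_a + prior_count) - np.log2(mean_b + prior_count)

    pvals = np.array(
        [
            _exact_nb_pvalue(sum_a[i], n_a, sum_b[i], n_b, phi[i], midp=midp)
            for i in range(len(genes))
        ]
    )
    padj = benjamini_hochberg(pvals)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "base_mean": mu_all,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
        }
    )
    return DETable(table=table)


# ---------------------------------------------------------------------------
# Signature thresholding
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    """Signed DE gene set: |log2FC| > lfc_min and padj < alpha (both strict)."""

    table: pd.DataFrame  # gene_id, direction, log2fc
    lfc_min: float = 1.0
    alpha: float = 0.001

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene_id"])

    def direction_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["direction"]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "Signature":
        return cls(pd.read_csv(path, sep="\t"))


def derive_signature(de: DETable, lfc_min: float = 1.0, alpha: float = 0.001) -> Signature:
    """Threshold a DE table into a signed signature (strict inequalities)."""
    t = de.table
    hit = (t["log2fc"].abs() > lfc_min) & (t["padj"] < alpha)
    sel = t.loc[hit, ["gene_id", "log2fc"]].copy()
    sel["direction"] = np.where(sel["log2fc"] > 0, "up", "down")
    return Signature(
        table=sel[["gene_id", "direction", "log2fc"]].reset_index(drop=True),
        lfc_min=lfc_min,
        alpha=alpha,
    )
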