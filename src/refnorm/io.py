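"""Count-matrix and sample-metadata containers with TSV readers/writers.

The exchange objects for the whole pipeline are a genes x samples
:class:`CountMatrix` (raw counts, TPM, or log2(TPM+1)) and a per-sample
:class:`SampleTable` carrying study, tissue site, sample type and optional
tumor purity.  Everything is tab-separated UTF-8 text; missing purity is
written as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary for sample_type.
SAMPLE_TYPES = ("tumor", "adjacent_normal", "reference_normal")

#: Allowed expression units.
UNITS = ("raw_count", "tpm", "log2_tpm_plus1")

TPM_TOTAL = 1e6


class ExpressionIOError(ValueError):
    """Raised for malformed matrices, metadata, or unit mismatches."""


@dataclass
class CountMatrix:
    """Genes x samples expression matrix with a declared unit.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    unit
        One of ``raw_count``, ``tpm``, ``log2_tpm_plus1``.
    """

    values: pd.DataFrame
    unit: str = "raw_count"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ExpressionIOError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ExpressionIOError(f"duplicate gene id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ExpressionIOError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionIOError("non-numeric values in count matrix")
        if self.unit in ("raw_count", "tpm") and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ExpressionIOError(
                f"negative value at gene {idx[g]!r}, sample {cols[s]!r} for unit {self.unit}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ExpressionIOError(f"samples absent from matrix: {missing[:5]}")
        return CountMatrix(self.values.loc[:, list(sample_ids)].copy(), self.unit)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise ExpressionIOError(f"genes absent from matrix: {missing[:5]}")
        return CountMatrix(self.values.loc[list(gene_ids), :].copy(), self.unit)


@dataclass
class SampleTable:
    """Per-sample annotations: study, tissue site, sample type, purity."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample_id", "study", "site", "sample_type")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ExpressionIOError(f"metadata missing required column {col!r}")
        if "purity" not in t.columns:
            t = t.copy()
            t["purity"] = np.nan
            self.table = t
        if t["sample_id"].duplicated().any():
            dup = t["sample_id"][t["sample_id"].duplicated()].iloc[0]
            raise ExpressionIOError(f"duplicate sample id in metadata: {dup!r}")
        bad = set(t["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ExpressionIOError(
                f"sample_type outside vocabulary {SAMPLE_TYPES}: {sorted(bad)}"
            )
        pur = pd.to_numeric(self.table["purity"], errors="coerce")
        with_value = pur.dropna()
        if ((with_value < 0) | (with_value > 1)).any():
            raise ExpressionIOError("purity outside [0, 1]")
        self.table = self.table.assign(purity=pur).reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def of_type(self, sample_type: str) -> pd.DataFrame:
        return self.table[self.table["sample_type"] == sample_type]

    def site_of(self) -> pd.Series:
        """sample_id -> site mapping."""
        return self.table.set_index("sample_id")["site"]

    def subset(self, sample_ids) -> "SampleTable":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleTable(keep.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, unit: str = "raw_count") -> CountMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ExpressionIOError(f"empty file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ExpressionIOError(f"empty file: {path}") from exc
    if df.shape[1] == 0:
        raise ExpressionIOError(f"no sample columns in {path}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        bad = df[non_numeric[0]]
        row = bad[pd.to_numeric(bad, errors="coerce").isna()].index
        raise ExpressionIOError(
            f"non-numeric cell in column {non_numeric[0]!r}"
            + (f", row {row[0]!r}" if len(row) else "")
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df, unit)


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    df = m.values
    if m.unit == "raw_count" and np.allclose(df.to_numpy() % 1, 0):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    return SampleTable(df)


def write_sample_table(t: SampleTable, path: str | Path) -> None:
    t.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gene_lengths(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ExpressionIOError("gene-length file needs columns gene_id, length")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_gene_lengths(lengths: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(lengths), "length": list(lengths.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def counts_to_tpm(counts: CountMatrix, gene_lengths: Mapping[str, float]) -> CountMatrix:
    """Length-normalize raw counts to transcripts per million.

    Per sample: ``rate_g = count_g / (length_g / 1000)`` and
    ``tpm_g = 1e6 * rate_g / sum(rates)``.  Columns with zero total stay
    all-zero (flagged with a warning) rather than dividing by zero.
    """
    if counts.unit != "raw_count":
        raise ExpressionIOError(f"counts_to_tpm expects raw_count, got {counts.unit}")
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise ExpressionIOError(f"no length for gene(s): {missing[:5]}")
    lengths = np.array([gene_lengths[g] for g in counts.gene_ids], dtype=float)
    nonpos = np.array(counts.gene_ids)[lengths <= 0]
    if len(nonpos):
        raise ExpressionIOError(f"non-positive length for gene(s): {list(nonpos[:5])}")
    rates = counts.values.to_numpy(dtype=float) / (lengths[:, None] / 1000.0)
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        logger.warning(
            "all-zero sample column(s) left as zero in TPM: %s",
            [counts.sample_ids[i] for i in np.flatnonzero(zero_cols)],
        )
    safe_totals = np.where(zero_cols, 1.0, totals)
    tpm = TPM_TOTAL * rates / safe_totals
    return CountMatrix(
        pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns),
        unit="tpm",
    )


def log_transform(m: CountMatrix) -> CountMatrix:
    """Elementwise log2(x + 1) on a TPM matrix."""
    if m.unit != "tpm":
        raise ExpressionIOError(f"log_transform expects tpm, got {m.unit}")
    return CountMatrix(np.log2(m.values + 1.0), unit="log2_tpm_plus1")


def filter_low_expression(
    m: CountMatrix, min_count: float = 10, min_fraction: float = 0.25
) -> CountMatrix:
    """Keep genes with >= ``min_count`` counts in >= ``min_fraction`` of samples.

    Applied before embedding/correlation so that sampling noise of barely
    detected genes does not dominate variance rankings; mirrors the
    abundance convention used by the differential-expression engine.
    """
    if m.unit != "raw_count":
        raise ExpressionIOError(f"filter_low_expression expects raw_count, got {m.unit}")
    frac = (m.values.to_numpy() >= min_count).mean(axis=1)
    keep = frac >= min_fraction
    return CountMatrix(m.values.loc[keep, :].copy(), m.unit)


def drop_zero_variance_genes(m: CountMatrix) -> CountMatrix:
    """Drop genes constant across all samples (required before correlations)."""
    var = m.values.to_numpy().var(axis=1)
    keep = var > 0
    if keep.all():
        return m
    return CountMatrix(m.values.loc[keep, :].copy(), m.unit)
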