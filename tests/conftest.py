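import numpy as np
import pandas as pd
import pytest

from refnorm import (
    CountMatrix,
    SampleTable,
    SimulationConfig,
    counts_to_tpm,
    drop_zero_variance_genes,
    filter_low_expression,
    log_transform,
    simulate_compendium,
)


@pytest.fixture(scope="session")
def compendium():
    """One default synthetic compendium shared across read-only tests."""
    cfg = SimulationConfig(seed=0)
    counts, meta, truth = simulate_compendium(cfg)
    return counts, meta, truth


@pytest.fixture(scope="session")
def compendium_logtpm(compendium):
    counts, meta, truth = compendium
    expressed = filter_low_expression(counts)
    tpm = counts_to_tpm(expressed, truth.gene_lengths)
    return drop_zero_variance_genes(log_transform(tpm)), tpm, meta, truth


@pytest.fixture()
def tiny_counts():
    """2 genes x 2 samples, hand-sized."""
    return CountMatrix(
        pd.DataFrame(
            [[10, 0], [10, 5]],
            index=["GA", "GB"],
            columns=["S1", "S2"],
        ),
        unit="raw_count",
    )


@pytest.fixture()
def simple_meta():
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "S4"],
                "study": ["st1"] * 4,
                "site": ["liver", "liver", "lung", "lung"],
                "sample_type": ["tumor", "tumor", "reference_normal", "reference_normal"],
                "purity": [0.9, 0.8, np.nan, np.nan],
            }
        )
    )
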