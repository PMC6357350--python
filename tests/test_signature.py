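import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from refnorm.io import CountMatrix
from refnorm.signature import (
    DETable,
    SignatureError,
    benjamini_hochberg,
    choose_empirical_controls,
    derive_signature,
    differential_expression,
    ruv_fit,
    ruv_normalize,
)


def _nb(rng, mu, phi, size):
    r = 1 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


def _matrix(vals, prefix="s"):
    vals = np.asarray(vals)
    return CountMatrix(
        pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(vals.shape[0])],
            columns=[f"{prefix}{i}" for i in range(vals.shape[1])],
        )
    )


def _two_group_counts(rng, n_genes, n_a, n_b, phi=0.1, lfc=None, mean_log=3.0, mean_sd=1.5):
    mu = np.exp(rng.normal(mean_log, mean_sd, n_genes))
    mu_a = mu * (2.0 ** lfc if lfc is not None else 1.0)
    a = _nb(rng, mu_a[:, None], phi, (n_genes, n_a))
    b = _nb(rng, mu[:, None], phi, (n_genes, n_b))
    cm = _matrix(np.hstack([a, b]))
    groups = pd.Series(["tumor"] * n_a + ["ref"] * n_b, index=cm.sample_ids)
    return cm, groups


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        got = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_unchanged(self):
        assert benjamini_hochberg(np.ones(5)).tolist() == [1.0] * 5

    def test_single_p_unchanged(self):
        assert benjamini_hochberg(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(SignatureError):
            benjamini_hochberg(np.array([0.5, 1.5]))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_reference_implementation(self, seed):
        p = np.random.default_rng(seed).uniform(size=25)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(benjamini_hochberg(p), expected, atol=1e-12)


class TestRUV:
    def test_k_zero_is_identity(self):
        rng = np.random.default_rng(0)
        cm = _matrix(rng.poisson(20, size=(50, 10)))
        fit = ruv_fit(cm, [], k=0)
        out = ruv_normalize(fit, cm)
        pd.testing.assert_frame_equal(out.values, cm.values)

    def test_recovers_rank_one_contamination(self):
        rng = np.random.default_rng(3)
        n_genes, n = 2000, 40
        mu = np.exp(rng.normal(3, 1.5, n_genes))
        factor = rng.normal(0, 1, n)
        loadings = rng.normal(0, 0.5, n_genes)
        counts = rng.poisson(np.exp(np.log(mu)[:, None] + loadings[:, None] * factor[None, :]))
        cm = _matrix(counts)
        fit = ruv_fit(cm, [f"g{i}" for i in range(200)], k=1)
        r = np.corrcoef(fit.W[:, 0], factor)[0, 1]
        assert abs(r) > 0.99

    def test_factor_columns_orthogonal(self):
        rng = np.random.default_rng(5)
        cm = _matrix(rng.poisson(30, size=(300, 20)))
        fit = ruv_fit(cm, [f"g{i}" for i in range(100)], k=3)
        gram = fit.W.T @ fit.W
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_k_at_least_sample_count_rejected(self):
        cm = _matrix(np.ones((10, 4), dtype=int))
        with pytest.raises(SignatureError):
            ruv_fit(cm, ["g0"], k=4)

    def test_empty_controls_with_positive_k_rejected(self):
        cm = _matrix(np.ones((10, 4), dtype=int))
        with pytest.raises(SignatureError, match="control"):
            ruv_fit(cm, [], k=1)


class TestEmpiricalControls:
    def test_all_genes_when_n_controls_is_gene_count(self):
        rng = np.random.default_rng(1)
        cm, groups = _two_group_counts(rng, 100, 4, 4)
        controls = choose_empirical_controls(cm, groups, n_controls=100)
        assert set(controls) == set(cm.gene_ids)

    def test_true_de_genes_avoid_control_set(self):
        rng = np.random.default_rng(2)
        lfc = np.zeros(2000)
        de_idx = rng.choice(2000, 100, replace=False)
        lfc[de_idx] = 3.0
        cm, groups = _two_group_counts(rng, 2000, 10, 10, lfc=lfc)
        controls = choose_empirical_controls(cm, groups, n_controls=100)
        de_genes = {f"g{i}" for i in de_idx}
        assert len(set(controls) & de_genes) == 0

    def test_null_controls_not_biased_by_abundance(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(4)
        cm, groups = _two_group_counts(rng, 3000, 8, 8)
        controls = choose_empirical_controls(cm, groups, n_controls=300)
        ranks = pd.Series(cm.values.mean(axis=1).rank(pct=True), index=cm.gene_ids)
        assert kstest(ranks[controls], "uniform").pvalue > 0.01

    def test_too_many_controls_rejected(self):
        rng = np.random.default_rng(0)
        cm, groups = _two_group_counts(rng, 50, 3, 3)
        with pytest.raises(SignatureError):
            choose_empirical_controls(cm, groups, n_controls=51)


class TestDifferentialExpression:
    def test_duplicated_groups_are_null(self):
        rng = np.random.default_rng(6)
        base = _nb(rng, np.exp(rng.normal(4, 1, 400))[:, None], 0.1, (400, 6))
        cm = _matrix(np.hstack([base, base]))
        groups = pd.Series(["tumor"] * 6 + ["ref"] * 6, index=cm.sample_ids)
        de = differential_expression(cm, groups)
        assert np.allclose(de.table["log2fc"], 0.0, atol=1e-9)
        assert (de.table["pvalue"] > 0.5).all()

    def test_label_swap_flips_logfc_keeps_p(self):
        rng = np.random.default_rng(7)
        cm, groups = _two_group_counts(rng, 500, 8, 8)
        de1 = differential_expression(cm, groups)
        swapped = groups.map({"tumor": "zz_ref", "ref": "aa_tumor"})
        de2 = differential_expression(cm, swapped)
        # aa_tumor (old ref) becomes numerator after the swap
        assert np.allclose(de1.table["log2fc"], -de2.table["log2fc"], atol=1e-9)
        assert np.allclose(de1.table["pvalue"], de2.table["pvalue"], atol=1e-9)

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(8)
        rates = {}
        for effect in (1.0, 3.0):
            lfc = np.zeros(1500)
            lfc[:150] = effect
            cm, groups = _two_group_counts(np.random.default_rng(8), 1500, 10, 10, lfc=lfc)
            de = differential_expression(cm, groups)
            t = de.table.set_index("gene_id")
            tested_de = [g for g in t.index if int(g[1:]) < 150]
            rates[effect] = (t.loc[tested_de, "padj"] < 0.05).mean()
        assert rates[3.0] >= rates[1.0]
        assert rates[3.0] > 0.9

    def test_ruv_k0_equals_no_normalization(self):
        rng = np.random.default_rng(9)
        cm, groups = _two_group_counts(rng, 300, 5, 5)
        fit = ruv_fit(cm, [], k=0)
        de_a = differential_expression(cm, groups, normalization=fit)
        de_b = differential_expression(cm, groups, normalization=None)
        pd.testing.assert_frame_equal(de_a.table, de_b.table)

    def test_single_sample_group_rejected(self):
        cm = _matrix(np.ones((20, 3), dtype=int) * 10)
        groups = pd.Series(["tumor", "ref", "ref"], index=cm.sample_ids)
        with pytest.raises(SignatureError, match="2 samples"):
            differential_expression(cm, groups)


class TestDeriveSignature:
    def _de(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "base_mean", "log2fc", "pvalue", "padj"])
        return DETable(df)

    def test_thresholds_are_strict(self):
        de = self._de(
            [
                ("at_lfc", 10, 1.0, 1e-9, 1e-9),  # |lfc| not > 1
                ("at_alpha", 10, 2.0, 1e-4, 0.001),  # padj not < 0.001
                ("in_sig", 10, -2.0, 1e-9, 1e-5),
            ]
        )
        sig = derive_signature(de)
        assert list(sig.table["gene_id"]) == ["in_sig"]
        assert sig.table["direction"].tolist() == ["down"]

    def test_empty_signature_allowed(self):
        de = self._de([("g", 10, 0.1, 0.9, 1.0)])
        assert len(derive_signature(de).table) == 0
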