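import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from refnorm.features import (
    AutoencoderParams,
    EmbeddingModel,
    FeatureSpaceError,
    encode,
    fit_pca_embedding,
    select_top_varying_genes,
    train_autoencoder,
)
from refnorm.io import CountMatrix


def _logm(vals, genes=None, samples=None):
    genes = genes or [f"g{i}" for i in range(vals.shape[0])]
    samples = samples or [f"s{i}" for i in range(vals.shape[1])]
    return CountMatrix(pd.DataFrame(vals, index=genes, columns=samples), unit="log2_tpm_plus1")


def _tpm_matrix(n_genes=60, n_samples=50, seed=0):
    rng = np.random.default_rng(seed)
    raw = rng.gamma(2.0, 50.0, size=(n_genes, n_samples))
    tpm = 1e6 * raw / raw.sum(axis=0)
    return CountMatrix(
        pd.DataFrame(tpm, index=[f"g{i}" for i in range(n_genes)],
                     columns=[f"s{i}" for i in range(n_samples)]),
        unit="tpm",
    )


SMALL_AE = dict(bottleneck=8, hidden=16, batch_size=16, epochs=60, learning_rate=2e-3)


class TestVaryingGenes:
    def test_k_saturates_at_gene_count(self):
        m = _logm(np.random.default_rng(0).normal(size=(5, 4)))
        model = select_top_varying_genes(m, m.sample_ids, k=100)
        assert model.dim == 5

    def test_variance_ranking(self):
        vals = np.array([[0.0, 4.0], [0.0, 2.0], [1.0, 1.0]])  # variances 8, 2, 0
        m = _logm(vals, genes=["hi", "mid", "flat"])
        model = select_top_varying_genes(m, m.sample_ids, k=2)
        assert list(model.arrays["selected"]) == ["hi", "mid"]

    def test_tie_break_is_lexicographic(self):
        vals = np.array([[0.0, 2.0], [0.0, 2.0], [0.0, 1.0]])
        m = _logm(vals, genes=["zz", "aa", "low"])
        model = select_top_varying_genes(m, m.sample_ids, k=2)
        assert list(model.arrays["selected"]) == ["aa", "zz"]

    def test_empty_cohort_rejected(self):
        m = _logm(np.zeros((3, 3)))
        with pytest.raises(FeatureSpaceError, match="cohort"):
            select_top_varying_genes(m, [])

    def test_enriched_for_true_tissue_genes(self, compendium_logtpm):
        """Top-variance genes over-represent genes with tissue shifts."""
        logm, _, meta, truth = compendium_logtpm
        k = 500
        model = select_top_varying_genes(logm, logm.sample_ids, k=k)
        tissue_genes = set(
            truth.tissue_gene_shifts.index[(truth.tissue_gene_shifts != 0).any(axis=1)]
        )
        hits = len(set(model.arrays["selected"]) & tissue_genes)
        p = hypergeom.sf(hits - 1, logm.n_genes, len(tissue_genes & set(logm.gene_ids)), k)
        assert p < 1e-6

    def test_encode_returns_selected_subvector(self):
        vals = np.arange(12, dtype=float).reshape(4, 3)
        m = _logm(vals)
        model = select_top_varying_genes(m, m.sample_ids, k=3)
        feats = encode(model, m)
        expected = m.values.loc[list(model.arrays["selected"])].T
        assert np.array_equal(feats.to_numpy(), expected.to_numpy())


class TestPCA:
    def _rank2(self, n=30, d=20, seed=1):
        rng = np.random.default_rng(seed)
        basis = rng.normal(size=(2, d))
        coords = rng.normal(size=(n, 2))
        X = coords @ basis + rng.normal(size=(1, d))  # affine offset
        return _logm(np.abs(X).T + 1.0) if False else CountMatrix(
            pd.DataFrame(X.T, index=[f"g{i}" for i in range(d)],
                         columns=[f"s{i}" for i in range(n)]),
            unit="log2_tpm_plus1",
        )

    def test_exact_low_rank_explains_everything(self):
        m = self._rank2()
        model = fit_pca_embedding(m, n_components=2)
        assert model.arrays["explained_variance_ratio"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_mean_profile_encodes_to_zero(self):
        m = self._rank2()
        model = fit_pca_embedding(m, n_components=2)
        mean_profile = CountMatrix(
            pd.DataFrame(m.values.mean(axis=1).to_frame("mean")), unit="log2_tpm_plus1"
        )
        z = encode(model, mean_profile)
        assert np.allclose(z.to_numpy(), 0.0, atol=1e-9)

    def test_reconstruction_error_decreases_with_rank(self):
        rng = np.random.default_rng(2)
        m = _logm(np.abs(rng.normal(size=(40, 35))))
        errs = []
        for k in (4, 8):
            model = fit_pca_embedding(m, n_components=k)
            z = encode(model, m).to_numpy()
            recon = z @ model.arrays["components"] + model.arrays["mean"]
            errs.append(np.mean((recon - m.values.to_numpy().T) ** 2))
        assert errs[1] <= errs[0]

    def test_low_rank_reconstruction_exact(self):
        m = self._rank2(seed=5)
        model = fit_pca_embedding(m, n_components=2)
        z = encode(model, m).to_numpy()
        recon = z @ model.arrays["components"] + model.arrays["mean"]
        assert np.allclose(recon, m.values.to_numpy().T, atol=1e-6)

    def test_too_many_components_rejected(self):
        m = self._rank2(n=10)
        with pytest.raises(FeatureSpaceError):
            fit_pca_embedding(m, n_components=10)


class TestAutoencoder:
    def test_bottleneck_width_and_loss_decreases(self):
        m = _tpm_matrix()
        model, curve = train_autoencoder(m, AutoencoderParams(**SMALL_AE, seed=1))
        feats = encode(model, m)
        assert feats.shape == (m.n_samples, SMALL_AE["bottleneck"])
        assert curve.train[-1] < curve.train[0]
        assert curve.test[-1] < 2 * curve.train[-1]

    def test_training_reproducible_for_fixed_seed(self):
        m = _tpm_matrix(seed=3)
        _, c1 = train_autoencoder(m, AutoencoderParams(**SMALL_AE, seed=9))
        _, c2 = train_autoencoder(m, AutoencoderParams(**SMALL_AE, seed=9))
        assert np.allclose(c1.train, c2.train, rtol=1e-6)
        assert np.allclose(c1.test, c2.test, rtol=1e-6)

    def test_encode_is_deterministic(self):
        m = _tpm_matrix(seed=4)
        model, _ = train_autoencoder(m, AutoencoderParams(**SMALL_AE, seed=0))
        f1 = encode(model, m).to_numpy()
        f2 = encode(model, m).to_numpy()
        assert np.array_equal(f1, f2)

    def test_serialization_round_trip(self, tmp_path):
        m = _tpm_matrix(seed=5)
        model, _ = train_autoencoder(m, AutoencoderParams(**SMALL_AE, seed=2))
        path = tmp_path / "model.npz"
        model.save(path)
        back = EmbeddingModel.load(path)
        assert np.allclose(encode(model, m), encode(back, m), rtol=1e-6)

    def test_bottleneck_wider_than_input_rejected(self):
        m = _tpm_matrix(n_genes=5)
        with pytest.raises(FeatureSpaceError, match="bottleneck"):
            train_autoencoder(m, AutoencoderParams(bottleneck=10, hidden=4, epochs=1))

    def test_wrong_unit_rejected(self):
        m = _logm(np.ones((10, 10)))
        with pytest.raises(FeatureSpaceError, match="tpm"):
            train_autoencoder(m, AutoencoderParams(**SMALL_AE))


class TestBatchMixing:
    def test_encoded_space_mixes_studies_and_separates_sites(self, compendium_logtpm):
        """Study labels are less separable in bottleneck space than in gene
        space, while tissue sites stay far more separable than studies."""
        from sklearn.metrics import silhouette_score

        from refnorm.benchmarks import AE_INPUT_K, SMALL_AE_PARAMS

        logm, tpm, meta, _ = compendium_logtpm
        normals = list(meta.of_type("reference_normal")["sample_id"])
        site = meta.table.set_index("sample_id")["site"].reindex(normals).to_numpy()
        study = meta.table.set_index("sample_id")["study"].reindex(normals).to_numpy()
        hv = select_top_varying_genes(logm, normals, k=AE_INPUT_K)
        ae, _ = train_autoencoder(
            CountMatrix(tpm.values.loc[list(hv.arrays["selected"]), normals], unit="tpm"),
            AutoencoderParams(**SMALL_AE_PARAMS, seed=0),
            site_labels=site,
        )
        vg = select_top_varying_genes(logm, normals, k=1000)
        f_ae = encode(ae, tpm.subset_samples(normals)).to_numpy()
        f_vg = encode(vg, logm.subset_samples(normals)).to_numpy()
        assert silhouette_score(f_ae, study) < silhouette_score(f_vg, study)
        assert silhouette_score(f_ae, site) > silhouette_score(f_ae, study)


class TestEncodeContracts:
    def test_missing_genes_listed(self):
        m = _tpm_matrix(n_genes=20)
        model, _ = train_autoencoder(
            m, AutoencoderParams(bottleneck=4, hidden=8, batch_size=16, epochs=5, seed=0)
        )
        smaller = CountMatrix(m.values.iloc[:10, :], unit="tpm")
        with pytest.raises(FeatureSpaceError, match="g1"):
            encode(model, smaller)

    def test_varying_genes_unit_mismatch_rejected(self):
        m = _logm(np.random.default_rng(0).normal(size=(6, 5)))
        model = select_top_varying_genes(m, m.sample_ids, k=3)
        tpm_like = CountMatrix(np.abs(m.values), unit="tpm")
        with pytest.raises(FeatureSpaceError, match="log2_tpm_plus1"):
            encode(model, tpm_like)
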