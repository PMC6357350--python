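import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from refnorm.io import SampleTable
from refnorm.selection import (
    CorrelationTable,
    SelectionError,
    call_tissue_of_origin,
    correlate_candidates,
    rank_sites,
    select_reference,
)


def _feats(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])])


def _meta_for(candidates, sites):
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": candidates,
                "study": "st",
                "site": sites,
                "sample_type": "reference_normal",
            }
        )
    )


def _ct(sample_ids, sites, corrs, feature_space="varying_genes"):
    return CorrelationTable(
        table=pd.DataFrame({"sample_id": sample_ids, "site": sites, "correlation": corrs}),
        feature_space=feature_space,
        correlation_kind="spearman",
    )


class TestCorrelateCandidates:
    def test_identical_profiles_correlate_perfectly(self):
        tumor = _feats([[1.0, 2.0, 3.0, 4.0]], prefix="t")
        cand = _feats([[1.0, 2.0, 3.0, 4.0]], prefix="c")
        ct = correlate_candidates(tumor, cand, kind="pearson", standardize=False)
        assert ct.table["correlation"].iloc[0] == pytest.approx(1.0)

    def test_decreasing_transform_gives_rank_reversal(self):
        tumor = _feats([[1.0, 2.0, 3.0, 4.0]], prefix="t")
        cand = _feats([[-1.0, -8.0, -27.0, -64.0]], prefix="c")  # -x^3
        ct = correlate_candidates(tumor, cand, kind="spearman", standardize=False)
        assert ct.table["correlation"].iloc[0] == pytest.approx(-1.0)

    def test_matches_naive_pairwise_loop(self):
        rng = np.random.default_rng(0)
        tumors = _feats(rng.normal(size=(5, 7)), prefix="t")
        cands = _feats(rng.normal(size=(5, 7)), prefix="c")
        for kind, func in [("pearson", pearsonr), ("spearman", spearmanr)]:
            ct = correlate_candidates(tumors, cands, kind=kind, standardize=False)
            for i, cid in enumerate(cands.index):
                expected = np.mean(
                    [func(cands.loc[cid], tumors.iloc[j]).statistic for j in range(5)]
                )
                got = ct.table.set_index("sample_id").loc[cid, "correlation"]
                assert got == pytest.approx(expected, abs=1e-12)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        tumors = _feats(rng.uniform(1, 5, size=(3, 10)), prefix="t")
        cands = _feats(rng.uniform(1, 5, size=(4, 10)), prefix="c")
        base = correlate_candidates(tumors, cands, kind="spearman", standardize=False)
        warped = correlate_candidates(
            tumors, np.exp(cands) + cands**3, kind="spearman", standardize=False
        )
        assert np.array_equal(
            base.table["correlation"].to_numpy(), warped.table["correlation"].to_numpy()
        )

    def test_zero_variance_candidate_excluded_with_warning(self, caplog):
        tumors = _feats([[1.0, 2.0, 3.0, 4.0]], prefix="t")
        cands = _feats([[5.0, 5.0, 5.0, 5.0]], prefix="c")
        with caplog.at_level("WARNING"):
            ct = correlate_candidates(tumors, cands, kind="pearson", standardize=False)
        assert np.isnan(ct.table["correlation"].iloc[0])
        assert "zero-variance" in caplog.text

    def test_too_few_features_rejected(self):
        with pytest.raises(SelectionError, match="3 features"):
            correlate_candidates(_feats([[1, 2]]), _feats([[1, 2]]), kind="pearson")


class TestRankSites:
    def test_single_site_normalized_to_one(self):
        ct = _ct(["a", "b"], ["liver", "liver"], [0.8, 0.6])
        r = rank_sites(ct)
        assert r.top_site == "liver"
        assert r.table["normalized"].iloc[0] == pytest.approx(1.0)

    def test_forced_two_site_arithmetic(self):
        ct = _ct(["a", "b", "c", "d"], ["A", "A", "B", "B"], [0.9, 0.9, 0.5, 0.5])
        r = rank_sites(ct)
        assert list(r.table["site"]) == ["A", "B"]
        assert r.table["normalized"].tolist() == pytest.approx([1.0, 0.5 / 0.9])

    def test_tie_breaks_lexicographically(self):
        ct = _ct(["a", "b"], ["zeta", "alpha"], [0.7, 0.7])
        r = rank_sites(ct)
        assert list(r.table["site"]) == ["alpha", "zeta"]

    def test_true_origin_ranks_first_on_synthetic_data(self, compendium_logtpm):
        from refnorm.features import encode, select_top_varying_genes

        logm, _, meta, truth = compendium_logtpm
        tumors = list(meta.of_type("tumor")["sample_id"])
        cands = list(meta.of_type("reference_normal")["sample_id"])
        model = select_top_varying_genes(logm, tumors, k=1000)
        ct = correlate_candidates(
            encode(model, logm.subset_samples(tumors)),
            encode(model, logm.subset_samples(cands)),
            kind="spearman",
            meta=meta,
        )
        r = rank_sites(ct, meta)
        assert r.top_site in ("liver", "liver_proximal")


class TestSelectReference:
    def _nine_candidate_ct(self):
        # nine bladder candidates, two clearly below the 25th percentile
        corrs = [0.92, 0.91, 0.93, 0.90, 0.94, 0.92, 0.91, 0.50, 0.40]
        ids = [f"b{i}" for i in range(9)]
        return _ct(ids, ["bladder"] * 9, corrs), _meta_for(ids, ["bladder"] * 9)

    def test_top_site_takes_all_site_members(self):
        ct, meta = self._nine_candidate_ct()
        ref = select_reference(ct, meta, "top_site")
        assert len(ref.sample_ids) == 9
        assert ref.site == "bladder"

    def test_percentile_filter_leaves_seven_of_nine(self):
        ct, meta = self._nine_candidate_ct()
        ref = select_reference(ct, meta, "pct25_within_site")
        assert len(ref.sample_ids) == 7
        assert set(ref.sample_ids) == {f"b{i}" for i in range(7)}

    def test_top50_saturates_on_small_pool(self):
        ids = [f"c{i}" for i in range(30)]
        ct = _ct(ids, ["x"] * 30, np.linspace(0, 1, 30))
        ref = select_reference(ct, _meta_for(ids, ["x"] * 30), "top50_any_site", n=50)
        assert len(ref.sample_ids) == 30
        assert ref.site == "NA"

    def test_top50_takes_highest_cross_site(self):
        ids = [f"c{i}" for i in range(10)]
        sites = ["A"] * 5 + ["B"] * 5
        corrs = [0.1, 0.2, 0.3, 0.9, 0.8, 0.95, 0.4, 0.5, 0.6, 0.7]
        ref = select_reference(_ct(ids, sites, corrs), _meta_for(ids, sites), "top50_any_site", n=3)
        got = set(ref.sample_ids)
        assert got == {"c3", "c4", "c5"}

    def test_random50_seeded_and_seed_sensitive(self):
        ids = [f"c{i}" for i in range(100)]
        ct = _ct(ids, ["x"] * 100, np.linspace(0, 1, 100))
        meta = _meta_for(ids, ["x"] * 100)
        r1 = select_reference(ct, meta, "random50", seed=1)
        r2 = select_reference(ct, meta, "random50", seed=1)
        r3 = select_reference(ct, meta, "random50", seed=2)
        assert r1.sample_ids == r2.sample_ids
        assert r1.sample_ids != r3.sample_ids
        assert len(r1.sample_ids) == 50

    def test_random_requires_seed(self):
        ct, meta = self._nine_candidate_ct()
        with pytest.raises(SelectionError, match="seed"):
            select_reference(ct, meta, "random50", seed=None)

    def test_manual_site_must_exist(self):
        ct, meta = self._nine_candidate_ct()
        with pytest.raises(SelectionError, match="bladder"):
            select_reference(ct, meta, "manual", manual_site="pancreas")

    def test_manual_selects_requested_site(self):
        ids = ["a1", "a2", "b1"]
        sites = ["lung", "lung", "liver"]
        ref = select_reference(
            _ct(ids, sites, [0.1, 0.2, 0.9]), _meta_for(ids, sites), "manual", manual_site="lung"
        )
        assert ref.sample_ids == ["a1", "a2"]


class TestTissueOfOriginCall:
    EXPECTED = {"kidney_papillary": {"primary": ["kidney"], "proximal": ["kidney_cortex"]}}

    def _ranking_with_top(self, top):
        ct = _ct(["a", "b"], [top, "other"], [0.9, 0.1])
        return rank_sites(ct)

    @pytest.mark.parametrize(
        "top,verdict",
        [
            ("kidney", "correct"),
            ("kidney_cortex", "proximal_correct"),
            ("bladder", "incorrect"),
        ],
    )
    def test_verdicts(self, top, verdict):
        got, top_site = call_tissue_of_origin(
            self._ranking_with_top(top), self.EXPECTED, "kidney_papillary"
        )
        assert got == verdict
        assert top_site == top

    def test_unknown_cancer_rejected(self):
        with pytest.raises(SelectionError, match="absent"):
            call_tissue_of_origin(self._ranking_with_top("kidney"), self.EXPECTED, "mystery")
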