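import numpy as np
import pytest
from scipy import stats

from xcmap import (
    default_design,
    derive_signature,
    generate_cohort,
    pool_signature,
    remove_genes,
    tissue_specific_genes,
)
from xcmap.io import ExpressionMatrix, GeneSet
from xcmap.signatures import differential_result, signal_to_noise, welch_t_by_gene


@pytest.fixture(scope="module")
def filtered_human(default_cohort):
    matrices, _, truth = default_cohort
    h = matrices["human"]
    ts = tissue_specific_genes(h, "blood", "skin")
    return remove_genes(h, ts), ts, truth


class TestWelch:
    def test_vectorized_welch_matches_per_gene_loop(self, default_cohort):
        matrices, _, _ = default_cohort
        h = matrices["human"]
        anno = h.annotations
        in_sub = anno["subset"] == "CD1c_DC"
        a = h.values.loc[:, (in_sub & (anno["tissue"] == "blood")).to_numpy()].to_numpy()
        b = h.values.loc[:, (in_sub & (anno["tissue"] == "skin")).to_numpy()].to_numpy()
        t_vec, p_vec = welch_t_by_gene(a, b)
        for i in range(0, h.n_genes, 97):
            t_i, p_i = stats.ttest_ind(a[i], b[i], equal_var=False)
            assert t_vec[i] == pytest.approx(t_i)
            assert p_vec[i] == pytest.approx(p_i)


class TestTissueFilter:
    def test_recovers_planted_tissue_genes(self, filtered_human, default_cohort):
        matrices, _, truth = default_cohort
        _, ts, _ = filtered_human
        planted = set(truth.tissue_genes["human"]["blood"]) | set(
            truth.tissue_genes["human"]["skin"]
        )
        recovery = len(set(ts.genes) & planted) / len(planted)
        assert recovery >= 0.95

    def test_no_signal_cohort_yields_few_false_positives(self, no_signal_cohort):
        matrices, _, _ = no_signal_cohort
        h = matrices["human"]
        ts = tissue_specific_genes(h, "blood", "skin")
        assert len(ts) <= 0.05 * h.n_genes

    def test_per_subset_union_method_also_supported(self, default_cohort):
        matrices, _, truth = default_cohort
        h = matrices["human"]
        ts = tissue_specific_genes(h, "blood", "skin", method="per_subset_union")
        planted = set(truth.tissue_genes["human"]["blood"]) | set(
            truth.tissue_genes["human"]["skin"]
        )
        # low power by construction, but what it flags should be real
        assert len(ts) > 0
        assert len(set(ts.genes) & planted) / max(len(ts), 1) > 0.5

    def test_missing_tissue_or_unmatched_subsets_error(self, default_cohort):
        matrices, _, _ = default_cohort
        h = matrices["human"]
        with pytest.raises(ValueError, match="tissue"):
            tissue_specific_genes(h, "blood", "liver")
        blood_only = h.select_samples((h.annotations["tissue"] == "blood").to_numpy())
        with pytest.raises(ValueError):
            tissue_specific_genes(blood_only, "blood", "skin")


class TestRemoveGenes:
    def test_removing_empty_set_is_identity(self, default_cohort):
        matrices, _, _ = default_cohort
        h = matrices["human"]
        out = remove_genes(h, GeneSet("none", ()))
        assert out.values.equals(h.values)

    def test_removal_is_idempotent(self, default_cohort):
        matrices, _, truth = default_cohort
        h = matrices["human"]
        s = GeneSet("t", truth.tissue_genes["human"]["blood"])
        once = remove_genes(h, s)
        twice = remove_genes(once, s)
        assert once.values.equals(twice.values)

    def test_removing_planted_tissue_genes_eliminates_tissue_signal(self, default_cohort):
        matrices, _, truth = default_cohort
        h = matrices["human"]
        planted = tuple(
            g for t in truth.tissue_genes["human"].values() for g in t
        )
        cleaned = remove_genes(h, GeneSet("planted", planted))
        residual = tissue_specific_genes(cleaned, "blood", "skin")
        assert len(residual) <= 0.05 * cleaned.n_genes

    def test_removing_everything_is_an_error(self, default_cohort):
        matrices, _, _ = default_cohort
        h = matrices["human"]
        with pytest.raises(ValueError, match="empty"):
            remove_genes(h, GeneSet("all", tuple(h.gene_ids)))


class TestDeriveSignature:
    def test_up_set_recovers_planted_markers(self, filtered_human):
        filt, _, truth = filtered_human
        sig = derive_signature(filt, "CD141_DC", size=150)
        markers = set(truth.marker_genes["cd141_like"]["human"]) & set(filt.gene_ids)
        assert len(set(sig.up) & markers) / len(markers) >= 0.90

    def test_snr_matches_direct_formula_loop(self, filtered_human):
        filt, _, _ = filtered_human
        mask = (filt.annotations["subset"] == "CD1c_DC").to_numpy()
        res = differential_result(filt, mask)
        tv = filt.values.loc[:, mask].to_numpy()
        rv = filt.values.loc[:, ~mask].to_numpy()
        for i in range(0, filt.n_genes, 131):
            mt, mr = tv[i].mean(), rv[i].mean()
            st = max(tv[i].std(), 0.2 * abs(mt), 0.2)
            sr = max(rv[i].std(), 0.2 * abs(mr), 0.2)
            expected = (mt - mr) / (st + sr)
            assert res.statistic.iloc[i] == pytest.approx(expected)

    def test_null_statistic_distribution_is_symmetric(self, no_signal_cohort):
        matrices, _, _ = no_signal_cohort
        h = matrices["human"]
        mask = (h.annotations["subset"] == "CD141_DC").to_numpy()
        snr = differential_result(h, mask).statistic.to_numpy()
        assert abs(np.median(snr)) < 0.02
        assert 0.4 < (snr > 0).mean() < 0.6

    def test_invariant_to_sample_column_order(self, filtered_human):
        filt, _, _ = filtered_human
        sig = derive_signature(filt, "pDC", size=50)
        rng = np.random.default_rng(3)
        perm = rng.permutation(filt.n_samples)
        cols = [filt.sample_ids[i] for i in perm]
        shuffled = ExpressionMatrix(filt.values[cols].copy(), filt.annotations.loc[cols].copy())
        assert derive_signature(shuffled, "pDC", size=50) == sig

    def test_stable_under_global_intensity_shift(self, filtered_human):
        """A constant added to every value leaves the SNR numerator unchanged;
        only the |mean|-dependent variance floor moves, so tag lists are
        nearly (not exactly) preserved."""
        filt, _, _ = filtered_human
        sig = derive_signature(filt, "pDC", size=50)
        shifted = ExpressionMatrix(filt.values + 1.5, filt.annotations.copy())
        sig2 = derive_signature(shifted, "pDC", size=50)
        assert len(set(sig.up) & set(sig2.up)) / 50 >= 0.85
        assert len(set(sig.down) & set(sig2.down)) / 50 >= 0.85

    def test_too_few_genes_is_an_error(self, filtered_human):
        filt, _, _ = filtered_human
        with pytest.raises(ValueError, match="genes"):
            derive_signature(filt, "pDC", size=filt.n_genes)

    def test_tissue_gene_removal_purifies_marker_content(self, default_cohort):
        """Filtering tissue genes increases planted-marker share of up-sets."""
        matrices, _, truth = default_cohort
        h = matrices["human"]
        design = default_design(seed=1, tissue_effect=3.0)
        mats, _, tr = generate_cohort(design)
        hh = mats["human"]
        filt = remove_genes(hh, tissue_specific_genes(hh, "blood", "skin"))
        markers = set(tr.marker_genes["cd141_like"]["human"])
        before = derive_signature(hh, "CD141_DC", 150, target_tissue="skin")
        after = derive_signature(filt, "CD141_DC", 150, target_tissue="skin")
        frac_before = len(set(before.up) & markers) / 150
        frac_after = len(set(after.up) & markers) / 150
        assert frac_after >= frac_before


class TestPoolSignature:
    def test_degenerate_self_pooling_preserves_ranking(self, filtered_human):
        filt, _, _ = filtered_human
        single = derive_signature(filt, "CD1c_DC", size=100)
        doubled = pool_signature([filt, filt], ["CD1c_DC", "CD1c_DC"], size=100)
        assert doubled.up == single.up
        assert doubled.down == single.down

    def test_pooled_lineage_signature_tracks_its_lineage(self, filtered_human):
        filt, _, truth = filtered_human
        cd141 = pool_signature([filt], ["CD141_DC"], size=150)
        single = derive_signature(filt, "CD141_DC", 150, target_tissue="skin")
        other = derive_signature(filt, "CD1c_DC", 150, target_tissue="skin")

        def jaccard(a, b):
            a, b = set(a), set(b)
            return len(a & b) / len(a | b)

        assert jaccard(cd141.up, single.up) > jaccard(cd141.up, other.up)

    def test_up_and_down_disjoint(self, filtered_human):
        filt, _, _ = filtered_human
        sig = pool_signature([filt], ["CD14_DC"], size=200)
        assert not (set(sig.up) & set(sig.down))

    def test_gene_space_mismatch_reports_symmetric_difference(self, filtered_human, default_cohort):
        filt, _, _ = filtered_human
        matrices, _, _ = default_cohort
        with pytest.raises(ValueError, match="symmetric difference"):
            pool_signature([filt, matrices["mouse"]], ["CD141_DC", "CD103_DC"])
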