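import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xcmap import (
    connectivity_score,
    directional_score,
    enrichment_table,
    ks_statistic,
    permutation_test,
    rank_profile,
    remove_genes,
    scale_scores,
    tissue_specific_genes,
)
from xcmap.enrichment import RankedList, _ks_from_positions_batch
from xcmap.signatures import GeneSignature, derive_signature

from conftest import make_matrix


def ks_running_sum_oracle(positions, n):
    """Independent enumeration: walk every rank position tracking the
    deviation between the tag set's empirical CDF and the uniform CDF."""
    hits = set(positions)
    t = len(hits)
    count = 0
    a = -np.inf  # max over hit positions of CDF excess at the position
    b = -np.inf  # max over hit positions of CDF deficit just before it
    for i in range(1, n + 1):
        if i in hits:
            b = max(b, i / n - count / t)
            count += 1
            a = max(a, count / t - i / n)
    return a if a > b else -b


def universe(n):
    return RankedList("ref", tuple(f"g{i:03d}" for i in range(n)))


def tag(r, positions):
    return [r.genes[p - 1] for p in positions]


class TestKsStatistic:
    def test_worked_top_pair(self):
        r = universe(10)
        assert ks_statistic(tag(r, [1, 2]), r) == pytest.approx(0.8)

    def test_worked_bottom_pair(self):
        r = universe(10)
        assert ks_statistic(tag(r, [9, 10]), r) == pytest.approx(-0.9)

    def test_contiguous_top_block_attains_one_minus_t_over_n(self):
        r = universe(10)
        assert ks_statistic(tag(r, [1, 2, 3, 4, 5]), r) == pytest.approx(1 - 5 / 10)

    @pytest.mark.parametrize("n", range(2, 10))
    def test_matches_enumeration_oracle_exhaustively(self, n):
        r = universe(n)
        for t in range(1, n):
            for positions in itertools.combinations(range(1, n + 1), t):
                expected = ks_running_sum_oracle(positions, n)
                assert ks_statistic(tag(r, positions), r) == pytest.approx(expected)

    def test_batch_and_scalar_paths_agree(self):
        rng = np.random.default_rng(0)
        n, t, B = 40, 7, 50
        pos = np.sort(
            np.array([rng.choice(np.arange(1, n + 1), t, replace=False) for _ in range(B)]),
            axis=1,
        )
        batch = _ks_from_positions_batch(pos, n)
        r = universe(n)
        for row, expected in zip(pos, batch):
            assert ks_statistic(tag(r, row), r) == pytest.approx(expected)

    def test_moving_tags_from_top_to_bottom_flips_sign(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            t = int(rng.integers(1, max(2, n // 4)))
            top = list(range(1, t + 1))
            bottom = list(range(n - t + 1, n + 1))
            r = universe(n)
            assert ks_statistic(tag(r, top), r) > 0
            assert ks_statistic(tag(r, bottom), r) < 0

    def test_missing_gene_error_names_it(self):
        r = universe(5)
        with pytest.raises(KeyError, match="absent"):
            ks_statistic(["absent"], r)

    def test_empty_and_full_sets_rejected(self):
        r = universe(5)
        with pytest.raises(ValueError):
            ks_statistic([], r)
        with pytest.raises(ValueError):
            ks_statistic(list(r.genes), r)


class TestRankProfile:
    def test_sorts_descending(self):
        m = make_matrix({"s1": [5.0, 1.0, 9.0]}, ["g_5", "g_1", "g_9"])
        assert rank_profile(m, "s1").genes == ("g_9", "g_5", "g_1")

    def test_all_equal_values_fall_back_to_lexicographic(self):
        m = make_matrix({"s1": [1.0, 1.0, 1.0]}, ["b", "c", "a"])
        assert rank_profile(m, "s1").genes == ("a", "b", "c")

    def test_reversed_values_reverse_the_ranking(self):
        m = make_matrix({"s1": [3.0, 1.0, 2.0], "s2": [-3.0, -1.0, -2.0]}, ["x", "y", "z"])
        fwd = rank_profile(m, "s1").genes
        rev = rank_profile(m, "s2").genes
        assert rev == tuple(reversed(fwd))


class TestConnectivityScore:
    @staticmethod
    def random_signature(rng, r, t_up, t_down):
        pick = rng.permutation(r.n)[: t_up + t_down] + 1
        return GeneSignature(
            name="q", up=tuple(tag(r, pick[:t_up])), down=tuple(tag(r, pick[t_up:]))
        )

    def test_antisymmetric_under_up_down_swap(self):
        rng = np.random.default_rng(2)
        r = universe(50)
        for _ in range(100):
            sig = self.random_signature(rng, r, 5, 7)
            swapped = GeneSignature(name="q", up=sig.down, down=sig.up)
            assert connectivity_score(swapped, r) == pytest.approx(-connectivity_score(sig, r))

    def test_same_sign_ks_pair_scores_zero(self):
        r = universe(20)
        # both tag sets in the top block: both KS statistics positive
        sig = GeneSignature(name="q", up=tuple(tag(r, [1, 2])), down=tuple(tag(r, [3, 4])))
        assert ks_statistic(sig.up, r) > 0 and ks_statistic(sig.down, r) > 0
        assert connectivity_score(sig, r) == 0.0

    def test_separated_signature_is_maximal_and_positive(self):
        r = universe(30)
        sig = GeneSignature(
            name="q", up=tuple(tag(r, [1, 2, 3])), down=tuple(tag(r, [28, 29, 30]))
        )
        score = connectivity_score(sig, r)
        assert score > 0
        rng = np.random.default_rng(3)
        others = [
            connectivity_score(self.random_signature(rng, r, 3, 3), r) for _ in range(200)
        ]
        assert score >= max(others)


class TestScaleScores:
    def test_definition(self):
        assert np.allclose(scale_scores([2.0, 1.0, -0.5]), [1.0, 0.5, -1.0])

    def test_all_zeros_unchanged(self):
        assert np.allclose(scale_scores([0.0, 0.0]), [0.0, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=30))
    def test_idempotent_sign_and_order_preserving(self, raw):
        once = scale_scores(raw)
        assert np.all(np.abs(once) <= 1.0 + 1e-12)
        assert np.allclose(scale_scores(once), once)
        assert np.array_equal(np.sign(once), np.sign(raw))
        order = np.argsort(raw, kind="stable")
        assert np.all(np.diff(once[order]) >= -1e-12)


class TestPermutationTest:
    def test_p_within_bounds_and_deterministic(self):
        rng = np.random.default_rng(4)
        r = universe(100)
        sig = TestConnectivityScore.random_signature(rng, r, 10, 10)
        p1 = permutation_test(sig, r, B=200, seed=7)
        p2 = permutation_test(sig, r, B=200, seed=7)
        assert p1 == p2
        assert 1 / 201 <= p1 <= 1.0

    def test_extreme_signature_attains_minimum_p(self):
        r = universe(200)
        sig = GeneSignature(
            name="q",
            up=tuple(tag(r, range(1, 21))),
            down=tuple(tag(r, range(181, 201))),
        )
        assert permutation_test(sig, r, B=1000, seed=0) == pytest.approx(1 / 1001)

    def test_oversized_tag_lists_rejected(self):
        from xcmap.enrichment import _null_directional_scores

        with pytest.raises(ValueError, match="universe"):
            _null_directional_scores(10, 6, 5, B=10, rng=np.random.default_rng(0))


@pytest.fixture(scope="module")
def filtered(default_cohort):
    matrices, _, truth = default_cohort
    h = matrices["human"]
    filt = remove_genes(h, tissue_specific_genes(h, "blood", "skin"))
    return filt, truth


class TestEnrichmentTable:
    def test_query_subset_scores_highest_on_itself(self, filtered):
        filt, _ = filtered
        sig = derive_signature(filt, "CD141_DC", 150, target_tissue="skin")
        results = enrichment_table(sig, filt, B=0)
        best = max(results, key=lambda r: r.mean_scaled)
        assert best.reference_subset == "CD141_DC"

    def test_monocyte_references_score_negative_against_cd141_query(self, filtered):
        filt, _ = filtered
        sig = derive_signature(filt, "CD141_DC", 150, target_tissue="skin")
        results = {r.reference_subset: r for r in enrichment_table(sig, filt, B=0)}
        assert results["CD14_DC"].mean_scaled < 0
        assert results["CD16_monocyte"].mean_scaled < 0

    def test_per_sample_and_subset_mean_modes_agree_in_rank_order(self, filtered):
        filt, _ = filtered
        sig = derive_signature(filt, "CD1c_DC", 150)
        by_sample = enrichment_table(sig, filt, per_sample=True, B=0)
        by_mean = enrichment_table(sig, filt, per_sample=False, B=0)
        order_a = [r.reference_subset for r in sorted(by_sample, key=lambda r: -r.mean_scaled)]
        order_b = [r.reference_subset for r in sorted(by_mean, key=lambda r: -r.mean_scaled)]
        assert order_a == order_b

    def test_signature_outside_universe_errors(self, filtered):
        filt, _ = filtered
        sig = GeneSignature(name="alien", up=("x1", "x2"), down=("x3", "x4"))
        with pytest.raises(ValueError, match="intersection"):
            enrichment_table(sig, filt, B=0)

    def test_majority_gene_loss_errors(self, filtered):
        filt, truth = filtered
        genes = filt.gene_ids
        # up list mostly absent from the universe
        up = tuple(f"missing{i}" for i in range(30)) + tuple(genes[:10])
        sig = GeneSignature(name="sparse", up=up, down=tuple(genes[50:90]))
        with pytest.raises(ValueError, match="half"):
            enrichment_table(sig, filt, B=0)
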