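import dataclasses
from itertools import combinations

import numpy as np
import pytest

from cernet.errors import DomainError
from cernet.gsea import RankedList, enrichment_score, gsea_test, signal_to_noise, _es_from_hits
from cernet.io_formats import GeneSetCollection
from conftest import toy_matrix


def brute_force_es(scores, hits, weight):
    """Independent oracle: evaluate the running sum at every position."""
    n = len(scores)
    n_hits = sum(hits)
    denom = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    running, max_pos, min_neg = 0.0, 0.0, 0.0
    for s, h in zip(scores, hits):
        if h:
            running += (abs(s) ** weight) / denom if denom else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        max_pos = max(max_pos, running)
        min_neg = min(min_neg, running)
    # same deterministic tie-break as the implementation: positive side wins
    return max_pos if max_pos >= -min_neg - 1e-9 else min_neg


class TestSignalToNoise:
    def test_equal_group_means_score_zero(self):
        # columns all sum to 100 so CPM leaves g0 flat across samples
        m = toy_matrix([[10, 10, 10, 10], [40, 60, 30, 70], [50, 30, 60, 20]])
        ranked = signal_to_noise(m)
        assert dict(zip(ranked.gene_ids, ranked.scores))["g0"] == pytest.approx(0.0)

    def test_group_swap_negates_scores(self, default_sim):
        m = default_sim["mrna"]
        swapped = dataclasses.replace(
            m,
            group_of={s: ("treated" if g == "control" else "control") for s, g in m.group_of.items()},
        )
        a = signal_to_noise(m)
        b = signal_to_noise(swapped)
        sa = dict(zip(a.gene_ids, a.scores))
        sb = dict(zip(b.gene_ids, b.scores))
        for gid in sa:
            assert sb[gid] == pytest.approx(-sa[gid], abs=1e-12)

    def test_matches_hand_arithmetic(self):
        # counts chosen so every column sums to 100 => cpm = count * 1e4
        counts = np.array(
            [
                [10, 20, 30, 40],
                [30, 20, 30, 20],
                [20, 20, 10, 10],
                [15, 25, 10, 20],
                [25, 15, 20, 10],
            ]
        )
        m = toy_matrix(counts)
        ranked = signal_to_noise(m)
        log = np.log2(counts * 1e4 + 0.5)
        by_id = dict(zip(ranked.gene_ids, ranked.scores))
        for i in range(5):
            mu_c, mu_t = log[i, :2].mean(), log[i, 2:].mean()
            sd_c = max(np.std(log[i, :2], ddof=1), 0.2 * abs(mu_c), 0.2)
            sd_t = max(np.std(log[i, 2:], ddof=1), 0.2 * abs(mu_t), 0.2)
            assert by_id[f"g{i}"] == pytest.approx((mu_t - mu_c) / (sd_t + sd_c))

    def test_single_sample_group_rejected(self):
        from cernet.io_formats import CountMatrix, FormatError

        with pytest.raises(Exception):
            CountMatrix(
                feature_ids=["g0"],
                rna_class="mRNA",
                sample_ids=["a", "b", "c"],
                group_of={"a": "control", "b": "control", "c": "treated"},
                counts=np.array([[1, 2, 3]]),
            )


class TestEnrichmentScore:
    def test_top_gene_singleton_weight_zero_is_one(self):
        ranked = RankedList([f"g{i}" for i in range(10)], np.linspace(5, -5, 10))
        es, running, leading = enrichment_score(ranked, {"g0"}, weight=0.0)
        assert es == pytest.approx(1.0)
        assert leading == ["g0"]

    def test_degenerate_sets_rejected(self):
        ranked = RankedList(["a", "b", "c"], np.array([2.0, 1.0, -1.0]))
        with pytest.raises(DomainError):
            enrichment_score(ranked, set())
        with pytest.raises(DomainError):
            enrichment_score(ranked, {"a", "b", "c"})

    def test_matches_brute_force_on_ten_gene_list(self):
        rng = np.random.default_rng(1)
        scores = np.sort(rng.normal(size=10))[::-1]
        ranked = RankedList([f"g{i}" for i in range(10)], scores)
        members = {"g1", "g4", "g7"}
        es, _, _ = enrichment_score(ranked, members, weight=1.0)
        hits = [g in members for g in ranked.gene_ids]
        assert es == pytest.approx(brute_force_es(scores, hits, 1.0))

    @pytest.mark.parametrize("n", range(3, 13))
    def test_oracle_grid_all_subset_sizes(self, n):
        """ES equals the exhaustive running sum for every subset of every size."""
        rng = np.random.default_rng(n)
        scores = np.sort(rng.normal(scale=2, size=n))[::-1]
        ids = [f"g{i}" for i in range(n)]
        ranked = RankedList(ids, scores)
        for k in range(1, n):
            for subset in combinations(range(n), k):
                members = {ids[i] for i in subset}
                hits = [g in members for g in ids]
                expected = brute_force_es(scores, hits, 1.0)
                es, _, _ = enrichment_score(ranked, members, 1.0)
                assert es == pytest.approx(expected, abs=1e-12)
                # the hit-compressed evaluator used inside permutations agrees
                fast = _es_from_hits(scores, np.array(subset), 1.0)
                assert fast == pytest.approx(expected, abs=1e-12)

    def test_reversal_mirrors_extremum_and_negates_es(self):
        # reversing a sign-symmetric ranked list negates the ES and mirrors
        # the extremum position (run_rev[j] = -run_fwd[n-2-j])
        scores = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        ids = [f"g{i}" for i in range(6)]
        es_fwd, run_fwd, _ = enrichment_score(RankedList(ids, scores), {"g0", "g1"})
        es_rev, run_rev, _ = enrichment_score(
            RankedList(ids[::-1], -scores[::-1]), {"g0", "g1"}
        )
        assert es_rev == pytest.approx(-es_fwd)
        n = len(ids)
        assert int(np.argmax(np.abs(run_rev))) == n - 2 - int(np.argmax(np.abs(run_fwd)))


class TestGseaTest:
    def _matrix_and_sets(self, default_sim):
        truth = default_sim["truth"]
        up = [f for f, s in truth.de_features["mRNA"] if s > 0][:12]
        sets = GeneSetCollection(sets=[("UPSET", "planted up", up)])
        return default_sim["mrna"], sets

    def test_planted_up_set_significant(self, default_sim):
        matrix, sets = self._matrix_and_sets(default_sim)
        res = gsea_test(matrix, sets, n_perm=200, rng_seed=5)
        row = res.iloc[0]
        assert row["es"] > 0 and row["nes"] > 1
        assert bool(row["significant"])

    def test_nominal_p_respects_add_one_floor(self, default_sim):
        matrix, sets = self._matrix_and_sets(default_sim)
        res = gsea_test(matrix, sets, n_perm=100, rng_seed=5)
        assert res.iloc[0]["nominal_p"] >= 1 / 101 - 1e-12
        assert res.iloc[0]["nominal_p"] < 0.05  # the planted set is extreme

    def test_deterministic_under_seed(self, default_sim):
        matrix, sets = self._matrix_and_sets(default_sim)
        a = gsea_test(matrix, sets, n_perm=100, rng_seed=9)
        b = gsea_test(matrix, sets, n_perm=100, rng_seed=9)
        assert a.equals(b)

    def test_random_sets_rarely_significant(self, default_sim):
        rng = np.random.default_rng(2)
        ids = default_sim["mrna"].feature_ids
        sets = GeneSetCollection(
            sets=[
                (f"R{j}", "rand", list(rng.choice(ids, size=20, replace=False)))
                for j in range(100)
            ]
        )
        res = gsea_test(default_sim["mrna"], sets, n_perm=200, rng_seed=3)
        assert res["significant"].mean() <= 0.05

    def test_small_n_perm_rejected(self, default_sim):
        matrix, sets = self._matrix_and_sets(default_sim)
        with pytest.raises(DomainError, match="n_perm"):
            gsea_test(matrix, sets, n_perm=50)

    def test_phenotype_mode_needs_enough_relabelings(self):
        m = toy_matrix(np.arange(20).reshape(5, 4) + 1)
        sets = GeneSetCollection(sets=[("T", "t", ["g0", "g1"])])
        with pytest.raises(DomainError, match="gene_set"):
            gsea_test(m, sets, n_perm=100, perm_mode="phenotype")
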