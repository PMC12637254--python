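"""Validation statistics: similarity score, clustering, outliers, bins, V3-V4."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amp2bgc import align, evaluate
from amp2bgc.atlas import atlas_from_profiles
from amp2bgc.errors import DataError
from amp2bgc.profiles import BGCProfile
from amp2bgc.simulate import SimConfig, evolve_sequences, evolve_traits, simulate_tree

profile_arrays = st.lists(st.integers(min_value=0, max_value=60), min_size=8, max_size=8)


def _p(values):
    return BGCProfile.from_array(values)


class TestSimilarity:
    def test_identical_profiles_score_one(self):
        p = _p([3, 0, 2, 1, 5, 0, 2, 1])
        assert evaluate.bgc_similarity(p, p) == 1.0

    def test_two_vs_zero(self):
        a = _p([2, 0, 0, 0, 0, 0, 0, 0])
        b = _p([0] * 8)
        assert evaluate.bgc_similarity(a, b) == pytest.approx((1 / 8) * (1 / 3 + 7), rel=1e-9)

    def test_ones_vs_zeros(self):
        assert evaluate.bgc_similarity(_p([1] * 8), _p([0] * 8)) == 0.5

    def test_salinispora_like_difference(self):
        # two genomes differing by 9 in a single class: (1/8)(1/10 + 7)
        a = _p([26, 0, 0, 0, 0, 0, 0, 0])
        b = _p([35, 0, 0, 0, 0, 0, 0, 0])
        assert evaluate.bgc_similarity(a, b) == pytest.approx(0.8875)

    def test_wrong_length_rejected(self):
        with pytest.raises(DataError):
            evaluate.bgc_similarity(np.ones(7), np.ones(7))

    @settings(max_examples=150, deadline=None)
    @given(profile_arrays, profile_arrays)
    def test_bounds_symmetry_identity(self, a, b):
        s = evaluate.bgc_similarity(np.array(a, float), np.array(b, float))
        assert 0 < s <= 1
        assert s == pytest.approx(evaluate.bgc_similarity(np.array(b, float), np.array(a, float)))
        assert (s == 1.0) == (a == b)

    @settings(max_examples=80, deadline=None)
    @given(profile_arrays, st.integers(0, 7))
    def test_strictly_decreasing_in_single_gap(self, a, idx):
        av = np.array(a, float)
        bv = av.copy()
        s0 = evaluate.bgc_similarity(av, bv)
        bv[idx] += 1
        s1 = evaluate.bgc_similarity(av, bv)
        assert s1 < s0


class TestPairwiseStats:
    def test_identical_pair(self):
        stats = evaluate.pairwise_stats([_p([1] * 8)] * 2)
        assert stats.mean == stats.median == stats.min == stats.max == 1.0
        assert stats.std == 0.0

    def test_three_profiles(self):
        zero, ones = _p([0] * 8), _p([1] * 8)
        stats = evaluate.pairwise_stats([zero, zero, ones])  # pair scores {1, 0.5, 0.5}
        assert stats.mean == pytest.approx(2 / 3)
        assert stats.median == 0.5
        assert stats.min == 0.5
        assert stats.max == 1.0

    def test_two_profiles_single_pair(self):
        stats = evaluate.pairwise_stats([_p([2] + [0] * 7), _p([0] * 8)])
        assert stats.mean == stats.min == stats.max

    def test_singleton_rejected(self):
        with pytest.raises(DataError):
            evaluate.pairwise_stats([_p([0] * 8)])


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng, seq, positions):
    s = list(seq)
    for pos in positions:
        s[pos] = [b for b in "ACGT" if b != s[pos]][rng.integers(3)]
    return "".join(s)


def _naive_greedy(sequences, threshold):
    """Independent reimplementation of the greedy loop (no k-mer screen)."""
    ordered = sorted(sequences, key=lambda item: (-len(item[1]), item[0]))
    centroids, clusters = [], []
    for sid, seq in ordered:
        for ci, (cid, cseq) in enumerate(centroids):
            identity, _, _ = align.align_identity(seq, cseq)
            if identity >= threshold:
                clusters[ci].append(sid)
                break
        else:
            centroids.append((sid, seq))
            clusters.append([sid])
    return clusters


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 300)
        clusters = evaluate.greedy_cluster([("a", seq), ("b", seq), ("c", seq)], 99)
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_distant_pair_stays_apart(self):
        rng = np.random.default_rng(1)
        a = _random_seq(rng, 400)
        b = _mutate(rng, a, rng.choice(400, size=200, replace=False))
        identity, _, _ = align.align_identity(a, b)
        assert identity < 97
        clusters = evaluate.greedy_cluster([("a", a), ("b", b)], 97)
        assert sorted(map(len, clusters)) == [1, 1]

    def test_chain_is_centroid_based_not_transitive(self):
        rng = np.random.default_rng(2)
        a = _random_seq(rng, 500)
        pos = rng.choice(np.arange(10, 490), size=20, replace=False)
        b = _mutate(rng, a, pos[:10])  # a~b = 98 %
        c = _mutate(rng, b, pos[10:])  # b~c = 98 %, a~c = 96 %
        assert align.align_identity(a, b)[0] >= 97
        assert align.align_identity(b, c)[0] >= 97
        assert align.align_identity(a, c)[0] < 97
        clusters = evaluate.greedy_cluster([("a", a), ("b", b), ("c", c)], 97)
        assert sorted(sorted(cl) for cl in clusters) == [["a", "b"], ["c"]]

    def test_empty_input(self):
        assert evaluate.greedy_cluster([], 97) == []

    def test_members_meet_threshold_to_centroid(self):
        rng = np.random.default_rng(3)
        base = _random_seq(rng, 350)
        seqs = [("s%02d" % i, _mutate(rng, base, rng.choice(350, size=rng.integers(0, 40), replace=False)))
                for i in range(15)]
        for thr in (97, 90):
            clusters = evaluate.greedy_cluster(seqs, thr)
            by_id = dict(seqs)
            for members in clusters:
                centroid = by_id[members[0]]
                for m in members:
                    assert align.align_identity(by_id[m], centroid)[0] >= thr

    def test_matches_independent_reimplementation(self):
        tree = simulate_tree(24, 12345, depth=0.1)
        seqs = sorted(evolve_sequences(tree, 500, 1.0, 54321).items())
        for thr in (99, 97, 90, 80):
            assert evaluate.greedy_cluster(seqs, thr) == _naive_greedy(seqs, thr)

    def test_cluster_count_nonincreasing_with_threshold(self):
        tree = simulate_tree(30, 77, depth=0.1)
        seqs = sorted(evolve_sequences(tree, 500, 1.0, 78).items())
        counts = [len(evaluate.greedy_cluster(seqs, t)) for t in (99, 97, 90, 80)]
        assert counts == sorted(counts, reverse=True)


class TestIdenticalMarkerConsistency:
    def test_multi_member_entries_only(self, tiny_atlas):
        stats = evaluate.identical_marker_consistency(tiny_atlas)
        assert len(stats) == 1  # one entry has two members
        # members [3,...] vs [4,...]: differ by 1 in PKSI -> (1/8)(1/2 + 7)
        assert stats[0].mean == pytest.approx((0.5 + 7) / 8)

    def test_identical_member_profiles(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 100)
        atlas = atlas_from_profiles(
            {"g1": seq, "g2": seq},
            {"g1": _p([2] + [0] * 7), "g2": _p([2] + [0] * 7)},
        )
        (stats,) = evaluate.identical_marker_consistency(atlas)
        assert stats.mean == stats.min == stats.max == 1.0 and stats.std == 0.0

    def test_singleton_atlas_empty(self):
        rng = np.random.default_rng(6)
        atlas = atlas_from_profiles(
            {"g1": _random_seq(rng, 100)}, {"g1": _p([1] * 8)}
        )
        assert evaluate.identical_marker_consistency(atlas) == []


class TestOutlierRate:
    def test_single_outlier(self):
        assert evaluate.outlier_rate([[26, 26, 26, 26, 26, 26, 35]]) == pytest.approx(1 / 7)

    def test_all_equal(self):
        assert evaluate.outlier_rate([[5] * 6]) == 0.0

    def test_pooled(self):
        groups = [[26] * 7, [26, 26, 26, 26, 26, 26, 35]]
        assert evaluate.outlier_rate(groups) == pytest.approx(1 / 14)

    def test_small_groups_skipped(self):
        assert evaluate.outlier_rate([[1, 2, 3], [4] * 5]) == 0.0

    def test_no_usable_group(self):
        with pytest.raises(DataError):
            evaluate.outlier_rate([[1, 2]])


class TestDeviationBins:
    @pytest.mark.parametrize("d,expected", [(0, "[0,1]"), (1, "[0,1]"), (1.01, "(1,5]"), (5, "(1,5]"), (6, "(5,inf)")])
    def test_boundaries(self, d, expected):
        summary = evaluate.deviation_bins([d], [0.0])
        assert summary.counts[expected] == 1

    def test_partition(self):
        rng = np.random.default_rng(8)
        devs = rng.uniform(0, 20, size=200)
        summary = evaluate.deviation_bins(devs, np.zeros(200))
        assert sum(summary.counts.values()) == 200
        assert sum(summary.proportions.values()) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            evaluate.deviation_bins([1.0], [1.0, 2.0])

    def test_failures_counted_apart(self):
        summary = evaluate.deviation_bins([0.0], [0.0], n_failures=3)
        assert summary.n_failures == 3
        assert sum(summary.proportions.values()) == pytest.approx(1.0)


class TestIdentityTiers:
    @pytest.mark.parametrize(
        "identity,tier",
        [(95.0, "90-95"), (100.0, "95-100"), (80.0, "0-80"), (0.0, "0-80"),
         (80.1, "80-90"), (90.0, "80-90"), (90.001, "90-95"), (95.001, "95-100")],
    )
    def test_boundary_convention(self, identity, tier):
        assert evaluate.identity_tier(identity) == tier

    def test_out_of_range(self):
        with pytest.raises(DataError):
            evaluate.identity_tier(101.0)

    def test_stratified_bins(self):
        out = evaluate.stratify_by_identity([3, 10, 5], [3, 3, 3], [99, 85, 70])
        assert out["95-100"].counts["[0,1]"] == 1
        assert out["80-90"].counts["(5,inf)"] == 1
        assert out["0-80"].counts["(1,5]"] == 1
        assert out["90-95"].n_success == 0


class TestPerClassEval:
    def test_identical_pairs(self):
        profiles = [_p([1, 2, 3, 0, 0, 0, 0, 0])] * 4
        out = evaluate.per_class_eval(profiles, profiles)
        for summary in out.values():
            assert summary.proportions["[0,1]"] == 1.0

    def test_single_class_divergence(self):
        a = [_p([0, 0, 6, 0, 0, 0, 0, 0])]
        b = [_p([0] * 8)]
        out = evaluate.per_class_eval(a, b)
        assert out["NRPS"].counts["(5,inf)"] == 1
        assert out["PKSI"].counts["[0,1]"] == 1

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            evaluate.per_class_eval([], [])


class TestExtractV3V4:
    FWD = "CCTACGGGAGGCAGCAG"  # concrete 341F variant (N->A, W->A)
    REV_SITE = evaluate.reverse_complement("GACTACACGGGTATCTAATCC")  # concrete 805R variant

    def _build(self, insert_len=425, seed=0):
        rng = np.random.default_rng(seed)
        lead = _random_seq(rng, 50)
        insert = _random_seq(rng, insert_len)
        tail = _random_seq(rng, 60)
        return lead + self.FWD + insert + self.REV_SITE + tail, insert

    def test_exact_sites(self):
        seq, insert = self._build()
        out = evaluate.extract_v3v4(seq)
        assert out == insert
        assert len(out) == 425

    def test_missing_reverse_site(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 50) + self.FWD + _random_seq(rng, 200)
        assert evaluate.extract_v3v4(seq) is None

    def test_mismatch_tolerance(self):
        seq, insert = self._build(seed=2)
        mutated = seq[:52] + ("A" if seq[52] != "A" else "C") + seq[53:]
        # the primer site now carries 1 mismatch; still found with max_mismatches=2
        assert evaluate.extract_v3v4(mutated) == insert

    def test_degenerate_primer_matches_any(self):
        seq, insert = self._build(seed=3)
        assert evaluate.extract_v3v4(seq, fwd_primer="N" * 17 , rev_primer="GACTACACGGGTATCTAATCC") is not None

    def test_malformed_primer(self):
        with pytest.raises(DataError):
            evaluate.extract_v3v4("ACGT" * 100, fwd_primer="ACGQ")


class TestSyntheticTrend:
    def test_similarity_declines_with_threshold(self):
        """Mean intra-cluster profile similarity is non-increasing from 99 % to 80 %."""
        means_per_rep = []
        for rep in range(5):
            cfg = SimConfig(n_tips=60, seed=1000 + rep, seq_length=800)
            tree = simulate_tree(cfg.n_tips, cfg.seed + 1, cfg.depth)
            seqs = sorted(evolve_sequences(tree, cfg.seq_length, cfg.rate, cfg.seed + 2).items())
            traits = evolve_traits(tree, cfg.root_profile, cfg.step_rate, cfg.seed + 3)
            profiles = {t: _p(v) for t, v in traits.items()}
            means = []
            for thr in (99, 97, 90, 80):
                clusters = evaluate.greedy_cluster(seqs, thr)
                stats = evaluate.cluster_similarity_stats(clusters, profiles)
                means.append(np.mean([s.mean for s in stats]) if stats else np.nan)
            means_per_rep.append(means)
        grand = np.nanmean(np.array(means_per_rep), axis=0)
        assert np.all(np.diff(grand) <= 1e-12), grand
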