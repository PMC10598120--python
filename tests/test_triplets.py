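import numpy as np
import pytest

import tripletgene as tg
from tripletgene.triplets import TripletCategory, semi_hard_filter


def _random_triplet_set(rng, n_samples=40, n_triplets=200):
    labels = np.array([0, 1] * (n_samples // 2))
    return labels, tg.build_triplets(labels, n_triplets, seed=int(rng.integers(2**31)))


class TestBuildTriplets:
    def test_balanced_anchor_classes_and_invariants(self):
        labels = np.array([0, 0, 1, 1])
        ts = tg.build_triplets(labels, 1000, seed=0)
        anchors_1 = int((labels[ts.anchors] == 1).sum())
        assert anchors_1 == 500 and len(ts) == 1000
        assert np.all(labels[ts.anchors] == labels[ts.positives])
        assert np.all(labels[ts.anchors] != labels[ts.negatives])
        assert np.all(ts.anchors != ts.positives)

    def test_positive_uniform_over_non_anchor_members(self):
        labels = np.array([0, 0, 0, 1, 1, 1, 1])
        ts = tg.build_triplets(labels, 20000, seed=1)
        # for 4-member class 1, each anchor's 3 possible positives ~ uniform
        mask = labels[ts.anchors] == 1
        for a in (3, 4, 5, 6):
            sel = ts.positives[mask & (ts.anchors == a)]
            _, counts = np.unique(sel, return_counts=True)
            assert counts.min() > 0.8 * counts.max()

    def test_single_member_class_rejected(self):
        with pytest.raises(ValueError, match="cannot draw a positive"):
            tg.build_triplets(np.array([0, 1, 1]), 10, seed=0)

    def test_same_seed_identical(self):
        labels = np.array([0, 0, 1, 1, 1])
        a = tg.build_triplets(labels, 100, seed=4)
        b = tg.build_triplets(labels, 100, seed=4)
        np.testing.assert_array_equal(a.anchors, b.anchors)
        np.testing.assert_array_equal(a.positives, b.positives)
        np.testing.assert_array_equal(a.negatives, b.negatives)

    def test_tsv_round_trip(self, tmp_path):
        ts = tg.build_triplets(np.array([0, 0, 1, 1]), 50, seed=2)
        ts.to_tsv(tmp_path / "t.tsv")
        back = tg.TripletSet.from_tsv(tmp_path / "t.tsv")
        np.testing.assert_array_equal(back.anchors, ts.anchors)
        np.testing.assert_array_equal(back.negatives, ts.negatives)


class TestCategorize:
    @pytest.mark.parametrize(
        "dp2,dn2,m,expected",
        [
            (1.0, 2.0, 0.5, TripletCategory.EASY),
            (1.0, 1.2, 0.5, TripletCategory.SEMI_HARD),
            (1.0, 0.8, 0.5, TripletCategory.HARD),
            (1.0, 1.0, 0.5, TripletCategory.SEMI_HARD),  # tie: gap 0 < m
            (1.0, 1.5, 0.5, TripletCategory.EASY),  # gap == m: loss exactly 0
        ],
    )
    def test_boundaries(self, dp2, dn2, m, expected):
        assert tg.categorize(dp2, dn2, m) == expected

    def test_zero_loss_iff_easy(self, rng):
        cfg = tg.LossConfig(use_switching=False, use_angular=False)
        for _ in range(300):
            t = tg.EmbeddedTriplet(*rng.standard_normal((3, 4)))
            dp2 = tg.distance2(t.x_a, t.x_p)
            dn2 = tg.distance2(t.x_a, t.x_n)
            easy = tg.categorize(dp2, dn2, cfg.margin) == TripletCategory.EASY
            assert (tg.triplet_loss(t, cfg) == 0.0) == easy


class TestCategorizeAll:
    def test_collapsed_embeddings_all_semi_hard(self, rng):
        labels, ts = _random_triplet_set(rng)
        E = np.ones((40, 5))
        cats, counts = tg.categorize_all(E, ts, m=0.5)
        assert counts.semi_hard == len(ts) and counts.easy == counts.hard == 0
        assert all(c == TripletCategory.SEMI_HARD for c in cats)

    def test_separated_clusters_all_easy(self, rng):
        labels, ts = _random_triplet_set(rng)
        E = np.where(labels[:, None] == 1, 50.0, -50.0) + rng.standard_normal((40, 3)) * 0.01
        _, counts = tg.categorize_all(E, ts, m=0.5)
        assert counts.easy == len(ts)

    def test_partition_invariant_random_embeddings(self, rng):
        labels, ts = _random_triplet_set(rng, n_triplets=1000)
        for _ in range(5):
            E = rng.standard_normal((40, 6)) * rng.uniform(0.1, 5)
            _, counts = tg.categorize_all(E, ts, m=0.5)
            assert counts.easy + counts.semi_hard + counts.hard == 1000
            assert counts.strict_semi_hard <= counts.semi_hard

    def test_index_out_of_range_rejected(self, rng):
        _, ts = _random_triplet_set(rng)
        with pytest.raises(IndexError):
            tg.categorize_all(np.zeros((10, 3)), ts, m=0.5)


def _brute_force_strict(E, ts, m):
    """Independent scalar double-categorization oracle."""
    keep = []
    for i in range(len(ts)):
        t = ts[i]
        dp2 = sum((E[t.anchor, j] - E[t.positive, j]) ** 2 for j in range(E.shape[1]))
        dn2 = sum((E[t.anchor, j] - E[t.negative, j]) ** 2 for j in range(E.shape[1]))
        dn2_sw = sum((E[t.positive, j] - E[t.negative, j]) ** 2 for j in range(E.shape[1]))
        fwd = (0 <= dn2 - dp2 < m)
        swt = (0 <= dn2_sw - dp2 < m)
        if fwd and swt:
            keep.append(i)
    return np.array(keep, dtype=int)


class TestStrictSemiHardFilter:
    def test_retained_when_both_orientations_semi_hard(self):
        E = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        ts = tg.TripletSet(np.array([0]), np.array([1]), np.array([2]), 0, 0, 0)
        # forward: dp2=1, dn2=1.25 -> semi-hard; switched dn2=1.25 by symmetry
        assert tg.strict_semi_hard_filter(E, ts, m=0.5).tolist() == [0]

    def test_rejected_when_switched_orientation_turns_hard(self):
        E = np.array([[0.0, 0.0], [1.0, 0.0], [1.1, 0.0]])
        ts = tg.TripletSet(np.array([0]), np.array([1]), np.array([2]), 0, 0, 0)
        # forward dn2=1.21 semi-hard, switched dn2=0.01 < dp2=1 -> hard
        assert len(tg.strict_semi_hard_filter(E, ts, m=0.5)) == 0

    def test_collapsed_embeddings_retain_everything(self, rng):
        _, ts = _random_triplet_set(rng)
        E = np.zeros((40, 4))
        assert len(tg.strict_semi_hard_filter(E, ts, m=0.5)) == len(ts)

    def test_invariant_under_anchor_positive_swap(self, rng):
        for _ in range(10):
            _, ts = _random_triplet_set(rng, n_triplets=300)
            E = rng.standard_normal((40, 5))
            a = tg.strict_semi_hard_filter(E, ts, m=0.5)
            b = tg.strict_semi_hard_filter(E, ts.swapped(), m=0.5)
            np.testing.assert_array_equal(a, b)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            _, ts = _random_triplet_set(rng, n_triplets=200)
            E = rng.standard_normal((40, 3)) * 0.6
            np.testing.assert_array_equal(
                tg.strict_semi_hard_filter(E, ts, m=0.5),
                _brute_force_strict(E, ts, 0.5),
            )

    def test_semi_hard_set_monotone_in_margin(self, rng):
        _, ts = _random_triplet_set(rng, n_triplets=500)
        E = rng.standard_normal((40, 4))
        prev_semi, prev_easy = set(), None
        for m in (0.1, 0.3, 0.6, 1.2, 2.5):
            semi = set(semi_hard_filter(E, ts, m).tolist())
            _, counts = tg.categorize_all(E, ts, m)
            assert prev_semi <= semi
            if prev_easy is not None:
                assert counts.easy <= prev_easy
            prev_semi, prev_easy = semi, counts.easy


class TestSelectHardSupplement:
    def _setup(self):
        # three hard triplets (negative closer than positive) with distinct losses
        E = np.array(
            [[0.0, 0.0], [2.0, 0.0], [0.1, 0.0],   # loss 4 - 0.01 + m
             [0.0, 5.0], [1.0, 5.0], [0.2, 5.0],   # loss 1 - 0.04 + m
             [0.0, 9.0], [3.0, 9.0], [0.3, 9.0]]   # loss 9 - 0.09 + m
        )
        ts = tg.TripletSet(
            np.array([0, 3, 6]), np.array([1, 4, 7]), np.array([2, 5, 8]), 0, 0, 0
        )
        return E, ts

    def test_k_zero_empty(self):
        E, ts = self._setup()
        assert len(tg.select_hard_supplement(E, ts, m=0.5, k=0)) == 0

    def test_least_loss_hard_triplets_selected(self):
        E, ts = self._setup()
        picked = tg.select_hard_supplement(E, ts, m=0.5, k=2)
        assert sorted(picked.tolist()) == [0, 1]  # losses ~4.5 and ~1.5 beat ~9.4

    def test_k_saturates_at_hard_count(self):
        E, ts = self._setup()
        assert len(tg.select_hard_supplement(E, ts, m=0.5, k=100)) == 3
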