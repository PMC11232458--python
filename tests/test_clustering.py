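import numpy as np
import pytest

from svlr.clustering import (DepthStats, Partition, adaptive_lambda,
                             cluster_partition, global_depth,
                             partition_signatures, signature_similarity,
                             spatial_distance)
from svlr.models import Signature

from oracles import brute_force_average_linkage, random_del_partition


def sig(t="DEL", s=0, e=0, name="r", c="chr1", p2=None, c2=None):
    return Signature(t=t, c=c, s=s, e=e, read_name=name, source="intra",
                     length=max(e - s, 0), c2=c2, p2=p2)


class TestSpatialDistance:
    def test_interval_types_measure_end_to_start_gap(self):
        assert spatial_distance(sig("DEL", 500, 1000), sig("DEL", 1500, 1600)) == 500
        assert spatial_distance(sig("DUP", 100, 900), sig("DUP", 950, 1000)) == 50

    def test_point_types_measure_start_to_start(self):
        assert spatial_distance(sig("INS", 200, 260), sig("INS", 200, 230)) == 0

    def test_overlapping_spans_have_zero_distance(self):
        # signatures of one large event must never be split apart
        assert spatial_distance(sig("DEL", 1000, 6000), sig("DEL", 1010, 6010)) == 0

    def test_mixed_types_rejected(self):
        with pytest.raises(ValueError):
            spatial_distance(sig("DEL", 0, 10), sig("INS", 0, 10))


class TestPartitioning:
    def test_gap_sweep(self):
        # point signatures with successive gaps 500, 900, 1200
        starts = [0, 500, 1400, 2600]
        sigs = [sig("DEL", s, s, name=f"r{i}") for i, s in enumerate(starts)]
        parts = partition_signatures(sigs, partition_gap=1000)
        assert [p.ld for p in parts] == [3, 1]

    def test_single_signature(self):
        parts = partition_signatures([sig("DEL", 10, 60)])
        assert len(parts) == 1 and parts[0].ld == 1

    def test_all_far_apart(self):
        sigs = [sig("INS", i * 5000, i * 5000 + 60, name=f"r{i}")
                for i in range(5)]
        assert [p.ld for p in partition_signatures(sigs)] == [1] * 5

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            partition_signatures([sig("DEL", 100, 150), sig("DEL", 0, 50)])

    def test_partitions_cover_input(self):
        rng = np.random.default_rng(1)
        sigs = sorted((sig("DEL", int(s), int(s) + 40, name=f"r{i}")
                       for i, s in enumerate(rng.integers(0, 50_000, 60))),
                      key=lambda x: x.s)
        parts = partition_signatures(sigs)
        flat = [m for p in parts for m in p.members]
        assert sorted(id(m) for m in flat) == sorted(id(s) for s in sigs)


class TestDepthAndLambda:
    def test_global_depth_is_mean_local_depth(self):
        parts = [Partition("DEL", "chr1", [sig()] * n) for n in (2, 4, 6)]
        assert global_depth(parts).gd["DEL"] == 4.0
        one = [Partition("INS", "chr1", [sig("INS")] * 7)]
        assert global_depth(one).gd["INS"] == 7.0
        skew = [Partition("DUP", "chr1", [sig("DUP")] * n) for n in (1, 1, 1, 9)]
        assert global_depth(skew).gd["DUP"] == 3.0

    def test_lambda_examples(self):
        assert adaptive_lambda(20, 20) == 20.0
        assert adaptive_lambda(10, 5) == 10.5
        assert adaptive_lambda(0.5, 0.5) == 1.0  # clamped to >= 1

    def test_lambda_rejects_non_positive(self):
        with pytest.raises(ValueError):
            adaptive_lambda(0, 5)


class TestSimilarity:
    def test_identical_signatures_score_zero(self):
        a = sig("DEL", 100, 200)
        assert signature_similarity(a, a, lam=5) == 0.0

    def test_hand_derived_scores(self):
        assert signature_similarity(sig("DEL", 100, 200), sig("DEL", 110, 210),
                                    lam=10) == pytest.approx(0.01)
        assert signature_similarity(sig("DEL", 100, 200), sig("DEL", 100, 150),
                                    lam=1) == pytest.approx(0.75)

    def test_symmetry(self):
        a, b = sig("DEL", 100, 300), sig("DEL", 150, 280)
        assert signature_similarity(a, b, 3.7) == signature_similarity(b, a, 3.7)

    def test_monotone_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            s1, s2 = rng.uniform(0, 1000, 2)
            a = sig("DEL", s1, s1 + rng.uniform(31, 500))
            b = sig("DEL", s2, s2 + rng.uniform(31, 500))
            lams = np.sort(rng.uniform(1, 50, 3))
            scores = [signature_similarity(a, b, l) for l in lams]
            assert all(x >= y - 1e-12 for x, y in zip(scores, scores[1:]))


class TestClusterPartition:
    def _stats(self, t="DEL", gd=10.0):
        return DepthStats(gd={t: gd}, n={t: 1})

    def test_similar_pair_merges(self):
        p = Partition("DEL", "chr1", [sig("DEL", 100, 200, "a"),
                                      sig("DEL", 110, 210, "b")])
        # lambda = |10-2|/10 + 10 = 10.8 -> S ~ 0.0093 < 0.3
        out = cluster_partition(p, self._stats())
        assert len(out) == 1 and out[0].support == 2

    def test_dissimilar_pair_stays_apart(self):
        p = Partition("DEL", "chr1", [sig("DEL", 100, 200, "a"),
                                      sig("DEL", 100, 150, "b")])
        out = cluster_partition(p, self._stats(gd=1.0))
        assert len(out) == 2

    def test_consensus_is_lower_median(self):
        members = [sig("DEL", 100, 220, "a"), sig("DEL", 102, 200, "b"),
                   sig("DEL", 104, 210, "c")]
        p = Partition("DEL", "chr1", members)
        out = cluster_partition(p, self._stats())
        assert len(out) == 1
        assert out[0].consensus_s == 102
        assert out[0].consensus_e == 210
        even = cluster_partition(
            Partition("DEL", "chr1", members[:2]), self._stats())
        assert even[0].consensus_s == 100  # lower median for even counts

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(250):
            members = random_del_partition(rng)
            p = Partition("DEL", "chr1", members)
            gd = float(rng.uniform(1, 30))
            stats = DepthStats(gd={"DEL": gd}, n={"DEL": 5})
            lam = adaptive_lambda(gd, p.ld)
            idx = {id(m): i for i, m in enumerate(members)}
            got = {frozenset(idx[id(m)] for m in cl.members)
                   for cl in cluster_partition(p, stats)}
            want = brute_force_average_linkage(members, lam, 0.3)
            assert got == want, f"trial {trial}"

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        members = random_del_partition(rng, max_n=10)
        stats = DepthStats(gd={"DEL": 8.0}, n={"DEL": 2})
        ref = {frozenset(m.read_name for m in cl.members)
               for cl in cluster_partition(
                   Partition("DEL", "chr1", members), stats)}
        for _ in range(5):
            perm = [members[i] for i in rng.permutation(len(members))]
            got = {frozenset(m.read_name for m in cl.members)
                   for cl in cluster_partition(
                       Partition("DEL", "chr1", perm), stats)}
            assert got == ref

    def test_clusters_are_disjoint_cover(self):
        rng = np.random.default_rng(4)
        members = random_del_partition(rng)
        out = cluster_partition(Partition("DEL", "chr1", members),
                                DepthStats(gd={"DEL": 4.0}, n={"DEL": 1}))
        flat = [id(m) for cl in out for m in cl.members]
        assert sorted(flat) == sorted(id(m) for m in members)
        assert len(set(flat)) == len(flat)
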