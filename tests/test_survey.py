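from functools import lru_cache

import numpy as np
import pytest

from cavscan.fixtures import make_toy_dimer
from cavscan.survey import (
    ChainPairRecord,
    convexity_survey,
    greedy_cluster,
    pairwise_identity,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def reference_identity(a: str, b: str) -> float:
    """Independent top-down DP for global-alignment identity.

    Scores match +1 / mismatch 0 / gap -1 with the same deterministic
    traceback preference (diagonal, then gap in b, then gap in a) as the
    package implementation, but computed by memoized recursion instead of
    an iterative matrix fill.
    """

    @lru_cache(maxsize=None)
    def score(i: int, j: int) -> int:
        if i == 0:
            return -j
        if j == 0:
            return -i
        s = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != "X") else 0
        return max(score(i - 1, j - 1) + s, score(i - 1, j) - 1, score(i, j - 1) - 1)

    al_a, al_b = [], []
    i, j = len(a), len(b)
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != "X") else 0
            if score(i, j) == score(i - 1, j - 1) + s:
                al_a.append(a[i - 1]); al_b.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and score(i, j) == score(i - 1, j) - 1:
            al_a.append(a[i - 1]); al_b.append("-")
            i -= 1
            continue
        al_a.append("-"); al_b.append(b[j - 1])
        j -= 1
    al_a = "".join(reversed(al_a))
    al_b = "".join(reversed(al_b))
    start = 0
    while al_a[start] == "-" or al_b[start] == "-":
        start += 1
    end = len(al_a)
    while al_a[end - 1] == "-" or al_b[end - 1] == "-":
        end -= 1
    cols = end - start
    if cols <= 0:
        return 0.0
    ident = sum(1 for x, y in zip(al_a[start:end], al_b[start:end])
                if x == y and x not in "-X")
    return ident / cols


def mutate(seq: str, n_mut: int, rng) -> str:
    s = list(seq)
    for pos in rng.choice(len(s), size=min(n_mut, len(s)), replace=False):
        s[pos] = AA[rng.integers(20)]
    return "".join(s)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKTAYIAK", "MKTAYIAK") == 1.0

    def test_direct_count(self):
        assert pairwise_identity("AAAA", "AAAT") == 0.75

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), 30))
            b = "".join(rng.choice(list(AA), 25))
            assert pairwise_identity(a, b) == pytest.approx(
                pairwise_identity(b, a), abs=1e-12
            )

    def test_x_never_matches(self):
        assert pairwise_identity("XXXX", "XXXX") == 0.0

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="position"):
            pairwise_identity("ACDZ", "ACDE")

    def test_matches_independent_dp_reference(self):
        """100 random pairs agree exactly with the memoized-recursion DP."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n, m = rng.integers(5, 60, 2)
            a = "".join(rng.choice(list(AA), n))
            if rng.random() < 0.5:
                b = mutate(a, int(rng.integers(0, n)), rng)[: rng.integers(3, n + 1)]
            else:
                b = "".join(rng.choice(list(AA), m))
            assert pairwise_identity(a, b) == pytest.approx(
                reference_identity(a, b), abs=1e-12
            )

    def test_agrees_with_biopython_score(self):
        """Optimal alignment score matches Biopython's global aligner."""
        Align = pytest.importorskip("Bio.Align")
        from cavscan.survey import _nw_align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = "".join(rng.choice(list(AA), rng.integers(10, 50)))
            b = "".join(rng.choice(list(AA), rng.integers(10, 50)))
            al_a, al_b = _nw_align(a, b)
            ours = sum(
                1 if (x == y and x != "-") else (-1 if "-" in (x, y) else 0)
                for x, y in zip(al_a, al_b)
            )
            assert ours == aligner.score(a, b)


def record(seq_a, seq_b, resolution=None, source="s"):
    return ChainPairRecord(
        source_id=source,
        chain_ids=("A", "B"),
        lengths=(len(seq_a), len(seq_b)),
        total_dsasa=500.0,
        resolution=resolution,
        sequences=(seq_a, seq_b),
    )


class TestGreedyCluster:
    def test_identical_records_one_cluster(self):
        recs = [record("MKTAYIAKQR", "LDNWETFKAG") for _ in range(5)]
        cs = greedy_cluster(recs)
        assert len(cs.clusters) == 1
        assert sorted(cs.clusters[0]) == [0, 1, 2, 3, 4]

    def test_unrelated_records_singletons(self):
        rng = np.random.default_rng(1)
        recs = [
            record("".join(rng.choice(list(AA), 40)), "".join(rng.choice(list(AA), 40)))
            for _ in range(4)
        ]
        cs = greedy_cluster(recs, identity_threshold=0.9)
        assert len(cs.clusters) == 4

    def test_planted_families_recovered(self):
        """20 records drawn from 3 identity families cluster exactly."""
        rng = np.random.default_rng(7)
        parents = [
            ("".join(rng.choice(list(AA), 50)), "".join(rng.choice(list(AA), 50)))
            for _ in range(3)
        ]
        recs, truth = [], []
        for k in range(20):
            fam = k % 3
            pa, pb = parents[fam]
            recs.append(record(mutate(pa, 5, rng), mutate(pb, 5, rng),
                               resolution=1.5 + 0.1 * k))
            truth.append(fam)
        cs = greedy_cluster(recs, identity_threshold=0.40)
        assert len(cs.clusters) == 3
        for members in cs.clusters:
            assert len({truth[m] for m in members}) == 1

    def test_clusters_partition_input(self):
        rng = np.random.default_rng(9)
        recs = [
            record("".join(rng.choice(list(AA), 30)), "".join(rng.choice(list(AA), 30)))
            for _ in range(10)
        ]
        cs = greedy_cluster(recs)
        all_members = sorted(m for c in cs.clusters for m in c)
        assert all_members == list(range(10))
        assert len(cs.representatives) == len(cs.clusters)

    def test_representatives_favor_resolution_then_length(self):
        recs = [
            record("MKTAYIAKQR", "LDNWETFKAG", resolution=2.5),
            record("MKTAYIAKQR", "LDNWETFKAG", resolution=1.2),
        ]
        cs = greedy_cluster(recs)
        assert cs.representatives == [1]

    def test_order_independence(self):
        rng = np.random.default_rng(11)
        parents = [("".join(rng.choice(list(AA), 40)),
                    "".join(rng.choice(list(AA), 40))) for _ in range(2)]
        recs = [record(mutate(parents[k % 2][0], 3, rng),
                       mutate(parents[k % 2][1], 3, rng),
                       resolution=1.0 + 0.05 * k, source=f"r{k}")
                for k in range(8)]
        cs1 = greedy_cluster(recs)
        shuffled_idx = list(range(8))[::-1]
        cs2 = greedy_cluster([recs[i] for i in shuffled_idx])
        sets1 = {frozenset(recs[m].source_id for m in c) for c in cs1.clusters}
        sets2 = {frozenset(recs[shuffled_idx[m]].source_id for m in c)
                 for c in cs2.clusters}
        assert sets1 == sets2


class TestConvexitySurvey:
    def test_complementary_dimers_negative_rank_correlation(self):
        dimers = [
            make_toy_dimer(contact_gap=0.5, radius=9 + 2 * i, seed=50 + i)
            for i in range(6)
        ]
        records, summary = convexity_survey(dimers, seed=3)
        assert summary["n_pairs"] == 6
        assert summary["spearman_rho"] <= -0.8
        for r in records:
            assert r.convexity_1 * r.convexity_2 < 0

    def test_single_complex_degenerate(self):
        d = make_toy_dimer(contact_gap=0.5, seed=1)
        records, summary = convexity_survey([d], seed=0)
        assert len(records) == 1
        assert summary["degenerate"]
        assert summary["spearman_rho"] is None

    def test_duplicates_flagged_degenerate(self):
        d = make_toy_dimer(contact_gap=0.5, seed=2)
        records, summary = convexity_survey([d] * 4, seed=0)
        assert len(records) == 4
        vals = {(r.convexity_1, r.convexity_2) for r in records}
        assert len(vals) == 1  # identical rows
        assert summary["degenerate"]

    def test_failures_skipped_not_fatal(self):
        good = make_toy_dimer(contact_gap=0.5, seed=4)
        bad = make_toy_dimer(contact_gap=50.0, seed=4)  # no interface
        records, summary = convexity_survey([good, bad], seed=0)
        assert summary["n_pairs"] == 1
        assert summary["n_skipped"] == 1
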