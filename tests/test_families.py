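"""Identity, clustering, consensus building, deduplication, family rules."""

import numpy as np
import pytest

from oracles import greedy_cluster_oracle, identity_oracle, revcomp
from retrofam.families import (
    build_consensus,
    classify_element_structure,
    define_families,
    deduplicate_library,
    greedy_cluster,
    pairwise_identity,
)
from retrofam.model import ConsensusEntry, RepeatHit


def entry(fid, seq):
    return ConsensusEntry(family_id=fid, superfamily="Gypsy", sequence=seq)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutated(rng, seq, n_subs):
    s = list(seq)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return "".join(s)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTAC") == 1.0

    def test_reverse_complement_is_identical(self):
        s = "ACGTACGTACGGTTAACC"
        assert pairwise_identity(s, revcomp(s)) == 1.0

    def test_two_terminal_mismatches(self):
        # 8 identical positions over a 10-base pair, whichever strand wins
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTTT") == pytest.approx(0.8)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_matches_dp_oracle_and_symmetry(self, rng):
        """Against an independent free-end-gap DP on random related pairs."""
        for _ in range(15):
            n = int(rng.integers(20, 45))
            a = random_seq(rng, n)
            choice = rng.random()
            if choice < 0.4:
                b = mutated(rng, a, int(rng.integers(0, n // 3)))
            elif choice < 0.6:
                b = revcomp(mutated(rng, a, int(rng.integers(0, n // 3))))
            else:
                b = random_seq(rng, int(rng.integers(15, 45)))
            expected = identity_oracle(a, b)
            assert pairwise_identity(a, b) == pytest.approx(expected, abs=1e-12)
            assert pairwise_identity(b, a) == pytest.approx(expected, abs=1e-12)


class TestGreedyCluster:
    def test_three_sequence_example(self, rng):
        s1 = random_seq(rng, 50)
        s2 = mutated(rng, s1, 5)  # ~0.9 identity
        s3 = random_seq(rng, 50)
        assert pairwise_identity(s1, s2) >= 0.8
        assert pairwise_identity(s3, s1) < 0.8 and pairwise_identity(s3, s2) < 0.8
        clusters = greedy_cluster([entry("a", s1), entry("b", s2), entry("c", s3)])
        parts = sorted(sorted(e.family_id for e in c) for c in clusters)
        assert parts == [["a", "b"], ["c"]]

    def test_mutually_dissimilar_singletons(self, rng):
        entries = [entry(f"e{i}", random_seq(rng, 60)) for i in range(4)]
        clusters = greedy_cluster(entries)
        assert sorted(len(c) for c in clusters) == [1, 1, 1, 1]

    def test_duplicates_share_a_cluster(self):
        s = "ACGTACGTACGTACGTACGT"
        clusters = greedy_cluster([entry("a", s), entry("b", s)])
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            greedy_cluster([entry("a", "ACGT")], threshold=0.0)
        with pytest.raises(ValueError):
            greedy_cluster([entry("a", "ACGT")], threshold=1.5)

    def test_partition_property(self, rng):
        entries = [
            entry(f"e{i}", random_seq(rng, int(rng.integers(30, 60))))
            for i in range(8)
        ]
        clusters = greedy_cluster(entries)
        flat = sorted(e.family_id for c in clusters for e in c)
        assert flat == sorted(e.family_id for e in entries)

    def test_join_predicate_held_at_join_time(self, rng):
        """Every member of a multi-entry cluster matches its founder at >=0.8."""
        base = random_seq(rng, 50)
        entries = [entry(f"m{i}", mutated(rng, base, int(rng.integers(0, 20))))
                   for i in range(6)]
        for cluster in greedy_cluster(entries):
            rep = cluster[0]
            for member in cluster[1:]:
                assert pairwise_identity(member.sequence, rep.sequence) >= 0.8


class TestBuildConsensus:
    def test_singleton_unchanged(self):
        assert build_consensus([entry("a", "ACGTACGT")]) == "ACGTACGT"

    def test_identical_members(self):
        e = entry("a", "ACGTACGTACGT")
        assert build_consensus([e, e, e]) == "ACGTACGTACGT"

    def test_majority_overrides_representative(self):
        rep = entry("rep", "ACGTACGT")
        m = entry("m1", "AGGTACGT")
        assert build_consensus([rep, m, entry("m2", "AGGTACGT")]) == "AGGTACGT"

    def test_tie_resolves_to_representative(self):
        # equal length: the lexicographically first label is the representative
        rep = entry("a_rep", "ACGTACGT")
        assert build_consensus([rep, entry("m1", "AGGTACGT")]) == "ACGTACGT"

    def test_result_has_representative_length(self, rng):
        rep = entry("rep", random_seq(rng, 60))
        members = [rep] + [
            entry(f"m{i}", mutated(rng, rep.sequence, 5)[5:]) for i in range(3)
        ]
        assert len(build_consensus(members)) == 60


class TestDeduplicateLibrary:
    def test_identical_novel_dropped(self):
        ref = [entry("r", "ACGTACGTACGTACGTACGT")]
        out = deduplicate_library([entry("n", "ACGTACGTACGTACGTACGT")], ref)
        assert [e.family_id for e in out] == ["r"]

    def test_empty_reference_keeps_all(self):
        novel = [entry("n1", "ACGTACGT"), entry("n2", "TTTTCCCC")]
        assert deduplicate_library(novel, []) == novel

    def test_similar_dropped_dissimilar_kept(self, rng):
        ref_seq = random_seq(rng, 60)
        ref = [entry("r", ref_seq)]
        near = entry("near", mutated(rng, ref_seq, 6))   # ~0.9
        far = entry("far", random_seq(rng, 60))          # ~0.5
        out = deduplicate_library([near, far], ref, threshold=0.8)
        assert [e.family_id for e in out] == ["r", "far"]
        # invariant: no surviving novel entry matches any reference at >= 0.8
        for e in out:
            if e.family_id != "r":
                assert pairwise_identity(e.sequence, ref_seq) < 0.8


def hit(species, chrom, start, length, fam="RLGy_1", hid=1):
    return RepeatHit(
        species=species, chromosome=chrom, start=start, end=start + length - 1,
        strand="+", family_id=fam, superfamily="Gypsy", hit_id=hid,
    )


LIB = [entry("RLGy_1", "A" * 500)]


class TestDefineFamilies:
    def test_strict_length_filter_trims_members(self):
        hits = [hit("s", "c1", 1000 * i, L, hid=i)
                for i, L in enumerate([150] * 10 + [100, 90], start=1)]
        (fam,) = define_families(hits, LIB)
        assert fam.total_copies() == 10

    def test_nine_copies_make_no_family(self):
        hits = [hit("s", "c1", 1000 * i, 500, hid=i) for i in range(1, 10)]
        assert define_families(hits, LIB) == []

    def test_boundary_101_bp_and_10_copies(self):
        hits = [hit("s", "c1", 1000 * i, 101, hid=i) for i in range(1, 11)]
        (fam,) = define_families(hits, LIB)
        assert fam.total_copies() == 10
        assert fam.consensus_length == 500

    def test_unknown_family_id_listed(self):
        with pytest.raises(ValueError, match="RLX_nope"):
            define_families(
                [hit("s", "c1", 1, 500, fam="RLX_nope")] * 10, LIB
            )

    def test_order_insensitive(self, rng):
        hits = [
            hit(sp, f"c{int(rng.integers(1, 4))}", int(rng.integers(1, 10**6)),
                int(rng.integers(150, 900)), hid=i)
            for i, sp in enumerate(
                rng.choice(["sp1", "sp2"], size=30), start=1
            )
        ]
        fams1 = define_families(hits, LIB)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert define_families(shuffled, LIB) == fams1

    def test_pooled_count_spans_species(self):
        hits = [hit("sp1", "c1", 1000 * i, 300, hid=i) for i in range(1, 7)]
        hits += [hit("sp2", "c1", 1000 * i, 300, hid=i) for i in range(1, 7)]
        (fam,) = define_families(hits, LIB)
        assert fam.copies_in("sp1") == 6 and fam.copies_in("sp2") == 6


@pytest.mark.parametrize(
    "length,consensus,expected",
    [(5200, 5200, "full"), (400, 5000, "remnant"), (2500, 5000, "full")],
)
def test_structure_classification(length, consensus, expected):
    h = hit("s", "c1", 1, length)
    assert classify_element_structure(h, consensus) == expected
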