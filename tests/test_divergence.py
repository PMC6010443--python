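"""Kimura-2-parameter distances, landscapes, distance matrices, NJ trees."""

import numpy as np
import pytest

from oracles import (
    kimura_closed_form,
    patristic_from_newick,
    random_additive_tree,
)
from retrofam.divergence import (
    DistanceMatrix,
    KimuraSaturationError,
    k2p_distance_matrix,
    k_bin,
    kimura_k2p,
    kimura_profile,
    neighbor_joining,
)
from retrofam.model import AlignmentRecord


def record_with_rates(n_cols, n_ti, n_tv, hid=1, fam="f"):
    """Gap-free alignment with exactly the requested substitution counts."""
    cons = ("ACGT" * (n_cols // 4 + 1))[:n_cols]
    elem = list(cons)
    for i in range(n_ti):  # transitions: A<->G, C<->T
        elem[i] = {"A": "G", "C": "T", "G": "A", "T": "C"}[elem[i]]
    for i in range(n_ti, n_ti + n_tv):  # transversions
        elem[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[elem[i]]
    return AlignmentRecord(hid, fam, "".join(elem), cons)


class TestKimuraK2P:
    def test_identical_rows_give_zero(self):
        assert kimura_k2p(record_with_rates(100, 0, 0)) == 0.0

    @pytest.mark.parametrize("ti,tv", [(10, 5), (20, 10), (2, 1), (30, 12)])
    def test_matches_closed_form(self, ti, tv):
        k = kimura_k2p(record_with_rates(100, ti, tv))
        assert k == pytest.approx(kimura_closed_form(ti / 100, tv / 100), abs=1e-9)

    def test_worked_values(self):
        assert kimura_k2p(record_with_rates(100, 10, 5)) == pytest.approx(17.02, abs=0.005)
        assert kimura_k2p(record_with_rates(100, 20, 10)) == pytest.approx(40.24, abs=0.005)

    def test_gap_and_n_columns_excluded(self):
        rec = AlignmentRecord(1, "f", "AC-GNT", "ACAGCT")
        # scorable columns: A/A, C/C, G/G, T/T -> K = 0
        assert kimura_k2p(rec) == 0.0

    def test_saturation_raises(self):
        with pytest.raises(KimuraSaturationError):
            kimura_k2p(record_with_rates(100, 50, 0))

    def test_no_scorable_columns(self):
        with pytest.raises(ValueError):
            kimura_k2p(AlignmentRecord(1, "f", "NN--", "NNAA"))

    def test_zero_iff_no_substitutions_and_monotone_in_p(self):
        assert kimura_k2p(record_with_rates(200, 1, 0)) > 0
        ks = [kimura_k2p(record_with_rates(200, ti, 10)) for ti in (0, 10, 20, 40)]
        assert ks == sorted(ks) and len(set(ks)) == len(ks)


class TestProfile:
    @pytest.mark.parametrize("k,expected", [(0.0, 0), (27.6, 27), (28.4, 28), (59.9, 59), (60.0, 60), (73.0, 60)])
    def test_floor_binning(self, k, expected):
        assert k_bin(k) == expected

    def test_identical_records_pile_in_bin_zero(self):
        recs = {"sp": [record_with_rates(120, 0, 0, hid=i) for i in range(10)]}
        prof = kimura_profile(recs, {("sp", "f"): "LOW"})
        assert prof.counts[("sp", "LOW")][0] == 10
        assert prof.total_scored() == 10

    def test_histogram_equals_bruteforce_tally(self):
        specs = [(10, 5), (20, 10), (0, 0), (5, 2), (30, 12)]
        recs = {"sp": [record_with_rates(100, ti, tv, hid=i)
                       for i, (ti, tv) in enumerate(specs)]}
        prof = kimura_profile(recs, {("sp", "f"): "MID"})
        expected = np.zeros(61, int)
        for ti, tv in specs:
            expected[k_bin(kimura_closed_form(ti / 100, tv / 100))] += 1
        assert (prof.counts[("sp", "MID")] == expected).all()

    def test_saturated_counted_separately(self):
        recs = {"sp": [record_with_rates(100, 50, 0), record_with_rates(100, 0, 0, hid=2)]}
        prof = kimura_profile(recs, {("sp", "f"): "LOW"})
        assert prof.saturated[("sp", "LOW")] == 1
        assert prof.total_scored() == 1

    def test_unknown_family_raises_when_strict(self):
        recs = {"sp": [record_with_rates(100, 0, 0, fam="ghost")]}
        with pytest.raises(ValueError, match="ghost"):
            kimura_profile(recs, {})
        prof = kimura_profile(recs, {}, strict=False)
        assert prof.skipped_no_class == 1


class TestDistanceMatrix:
    def test_identical_triplet_is_all_zero(self):
        seqs = [("a", "ACGT" * 30), ("b", "ACGT" * 30), ("c", "ACGT" * 30)]
        dm = k2p_distance_matrix(seqs)
        assert np.allclose(dm.d, 0)

    def test_pair_consistent_with_element_function(self):
        rec = record_with_rates(100, 10, 0)
        seqs = [("a", rec.aligned_element), ("b", rec.aligned_consensus), ("c", rec.aligned_consensus)]
        dm = k2p_distance_matrix(seqs)
        assert dm.d[0, 1] == pytest.approx(kimura_k2p(rec), abs=1e-12)

    def test_matrix_matches_elementwise_recomputation(self, rng):
        from retrofam.simulate import mutate_k2p, random_consensus

        ancestor = random_consensus(300, rng)
        seqs = [
            (f"t{i}", mutate_k2p(ancestor, k, 2.0, rng))
            for i, k in enumerate((5.0, 12.0, 20.0, 30.0))
        ]
        dm = k2p_distance_matrix(seqs)
        assert np.allclose(dm.d, dm.d.T)
        for i in range(4):
            for j in range(i + 1, 4):
                rec = AlignmentRecord(1, "f", seqs[i][1], seqs[j][1])
                assert dm.d[i, j] == pytest.approx(kimura_k2p(rec), abs=1e-12)

    def test_ragged_msa_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance_matrix([("a", "ACGT"), ("b", "ACG"), ("c", "ACGT")])

    def test_saturated_pair_named(self):
        hot = record_with_rates(100, 50, 0)
        seqs = [("x", hot.aligned_element), ("y", hot.aligned_consensus), ("z", hot.aligned_consensus)]
        with pytest.raises(KimuraSaturationError, match=r"\(x, y\)"):
            k2p_distance_matrix(seqs)


class TestNeighborJoining:
    EX = DistanceMatrix(
        ["A", "B", "C", "D"],
        np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float),
    )

    def test_recovers_known_additive_tree(self):
        newick = neighbor_joining(self.EX, clamp_negative=False)
        pat = patristic_from_newick(newick, self.EX.labels)
        assert np.allclose(pat, self.EX.d, atol=1e-9)
        # split AB|CD: A-B path avoids the internal edge
        assert "(A:1,B:2)" in newick or "(B:2,A:1)" in newick

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float))
        newick = neighbor_joining(dm)
        # three-point formulas: la=1, lb=3, lc=5
        assert newick == "(a:1,b:3,c:5);"

    def test_taxon_order_invariance(self):
        perm = [2, 0, 3, 1]
        dm2 = DistanceMatrix(
            [self.EX.labels[i] for i in perm], self.EX.d[np.ix_(perm, perm)]
        )
        pat1 = patristic_from_newick(neighbor_joining(self.EX), self.EX.labels)
        pat2 = patristic_from_newick(neighbor_joining(dm2), self.EX.labels)
        assert np.allclose(pat1, pat2, atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], np.array(
                [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float))

    def test_exact_on_random_additive_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            labels, d = random_additive_tree(rng, int(rng.integers(4, 9)))
            newick = neighbor_joining(DistanceMatrix(labels, d), clamp_negative=False)
            assert np.allclose(patristic_from_newick(newick, labels), d, atol=1e-6)

    def test_topology_agrees_with_skbio(self):
        import io

        from skbio import DistanceMatrix as SkDM
        from skbio import TreeNode
        from skbio.tree import nj

        rng = np.random.default_rng(9)
        labels, d = random_additive_tree(rng, 7)
        ours = TreeNode.read(io.StringIO(neighbor_joining(DistanceMatrix(labels, d))))
        theirs = nj(SkDM(d, labels))
        assert ours.compare_rfd(theirs) == 0.0


def test_simulated_elements_recover_target_divergence(rng):
    """Mean estimated K over 100 simulated 1-kb elements within +-2 of 28."""
    from retrofam.simulate import mutate_k2p, random_consensus

    cons = random_consensus(1000, rng)
    ks = []
    for i in range(100):
        mutated = mutate_k2p(cons, 28.0, 2.0, rng)
        ks.append(kimura_k2p(AlignmentRecord(i, "f", mutated, cons)))
    assert abs(np.mean(ks) - 28.0) < 2.0
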