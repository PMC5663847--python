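"""Sequence diversity, Tajima's D, Hudson F_ST and the Snn statistic."""

import itertools

import numpy as np
import pytest

from rpabc.popdata import HaplotypeAlignment, PopulationPartition
from rpabc import sumstats


def test_hand_counted_alignment(toy_alignment):
    rec = sumstats.sequence_diversity(toy_alignment, include_total=True)[0]
    # sites 2 and 9 are singletons, site 5 is shared by s2,s3
    assert rec.s == 3
    assert rec.singletons == 2
    assert rec.shared_polymorphisms == 1
    assert rec.n_hap == 4
    # Hd: all 4 haplotypes distinct -> (4/3) * (1 - 4*(1/16)) = 1
    assert rec.hd == pytest.approx(1.0)
    # pairwise differences: d(0,1)=1 d(0,2)=1 d(0,3)=2 d(1,2)=2 d(1,3)=3 d(2,3)=1
    pi_total = (1 + 1 + 2 + 2 + 3 + 1) / 6
    assert rec.pi_per_site == pytest.approx(pi_total / 10)
    a1 = 1 + 1 / 2 + 1 / 3
    assert rec.theta_w_per_site == pytest.approx(3 / a1 / 10)


def test_monomorphic_alignment_degenerate():
    aln = HaplotypeAlignment(["a", "b", "c"], ["ACGT"] * 3)
    rec = sumstats.sequence_diversity(aln)[0]
    assert (rec.s, rec.n_hap) == (0, 1)
    assert rec.pi_per_site == rec.theta_w_per_site == rec.hd == 0.0
    assert rec.tajima_d == 0.0 and rec.tajima_degenerate
    d, p, degen = sumstats.tajima_d_test(aln, n_sims=100, seed=1)
    assert d == 0.0 and p is None and degen


def test_singletons_plus_shared_equals_s(rng):
    for _ in range(20):
        n, L = int(rng.integers(3, 12)), int(rng.integers(5, 40))
        mat = rng.choice(list("ACGT"), size=(n, L), p=[0.85, 0.05, 0.05, 0.05])
        aln = HaplotypeAlignment([f"s{i}" for i in range(n)],
                                 ["".join(r) for r in mat])
        rec = sumstats.sequence_diversity(aln)[0]
        assert rec.s == rec.singletons + rec.shared_polymorphisms
        assert rec.n_hap <= n


def test_tajima_d_matches_independent_formula(toy_alignment):
    """Recompute D from scratch: raw pairwise-difference loops and the
    published variance constants, fully independent of the library path."""
    seqs = toy_alignment.sequences
    n = len(seqs)
    pi = np.mean([sum(c1 != c2 for c1, c2 in zip(seqs[i], seqs[j]))
                  for i, j in itertools.combinations(range(n), 2)])
    S = sum(len(set(col)) > 1 for col in zip(*seqs))
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    expected = (pi - S / a1) / np.sqrt(c1 / a1 * S
                                       + c2 / (a1 ** 2 + a2) * S * (S - 1))
    rec = sumstats.sequence_diversity(toy_alignment)[0]
    assert rec.tajima_d == pytest.approx(expected, abs=1e-10)


def test_tajima_null_distribution_properties():
    null = sumstats.simulate_tajima_null(n=20, theta=3.0, n_sims=2000, seed=9)
    assert len(null) == 2000
    # under the null D is centred near zero with a spread of order one
    assert abs(np.mean(null)) < 0.15
    assert 0.5 < np.std(null) < 1.5


class TestHudsonFst:
    def test_identical_distributions_near_zero(self):
        # the within-population estimator samples pairs without replacement,
        # so a single realization carries an O(1/n) bias; at n=50 per group
        # identical haplotype distributions must give F_ST within a few percent
        # of zero
        seqs = ["AAAA"] * 25 + ["AATA"] * 25
        aln = HaplotypeAlignment([f"x{i}" for i in range(100)], seqs * 2)
        mat = aln.as_matrix()
        fst = sumstats.hudson_fst(mat[:50], mat[50:])
        assert fst == pytest.approx(0.0, abs=0.05)

    def test_reciprocally_fixed_gives_one(self):
        aln = HaplotypeAlignment(["a", "b", "c", "d"],
                                 ["AAAA", "AAAA", "TTAA", "TTAA"])
        mat = aln.as_matrix()
        assert sumstats.hudson_fst(mat[:2], mat[2:]) == pytest.approx(1.0)

    def test_invariant_to_haplotype_relabelling(self, rng):
        # only the distance structure matters: permuting columns or swapping
        # base identities consistently leaves F_ST unchanged
        mat = rng.choice(list("ACGT"), size=(8, 20))
        swapped = np.select([mat == "A", mat == "C", mat == "G", mat == "T"],
                            ["G", "T", "A", "C"], default="N")
        f1 = sumstats.hudson_fst(mat[:4], mat[4:])
        f2 = sumstats.hudson_fst(swapped[:4], swapped[4:])
        assert f1 == pytest.approx(f2, abs=1e-12)


class TestSnn:
    def test_disjoint_haplotype_sets(self):
        # eight distinct haplotypes per group, within-group distances always
        # smaller than between-group ones: Snn = 1 and essentially no label
        # permutation can reach it
        base_a, base_b = "AAAAAAAA", "TTTTTTTT"
        seqs_a = [base_a[:i] + "C" + base_a[i + 1:] for i in range(8)]
        seqs_b = [base_b[:i] + "G" + base_b[i + 1:] for i in range(8)]
        aln = HaplotypeAlignment(
            [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)],
            seqs_a + seqs_b)
        part = PopulationPartition(
            {f"a{i}": "A" for i in range(8)} | {f"b{i}": "B" for i in range(8)},
            ["A", "B"])
        res = sumstats.snn_test(aln, part, ("A", "B"), n_perm=200, seed=3)
        assert res.snn == pytest.approx(1.0)
        assert res.p_value <= 3 / (res.n_permutations + 1)

    def test_tie_weights_match_hand_enumeration(self):
        # six sequences; s0 is equidistant (1 diff) from s1 (same pop) and
        # s3 (other pop): its contribution is 1/2
        seqs = ["AAAA",  # s0 pop A
                "AAAT",  # s1 pop A  d(s0,s1)=1
                "CCCC",  # s2 pop A
                "AAAC",  # s3 pop B  d(s0,s3)=1
                "GGGG",  # s4 pop B
                "GGGT"]  # s5 pop B
        ids = [f"s{i}" for i in range(6)]
        aln = HaplotypeAlignment(ids, seqs)
        part = PopulationPartition(
            {"s0": "A", "s1": "A", "s2": "A",
             "s3": "B", "s4": "B", "s5": "B"}, ["A", "B"])
        # hand enumeration of nearest neighbours:
        # s0: ties s1(A), s3(B) at d=1 -> 1/2
        # s1: ties s0(A), s3(B) at d=1 -> 1/2
        # s2: unique nearest s3(B) at d=3 -> 0
        # s3: ties s0, s1 (both A) at d=1 -> 0
        # s4: nearest s5(B) at d=1 -> 1 ; s5: nearest s4(B) -> 1
        expected = np.mean([0.5, 0.5, 0.0, 0.0, 1.0, 1.0])
        res = sumstats.snn_test(aln, part, ("A", "B"), n_perm=10, seed=1)
        assert res.snn == pytest.approx(expected, abs=1e-12)


def test_pairwise_fst_mtdna_excludes_singletons_and_reports(rng):
    ids = [f"x{i}" for i in range(9)]
    seqs = (["AAAA"] * 4 + ["TTTT"] * 4 + ["GGGG"])
    aln = HaplotypeAlignment(ids, seqs)
    part = PopulationPartition(
        {ids[i]: ("A" if i < 4 else "B" if i < 8 else "C")
         for i in range(9)}, ["A", "B", "C"])
    res = sumstats.pairwise_fst_mtdna(aln, part, n_perm=50, seed=2)
    pairs = [r.pair for r in res]
    assert ("A", "B") in pairs and len(pairs) == 1  # C has n=1, excluded
    assert res[0].fst == pytest.approx(1.0)
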