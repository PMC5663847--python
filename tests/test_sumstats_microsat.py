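"""Microsatellite diversity statistics against closed forms and brute force."""

import itertools

import numpy as np
import pytest

from rpabc.popdata import GenotypeTable, PopulationPartition
from rpabc import sumstats
from conftest import random_genotype_table


def _single_pop_partition(geno):
    return PopulationPartition({i: "P" for i in geno.individual_ids}, ["P"])


def test_he_closed_form_half_half():
    # one locus, two alleles at 0.5/0.5 -> He = 0.5
    alleles = np.array([[[10, 11]], [[10, 11]], [[10, 11]], [[10, 11]]])
    geno = GenotypeTable(["a", "b", "c", "d"], ["L"], alleles)
    he, ho = sumstats.heterozygosity(geno)
    assert he[0] == pytest.approx(0.5)
    assert ho[0] == pytest.approx(1.0)


def test_wc_fis_matches_direct_variance_components(toy_geno):
    # independent evaluation: plain-python loops over loci and alleles
    sum_b = sum_c = 0.0
    for l in range(toy_geno.n_loci):
        col = toy_geno.alleles[:, l, :]
        n = len(col)
        for a in set(col.ravel()):
            copies = sum((pair == a).sum() for pair in col)
            p = copies / (2 * n)
            het = sum(1 for pair in col if (pair == a).sum() == 1) / n
            sum_b += n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * het)
            sum_c += het / 2
    expected = 1 - sum_c / (sum_b + sum_c)
    assert sumstats.inbreeding_fis(toy_geno) == pytest.approx(expected, abs=1e-12)


def test_fis_monomorphic_undefined():
    geno = GenotypeTable(["a", "b"], ["L"], np.full((2, 1, 2), 7))
    assert sumstats.inbreeding_fis(geno) is None
    f, p = sumstats.fis_permutation_test(geno, 100, seed=1)
    assert f is None and p is None


class TestAllelicRichness:
    def test_full_sample_reproduces_allele_counts(self, rng):
        geno = random_genotype_table(rng, n=8, n_loci=3, missing_rate=0.0,
                                     n_pops=1)
        part = _single_pop_partition(geno)
        ar, _ = sumstats.allelic_richness(geno, part, g=16)["P"]
        counts = [len(sumstats.allele_counts(geno, l)) for l in range(3)]
        assert ar == pytest.approx(np.mean(counts), abs=1e-12)

    def test_enumeration_example(self):
        # counts (3,1), N=4, g=2: A_r = 1 + 1/2 = 1.5
        alleles = np.array([[[10, 10]], [[10, 12]]])
        geno = GenotypeTable(["a", "b"], ["L"], alleles)
        part = _single_pop_partition(geno)
        ar, _ = sumstats.allelic_richness(geno, part, g=2)["P"]
        assert ar == pytest.approx(1.5, abs=1e-12)

    def test_matches_exhaustive_subsampling(self, rng):
        geno = random_genotype_table(rng, n=5, n_loci=1, missing_rate=0.0,
                                     n_pops=1)
        part = _single_pop_partition(geno)
        g = 4
        copies = geno.alleles[:, 0, :].ravel()
        vals = [len(set(copies[list(idx)]))
                for idx in itertools.combinations(range(len(copies)), g)]
        ar, _ = sumstats.allelic_richness(geno, part, g=g)["P"]
        assert ar == pytest.approx(np.mean(vals), abs=1e-10)

    def test_g_too_large_names_locus(self, rng):
        geno = random_genotype_table(rng, n=4, n_loci=2, missing_rate=0.3,
                                     n_pops=1)
        with pytest.raises(sumstats.StatError, match="loc"):
            sumstats.allelic_richness(geno, _single_pop_partition(geno), g=9)


class TestPrivateAllelicRichness:
    def _two_pop(self, allele_a, allele_b):
        alleles = np.array([[[allele_a] * 2]] * 3 + [[[allele_b] * 2]] * 3)
        geno = GenotypeTable([f"i{k}" for k in range(6)], ["L"], alleles)
        part = PopulationPartition(
            {f"i{k}": ("A" if k < 3 else "B") for k in range(6)}, ["A", "B"])
        return geno, part

    def test_shared_fixed_allele_gives_zero(self):
        geno, part = self._two_pop(9, 9)
        pa = sumstats.private_allelic_richness(geno, part, g=2)
        assert pa["A"][0] == pytest.approx(0.0)
        assert pa["B"][0] == pytest.approx(0.0)

    def test_distinct_fixed_alleles_give_one(self):
        geno, part = self._two_pop(9, 13)
        for g in (2, 4, 6):
            pa = sumstats.private_allelic_richness(geno, part, g=g)
            assert pa["A"][0] == pytest.approx(1.0)
            assert pa["B"][0] == pytest.approx(1.0)

    def test_matches_brute_force_three_pops(self, rng):
        geno = random_genotype_table(rng, n=9, n_loci=1, missing_rate=0.0,
                                     n_pops=3)
        part = PopulationPartition(
            {ind: f"pop{1 + k // 3}" for k, ind in
             enumerate(geno.individual_ids)}, ["pop1", "pop2", "pop3"])
        g = 2
        copies = {lab: geno.subset(part.members(lab, geno.individual_ids))
                  .alleles[:, 0, :].ravel() for lab in part.labels}
        expected = {}
        for focal in part.labels:
            others = [l for l in part.labels if l != focal]
            total = 0.0
            count = 0
            for sub_f in itertools.combinations(range(6), g):
                sets_f = set(copies[focal][list(sub_f)])
                for subs in itertools.product(
                        *[itertools.combinations(range(6), g) for _ in others]):
                    present_elsewhere = set()
                    for lab, sub in zip(others, subs):
                        present_elsewhere |= set(copies[lab][list(sub)])
                    total += len(sets_f - present_elsewhere)
                    count += 1
            expected[focal] = total / count
        pa = sumstats.private_allelic_richness(geno, part, g=g)
        for lab in part.labels:
            assert pa[lab][0] == pytest.approx(expected[lab], abs=1e-10)


class TestGarzaWilliamson:
    def test_contiguous_alleles_give_one(self):
        alleles = np.array([[[10, 11]], [[11, 12]]])
        geno = GenotypeTable(["a", "b"], ["L"], alleles)
        m = sumstats.garza_williamson_m(geno, _single_pop_partition(geno))
        assert m["P"] == pytest.approx(1.0)

    def test_gapped_alleles_closed_form(self):
        alleles = np.array([[[50, 52]], [[54, 54]]])
        geno = GenotypeTable(["a", "b"], ["L"], alleles)
        m = sumstats.garza_williamson_m(geno, _single_pop_partition(geno))
        assert m["P"] == pytest.approx(3 / 5)

    def test_shift_invariance(self, rng):
        geno = random_genotype_table(rng, n=10, n_loci=4, missing_rate=0.1,
                                     n_pops=1)
        part = _single_pop_partition(geno)
        m1 = sumstats.garza_williamson_m(geno, part)
        shifted = GenotypeTable(
            geno.individual_ids, geno.locus_names,
            np.where(geno.alleles > 0, geno.alleles + 7, geno.alleles),
            locality=geno.locality)
        m2 = sumstats.garza_williamson_m(shifted, part)
        assert m1["P"] == pytest.approx(m2["P"], abs=1e-12)

    def test_mgw_test_contract(self):
        null = np.linspace(0.3, 1.0, 200)
        assert sumstats.m_gw_test(1.01, 10, 11, null_values=null) == 1.0
        assert sumstats.m_gw_test(0.2, 10, 11, null_values=null) == 0.0
        with pytest.raises(sumstats.StatError, match="n_sims"):
            sumstats.m_gw_test(0.5, 10, 11, n_sims=50)


class TestWeirCockerhamTheta:
    def test_fixed_differences_approach_one(self):
        alleles = np.concatenate([np.full((8, 3, 2), 10),
                                  np.full((8, 3, 2), 20)])
        geno = GenotypeTable([f"i{k}" for k in range(16)],
                             ["A", "B", "C"], alleles)
        part = PopulationPartition(
            {f"i{k}": ("p1" if k < 8 else "p2") for k in range(16)},
            ["p1", "p2"])
        theta = sumstats.wc_theta(
            [geno.subset(part.members("p1", geno.individual_ids)),
             geno.subset(part.members("p2", geno.individual_ids))])
        assert theta == pytest.approx(1.0, abs=1e-9)

    def test_panmixia_mean_near_zero(self):
        # two labels drawn from one Hardy-Weinberg pool: E[theta] ~ 0
        rng = np.random.default_rng(7)
        thetas = []
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        for _ in range(200):
            copies = rng.choice(4, size=(60, 8, 2), p=freqs) + 10
            geno = GenotypeTable([f"i{k}" for k in range(60)],
                                 [f"L{j}" for j in range(8)], copies)
            thetas.append(sumstats.wc_theta(
                [geno.subset(geno.individual_ids[:30]),
                 geno.subset(geno.individual_ids[30:])]))
        assert abs(np.mean(thetas)) < 0.005

    def test_pairwise_report_with_ci_and_p(self, rng):
        geno = random_genotype_table(rng, n=24, n_loci=5, missing_rate=0.05,
                                     n_pops=2)
        part = PopulationPartition(
            {i: l for i, l in zip(geno.individual_ids, geno.locality)},
            ["pop1", "pop2"])
        res = sumstats.pairwise_fst_microsat(geno, part, n_boot=200,
                                             n_perm=200, seed=5)
        assert len(res) == 1
        rec = res[0]
        assert rec.ci95[0] <= rec.ci95[1]
        assert 0 < rec.p_value <= 1
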