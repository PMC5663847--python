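"""Data model, GenePop/CSV/FASTA round trips, and the inclusion filter."""

import numpy as np
import pytest

from rpabc.popdata import (GenotypeTable, HaplotypeAlignment, PopDataError,
                           PopulationPartition, filter_individuals,
                           read_genotypes, read_haplotypes, read_partition,
                           write_genotypes, write_haplotypes, write_partition)
from conftest import random_genotype_table

GENEPOP_TEXT = """example title
locA
locB, locC
Pop
a1 , 0810 0505 1212
a2 , 0812 0000 1214
Pop
b1 , 1010 0506 1212
"""


def test_genepop_parse_two_pops_three_loci(tmp_path):
    p = tmp_path / "x.gen"
    p.write_text(GENEPOP_TEXT)
    t = read_genotypes(p, "genepop")
    assert t.locus_names == ["locA", "locB", "locC"]
    assert t.n_individuals == 3
    assert t.locality == ["pop1", "pop1", "pop2"]
    assert t.typed_mask()[1, 1] == False  # 0000 missing  # noqa: E712
    assert tuple(t.alleles[0, 0]) == (8, 10)


def test_csv_missing_code_sets_mask(tmp_path):
    p = tmp_path / "x.csv"
    p.write_text("id,locality,L1_a,L1_b,L2_a,L2_b\n"
                 "i1,XCSS,10,12,0,0\n"
                 "i2,PY,11,11,8,9\n")
    t = read_genotypes(p, "csv")
    assert t.typed_mask().tolist() == [[True, False], [True, True]]
    assert t.locality == ["XCSS", "PY"]


@pytest.mark.parametrize("format", ["genepop", "csv"])
def test_roundtrip_random_tables(tmp_path, rng, format):
    for k in range(10):
        t = random_genotype_table(rng, n=rng.integers(3, 15),
                                  n_loci=rng.integers(1, 6))
        path = tmp_path / f"t{k}.{format}"
        write_genotypes(t, path, format=format)
        back = read_genotypes(path, format)
        assert back == t


def test_bp_to_repeat_units_conversion(tmp_path):
    p = tmp_path / "x.csv"
    p.write_text("id,locality,L1_a,L1_b\ni1,PY,120,124\n")
    t = read_genotypes(p, "csv", motif_lengths=[4], units="bp")
    assert tuple(t.alleles[0, 0]) == (30, 31)
    p2 = tmp_path / "y.csv"
    p2.write_text("id,locality,L1_a,L1_b\ni1,PY,121,124\n")
    with pytest.raises(PopDataError, match="not a multiple"):
        read_genotypes(p2, "csv", motif_lengths=[4], units="bp")


def test_half_missing_genotype_rejected(tmp_path):
    p = tmp_path / "x.gen"
    p.write_text("t\nlocA\nPop\na1 , 0800\n")
    with pytest.raises(PopDataError, match="half-missing"):
        read_genotypes(p, "genepop")


def test_invariants_enforced():
    with pytest.raises(PopDataError, match="duplicate"):
        GenotypeTable(["a", "a"], ["L"], np.full((2, 1, 2), 5))
    with pytest.raises(PopDataError, match="positive"):
        GenotypeTable(["a"], ["L"], np.full((1, 1, 2), -3))


def test_fasta_roundtrip_and_ambiguity(tmp_path):
    aln = HaplotypeAlignment(["a", "b"], ["ACGTACGTAC", "ACGTACGTNC"])
    path = tmp_path / "a.fasta"
    write_haplotypes(aln, path)
    back = read_haplotypes(path)
    assert back.individual_ids == aln.individual_ids
    assert back.sequences == aln.sequences
    assert back.excluded_sites().tolist() == [8]
    assert back.as_matrix().shape == (2, 9)


def test_unequal_fasta_lengths_rejected(tmp_path):
    path = tmp_path / "a.fasta"
    path.write_text(">a\nACGT\n>b\nACG\n")
    with pytest.raises(PopDataError, match="unequal"):
        read_haplotypes(path)


def test_partition_roundtrip_and_validation(tmp_path):
    part = PopulationPartition({"a": "PY", "b": "TL"}, ["PY", "TL"])
    path = tmp_path / "p.csv"
    write_partition(part, path)
    back = read_partition(path)
    assert back.assignment == part.assignment
    assert back.labels == part.labels
    geno = GenotypeTable(["a"], ["L"], np.full((1, 1, 2), 5))
    with pytest.raises(PopDataError, match="unknown individuals"):
        back.validate_against(geno, None)


class TestInclusionFilter:
    def _geno(self, typed_per_ind):
        n_loci = 11
        rows = []
        for t in typed_per_ind:
            row = [[9, 9]] * t + [[-1, -1]] * (n_loci - t)
            rows.append(row)
        return GenotypeTable([f"i{k}" for k in range(len(typed_per_ind))],
                             [f"L{j}" for j in range(n_loci)],
                             np.array(rows))

    def test_rules(self):
        geno = self._geno([11, 5, 5, 6, 4])
        mt = HaplotypeAlignment(["i1", "i4"], ["ACGT", "ACGT"])
        kept, report = filter_individuals(geno, mt)
        # i0: 11 loci, no mtDNA -> kept; i1: 5 loci + mtDNA -> kept;
        # i2: 5 loci, no mtDNA -> removed; i3: 6 loci -> kept;
        # i4: 4 loci + mtDNA -> removed
        assert kept.individual_ids == ["i0", "i1", "i3"]
        assert [r[0] for r in report.removed] == ["i2", "i4"]

    def test_idempotent(self, rng):
        geno = random_genotype_table(rng, n=30, n_loci=11, missing_rate=0.45)
        mt = HaplotypeAlignment(geno.individual_ids[:15], ["ACGT"] * 15)
        once, _ = filter_individuals(geno, mt)
        twice, rep = filter_individuals(once, mt)
        assert twice == once
        assert rep.removed == []
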