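"""Coalescent analytics, mutation models and dataset reproducibility."""

import numpy as np
import pytest
import tskit

from rpabc.coalsim import (DemographyError, MutationModel, RealizedDemography,
                           ResizeEvent, SamplingDesign, ScenarioDraw,
                           SplitEvent, gsm_step, mutate_microsat,
                           mutate_sequence, sample_genealogy, simulate_dataset)


def constant_demography(n=500.0):
    return RealizedDemography(populations={"P": n})


def two_tip_tree(tmrca: float) -> tskit.TreeSequence:
    """A fixed two-tip genealogy with known divergence, built directly."""
    tables = tskit.TableCollection(sequence_length=1.0)
    tables.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0)
    tables.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0)
    tables.nodes.add_row(flags=0, time=tmrca)
    tables.edges.add_row(left=0, right=1, parent=2, child=0)
    tables.edges.add_row(left=0, right=1, parent=2, child=1)
    tables.sort()
    return tables.tree_sequence()


class TestGenealogyAnalytics:
    def test_single_lineage_has_no_coalescence(self):
        ts = next(iter([sample_genealogy(constant_demography(), {"P": 1},
                                         "mtDNA", seed=1)]))
        assert ts.num_samples == 1
        assert ts.first().num_edges == 0

    def test_pairwise_tmrca_is_2n(self):
        n_dip = 400.0
        reps = sample_genealogy(constant_demography(n_dip), {"P": 1},
                                "nuclear", seed=11, num_replicates=10_000)
        tmrcas = np.array([ts.first().time(ts.first().root) for ts in reps])
        se = tmrcas.std() / np.sqrt(len(tmrcas))
        assert abs(tmrcas.mean() - 2 * n_dip) < 3 * se

    def test_mtdna_tmrca_is_quarter_of_nuclear(self):
        n_dip = 400.0
        reps = sample_genealogy(constant_demography(n_dip), {"P": 2},
                                "mtDNA", seed=13, num_replicates=10_000)
        tmrcas = np.array([ts.first().time(ts.first().root) for ts in reps])
        se = tmrcas.std() / np.sqrt(len(tmrcas))
        assert abs(tmrcas.mean() - 2 * n_dip / 4) < 3 * se

    def test_total_branch_length_n10(self):
        n_dip = 300.0
        reps = sample_genealogy(constant_demography(n_dip), {"P": 5},
                                "nuclear", seed=17, num_replicates=10_000)
        totals = np.array([ts.first().total_branch_length for ts in reps])
        expected = 4 * n_dip * sum(1 / i for i in range(1, 10))
        se = totals.std() / np.sqrt(len(totals))
        assert abs(totals.mean() - expected) < 3 * se

    def test_coalescent_event_count(self):
        for seed in range(1, 6):
            ts = next(sample_genealogy(constant_demography(), {"P": 6},
                                       "nuclear", seed=seed, num_replicates=1))
            tree = ts.first()
            internal = sum(1 for u in tree.nodes() if tree.num_children(u) > 0)
            assert internal == ts.num_samples - tree.num_roots


class TestMicrosatMutation:
    def test_zero_rate_keeps_root_allele(self):
        ts = two_tip_tree(1000.0)
        model = MutationModel(mu_mic=0.0, p_gsm=0.2)
        sizes = mutate_microsat(ts, model, np.random.default_rng(1))
        assert np.all(sizes == (1 + 40) // 2)

    def test_strict_stepwise_single_step(self):
        rng = np.random.default_rng(2)
        steps = [gsm_step(0.0, rng) for _ in range(500)]
        assert set(np.abs(steps)) == {1}
        # signs balanced
        assert 0.35 < np.mean(np.array(steps) > 0) < 0.65

    @pytest.mark.parametrize("p_gsm", [0.0, 0.3])
    def test_pairwise_variance_closed_form(self, p_gsm):
        # two lineages diverged t generations: E[(size difference)^2]
        # = 2 mu t (1 + P) / (1 - P)^2 for an unbounded geometric step model
        mu, t = 5e-4, 5000.0
        ts = two_tip_tree(t)
        model = MutationModel(mu_mic=mu, p_gsm=p_gsm, range_bound=None)
        rng = np.random.default_rng(5)
        diffs = np.array([np.diff(mutate_microsat(ts, model, rng))[0]
                          for _ in range(10_000)], dtype=float)
        sq = diffs ** 2
        expected = 2 * mu * t * (1 + p_gsm) / (1 - p_gsm) ** 2
        se = sq.std() / np.sqrt(len(sq))
        assert abs(sq.mean() - expected) < 3 * se

    def test_reflection_keeps_alleles_in_range(self):
        ts = two_tip_tree(50_000.0)
        model = MutationModel(mu_mic=5e-3, p_gsm=0.3, range_bound=12)
        rng = np.random.default_rng(8)
        for _ in range(50):
            sizes = mutate_microsat(ts, model, rng)
            assert np.all((sizes >= 1) & (sizes <= 12))


class TestSequenceMutation:
    def test_zero_rate_identical_sequences(self):
        dem = constant_demography(200.0)
        ts = sample_genealogy(dem, {"P": 5}, "mtDNA", seed=3,
                              sequence_length=100)
        model = MutationModel(mu_mt=0.0)
        seqs = mutate_sequence(ts, model, np.random.default_rng(4))
        assert len(set(seqs)) == 1

    def test_watterson_expected_segregating_sites(self):
        # haploid mtDNA deme of N/2 copies: E[S] = N mu L a_{n-1}
        n_dip, mu, L, n = 200.0, 2e-6, 500, 16
        theta = n_dip * mu * L
        a = sum(1 / i for i in range(1, n))
        reps = sample_genealogy(constant_demography(n_dip), {"P": n}, "mtDNA",
                                seed=23, num_replicates=3000,
                                sequence_length=L)
        model = MutationModel(mu_mt=mu)
        rng = np.random.default_rng(99)
        s_vals = []
        for ts in reps:
            seqs = mutate_sequence(ts, model, rng)
            cols = np.array([list(s) for s in seqs])
            s_vals.append(sum(len(set(c)) > 1 for c in cols.T))
        s_vals = np.array(s_vals, dtype=float)
        se = s_vals.std() / np.sqrt(len(s_vals))
        assert abs(s_vals.mean() - theta * a) < 3 * se

    def test_extreme_kappa_gives_transitions_only(self):
        dem = constant_demography(500.0)
        ts = sample_genealogy(dem, {"P": 10}, "mtDNA", seed=31,
                              sequence_length=300)
        model = MutationModel(mu_mt=5e-5, kappa=1e9)
        seqs = mutate_sequence(ts, model, np.random.default_rng(7))
        cols = np.array([list(s) for s in seqs]).T
        transitions = ({"A", "G"}, {"C", "T"})
        for col in cols:
            states = set(col)
            if len(states) > 1:
                assert states <= transitions[0] or states <= transitions[1]


class TestSimulateDataset:
    def _draw(self):
        dem = RealizedDemography(
            populations={"A": 300.0, "B": 300.0, "ANC": 500.0},
            events=[SplitEvent(80.0, ["A", "B"], "ANC")])
        return ScenarioDraw({}, dem, MutationModel())

    def test_same_seed_identical(self):
        design = SamplingDesign(n_diploid={"A": 6, "B": 4},
                                n_mt={"A": 4, "B": 3}, n_loci=5, mt_length=120)
        g1, m1 = simulate_dataset(self._draw(), design, seed=77)
        g2, m2 = simulate_dataset(self._draw(), design, seed=77)
        assert g1 == g2
        assert m1.sequences == m2.sequences
        g3, _ = simulate_dataset(self._draw(), design, seed=78)
        assert g3 != g1

    def test_dimensions_and_labels(self):
        design = SamplingDesign(n_diploid={"A": 6, "B": 4},
                                n_mt={"A": 4, "B": 3}, n_loci=5, mt_length=120)
        geno, mt = simulate_dataset(self._draw(), design, seed=5)
        assert geno.n_individuals == 10 and geno.n_loci == 5
        assert geno.locality == ["A"] * 6 + ["B"] * 4
        assert mt.n_sequences == 7 and mt.length == 120
        # mtDNA sample ids are a subset of the nuclear ones here
        assert set(mt.individual_ids) <= set(geno.individual_ids)


def test_demography_validation_errors():
    with pytest.raises(DemographyError, match="single root"):
        RealizedDemography(populations={"A": 10.0, "B": 10.0}).validate()
    with pytest.raises(DemographyError, match="> 0"):
        RealizedDemography(
            populations={"A": 10.0, "ANC": 10.0},
            events=[SplitEvent(0.0, ["A"], "ANC")]).validate()
    with pytest.raises(DemographyError, match="merges"):
        RealizedDemography(
            populations={"A": 1.0, "B": 1.0, "M": 1.0, "ANC": 1.0},
            events=[SplitEvent(50.0, ["A"], "M"),
                    SplitEvent(10.0, ["M", "B"], "ANC")]).validate()
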