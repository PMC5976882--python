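"""The synthetic community generator: determinism, planted structure,
conservation laws."""

import numpy as np
import pytest

from maglink.errors import InvalidParameterError
from maglink.synthetic import (mutate_genome, simulate_community,
                               simulate_genome, simulate_reads,
                               simulate_time_series)
from maglink.tables import AbundanceTable

from conftest import full_truth


class TestSimulateGenome:
    def test_length_and_alphabet(self):
        g = simulate_genome(1000, 0.5, seed=1)
        assert len(g.sequence) == 1000
        assert set(g.sequence) <= set("ACGT")

    def test_zero_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_genome(0, 0.5, seed=1)

    def test_gc_content_calibrated(self):
        # binomial SE of GC at L=1e5 is ~0.0015, so +-0.01 is ~6 sigma
        g = simulate_genome(100_000, 0.6, seed=7)
        gc = sum(b in "GC" for b in g.sequence) / len(g.sequence)
        assert abs(gc - 0.6) < 0.01

    def test_deterministic(self):
        assert simulate_genome(500, 0.4, seed=3).sequence == \
            simulate_genome(500, 0.4, seed=3).sequence


class TestMutateGenome:
    def test_zero_divergence_identity(self):
        g = simulate_genome(1000, 0.5, seed=1)
        assert mutate_genome(g, 0.0, seed=2).sequence == g.sequence

    @pytest.mark.parametrize("divergence,length", [(0.05, 100_000), (0.01, 1000),
                                                   (0.10, 5000)])
    def test_hamming_distance_exact(self, divergence, length):
        g = simulate_genome(length, 0.5, seed=1)
        mut = mutate_genome(g, divergence, seed=2)
        ham = sum(a != b for a, b in zip(g.sequence, mut.sequence))
        assert ham == round(divergence * length)
        assert len(mut.sequence) == length  # substitution-only, no indels

    def test_invalid_divergence_rejected(self):
        g = simulate_genome(100, 0.5, seed=1)
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(InvalidParameterError):
                mutate_genome(g, bad, seed=2)

    def test_deterministic(self):
        g = simulate_genome(2000, 0.5, seed=1)
        assert mutate_genome(g, 0.05, seed=9).sequence == \
            mutate_genome(g, 0.05, seed=9).sequence


class TestSimulateCommunity:
    def test_degenerate_single_genome(self, panel):
        com = simulate_community(1, 1, 0.0, 0.10, full_truth(1, panel),
                                 seed=1, genome_length=2000, panel=panel)
        assert len(com.genomes) == 1
        assert set(com.true_population.values()) == {"pop1"}

    def test_divergence_ordering_enforced(self, panel):
        with pytest.raises(InvalidParameterError):
            simulate_community(2, 2, 0.10, 0.01, full_truth(2, panel),
                               seed=1, panel=panel)

    def test_planted_auxotrophy_removes_pathway_genes(self, panel):
        truth = full_truth(1, panel, absent={("pop1", "biotin")})
        com = simulate_community(1, 1, 0.0, 0.10, truth, seed=1,
                                 genome_length=2000, panel=panel)
        biotin = next(p for p in panel if p.metabolite == "biotin")
        g = com.genomes[0]
        missing_steps = [step for step in biotin.steps
                         if not any(f in g.gene_families for f in step)]
        assert len(missing_steps) == 1
        assert com.auxotrophy_truth[(g.id, "biotin")] is True

    def test_proportions_sum_to_one(self, small_community):
        assert abs(sum(small_community.true_proportions.values()) - 1.0) < 1e-9

    def test_deterministic(self, panel):
        truth = full_truth(2, panel)
        a = simulate_community(2, 2, 0.01, 0.1, truth, seed=5,
                               genome_length=3000, panel=panel)
        b = simulate_community(2, 2, 0.01, 0.1, truth, seed=5,
                               genome_length=3000, panel=panel)
        assert [g.sequence for g in a.genomes] == [g.sequence for g in b.genomes]
        assert a.true_proportions == b.true_proportions


class TestSimulateReads:
    def test_single_genome_gets_all_reads(self, panel):
        com = simulate_community(1, 1, 0.0, 0.1, full_truth(1, panel),
                                 seed=1, genome_length=2000, panel=panel)
        reads = simulate_reads(com, 100, 150, 0.0, seed=2)
        assert len(reads.reads) == 100
        assert all(origin == com.genomes[0].id for _r, _s, origin in reads.reads)

    def test_counts_conserved(self, small_community):
        reads = simulate_reads(small_community, 1000, 100, 0.01, seed=3)
        assert len(reads.reads) == 1000
        assert all(len(s) == 100 for _r, s, _o in reads.reads)

    def test_multinomial_counts_near_proportions(self, panel):
        com = simulate_community(2, 1, 0.0, 0.1, full_truth(2, panel),
                                 seed=1, genome_length=2000, panel=panel,
                                 proportions=None)
        com.true_proportions = {com.genomes[0].id: 0.5, com.genomes[1].id: 0.5}
        reads = simulate_reads(com, 10_000, 100, 0.0, seed=4)
        count_a = sum(1 for _r, _s, o in reads.reads if o == com.genomes[0].id)
        assert abs(count_a - 5000) <= 3 * np.sqrt(10_000 * 0.25)

    def test_read_length_validated(self, small_community):
        with pytest.raises(InvalidParameterError):
            simulate_reads(small_community, 10, 10_000_000, 0.0, seed=1)


class TestSimulateTimeSeries:
    @staticmethod
    def blocks(n_focal, n_env, n_blocks=2):
        b = {f"culture_{i:02d}": f"b{i % n_blocks}" for i in range(1, n_focal + 1)}
        b.update({f"ts_{j:02d}": f"b{j % n_blocks}" for j in range(1, n_env + 1)})
        return b

    def test_row_count_and_closure(self):
        ts = simulate_time_series(2, 4, 45, self.blocks(2, 4), 0.5, seed=1)
        assert len(ts.sample_ids) == 45
        assert np.allclose(ts.values.sum(axis=1), 1.0, atol=1e-9)
        assert ts.kind == "fractions"

    def test_near_perfect_block_gives_spearman_one(self):
        from scipy.stats import spearmanr
        b = {"culture_01": "b0", "ts_01": "b0"}
        ts = simulate_time_series(1, 1, 40, b, 0.999999, seed=2)
        rho = spearmanr(ts.column("culture_01"), ts.column("ts_01")).statistic
        assert rho == 1.0

    def test_planted_rho_recovered(self):
        # Monte-Carlo: median sample Spearman near the planted 0.8
        from scipy.stats import spearmanr
        rhos = []
        for seed in range(20):
            ts = simulate_time_series(1, 1, 113, {"culture_01": "b", "ts_01": "b"},
                                      0.8, seed=seed)
            rhos.append(spearmanr(ts.column("culture_01"),
                                  ts.column("ts_01")).statistic)
        assert abs(np.median(rhos) - 0.8) < 0.15

    def test_cross_block_uncorrelated(self):
        from scipy.stats import spearmanr
        b = {"culture_01": "b0", "ts_01": "b1"}
        rhos = [spearmanr(*(lambda t: (t.column("culture_01"), t.column("ts_01")))(
            simulate_time_series(1, 1, 113, b, 0.9, seed=s))).statistic
            for s in range(10)]
        assert abs(np.median(rhos)) < 0.2

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_time_series(1, 1, 2, {"culture_01": "b", "ts_01": "b"},
                                 0.5, seed=1)

    def test_deterministic(self):
        b = self.blocks(2, 3)
        t1 = simulate_time_series(2, 3, 10, b, 0.5, seed=9)
        t2 = simulate_time_series(2, 3, 10, b, 0.5, seed=9)
        assert np.array_equal(t1.values, t2.values)
        assert t1.sample_ids == t2.sample_ids


def test_abundance_table_rejects_bad_fractions():
    with pytest.raises(InvalidParameterError):
        AbundanceTable(sample_ids=["s1"], taxon_ids=["a", "b"],
                       values=np.array([[0.4, 0.4]]), kind="fractions")
    with pytest.raises(InvalidParameterError):
        AbundanceTable(sample_ids=["s1"], taxon_ids=["a"],
                       values=np.array([[-1.0]]), kind="raw-counts")
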