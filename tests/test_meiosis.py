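import numpy as np
import pytest
from scipy import stats

import gpsel as g
from gpsel.linkage_map import GeneticMap
from gpsel.meiosis import HaploIndividual, _gametes_from_stacks


def two_snp_map(r):
    """One chromosome, two SNPs separated by the Haldane distance giving r."""
    cm = 100.0 * g.haldane_inverse(r)
    return GeneticMap(chrom=["1", "1"], snp_ids=["a", "b"], bp=[0, 1000],
                      cm=[0.0, cm])


def flat_map(n_snps, cm_spacing=1.0, chrom="1"):
    return GeneticMap(
        chrom=[chrom] * n_snps, snp_ids=[f"s{i}" for i in range(n_snps)],
        bp=np.arange(n_snps) * 1000, cm=np.arange(n_snps) * cm_spacing,
    )


class TestFounderPhasing:
    def test_homozygous_phases_deterministically(self):
        rng = np.random.default_rng(0)
        s = np.array([1, -1, 1, -1], dtype=np.int8)
        ind = g.founder_from_scores(s, rng)
        np.testing.assert_array_equal(ind.h1, s)
        np.testing.assert_array_equal(ind.h2, s)

    def test_het_locus_differs_between_haplotypes(self):
        rng = np.random.default_rng(1)
        ind = g.founder_from_scores(np.array([1, 0, -1]), rng)
        assert ind.h1[1] == -ind.h2[1]
        assert abs(ind.h1[1]) == 1

    def test_score_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        s = rng.choice([-1, 0, 1], size=200)
        ind = g.founder_from_scores(s, rng)
        np.testing.assert_array_equal(ind.scores(), s)


class TestGametes:
    def test_no_recombination_transmits_intact_chromosome(self):
        rng = np.random.default_rng(3)
        gm = GeneticMap(chrom=["1"] * 5, snp_ids=list("abcde"),
                        bp=np.arange(5), cm=np.zeros(5))
        ind = HaploIndividual(np.ones(5, dtype=np.int8),
                              -np.ones(5, dtype=np.int8))
        for _ in range(20):
            gam = g.sample_gamete(ind, gm, rng)
            assert np.all(gam == 1) or np.all(gam == -1)

    def test_homozygote_gamete_fixed(self):
        rng = np.random.default_rng(4)
        gm = flat_map(10)
        h = np.ones(10, dtype=np.int8)
        ind = HaploIndividual(h, h.copy())
        np.testing.assert_array_equal(g.sample_gamete(ind, gm, rng), h)

    @pytest.mark.parametrize("r", [0.01, 0.1, 0.3])
    def test_recombinant_fraction_matches_haldane(self, r):
        """Empirical adjacent-marker recombination within 3 binomial SE."""
        rng = np.random.default_rng(5)
        gm = two_snp_map(r)
        ind = HaploIndividual(np.array([1, 1], dtype=np.int8),
                              np.array([-1, -1], dtype=np.int8))
        n = 10_000
        gams = g.sample_gamete(ind, gm, rng, n=n)
        recomb = np.mean(gams[:, 0] != gams[:, 1])
        se = np.sqrt(r * (1 - r) / n)
        assert abs(recomb - r) <= 3 * se

    def test_interchromosome_independence(self):
        """Markers on different chromosomes recombine at rate ~0.5."""
        rng = np.random.default_rng(6)
        gm = GeneticMap(chrom=["1", "2"], snp_ids=["a", "b"], bp=[0, 0],
                        cm=[0.0, 0.0])
        ind = HaploIndividual(np.array([1, 1], dtype=np.int8),
                              np.array([-1, -1], dtype=np.int8))
        n = 10_000
        gams = g.sample_gamete(ind, gm, rng, n=n)
        rhat = np.mean(gams[:, 0] != gams[:, 1])
        assert abs(rhat - 0.5) <= 3 * np.sqrt(0.25 / n)


class TestCrossAndSelf:
    def test_inbred_cross_deterministic_midparent(self):
        rng = np.random.default_rng(7)
        gm = flat_map(30)
        s1 = np.random.default_rng(1).choice([-1, 1], size=30)
        s2 = np.random.default_rng(2).choice([-1, 1], size=30)
        p1 = g.founder_from_scores(s1, rng, id="p1")
        p2 = g.founder_from_scores(s2, rng, id="p2")
        f1 = g.cross(p1, p2, gm, rng)
        np.testing.assert_array_equal(f1.scores(), (s1 + s2) // 2)
        assert f1.parents == ("p1", "p2")

    def test_self_of_inbred_is_clone(self):
        rng = np.random.default_rng(8)
        gm = flat_map(20)
        s = np.random.default_rng(3).choice([-1, 1], size=20)
        p = g.founder_from_scores(s, rng, id="p")
        pop = g.self_progeny(p, 10, gm, rng)
        np.testing.assert_array_equal(pop.scores(), np.tile(s, (10, 1)))

    def test_opposite_parents_give_all_het_f1(self):
        rng = np.random.default_rng(9)
        gm = flat_map(15)
        p1 = g.founder_from_scores(np.ones(15, dtype=np.int8), rng)
        p2 = g.founder_from_scores(-np.ones(15, dtype=np.int8), rng)
        f1 = g.cross(p1, p2, gm, rng)
        assert np.all(f1.scores() == 0)

    def test_f2_mendelian_segregation(self):
        """Unlinked heterozygous locus segregates 1/4 : 1/2 : 1/4 in F2."""
        rng = np.random.default_rng(10)
        gm = flat_map(1)
        f1 = HaploIndividual(np.array([1], dtype=np.int8),
                             np.array([-1], dtype=np.int8))
        pop = g.self_progeny(f1, 10_000, gm, rng)
        s = pop.scores()[:, 0]
        counts = [(s == -1).sum(), (s == 0).sum(), (s == 1).sum()]
        res = stats.chisquare(counts, f_exp=[2500, 5000, 2500])
        assert res.pvalue > 0.001

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        gm = flat_map(5)
        p1 = HaploIndividual(np.ones(5, dtype=np.int8), np.ones(5, dtype=np.int8))
        p2 = HaploIndividual(np.ones(4, dtype=np.int8), np.ones(4, dtype=np.int8))
        with pytest.raises(ValueError):
            g.cross(p1, p2, gm, rng)


class TestPopulations:
    def test_population_scores_entries_valid(self):
        rng = np.random.default_rng(12)
        gm = flat_map(50)
        f1 = HaploIndividual(np.ones(50, dtype=np.int8),
                             -np.ones(50, dtype=np.int8))
        pop = g.self_progeny(f1, 200, gm, rng)
        s = g.population_scores(pop)
        assert np.isin(s, [-1, 0, 1]).all()

    def test_founders_round_trip(self, panel):
        rng = np.random.default_rng(13)
        pop = g.founders_from_matrix(panel["m"], rng)
        np.testing.assert_array_equal(
            g.population_scores(pop), panel["m"].scores.astype(np.int8)
        )

    def test_heterozygosity_halves_per_selfed_generation(self):
        """From an all-het F1, het frequency at F10 ~ (1/2)^9, +-30% relative."""
        rng = np.random.default_rng(14)
        n_ind, n_loci = 2000, 500
        gm = flat_map(n_loci, cm_spacing=0.5)
        h1 = np.ones((n_ind, n_loci), dtype=np.int8)
        h2 = -np.ones((n_ind, n_loci), dtype=np.int8)
        pop = g.HaploPopulation(h1=h1, h2=h2, generation="F1")
        for gen in range(2, 11):  # single-seed descent, no selection
            pop = g.self_population(pop, 1, gm, rng, generation=f"F{gen}")
        het = float((pop.scores() == 0).mean())
        expected = 0.5**9
        assert abs(het - expected) / expected <= 0.30

    def test_write_population(self, tmp_path):
        rng = np.random.default_rng(15)
        gm = flat_map(4)
        f1 = HaploIndividual(np.ones(4, dtype=np.int8),
                             -np.ones(4, dtype=np.int8), id="x")
        pop = g.self_progeny(f1, 3, gm, rng, generation="F2")
        from gpsel.meiosis import write_population

        write_population(pop, tmp_path / "g.tsv", tmp_path / "ped.tsv")
        assert (tmp_path / "g.tsv").read_text().count("\n") == 4
        assert "parent1" in (tmp_path / "ped.tsv").read_text()
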