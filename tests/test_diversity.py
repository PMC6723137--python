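import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from conftest import matrix_from_rows, random_matrix
from selfdiv import diversity as dv
from selfdiv.genotype_io import MISSING, PhasedGenotypeMatrix


class TestAlleleFrequencies:
    def test_fixed_ref_and_even_split(self):
        g = matrix_from_rows([[(0, 0), (0, 1)], [(0, 0), (1, 0)]])
        p = dv.allele_frequencies(g)
        np.testing.assert_allclose(p, [0.0, 0.5])

    def test_matches_brute_force_tally_with_missing_data(self):
        g = random_matrix(n=16, markers_per_chrom=(25, 25), seed=11, missing_rate=0.1)
        np.testing.assert_allclose(
            dv.allele_frequencies(g), oracle.tally_allele_frequency(g.alleles), rtol=1e-12
        )

    def test_all_missing_marker_flagged_nan(self):
        g = matrix_from_rows([[(0, 1), (MISSING, MISSING)], [(1, 1), (MISSING, MISSING)]])
        with pytest.warns(UserWarning, match="no non-missing"):
            p = dv.allele_frequencies(g)
        assert np.isnan(p[1])


class TestHeterozygosity:
    @pytest.mark.parametrize("p,he", [(0.5, 0.5), (1.0, 0.0), (0.9, 0.18)])
    def test_expected_heterozygosity_formula(self, p, he):
        n = 10
        n_alt = int(round(2 * n * p))
        calls = [1] * n_alt + [0] * (2 * n - n_alt)
        rows = [[(calls[2 * i], calls[2 * i + 1])] for i in range(n)]
        _, mean_he = dv.expected_heterozygosity(matrix_from_rows(rows))
        assert mean_he == pytest.approx(he, abs=1e-12)

    def test_observed_heterozygosity_counts_heterozygotes(self):
        g = matrix_from_rows([[(0, 0)], [(0, 1)], [(1, 1)], [(0, 1)]])
        ho, mean_ho = dv.observed_heterozygosity(g)
        assert mean_ho == pytest.approx(0.5)

    def test_all_heterozygous_gives_one(self):
        g = matrix_from_rows([[(0, 1), (1, 0)], [(0, 1), (0, 1)]])
        assert dv.observed_heterozygosity(g)[1] == pytest.approx(1.0)

    def test_missing_individuals_excluded_per_marker(self):
        g = matrix_from_rows([[(0, 1)], [(MISSING, 1)], [(0, 0)]])
        ho, _ = dv.observed_heterozygosity(g)
        assert ho[0] == pytest.approx(0.5)


class TestFis:
    def test_all_homozygous_gives_one(self):
        g = matrix_from_rows([[(0, 0), (1, 1)], [(1, 1), (0, 0)], [(0, 0), (0, 0)]])
        assert dv.inbreeding_coefficient(g) == pytest.approx(1.0)

    def test_hardy_weinberg_sample_is_near_zero(self):
        # random-mating oracle: independent allele draws at 100 loci, n=10^4
        rng = np.random.default_rng(42)
        p = rng.uniform(0.1, 0.9, 100)
        alleles = (rng.random((10_000, 100, 2)) < p[None, :, None]).astype(np.int8)
        g = PhasedGenotypeMatrix(
            individuals=[f"i{k}" for k in range(10_000)],
            alleles=alleles,
            phased=True,
            gmap=random_matrix(markers_per_chrom=(50, 50)).gmap,
        )
        assert abs(dv.inbreeding_coefficient(g)) < 0.02

    def test_ho_equal_he_gives_zero(self):
        # p = 0.5 with every individual heterozygous: Ho = 0.5? no, Ho=1;
        # construct Ho = He = 0.5 instead: half heterozygotes at p=0.5
        g = matrix_from_rows([[(0, 1)], [(1, 0)], [(0, 0)], [(1, 1)]])
        assert dv.inbreeding_coefficient(g) == pytest.approx(0.0, abs=1e-12)

    def test_no_passing_markers_is_an_error(self):
        g = matrix_from_rows([[(0, 0)], [(0, 0)]])
        with pytest.raises(ValueError, match="Fis undefined"):
            dv.inbreeding_coefficient(g)

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_marker_and_individual_order(self, rnd):
        g = random_matrix(n=10, markers_per_chrom=(20,), seed=5, missing_rate=0.05)
        ref = dv.inbreeding_coefficient(g)
        ind = list(range(g.n_individuals))
        rnd.shuffle(ind)
        mk = list(range(g.n_markers))
        rnd.shuffle(mk)
        shuffled = PhasedGenotypeMatrix(
            individuals=[g.individuals[i] for i in ind],
            alleles=g.alleles[np.ix_(ind, mk)],
            phased=True,
            gmap=random_matrix(markers_per_chrom=(20,)).gmap,
        )
        assert dv.inbreeding_coefficient(shuffled) == pytest.approx(ref, rel=1e-12)


class TestIdentityDisequilibrium:
    def test_every_individual_fully_heterozygous_gives_zero(self):
        g = matrix_from_rows([[(0, 1), (0, 1), (1, 0)]] * 5)
        g2, _ = dv.identity_disequilibrium_g2(g, n_boot=10, seed=0)
        assert g2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_complete_data(self):
        g = random_matrix(n=20, markers_per_chrom=(15, 15), seed=7)
        het = (g.alleles[:, :, 0] != g.alleles[:, :, 1])
        expected = oracle.brute_g2(het.astype(int))
        got, _ = dv.identity_disequilibrium_g2(g, n_boot=2, seed=0)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_matches_brute_force_with_missing_data(self):
        g = random_matrix(n=15, markers_per_chrom=(12,), seed=9, missing_rate=0.15)
        valid = (g.alleles != MISSING).all(axis=2)
        het = (g.alleles[:, :, 0] != g.alleles[:, :, 1]) & valid
        expected = oracle.brute_g2(het.astype(int), valid)
        got, _ = dv.identity_disequilibrium_g2(g, n_boot=2, seed=0)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_undefined_without_heterozygotes(self):
        g = matrix_from_rows([[(0, 0), (1, 1)], [(1, 1), (0, 0)]])
        with pytest.warns(UserWarning, match="undefined"):
            g2, se = dv.identity_disequilibrium_g2(g)
        assert np.isnan(g2) and np.isnan(se)

    def test_random_mating_population_has_g2_near_zero(self):
        # 1000 random-mating individuals: heterozygosity uncorrelated across loci
        rng = np.random.default_rng(3)
        p = rng.uniform(0.2, 0.8, 40)
        alleles = (rng.random((1000, 40, 2)) < p[None, :, None]).astype(np.int8)
        g = PhasedGenotypeMatrix(
            individuals=[f"i{k}" for k in range(1000)],
            alleles=alleles,
            phased=True,
            gmap=random_matrix(markers_per_chrom=(40,)).gmap,
        )
        g2, se = dv.identity_disequilibrium_g2(g, n_boot=50, seed=1)
        assert abs(g2) < max(3 * se, 0.01)

    def test_partial_selfing_population_has_positive_g2(self, partial_selfing_sample):
        sample, _ = partial_selfing_sample
        g2, se = dv.identity_disequilibrium_g2(sample, n_boot=50, seed=2)
        assert g2 > 0
        # point estimate agrees with the direct double-loop definition
        het = (sample.alleles[:, :, 0] != sample.alleles[:, :, 1])
        assert g2 == pytest.approx(oracle.brute_g2(het.astype(int)), rel=1e-10)


class TestEffectiveHaplotypeNumber:
    def test_four_equifrequent_haplotypes(self):
        # 2 individuals -> 4 haplotypes, all distinct
        rows = [
            [(0, 1), (0, 1), (0, 0), (0, 1), (0, 1), (0, 1), (0, 1), (0, 1), (0, 1), (0, 1)],
            [(1, 0), (0, 1), (1, 1), (0, 1), (0, 1), (0, 1), (0, 1), (0, 1), (0, 1), (0, 1)],
        ]
        table, mean_he = dv.effective_haplotype_number(matrix_from_rows(rows))
        assert mean_he == pytest.approx(4.0)

    def test_monomorphic_window_gives_one(self):
        rows = [[(0, 0)] * 10] * 4
        _, mean_he = dv.effective_haplotype_number(matrix_from_rows(rows))
        assert mean_he == pytest.approx(1.0)

    def test_frequencies_half_quarter_quarter(self):
        # 2 individuals: haplotypes A,A,B,C -> k = (0.5, 0.25, 0.25)
        a = [0] * 10
        b = [1] * 10
        c = [0, 1] * 5
        rows = [
            [(x, y) for x, y in zip(a, a)],
            [(x, y) for x, y in zip(b, c)],
        ]
        _, mean_he = dv.effective_haplotype_number(matrix_from_rows(rows))
        assert mean_he == pytest.approx(1 / 0.375)

    def test_matches_brute_force_and_trailing_markers_dropped(self):
        g = random_matrix(n=12, markers_per_chrom=(25,), seed=13)
        table, _ = dv.effective_haplotype_number(g, window=10)
        assert len(table) == 2  # 25 markers -> 2 windows, 5 dropped
        for _, row in table.iterrows():
            block = g.alleles[:, row["start"] : row["start"] + 10, :]
            assert row["he"] == pytest.approx(oracle.brute_he_window(block), rel=1e-10)

    def test_refuses_unphased_input(self):
        g = random_matrix(n=4, markers_per_chrom=(10,), seed=1, phased=False)
        with pytest.raises(Exception, match="unphased"):
            dv.effective_haplotype_number(g)

    def test_invariant_under_allele_relabeling(self):
        g = random_matrix(n=10, markers_per_chrom=(20,), seed=21)
        flipped = PhasedGenotypeMatrix(
            individuals=g.individuals, alleles=(1 - g.alleles).astype(np.int8),
            phased=True, gmap=g.gmap,
        )
        _, he_ref = dv.effective_haplotype_number(g)
        _, he_flip = dv.effective_haplotype_number(flipped)
        assert he_flip == pytest.approx(he_ref, rel=1e-12)

    def test_individual_with_missing_call_dropped_from_window_only(self):
        g = random_matrix(n=8, markers_per_chrom=(20,), seed=2)
        alleles = g.alleles.copy()
        alleles[0, 3, 0] = MISSING  # individual 0 leaves window 1 only
        g2 = PhasedGenotypeMatrix(g.individuals, alleles, True, g.gmap)
        table, _ = dv.effective_haplotype_number(g2)
        assert table["n_units"].tolist() == [14, 16]

    def test_diploid_unit_counts_genotype_pairs(self):
        # 4 identical homozygotes: 1 diploid genotype, he = 1 in both units
        rows = [[(0, 0)] * 10] * 4
        _, he_d = dv.effective_haplotype_number(matrix_from_rows(rows), unit="diploid")
        assert he_d == pytest.approx(1.0)
        # two phase orderings of the same unordered genotype are one unit
        a, b = [0] * 10, [1] * 10
        rows = [[(x, y) for x, y in zip(a, b)], [(y, x) for x, y in zip(a, b)]]
        _, he_d = dv.effective_haplotype_number(matrix_from_rows(rows), unit="diploid")
        assert he_d == pytest.approx(1.0)


class TestJackknife:
    def test_sample_of_exactly_subset_size_is_identity(self):
        g = random_matrix(n=16, markers_per_chrom=(20,), seed=4)
        full = dv.expected_heterozygosity(g)[1]
        assert dv.jackknife_match(lambda x: dv.expected_heterozygosity(x)[1], g) == full

    def test_metric_sample_size_returns_subset_size(self):
        g = random_matrix(n=30, markers_per_chrom=(10,), seed=4)
        assert dv.jackknife_match(lambda x: x.n_individuals, g, subset_size=16) == 16.0

    def test_exhaustive_enumeration_matches_combinatorial_mean(self):
        g = random_matrix(n=18, markers_per_chrom=(12,), seed=6)
        metric = lambda x: dv.expected_heterozygosity(x)[1]
        got = dv.jackknife_match(metric, g, subset_size=16, max_subsets=200)
        expected = np.mean(
            [metric(g.subset(list(c))) for c in itertools.combinations(range(18), 16)]
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_fewer_individuals_than_subset_warns_and_uses_full_sample(self):
        g = random_matrix(n=10, markers_per_chrom=(10,), seed=8)
        with pytest.warns(UserWarning, match="full sample"):
            got = dv.jackknife_match(lambda x: x.n_individuals, g, subset_size=16)
        assert got == 10.0


class TestFrequencyChangeCorrelation:
    def _shifted(self, g, delta):
        # build a sample whose frequencies move by ~delta via independent draws
        rng = np.random.default_rng(0)
        p = np.clip(dv.allele_frequencies(g) + delta, 0.0, 1.0)
        alleles = (rng.random((2000, len(p), 2)) < p[None, :, None]).astype(np.int8)
        return PhasedGenotypeMatrix(
            [f"i{k}" for k in range(2000)], alleles, True, g.gmap
        )

    def test_exact_reversal_gives_minus_one(self):
        rng = np.random.default_rng(1)
        gA = random_matrix(n=500, markers_per_chrom=(30,), seed=1)
        pA = dv.allele_frequencies(gA)
        d = rng.uniform(-0.05, 0.05, 30)
        pB, pC = pA + d, pA  # second episode exactly undoes the first

        def exact(p):
            n = 10  # 20 allele calls per marker: frequencies exactly representable?
            counts = np.round(p * 40).astype(int)
            alleles = np.zeros((20, len(p), 2), np.int8)
            for j, c in enumerate(counts):
                flat = np.zeros(40, np.int8)
                flat[:c] = 1
                alleles[:, j, :] = flat.reshape(20, 2)
            return PhasedGenotypeMatrix([f"i{k}" for k in range(20)], alleles, True, gA.gmap)

        a, b, c = exact(pA), exact(pB), exact(pC)
        r = dv.frequency_change_correlation(a, b, c)
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_identical_changes_give_plus_one(self):
        rng = np.random.default_rng(2)
        gA = random_matrix(n=500, markers_per_chrom=(30,), seed=2)
        pA = dv.allele_frequencies(gA)
        d = rng.uniform(0.01, 0.05, 30)

        def exact(p):
            counts = np.round(np.clip(p, 0, 1) * 40).astype(int)
            alleles = np.zeros((20, len(p), 2), np.int8)
            for j, c in enumerate(counts):
                flat = np.zeros(40, np.int8)
                flat[:c] = 1
                alleles[:, j, :] = flat.reshape(20, 2)
            return PhasedGenotypeMatrix([f"i{k}" for k in range(20)], alleles, True, gA.gmap)

        a = exact(pA)
        b = exact(dv.allele_frequencies(a) + d)
        c = exact(dv.allele_frequencies(b) + d)
        r = dv.frequency_change_correlation(a, b, c)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_independent_changes_near_zero_against_permutation(self):
        gA = random_matrix(n=1000, markers_per_chrom=(60,), seed=3)
        gB = self._shifted(gA, np.random.default_rng(4).uniform(-0.05, 0.05, 60))
        gC = self._shifted(gB, np.random.default_rng(5).uniform(-0.05, 0.05, 60))
        r = dv.frequency_change_correlation(gA, gB, gC)
        # permutation null for |r| over 60 markers
        rng = np.random.default_rng(6)
        pA, pB, pC = (dv.allele_frequencies(x) for x in (gA, gB, gC))
        d1, d2 = pB - pA, pC - pB
        null = [
            abs(np.corrcoef(d1, rng.permutation(d2))[0, 1]) for _ in range(500)
        ]
        assert abs(r) < np.quantile(null, 0.99)

    def test_too_few_polymorphic_markers_is_an_error(self):
        g = matrix_from_rows([[(0, 0), (1, 1), (0, 1)]] * 4)
        with pytest.raises(ValueError, match="polymorphic"):
            dv.frequency_change_correlation(g, g, g)


def test_diversity_report_assembles_all_statistics(partial_selfing_sample):
    sample, truth = partial_selfing_sample
    rep = dv.diversity_report(sample, "androdioecious-like", seed=1)
    assert 0 < rep.mean_He <= 0.5
    assert 0 <= rep.mean_Ho <= 1
    assert rep.Fis <= 1
    assert rep.mean_he >= 1
    assert rep.n_markers_used > 0
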