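"""Forensic and population statistics against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apestr.forensic_stats import (
    allele_frequencies,
    bonferroni,
    combined_rmp,
    diversity_increments,
    fis,
    heterozygosity,
    hwe_permutation_test,
    match_probability,
    pe_tpi,
    pic,
)
from oracles import hexp_direct, hobs_direct, pic_double_sum, pm_pairwise


def random_genotypes(rng, n, k):
    p = rng.dirichlet(np.ones(k))
    copies = rng.choice(k, size=2 * n, p=p)
    return [tuple(copies[2 * i : 2 * i + 2]) for i in range(n)]


class TestFrequencies:
    def test_counting(self):
        ft = allele_frequencies([("A", "A"), ("A", "B")])
        assert ft.freqs == {"A": 0.75, "B": 0.25} and ft.n_chrom == 4

    def test_monomorphic(self):
        assert allele_frequencies([("A", "A")] * 3).freqs == {"A": 1.0}

    def test_sampling_error_within_binomial_bound(self, rng):
        p_true = 0.3
        n = 200
        copies = rng.random(2 * n) < p_true
        geno = [(bool(copies[2 * i]), bool(copies[2 * i + 1])) for i in range(n)]
        est = allele_frequencies(geno).freqs.get(True, 0.0)
        bound = 3 * math.sqrt(p_true * (1 - p_true) / (2 * n))
        assert abs(est - p_true) < bound


class TestHeterozygosity:
    def test_all_hom(self):
        assert heterozygosity([("A", "A")] * 5) == (0.0, 0.0)

    def test_two_hets_closed_form(self):
        hobs, hexp = heterozygosity([("A", "B"), ("A", "B")])
        assert hobs == 1.0
        assert hexp == pytest.approx(4 / 3 * 0.5)

    def test_small_sample_hexp_undefined(self):
        assert heterozygosity([("A", "B")])[1] is None

    def test_matches_direct_computation(self, rng):
        for _ in range(50):
            geno = random_genotypes(rng, int(rng.integers(3, 50)), int(rng.integers(2, 10)))
            hobs, hexp = heterozygosity(geno)
            assert hobs == pytest.approx(hobs_direct(geno), abs=1e-12)
            assert hexp == pytest.approx(hexp_direct(geno), abs=1e-12)


class TestPic:
    def test_single_allele(self):
        assert pic([1.0]) == 0.0

    def test_biallelic_half(self):
        assert pic([0.5, 0.5]) == pytest.approx(0.375)

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(200):
            p = rng.dirichlet(np.ones(int(rng.integers(2, 10))))
            assert pic(p) == pytest.approx(pic_double_sum(list(p)), abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=10))
    def test_bounded_by_expected_heterozygosity(self, weights):
        p = np.array(weights) / sum(weights)
        assert pic(p) <= 1.0 - float((p**2).sum()) + 1e-9


class TestMatchProbability:
    def test_identical_cohort(self):
        pm, pd = match_probability([("A", "A")] * 4)
        assert pm == 1.0 and pd == 0.0

    def test_two_genotypes_even(self):
        pm, _ = match_probability([("A", "A"), ("A", "B")])
        assert pm == 0.5

    def test_unordered_comparison(self):
        pm, _ = match_probability([("A", "B"), ("B", "A")])
        assert pm == 1.0

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(200):
            geno = random_genotypes(rng, int(rng.integers(2, 50)), int(rng.integers(2, 8)))
            pm, pd = match_probability(geno)
            assert pm == pytest.approx(pm_pairwise(geno), abs=1e-12)
            assert pd == pytest.approx(1.0 - pm, abs=1e-15)


class TestPeTpi:
    @pytest.mark.parametrize(
        "h,pe,tpi",
        [(0.0, 0.0, 0.5), (0.5, 0.1875, 1.0)],
    )
    def test_closed_forms(self, h, pe, tpi):
        got_pe, got_tpi = pe_tpi(h)
        assert got_pe == pytest.approx(pe) and got_tpi == pytest.approx(tpi)

    def test_full_heterozygosity_boundary(self):
        pe, tpi = pe_tpi(1.0)
        assert pe == pytest.approx(1.0) and tpi is None


class TestCombinedRmp:
    def test_product(self):
        assert combined_rmp([0.1, 0.2]) == pytest.approx(0.02)

    def test_identity_locus(self):
        assert combined_rmp([1.0, 0.25]) == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combined_rmp([])

    def test_never_above_min_pm(self, rng):
        for _ in range(50):
            pms = rng.uniform(0.05, 1.0, int(rng.integers(1, 20)))
            assert combined_rmp(list(pms)) <= pms.min() + 1e-15


class TestFis:
    def test_hwe_equilibrium_zero(self):
        geno = [("A", "B"), ("A", "A"), ("B", "B"), ("A", "B")]
        hobs, hexp = heterozygosity(geno)
        assert fis(geno) == pytest.approx(1 - hobs / hexp)

    def test_all_hom_polymorphic_is_one(self):
        assert fis([("A", "A"), ("B", "B")] * 10) == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        assert fis([("A", "A")] * 10) is None

    @pytest.mark.parametrize("method", ["nei", "wc"])
    def test_inbreeding_recovery(self, rng, method):
        """Simulate genotypes with true F = 0.2 and recover it within 0.05."""
        f_true, n, k = 0.2, 500, 6
        p = np.full(k, 1 / k)
        geno = []
        for _ in range(n):
            if rng.random() < f_true:
                a = rng.choice(k, p=p)
                geno.append((int(a), int(a)))
            else:
                geno.append((int(rng.choice(k, p=p)), int(rng.choice(k, p=p))))
        assert fis(geno, method=method) == pytest.approx(f_true, abs=0.05)


class TestHwePermutation:
    def test_monomorphic_returns_one(self):
        assert hwe_permutation_test([("A", "A")] * 10) == 1.0

    def test_extreme_het_excess_significant(self):
        p = hwe_permutation_test([("A", "B")] * 20, n_perm=10000, seed=7)
        assert p <= 0.01

    def test_hwe_data_not_significant(self, rng):
        geno = random_genotypes(rng, 100, 5)
        assert hwe_permutation_test(geno, n_perm=2000, seed=3) > 0.01

    def test_seed_reproducible(self):
        geno = [("A", "B"), ("A", "A"), ("B", "B")] * 10
        assert hwe_permutation_test(geno, seed=5) == hwe_permutation_test(geno, seed=5)


class TestDiversityIncrements:
    def test_same_length_array_variants(self):
        alleles = [("10", "AAAA", "xAAAAy"), ("10", "AAAT", "xAAATy")]
        assert diversity_increments(alleles) == (1, 2, 2)

    def test_identical_alleles(self):
        assert diversity_increments([("10", "A", "xA")] * 5) == (1, 1, 1)

    def test_flank_variant_counts_only_at_full_layer(self):
        alleles = [("10", "AAAA", "xAAAAy"), ("10", "AAAA", "zAAAAy")]
        assert diversity_increments(alleles) == (1, 1, 2)

    def test_layer_monotonicity(self, rng):
        for _ in range(100):
            alleles = [
                (int(rng.integers(3)), int(rng.integers(5)), int(rng.integers(8)))
                for _ in range(20)
            ]
            n_len, n_arr, n_full = diversity_increments(alleles)
            assert n_len <= n_arr <= n_full


class TestBonferroni:
    def test_single_test(self):
        assert bonferroni([0.01]) == [True]

    def test_family_of_ten(self):
        assert bonferroni([0.01], m=10) == [False]

    def test_family_wise_error_controlled(self, rng):
        hits = 0
        trials = 200
        for _ in range(trials):
            ps = rng.uniform(size=100)
            hits += any(bonferroni(list(ps)))
        assert hits / trials <= 0.08  # alpha 0.05 plus sampling slack
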