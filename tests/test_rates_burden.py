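"""Watterson rate estimation, masks, burden simulation and tail tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retrokit import rates_burden as rb
from retrokit import synthetic_data as syn


class TestHarmonicNumber:
    @pytest.mark.parametrize("k,expected", [(1, 1.0), (3, 1 + 0.5 + 1 / 3)])
    def test_small_values(self, k, expected):
        assert rb.harmonic_number(k) == pytest.approx(expected, abs=1e-12)

    def test_large_value_against_direct_summation(self):
        oracle = sum(1 / i for i in range(1, 5008))
        assert rb.harmonic_number(5007) == pytest.approx(oracle, abs=1e-10)
        assert rb.harmonic_number(5007) == pytest.approx(9.095908, abs=1e-6)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            rb.harmonic_number(0)


class TestMasks:
    def test_uniform_coverage_single_interval(self):
        mask = rb.build_mask({"chr1": np.full(1_000_000, 30.0)})
        assert mask.intervals == {"chr1": [(0, 1_000_000)]}
        assert mask.length == 1_000_000

    def test_low_coverage_empty(self):
        mask = rb.build_mask({"chr1": np.full(10_000, 5.0)})
        assert mask.length == 0

    def test_alternating_blocks(self):
        cov = np.tile(np.concatenate([np.full(100, 20.0), np.full(100, 5.0)]), 50)
        mask = rb.build_mask({"chr1": cov})
        assert mask.length == 5_000
        assert len(mask.intervals["chr1"]) == 50

    def test_combine_subtract(self):
        a = rb.MaskSet({"chr1": [(0, 100)]})
        b = rb.MaskSet({"chr1": [(50, 60)]})
        out = rb.combine_masks([a, b], "subtract")
        assert out.intervals == {"chr1": [(0, 50), (60, 100)]}
        assert out.length == 90

    def test_combine_intersect_with_empty(self):
        a = rb.MaskSet({"chr1": [(0, 100)]})
        assert rb.combine_masks([a, rb.MaskSet({})], "intersect").length == 0

    def test_union_of_adjacent(self):
        a = rb.MaskSet({"chr1": [(0, 50)]})
        b = rb.MaskSet({"chr1": [(50, 100)]})
        assert rb.combine_masks([a, b], "union").intervals == {"chr1": [(0, 100)]}

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            rb.combine_masks([rb.MaskSet({}), rb.MaskSet({})], "xor")

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(0, 500)),
                    max_size=12),
           st.lists(st.tuples(st.integers(0, 500), st.integers(0, 500)),
                    max_size=12))
    def test_interval_algebra_identities(self, ivs_a, ivs_b):
        a = rb.MaskSet({"c": [(min(s, e), max(s, e) + 1) for s, e in ivs_a]})
        b = rb.MaskSet({"c": [(min(s, e), max(s, e) + 1) for s, e in ivs_b]})
        diff = rb.combine_masks([a, b], "subtract")
        back = rb.combine_masks([diff, b], "union")
        union = rb.combine_masks([a, b], "union")
        # (A - B) + B covers A, and lengths are subadditive
        assert rb.combine_masks([back, a], "intersect").length == a.length
        assert union.length <= a.length + b.length
        assert diff.length == a.length - rb.combine_masks([a, b], "intersect").length


class TestWatterson:
    def test_published_cohort_inputs_reproduce_printed_rates(self):
        panel = rb.watterson_mu({"Alu": 8554, "L1": 2047, "SVA": 329},
                              {"Alu": 1.1130e9, "L1": 9.599e8, "SVA": 1.1130e9},
                              n_individuals=2504)
        assert panel.combined_mu == pytest.approx(1.39e-11, abs=0.005e-11)
        assert round(panel.combined_mu, 12) * 1e11 == pytest.approx(1.4, abs=0.05)
        parents = rb.watterson_mu({"Alu": 653, "L1": 107, "SVA": 30},
                              {c: 74.2e6 for c in ("Alu", "L1", "SVA")},
                              n_individuals=17032)
        assert parents.combined_mu == pytest.approx(1.21e-11, abs=0.005e-11)

    def test_no_sites_zero_rate(self):
        est = rb.watterson_mu({"Alu": 0}, {"Alu": 1e9}, 100)
        assert est.combined_mu == 0.0

    def test_zero_length_with_sites_rejected(self):
        with pytest.raises(ValueError):
            rb.watterson_mu({"Alu": 5}, {"Alu": 0.0}, 100)

    def test_parameter_recovery_within_ten_percent(self):
        """Simulate S ~ Poisson(Theta a L) under a known rate; the combined
        estimate stays within 10% relative error across 100 cohorts."""
        mu_true = {"Alu": 1.0e-11, "L1": 2.5e-12, "SVA": 4.0e-13}
        L = {"Alu": 1.0e9, "L1": 0.9e9, "SVA": 1.0e9}
        n, ne = 2504, 10_000
        a = rb.harmonic_number(2 * n - 1)
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(100):
            S = {c: int(rng.poisson(mu_true[c] * 8 * ne * a * L[c]))
                 for c in mu_true}
            est = rb.watterson_mu(S, L, n, Ne=ne)
            truth = sum(mu_true.values())
            errs.append(abs(est.combined_mu - truth) / truth)
        assert float(np.mean(errs)) < 0.10
        assert float(np.median(errs)) < 0.10


class TestExtrapolation:
    def test_genomewide_expectation(self):
        n, per = rb.expected_denovo(1.2e-11, 9738)
        assert n == 677
        n2, per2 = rb.expected_denovo(1.39e-11, 1)
        assert 12 <= per2 <= 14

    def test_zero_rate(self):
        assert rb.expected_denovo(0.0, 100)[0] == 0


class TestPlacementSimulation:
    def test_lambda_matches_compartment_fraction(self, two_chrom_genome):
        fr = two_chrom_genome.compartment_fractions()
        out = rb.simulate_denovo_placements(677, 100, two_chrom_genome, seed=5)
        by_comp = {e.compartment: e for e in out if e.gene_set == "all"}
        for comp in ("exonic", "intronic", "intergenic", "enhancer"):
            lam = by_comp[comp].lam
            expect = 677 * fr[comp]
            mc_se = math.sqrt(max(expect, 1.0) / 100)
            assert abs(lam - expect) < 4 * mc_se
        assert sum(e.lam for e in by_comp.values()) == pytest.approx(677)

    def test_reproducible_for_fixed_seed(self, toy_genome):
        a = rb.simulate_denovo_placements(50, 1, toy_genome, seed=3)
        b = rb.simulate_denovo_placements(50, 1, toy_genome, seed=3)
        assert [(e.compartment, e.lam) for e in a] == \
               [(e.compartment, e.lam) for e in b]

    def test_interval_reconstruction(self):
        lo, hi = rb.lambda_interval(12.3)
        assert round(lo, 1) == 5.4
        assert round(hi, 1) == 19.2

    def test_gene_set_counts_bounded_by_compartment(self, toy_genome):
        subset = set(sorted(toy_genome.genes)[:3])
        out = rb.simulate_denovo_placements(200, 20, toy_genome,
                                            gene_sets={"sub": subset}, seed=9)
        lam = {(e.gene_set, e.compartment): e.lam for e in out}
        assert lam[("sub", "exonic")] <= lam[("all", "exonic")]
        assert lam[("sub", "intronic")] <= lam[("all", "intronic")]


class TestTailProbabilities:
    def test_poisson_examples(self):
        assert rb.poisson_upper_p(0, 5.0) == 1.0
        expected = 1 - math.exp(-1) * (1 + 1 + 0.5)
        assert rb.poisson_upper_p(3, 1.0) == pytest.approx(expected, abs=1e-12)
        # brute-force pmf summation
        lam = 12.3
        brute = sum(math.exp(-lam) * lam ** k / math.factorial(k)
                    for k in range(0, 12))
        assert rb.poisson_upper_p(12, lam) == pytest.approx(1 - brute, abs=1e-12)
        assert rb.poisson_upper_p(12, lam) == pytest.approx(0.5722, abs=1e-4)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 60), st.floats(0.01, 50))
    def test_poisson_matches_bruteforce(self, obs, lam):
        brute = 1 - sum(math.exp(-lam) * lam ** k / math.factorial(k)
                        for k in range(obs))
        assert rb.poisson_upper_p(obs, lam) == pytest.approx(
            max(brute, 0.0), abs=1e-12)

    def test_binomial_examples(self):
        assert rb.binomial_upper_p(4, 6, 0.5) == pytest.approx(22 / 64, abs=1e-12)
        assert rb.binomial_upper_p(0, 6, 0.77) == 1.0
        assert rb.binomial_upper_p(6, 6, 0.0) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 30).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, n),
                            st.floats(0.0, 1.0))))
    def test_binomial_matches_enumeration(self, knp):
        n, k, p = knp
        brute = sum(math.comb(n, i) * p ** i * (1 - p) ** (n - i)
                    for i in range(k, n + 1))
        assert rb.binomial_upper_p(k, n, p) == pytest.approx(brute, abs=1e-12)
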