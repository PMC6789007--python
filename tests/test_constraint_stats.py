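"""Constraint proportions, exact tests against enumeration oracles,
genotype QC and downsampling statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from retrokit import constraint_stats as cs
from retrokit import synthetic_data as syn
from retrokit.rates_burden import harmonic_number


class TestProportions:
    def test_singleton_closed_form(self):
        out = cs.singleton_proportion([1, 1, 1, 1, 2, 3, 5, 2, 9, 4])
        assert out.proportion == pytest.approx(0.4)
        assert out.ci_half_width == pytest.approx(
            1.96 * math.sqrt(0.4 * 0.6 / 10), rel=1e-4)

    def test_all_singletons_zero_width(self):
        out = cs.singleton_proportion([1] * 8)
        assert out.proportion == 1.0 and out.ci_half_width == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.singleton_proportion([])

    def test_neutral_cohort_matches_watterson_expectation(self, toy_genome):
        coh = syn.gen_mei_cohort(toy_genome, 500, {"Alu": 200.0}, seed=7)
        # singletons defined on allele count (one carrier haplotype)
        out = cs.singleton_proportion(
            [r.allele_count for r in coh.records])
        expected = 1 / harmonic_number(2 * 500 - 1)
        assert out.proportion == pytest.approx(expected, rel=0.12)

    def test_pli_proportion(self):
        vals = [0.95] * 5 + [0.1] * 15
        out = cs.pli_proportion(vals)
        assert out.proportion == pytest.approx(0.25)
        assert out.ci_half_width == pytest.approx(
            1.96 * math.sqrt(0.25 * 0.75 / 20), rel=1e-4)
        assert cs.pli_proportion([0.5] * 20).proportion == 0.0

    def test_pli_empty_flagged(self):
        with pytest.warns(UserWarning):
            assert cs.pli_proportion([]) is None

    def test_pooled_proportion_is_weighted_average(self):
        a = [1, 1, 2, 3]
        b = [1, 5, 5, 5, 5, 5]
        pa = cs.singleton_proportion(a).proportion
        pb = cs.singleton_proportion(b).proportion
        pooled = cs.singleton_proportion(a + b).proportion
        assert pooled == pytest.approx((4 * pa + 6 * pb) / 10)

    def test_planted_equal_pli_constraint_indistinguishable(self):
        """Exonic-MEI vs nonsense-SNV high-pLI proportions planted equal:
        the Wald intervals overlap."""
        rng = np.random.default_rng(4)
        true_p = 0.55
        mei = rng.uniform(0.91, 1.0, 40)
        mei[: int(40 * (1 - true_p))] = rng.uniform(0.0, 0.5, int(40 * (1 - true_p)))
        snv = rng.uniform(0.91, 1.0, 400)
        snv[: int(400 * (1 - true_p))] = rng.uniform(0.0, 0.5, int(400 * (1 - true_p)))
        a = cs.pli_proportion(mei)
        b = cs.pli_proportion(snv)
        assert abs(a.proportion - b.proportion) < a.ci_half_width + b.ci_half_width


class TestFisher:
    def test_diagonal_table(self):
        assert cs.fisher_2x2(2, 0, 0, 2) == pytest.approx(1 / 3, abs=1e-12)

    def test_exchangeable_table(self):
        assert cs.fisher_2x2(1, 1, 1, 1) == 1.0

    def test_zero_margin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert cs.fisher_2x2(0, 0, 3, 4) == 1.0

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_matches_enumeration_and_scipy(self, a, b, c, d):
        n, r1, c1 = a + b + c + d, a + b, a + c
        if n == 0 or r1 in (0, n) or c1 in (0, n):
            return
        # brute force: enumerate all tables with the same margins
        p_obs = (math.comb(r1, a) * math.comb(n - r1, c1 - a)) / math.comb(n, c1)
        total = 0.0
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
            pk = (math.comb(r1, k) * math.comb(n - r1, c1 - k)) / math.comb(n, c1)
            if pk <= p_obs * (1 + 1e-9):
                total += pk
        ours = cs.fisher_2x2(a, b, c, d)
        assert ours == pytest.approx(min(total, 1.0), abs=1e-9)
        theirs = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestOrientationBias:
    @pytest.mark.parametrize("sense,anti,chi2,p", [
        (50, 50, 0.0, 1.0),
        (60, 40, 4.0, 0.0455),
        (0, 10, 10.0, 0.00157),
    ])
    def test_closed_form(self, sense, anti, chi2, p):
        c, pv = cs.orientation_bias_test(sense, anti)
        assert c == pytest.approx(chi2, abs=1e-9)
        assert pv == pytest.approx(p, abs=5e-4)


class TestMissingness:
    def test_genotype_thresholds(self):
        gq = np.array([[19, 20, 35]])
        dp = np.array([[30, 7, 30]])
        ad_alt = np.array([[15, 3, 15]])
        ad_ref = np.array([[15, 4, 15]])
        het = np.array([[True, True, True]])
        keep, missing = cs.snv_missingness_filter(gq, dp, ad_alt, ad_ref, het)
        assert missing.tolist() == [[True, True, False]]

    def test_balanced_het_not_missing(self):
        keep, missing = cs.snv_missingness_filter(
            np.array([[99]]), np.array([[30]]), np.array([[15]]),
            np.array([[15]]), np.array([[True]]))
        assert not missing[0, 0] and keep[0]

    def test_extreme_imbalance_missing(self):
        # 30 reads all ref in a het call: binomial p = 2 * 0.5^30 << 0.001
        keep, missing = cs.snv_missingness_filter(
            np.array([[99]]), np.array([[30]]), np.array([[0]]),
            np.array([[30]]), np.array([[True]]))
        assert missing[0, 0]

    def test_variant_dropped_above_half_missing(self):
        n = 100
        gq = np.full((1, n), 99)
        gq[0, :51] = 10           # 51% missing
        keep, _ = cs.snv_missingness_filter(
            gq, np.full((1, n), 30), np.full((1, n), 15),
            np.full((1, n), 15), np.full((1, n), True))
        assert not keep[0]
        gq[0, :51] = 99
        gq[0, :50] = 10           # exactly 50% stays
        keep, _ = cs.snv_missingness_filter(
            gq, np.full((1, n), 30), np.full((1, n), 15),
            np.full((1, n), 15), np.full((1, n), True))
        assert keep[0]

    def test_vqslod_prefilter(self):
        args = (np.full((2, 4), 99), np.full((2, 4), 30), np.full((2, 4), 15),
                np.full((2, 4), 15), np.full((2, 4), True))
        keep, _ = cs.snv_missingness_filter(*args,
                                            vqslod=np.array([-2.5, -2.0]))
        assert keep.tolist() == [False, True]

    def test_order_independent(self):
        rng = np.random.default_rng(1)
        gq = rng.integers(0, 99, (3, 40))
        dp = rng.integers(0, 60, (3, 40))
        alt = rng.integers(0, 30, (3, 40))
        ref = rng.integers(0, 30, (3, 40))
        het = rng.random((3, 40)) < 0.5
        keep, missing = cs.snv_missingness_filter(gq, dp, alt, ref, het)
        perm = rng.permutation(40)
        keep_p, missing_p = cs.snv_missingness_filter(
            gq[:, perm], dp[:, perm], alt[:, perm], ref[:, perm], het[:, perm])
        assert np.array_equal(keep, keep_p)
        assert np.array_equal(missing[:, perm], missing_p)


class TestDownsampling:
    def _carriers(self, seed=0, n_sites=300, n_samples=60, p=0.02):
        rng = np.random.default_rng(seed)
        return rng.random((n_sites, n_samples)) < p

    def test_reference_at_mean_gives_zero(self):
        mat = self._carriers()
        # replay the replicate stream to find its mean, then use that as
        # the "reference" count: z must be ~0
        rng = np.random.default_rng(1)
        counts = [int(mat[:, rng.choice(60, 30, replace=False)].any(axis=1).sum())
                  for _ in range(400)]
        z = cs.downsample_zscore({"Alu": float(np.mean(counts))},
                                 {"Alu": mat}, 30, reps=400, seed=1)
        assert abs(z["Alu"]) < 1e-9

    def test_one_sd_above(self):
        mat = self._carriers(seed=3)
        rng = np.random.default_rng(5)
        counts = [int(mat[:, rng.choice(60, 30, replace=False)].any(axis=1).sum())
                  for _ in range(400)]
        ref = int(round(np.mean(counts) + np.std(counts, ddof=1)))
        z = cs.downsample_zscore({"Alu": ref}, {"Alu": mat}, 30,
                                 reps=400, seed=5)
        assert z["Alu"] == pytest.approx(1.0, abs=0.25)

    def test_full_cohort_subset_degenerate(self):
        mat = self._carriers()
        with pytest.raises(ValueError, match="degenerate"):
            cs.downsample_zscore({"Alu": 10}, {"Alu": mat}, 60, reps=50, seed=2)


class TestExpressionFilter:
    def test_median_threshold(self):
        df = pd.DataFrame({"s1": [0.0, 1.0, 5.0], "s2": [0.0, 1.0, 6.0],
                           "s3": [5.0, 1.0, 7.0]},
                          index=["low", "boundary", "high"])
        kept = cs.median_expression_filter(df)
        assert list(kept) == ["boundary", "high"]   # median >= 1 is inclusive

    def test_all_nan_gene_excluded_with_warning(self):
        df = pd.DataFrame({"s1": [np.nan, 2.0], "s2": [np.nan, 2.0]},
                          index=["empty", "ok"])
        with pytest.warns(UserWarning):
            kept = cs.median_expression_filter(df)
        assert list(kept) == ["ok"]


class TestSummaryArithmetic:
    def test_diagnostic_yield(self):
        per, pct, hw = cs.diagnostic_yield(4, 9738)
        assert per == pytest.approx(2434.5)
        assert pct == pytest.approx(0.0411, abs=1e-3)
        assert hw == pytest.approx(0.04, abs=0.01)

    def test_combined_error_rate(self):
        assert cs.combined_error_rate(649, 541) == pytest.approx(295.05, abs=0.01)
        assert round(cs.combined_error_rate(649, 541)) == 295

    def test_ascertained_fraction(self):
        assert cs.ascertained_fraction(26.6, 1200) == pytest.approx(2.2167, abs=1e-3)
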