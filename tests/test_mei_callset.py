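"""MEI call-set filtering and annotation: low-complexity rule against a
brute-force oracle, hard filters and their ledger, consequence priority,
allele-frequency recomputation, per-individual summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retrokit import mei_callset as mc
from retrokit import synthetic_data as syn


def lc_oracle(seq, min_run=15, max_distinct=2):
    """Enumerate every min_run-mer; N never belongs to a qualifying run."""
    seq = seq.upper()
    for i in range(len(seq) - min_run + 1):
        window = seq[i:i + min_run]
        if "N" in window:
            continue
        if len(set(window)) <= max_distinct:
            return True
    return False


def make_record(genotypes, **kw):
    defaults = dict(site_id="s1", me_class="Alu", chrom="chr1", pos=100,
                    genotypes=np.array(genotypes), filters={"PASS"},
                    split_reads=5, assess=5)
    defaults.update(kw)
    return mc.MeiRecord(**defaults)


class TestLowComplexityFlag:
    @pytest.mark.parametrize("seq,expected", [
        ("A" * 15, True),
        ("GG" + "A" * 15 + "CC", True),
        ("ATATATATATATATA", True),          # 15 bp, two distinct
        ("ACG" * 20, False),                # period 3: any 15-mer has 3 bases
        ("A" * 14, False),                  # one short of the run length
        ("A" * 7 + "N" + "A" * 7, False),   # N breaks runs
    ])
    def test_rule_boundaries(self, seq, expected):
        assert mc.low_complexity_flag(seq) is expected
        assert lc_oracle(seq) is expected

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            mc.low_complexity_flag("ACGTX" + "A" * 20)

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=120))
    def test_matches_bruteforce_oracle(self, seq):
        assert mc.low_complexity_flag(seq) == lc_oracle(seq)

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="AT", min_size=15, max_size=40))
    def test_two_letter_sequences_always_flagged(self, seq):
        assert mc.low_complexity_flag(seq)


class TestCallsetFilters:
    def test_call_rate_boundary(self):
        gts = [0] * 20 + [-1] * 80          # call rate 0.20
        kept, ledger = mc.apply_callset_filters([make_record(gts)], 100)
        assert kept == [] and ledger["call_rate"] == 1
        gts = [1] * 25 + [-1] * 75          # call rate 0.25 passes
        kept, _ = mc.apply_callset_filters([make_record(gts)], 100)
        assert len(kept) == 1

    @pytest.mark.parametrize("sr,retained", [(2, False), (3, True)])
    def test_split_read_boundary(self, sr, retained):
        kept, _ = mc.apply_callset_filters(
            [make_record([1] * 10, split_reads=sr)], 10)
        assert bool(kept) is retained

    @pytest.mark.parametrize("assess,retained", [(2, False), (3, True)])
    def test_assess_boundary(self, assess, retained):
        kept, _ = mc.apply_callset_filters(
            [make_record([1] * 10, assess=assess)], 10)
        assert bool(kept) is retained

    def test_rsd_filter_value_is_allowed(self):
        rec = make_record([1] * 9 + [0], filters={"rSD"}, assess=3, split_reads=5)
        kept, _ = mc.apply_callset_filters([rec], 10)
        assert kept == [rec]

    def test_other_filter_values_removed(self):
        rec = make_record([1] * 10, filters={"PASS", "s25"})
        kept, ledger = mc.apply_callset_filters([rec], 10)
        assert kept == [] and ledger["filter_field"] == 1

    def test_lc_removed_and_attributed_first(self):
        rec = make_record([1] * 10, filters={"PASS", "lc"}, split_reads=0)
        kept, ledger = mc.apply_callset_filters([rec], 10)
        assert kept == []
        assert ledger["lc"] == 1 and ledger["split_reads"] == 0

    def test_idempotent(self, toy_genome):
        coh = syn.gen_mei_cohort(toy_genome, 40, {"Alu": 8.0}, seed=3,
                                 missing_rate=0.1)
        once, ledger1 = mc.apply_callset_filters(coh.records, 40)
        twice, ledger2 = mc.apply_callset_filters(once, 40)
        assert [r.site_id for r in once] == [r.site_id for r in twice]
        assert ledger2["retained"] == len(once)

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            mc.apply_callset_filters([], 0)


class TestLcWindow:
    def test_planted_homopolymer_flagged(self, toy_genome):
        chrom = sorted(toy_genome.chrom_lengths)[0]
        seq = dict(toy_genome.sequence)
        pos = 5000
        seq[chrom] = seq[chrom][:pos + 20] + "A" * 15 + seq[chrom][pos + 35:]
        rec = make_record([1] * 4, chrom=chrom, pos=pos)
        far = make_record([1] * 4, chrom=chrom, pos=pos + 20_000, site_id="s2")
        mc.apply_lc_filter([rec, far], seq)
        assert "lc" in rec.filters
        # the distant record may only be flagged if its own context is LC
        window = seq[chrom][far.pos - 50:far.pos + 51]
        assert ("lc" in far.filters) == mc.low_complexity_flag(window)


class TestConsequence:
    def test_priority_enhancer_over_gene(self):
        from retrokit.genome import GeneModel, ToyGenome
        gene = GeneModel("TX1", "chr1", [(100, 200), (900, 1000)], pli=0.95)
        genome = ToyGenome({"chr1": 10_000}, {"TX1": gene},
                           [("chr1", 400, 600)])  # enhancer inside the intron
        rec = make_record([1], chrom="chr1", pos=500)
        assert mc.annotate_consequence(rec, genome).consequence == "enhancer"
        assert mc.annotate_consequence(
            make_record([1], chrom="chr1", pos=150), genome).consequence == "exonic"
        assert mc.annotate_consequence(
            make_record([1], chrom="chr1", pos=700), genome).consequence == "intronic"
        out = mc.annotate_consequence(make_record([1], chrom="chr1", pos=5000), genome)
        assert out.consequence == "intergenic" and out.gene_id is None

    def test_gene_and_pli_attached(self):
        from retrokit.genome import GeneModel, ToyGenome
        gene = GeneModel("TX1", "chr1", [(100, 200)], pli=0.97)
        genome = ToyGenome({"chr1": 1000}, {"TX1": gene}, [])
        ann = mc.annotate_consequence(make_record([1], pos=150), genome)
        assert ann.gene_id == "TX1" and ann.pli == 0.97

    def test_off_chromosome_rejected(self, toy_genome):
        rec = make_record([1], chrom="chr1", pos=10**9)
        with pytest.raises(ValueError):
            mc.annotate_consequence(rec, toy_genome)

    def test_partition_over_cohort(self, toy_genome):
        coh = syn.gen_mei_cohort(toy_genome, 30, {"Alu": 10.0}, seed=6)
        ann = mc.annotate_records(coh.records, toy_genome)
        assert len(ann) == len(coh.records)
        assert ann["consequence"].isin(
            ["enhancer", "exonic", "intronic", "intergenic"]).all()


class TestAlleleFrequency:
    def test_simple_het(self):
        rec = make_record([1] + [0] * 99)
        assert mc.recompute_af(rec) == pytest.approx(0.005)

    def test_missing_excluded_from_denominator(self):
        rec = make_record([1] + [0] * 49 + [-1] * 50)
        assert mc.recompute_af(rec) == pytest.approx(0.01)

    def test_all_ref_is_zero(self):
        assert mc.recompute_af(make_record([0] * 10)) == 0.0

    def test_all_missing_flagged(self):
        with pytest.raises(ValueError, match="missing"):
            mc.recompute_af(make_record([-1] * 5))

    def test_subset_af(self):
        rec = make_record([2, 1, 0, 0])
        assert mc.recompute_af(rec, subset=[0, 1]) == pytest.approx(0.75)


class TestCountSummary:
    def test_generator_truth_recovered(self, toy_genome):
        coh = syn.gen_mei_cohort(toy_genome, 400, {"Alu": 23.6}, seed=2,
                                 max_af=0.05)
        summary = mc.per_individual_count_summary(coh.records, 400)
        alu = summary[summary["class"] == "Alu"].iloc[0]
        se = alu["sd_per_individual"] / np.sqrt(400)
        assert abs(alu["mean_per_individual"] - 23.6) < 3 * se
        assert alu["poisson_gof_p"] > 0.01

    def test_single_individual_sd_zero(self):
        rec = make_record([1])
        with pytest.warns(UserWarning, match="single individual"):
            summary = mc.per_individual_count_summary([rec], 1)
        assert (summary["sd_per_individual"] == 0).all()

    def test_gof_non_rejection_rate_for_poisson_totals(self):
        # direct Poisson(33.0) draws: the fit should accept >= 95% of seeds
        rejections = 0
        for seed in range(40):
            counts = np.random.default_rng(seed).poisson(33.0, size=300)
            _, p = mc.poisson_gof(counts)
            rejections += p < 0.01
        assert rejections <= 2
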