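"""Post-discovery filtering and annotation of mobile-element-insertion calls.

Operates on MELT-style VCF records for the three active human ME classes
(Alu, L1, SVA): a low-complexity-context flag, hard call-set filters
(call rate, split-read support, ASSESS score, FILTER column), the
single-consequence annotation rule with enhancer priority, allele-frequency
recomputation that accounts for missing genotypes, and per-individual
count summaries with a Poisson goodness-of-fit check.

Genotypes are encoded as integers: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ToyGenome

ME_CLASSES = ("Alu", "L1", "SVA")

GT_REF, GT_HET, GT_HOM, GT_MISSING = 0, 1, 2, -1

# Call-set filter defaults
MIN_CALL_RATE = 0.25
MIN_SPLIT_READS = 3          # "<= 2 split reads ... were filtered"
MIN_ASSESS = 3               # "ASSESS score < 3 ... filtered"
ALLOWED_FILTERS = frozenset({"PASS", "rSD"})
LC_MIN_RUN = 15              # run length defining a low-complexity repeat
LC_MAX_DISTINCT = 2          # "composed of two or fewer nucleotides"
LC_FLANK = 50                # variants internal or adjacent (+/- 50 bp)

# Fixed attribution order for the filter ledger
FILTER_ORDER = ("lc", "call_rate", "split_reads", "assess", "filter_field")


@dataclass
class MeiRecord:
    """One MEI site with caller annotations and cohort genotypes."""

    site_id: str
    me_class: str
    chrom: str
    pos: int                      # 0-based internally; VCF I/O converts
    genotypes: np.ndarray         # int array over cohort samples
    filters: Set[str] = field(default_factory=lambda: {"PASS"})
    split_reads: int = 0
    assess: int = 5
    insert_length: Optional[int] = None
    orientation: Optional[str] = None   # sense/antisense vs containing gene

    def __post_init__(self) -> None:
        if self.me_class not in ME_CLASSES:
            raise ValueError(f"unknown ME class {self.me_class!r}")
        if not 0 <= self.assess <= 5:
            raise ValueError("ASSESS must be in [0, 5]")
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        bad = ~np.isin(self.genotypes, (GT_REF, GT_HET, GT_HOM, GT_MISSING))
        if bad.any():
            raise ValueError("genotypes must be in {-1, 0, 1, 2}")

    @property
    def call_rate(self) -> float:
        return float(np.mean(self.genotypes != GT_MISSING))

    @property
    def carrier_count(self) -> int:
        return int(np.sum(self.genotypes > 0))

    @property
    def allele_count(self) -> int:
        g = self.genotypes
        return int(np.sum(g[g > 0]))


@dataclass
class ConsequenceAnnotation:
    consequence: str                      # enhancer|exonic|intronic|intergenic
    gene_id: Optional[str] = None
    pli: Optional[float] = None


def low_complexity_flag(window_sequence: str,
                        min_run: int = LC_MIN_RUN,
                        max_distinct: int = LC_MAX_DISTINCT) -> bool:
    """True iff the window contains a run of >= ``min_run`` bp composed of
    <= ``max_distinct`` distinct nucleotides.

    The window is the reference sequence spanning the insertion point
    +/- 50 bp. ``N`` is permitted in the window but breaks runs (a
    qualifying run must be all A/C/G/T). Any other symbol is an error.
    """
    seq = window_sequence.upper()
    if any(c not in "ACGTN" for c in seq):
        bad = sorted({c for c in seq if c not in "ACGTN"})
        raise ValueError(f"non-ACGTN symbols in window: {bad}")
    n = len(seq)
    if n < min_run:
        return False
    # sliding window of fixed length with nucleotide counts
    for segment in seq.split("N"):
        m = len(segment)
        if m < min_run:
            continue
        counts = {c: 0 for c in "ACGT"}
        distinct = 0
        for i, c in enumerate(segment):
            if counts[c] == 0:
                distinct += 1
            counts[c] += 1
            if i >= min_run:
                out = segment[i - min_run]
                counts[out] -= 1
                if counts[out] == 0:
                    distinct -= 1
            if i >= min_run - 1 and distinct <= max_distinct:
                return True
    return False


def apply_lc_filter(records: Iterable[MeiRecord],
                    reference: Dict[str, str],
                    flank: int = LC_FLANK) -> None:
    """Add ``lc`` to FILTER of records in low-complexity context (in place)."""
    for rec in records:
        seq = reference[rec.chrom]
        lo = max(0, rec.pos - flank)
        hi = min(len(seq), rec.pos + flank + 1)
        if low_complexity_flag(seq[lo:hi]):
            rec.filters.add("lc")


def apply_callset_filters(records: Sequence[MeiRecord],
                          cohort_size: int,
                          min_call_rate: float = MIN_CALL_RATE,
                          min_split_reads: int = MIN_SPLIT_READS,
                          min_assess: int = MIN_ASSESS,
                          allowed_filters: frozenset = ALLOWED_FILTERS,
                          ) -> Tuple[List[MeiRecord], Dict[str, int]]:
    """Hard call-set filters; returns (retained records, removal ledger).

    A record is retained iff: no ``lc`` flag, call rate >= 25%, split-read
    support >= 3, ASSESS >= 3, and FILTER is a subset of {PASS, rSD}. Each
    removed record is attributed to its first failing criterion in the
    fixed order lc, call_rate, split_reads, assess, filter_field.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    ledger = {k: 0 for k in FILTER_ORDER}
    ledger["retained"] = 0
    kept: List[MeiRecord] = []
    for rec in records:
        non_lc = rec.filters - {"lc"}
        if "lc" in rec.filters:
            ledger["lc"] += 1
        elif rec.call_rate < min_call_rate:
            ledger["call_rate"] += 1
        elif rec.split_reads < min_split_reads:
            ledger["split_reads"] += 1
        elif rec.assess < min_assess:
            ledger["assess"] += 1
        elif not non_lc <= allowed_filters:
            ledger["filter_field"] += 1
        else:
            ledger["retained"] += 1
            kept.append(rec)
    return kept, ledger


def annotate_consequence(record: MeiRecord, genome: ToyGenome,
                         ) -> ConsequenceAnnotation:
    """Single consequence with priority enhancer > exonic > intronic >
    intergenic; gene id and pLI attached for genic hits."""
    comp, gene = genome.compartment_of(record.chrom, record.pos)
    if gene is not None:
        return ConsequenceAnnotation(comp, gene.transcript_id, gene.pli)
    return ConsequenceAnnotation(comp)


def annotate_records(records: Sequence[MeiRecord], genome: ToyGenome,
                     ) -> pd.DataFrame:
    rows = []
    for rec in records:
        ann = annotate_consequence(rec, genome)
        rows.append({"site_id": rec.site_id, "me_class": rec.me_class,
                     "chrom": rec.chrom, "pos": rec.pos,
                     "consequence": ann.consequence, "gene_id": ann.gene_id,
                     "pli": ann.pli})
    return pd.DataFrame(rows)


def recompute_af(record: MeiRecord,
                 subset: Optional[Sequence[int]] = None) -> float:
    """Allele frequency over a sample subset, excluding missing genotypes.

    AF = alt allele count / (2 x non-missing diploid samples). Raises if
    every genotype in the subset is missing.
    """
    g = record.genotypes if subset is None else record.genotypes[np.asarray(subset)]
    called = g != GT_MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError(f"{record.site_id}: all genotypes missing in subset")
    return float(np.sum(g[called & (g > 0)])) / (2 * n_called)


def poisson_gof(counts: Sequence[int], mean: Optional[float] = None,
                min_expected: float = 5.0) -> Tuple[float, float]:
    """Chi-square goodness of fit of integer counts against Poisson.

    Bins 0..max are merged from the tail (and head) until every expected
    bin count is >= ``min_expected``; degrees of freedom are
    (bins - 1 - 1) when the mean is estimated from the data. Returns
    (chi2, p). With fewer than 2 usable bins returns (0.0, 1.0).
    """
    counts = np.asarray(counts, dtype=int)
    lam = float(counts.mean()) if mean is None else float(mean)
    n = counts.size
    kmax = int(counts.max()) if n else 0
    support = np.arange(kmax + 1)
    probs = stats.poisson.pmf(support, lam)
    probs = np.append(probs, stats.poisson.sf(kmax, lam))  # tail bin
    obs = np.append(np.bincount(counts, minlength=kmax + 1), 0)
    exp = probs * n
    # merge adjacent bins until all expected >= min_expected
    merged_obs: List[float] = []
    merged_exp: List[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            merged_obs.append(acc_o)
            merged_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and merged_exp:
        merged_obs[-1] += acc_o
        merged_exp[-1] += acc_e
    if len(merged_exp) < 2:
        return 0.0, 1.0
    dof = len(merged_exp) - 1 - (1 if mean is None else 0)
    dof = max(dof, 1)
    chi2 = float(np.sum((np.array(merged_obs) - np.array(merged_exp)) ** 2
                        / np.array(merged_exp)))
    return chi2, float(stats.chi2.sf(chi2, dof))


def per_individual_count_summary(records: Sequence[MeiRecord],
                                 n_samples: int) -> pd.DataFrame:
    """Per-class mean +/- SD of sites per individual and Poisson GOF p.

    A sample "has" a site if genotyped het or hom. Returns one row per ME
    class plus a combined ``Total`` row. With a single individual the SD is
    reported as 0 (there is no between-individual spread to estimate).
    """
    import warnings
    rows = []
    per_class = {c: np.zeros(n_samples, dtype=int) for c in ME_CLASSES}
    for rec in records:
        per_class[rec.me_class] += (rec.genotypes > 0).astype(int)
    total = sum(per_class.values())
    for label, counts in [*per_class.items(), ("Total", total)]:
        if n_samples <= 1:
            warnings.warn("single individual: SD reported as 0")
            sd = 0.0
        else:
            sd = float(np.std(counts, ddof=1))
        chi2, p = poisson_gof(counts)
        rows.append({"class": label, "total_sites":
                     int(sum(r.carrier_count > 0 for r in records
                             if label in (r.me_class, "Total"))),
                     "mean_per_individual": float(np.mean(counts)),
                     "sd_per_individual": sd,
                     "poisson_gof_p": p})
    return pd.DataFrame(rows)
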