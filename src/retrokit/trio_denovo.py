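"""Trio de novo candidate identification, mosaicism statistics and
long-read phasing of insertions to nearby heterozygous SNVs.

A candidate de novo insertion is genotyped heterozygous in a single
proband and homozygous reference in both parents, and (by default) is
carried by no one else in the cohort. Apparent de novos can instead be
false-negative parental genotypes from low-level mosaicism; the allelic
proportion (fraction of reads supporting the insertion allele), a z-test
of per-locus hom-ref allelic proportions against the cohort, and a
Kolmogorov-Smirnov comparison of read-start distributions assess that
possibility. Phasing counts per-read co-occurrence of the insertion with
the alleles of the nearest heterozygous SNV to assign parental origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .mei_callset import GT_HET, GT_MISSING, GT_REF

ORIGIN_CONSISTENCY = 0.90  # fraction of insertion-bearing reads that must agree


@dataclass
class TrioCall:
    """Genotypes and site read counts for one site in one trio."""

    site_id: str
    trio_id: str
    proband_gt: int
    father_gt: int
    mother_gt: int
    alt_reads: Dict[str, int] = field(default_factory=dict)  # member -> count
    ref_reads: Dict[str, int] = field(default_factory=dict)


def find_candidate_denovos(calls: Sequence[TrioCall],
                           other_carrier_sites: Optional[Set[str]] = None,
                           require_unique: bool = True) -> List[TrioCall]:
    """Sites het in exactly one proband with hom-ref parents.

    ``calls`` covers all trios in the cohort (one TrioCall per site x
    trio). With ``require_unique`` (default) a site carried by any other
    cohort member — another proband, a parent, or anyone listed in
    ``other_carrier_sites`` — is excluded. Sites with a missing parental
    genotype are excluded (logged via the returned list simply omitting
    them).
    """
    by_site: Dict[str, List[TrioCall]] = {}
    for c in calls:
        by_site.setdefault(c.site_id, []).append(c)
    out: List[TrioCall] = []
    for site_id, site_calls in by_site.items():
        candidates = []
        other_carriers = other_carrier_sites is not None and site_id in other_carrier_sites
        for c in site_calls:
            if c.father_gt == GT_MISSING or c.mother_gt == GT_MISSING:
                continue
            if (c.proband_gt == GT_HET and c.father_gt == GT_REF
                    and c.mother_gt == GT_REF):
                candidates.append(c)
            elif c.proband_gt > 0 or c.father_gt > 0 or c.mother_gt > 0:
                other_carriers = True
        if len(candidates) == 1 and (not require_unique or not other_carriers):
            out.extend(candidates)
        elif len(candidates) > 1 and not require_unique:
            out.extend(candidates)
    return sorted(out, key=lambda c: (c.site_id, c.trio_id))


def allelic_proportion(alt: int, ref: int) -> float:
    """Fraction of reads supporting the insertion allele, alt/(alt+ref)."""
    if alt < 0 or ref < 0:
        raise ValueError("read counts must be >= 0")
    if alt + ref == 0:
        raise ValueError("zero depth: allelic proportion undefined")
    return alt / (alt + ref)


def mosaic_locus_ztest(locus_homref_props: Sequence[float],
                       cohort_loci_means: Sequence[float],
                       ) -> Tuple[float, float]:
    """One-sample z-test of a locus's mean hom-ref allelic proportion
    against the cohort distribution of per-locus means.

    An elevated mean allelic proportion among hom-ref genotypes at a locus
    indicates systematic genotyping/sequencing error there rather than
    genuine mosaicism. Returns (z, two-sided p).
    """
    locus = np.asarray(locus_homref_props, dtype=float)
    null = np.asarray(cohort_loci_means, dtype=float)
    if null.size < 2:
        raise ValueError("need >= 2 cohort loci to form the null distribution")
    sd = float(np.std(null, ddof=1))
    # guard includes float residue from numerically identical values
    if sd <= 1e-12 * max(1.0, abs(float(null.mean()))):
        raise ValueError("zero variance in the cohort null distribution")
    z = (float(locus.mean()) - float(null.mean())) / sd
    p = 2 * float(stats.norm.sf(abs(z)))
    return z, p


def read_start_ks(starts_a: Sequence[float], starts_b: Sequence[float],
                  ) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test of read-start distributions
    (read starts within +/- 250 bp of the insertion site in two samples).
    Asymptotic p-value."""
    a = np.asarray(starts_a, dtype=float)
    b = np.asarray(starts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both start-site samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class PhaseCount:
    """Per-read phase tallies of an insertion against one het SNV."""

    snv_id: str
    mei_snv: int = 0        # insertion-bearing read carrying the SNV alt
    mei_ref: int = 0        # insertion-bearing read carrying the SNV ref
    nomei_snv: int = 0
    nomei_ref: int = 0
    origin: str = "unknown"  # father | mother | unknown


def phase_mei_to_snv(reads: Iterable[Tuple[bool, str]],
                     snv_id: str,
                     ref_allele: str,
                     alt_allele: str,
                     father_alleles: Set[str],
                     mother_alleles: Set[str],
                     consistency: float = ORIGIN_CONSISTENCY,
                     ) -> PhaseCount:
    """Tally the four read phases (MEI+SNV+, MEI+SNV-, MEI-SNV+, MEI-SNV-)
    and infer parental origin.

    ``reads`` yields (insertion_present, snv_allele) per long read. Origin
    is assigned when >= ``consistency`` of insertion-bearing reads carry
    one SNV allele AND that allele is unique to one parent; a phased
    allele present in both parents leaves the origin unknown.
    """
    pc = PhaseCount(snv_id=snv_id)
    mei_allele_counts: Dict[str, int] = {}
    for mei_present, allele in reads:
        if allele not in (ref_allele, alt_allele):
            continue  # sequencing error at the SNV position
        is_alt = allele == alt_allele
        if mei_present:
            pc.mei_snv += is_alt
            pc.mei_ref += not is_alt
            mei_allele_counts[allele] = mei_allele_counts.get(allele, 0) + 1
        else:
            pc.nomei_snv += is_alt
            pc.nomei_ref += not is_alt
    n_mei = pc.mei_snv + pc.mei_ref
    if n_mei == 0:
        raise ValueError("no insertion-bearing reads: cannot phase")
    top_allele, top_n = max(mei_allele_counts.items(), key=lambda kv: kv[1])
    if top_n / n_mei < consistency:
        return pc  # ambiguous phase
    in_father = top_allele in father_alleles
    in_mother = top_allele in mother_alleles
    if in_father and not in_mother:
        pc.origin = "father"
    elif in_mother and not in_father:
        pc.origin = "mother"
    return pc
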