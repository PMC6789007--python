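"""Synthetic fixtures with the statistical structure the pipeline assumes.

Everything the toolkit consumes can be generated here, seeded and
deterministic: a toy annotated genome, read pairs spanning
retroduplication junctions, cohort insertion call sets with a neutral
site-frequency spectrum and Poisson per-individual counts, trios with
planted de novo events and mosaic parents, and methylation beta matrices
with planted differential CpGs.

Defaults mirror the study conditions the pipeline was built for: Alu/L1/
SVA per-parent means of 23.6 / 2.8 / 0.2, neutral (1/i) allele-frequency
spectrum, insert sizes around 350 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genome import GeneModel, ToyGenome
from .mei_callset import GT_HET, GT_HOM, GT_REF, ME_CLASSES, MeiRecord
from .ppg_caller import ReadPairObservation
from .rates_burden import harmonic_number
from .trio_denovo import TrioCall

#: Mean insertion sites per unaffected parent by class (the modelled cohort)
DEFAULT_CLASS_MEANS = {"Alu": 23.6, "L1": 2.8, "SVA": 0.2}
DEFAULT_READ_LEN = 100
DEFAULT_INSERT_MEAN = 350
DEFAULT_INSERT_SD = 35
_PLACEMENT_RETRIES = 200


class PlacementError(RuntimeError):
    """Raised when features cannot be placed after bounded retries."""


# --------------------------------------------------------------------------
# Toy genome
# --------------------------------------------------------------------------

def gen_toy_genome(n_chrom: int = 1,
                   chrom_len: int = 1_000_000,
                   n_genes: int = 10,
                   seed: int = 0,
                   n_enhancers: Optional[int] = None,
                   exons_per_gene: Tuple[int, int] = (3, 8),
                   exon_len: Tuple[int, int] = (100, 300),
                   intron_len: Tuple[int, int] = (500, 3000),
                   enhancer_len: Tuple[int, int] = (200, 800),
                   with_sequence: bool = True) -> ToyGenome:
    """Deterministic toy genome with non-overlapping genes and enhancers.

    Genes carry a pLI drawn uniformly (so pLI-based filters and
    proportions are exercised); exons are ordered and non-overlapping;
    enhancers fall strictly in intergenic space. Raises
    :class:`PlacementError` if a feature cannot be placed after bounded
    retries (genome too small for the request).
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = {f"chr{i + 1}": int(chrom_len) for i in range(n_chrom)}
    chroms = sorted(chrom_lengths)
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}

    def place(span: int) -> Tuple[str, int]:
        for _ in range(_PLACEMENT_RETRIES):
            chrom = chroms[rng.integers(len(chroms))]
            if chrom_lengths[chrom] <= span:
                continue
            start = int(rng.integers(0, chrom_lengths[chrom] - span))
            if all(e <= start or s >= start + span for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + span))
                return chrom, start
        raise PlacementError(f"could not place a {span} bp feature after "
                             f"{_PLACEMENT_RETRIES} retries")

    genes: Dict[str, GeneModel] = {}
    for gi in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        ex_lens = rng.integers(exon_len[0], exon_len[1] + 1, size=n_ex)
        in_lens = rng.integers(intron_len[0], intron_len[1] + 1, size=max(0, n_ex - 1))
        span = int(ex_lens.sum() + in_lens.sum())
        chrom, start = place(span)
        exons = []
        pos = start
        for i, el in enumerate(ex_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el) + (int(in_lens[i]) if i < len(in_lens) else 0)
        tid = f"TX{gi + 1:04d}"
        genes[tid] = GeneModel(tid, chrom, exons,
                               strand="+" if rng.random() < 0.5 else "-",
                               pli=float(np.round(rng.random(), 4)))

    if n_enhancers is None:
        n_enhancers = max(2, n_genes // 2) if n_genes else 2
    enhancers = []
    for _ in range(n_enhancers):
        span = int(rng.integers(enhancer_len[0], enhancer_len[1] + 1))
        chrom, start = place(span)
        enhancers.append((chrom, start, start + span))

    sequence = None
    if with_sequence:
        bases = np.array(list("ACGT"))
        sequence = {c: "".join(rng.choice(bases, size=chrom_lengths[c]))
                    for c in chroms}
    return ToyGenome(chrom_lengths, genes, enhancers, sequence)


# --------------------------------------------------------------------------
# PPG read sets
# --------------------------------------------------------------------------

def gen_ppg_readset(genome: ToyGenome,
                    donor_gene: str,
                    n_drp: int = 6,
                    n_srp: int = 2,
                    n_background: int = 500,
                    insert_mean: int = DEFAULT_INSERT_MEAN,
                    seed: int = 0,
                    sample: str = "S0",
                    insert_sd: int = DEFAULT_INSERT_SD,
                    read_len: int = DEFAULT_READ_LEN,
                    ) -> List[ReadPairObservation]:
    """Read pairs for one sample carrying (or not) a retroduplication.

    Emits exactly ``n_drp`` pairs whose mates fall in different exons of
    the donor with apparent insert size far above the background
    distribution, ``n_srp`` split reads spanning an exon-exon junction,
    and ``n_background`` concordant pairs drawn Normal(insert_mean,
    insert_sd) placed away from exon-pair-linking configurations.
    """
    if donor_gene not in genome.genes:
        raise KeyError(f"unknown donor gene {donor_gene!r}")
    gene = genome.genes[donor_gene]
    if (n_drp > 0 or n_srp > 0) and gene.n_exons < 2:
        raise ValueError(f"{donor_gene}: donor needs >= 2 exons")
    rng = np.random.default_rng(seed)
    reads: List[ReadPairObservation] = []
    counter = 0

    def exon_segment(exon: Tuple[int, int]) -> Tuple[int, int]:
        s, e = exon
        seg_len = min(read_len, e - s)
        off_max = (e - s) - seg_len
        off = int(rng.integers(0, off_max + 1)) if off_max > 0 else 0
        return s + off, s + off + seg_len

    # evidence pairs: mates in two different exons; apparent insert spans
    # the intervening intron(s), so it dwarfs the concordant distribution
    pairs = [(i, j) for i in range(gene.n_exons) for j in range(i + 1, gene.n_exons)]
    for k in range(n_drp):
        i, j = pairs[k % len(pairs)]
        s1, e1 = exon_segment(gene.exons[i])
        s2, e2 = exon_segment(gene.exons[j])
        reads.append(ReadPairObservation(sample, gene.chrom, s1, e1,
                                         gene.chrom, s2, e2,
                                         insert_size=e2 - s1, is_split=False,
                                         name=f"drp{counter}"))
        counter += 1
    for k in range(n_srp):
        i, j = pairs[k % len(pairs)]
        # split read: two segments abutting the junction boundaries
        s1, e1 = gene.exons[i][1] - min(read_len // 2, gene.exons[i][1] - gene.exons[i][0]), gene.exons[i][1]
        s2 = gene.exons[j][0]
        e2 = s2 + min(read_len // 2, gene.exons[j][1] - s2)
        reads.append(ReadPairObservation(sample, gene.chrom, s1, e1,
                                         gene.chrom, s2, e2,
                                         insert_size=e2 - s1, is_split=True,
                                         name=f"srp{counter}"))
        counter += 1

    chroms = sorted(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(n_background):
        for _attempt in range(_PLACEMENT_RETRIES):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            insert = max(2 * read_len + 1,
                         int(rng.normal(insert_mean, insert_sd)))
            start = int(rng.integers(0, max(1, genome.chrom_lengths[chrom] - insert)))
            s1, e1 = start, start + read_len
            e2 = start + insert
            s2 = e2 - read_len
            obs = ReadPairObservation(sample, chrom, s1, e1, chrom, s2, e2,
                                      insert_size=insert, is_split=False,
                                      name=f"bg{counter}")
            # background must not itself link two exons of one transcript
            hits = [g for g in genome.genes_overlapping(chrom, s1, e2)
                    if g.exon_index_overlapping(s1, e1) is not None
                    and g.exon_index_overlapping(s2, e2) is not None
                    and g.exon_index_overlapping(s1, e1) != g.exon_index_overlapping(s2, e2)]
            if not hits:
                reads.append(obs)
                counter += 1
                break
        else:
            raise PlacementError("could not place a background pair")
    return reads


def gen_ppg_cohort_readsets(genome: ToyGenome,
                            donor_gene: str,
                            carriers: Sequence[str],
                            non_carriers: Sequence[str],
                            seed: int = 0,
                            n_drp: int = 6,
                            n_srp: int = 2,
                            n_background: int = 400,
                            ) -> List[ReadPairObservation]:
    """Cohort of read sets: carriers get planted retroduplication evidence,
    non-carriers background only."""
    reads: List[ReadPairObservation] = []
    rng = np.random.default_rng(seed)
    for s in carriers:
        reads.extend(gen_ppg_readset(genome, donor_gene, n_drp=n_drp,
                                     n_srp=n_srp, n_background=n_background,
                                     seed=int(rng.integers(2 ** 31)), sample=s))
    for s in non_carriers:
        reads.extend(gen_ppg_readset(genome, donor_gene, n_drp=0, n_srp=0,
                                     n_background=n_background,
                                     seed=int(rng.integers(2 ** 31)), sample=s))
    return reads


# --------------------------------------------------------------------------
# MEI cohorts
# --------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """A simulated insertion cohort with full truth bookkeeping."""

    samples: List[str]
    records: List[MeiRecord]
    trios: List[Tuple[str, str, str]] = field(default_factory=list)  # proband, father, mother
    denovo_sites: List[str] = field(default_factory=list)
    mosaic_parents: Dict[str, float] = field(default_factory=dict)   # sample -> cell fraction
    class_means: Dict[str, float] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    def per_individual_counts(self, me_class: Optional[str] = None) -> np.ndarray:
        counts = np.zeros(len(self.samples), dtype=int)
        for rec in self.records:
            if me_class is None or rec.me_class == me_class:
                counts += (rec.genotypes > 0).astype(int)
        return counts


def _spectrum_support(n_hap: int, sfs: str, max_af: float,
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Allele-count support and weights of the requested spectrum.

    ``max_af`` truncates the spectrum at a maximum population allele
    frequency: 1.0 keeps the full neutral spectrum (the Watterson model's
    analytic truth); a small value emulates a call set dominated by rare,
    recent insertions, for which per-individual site counts are Poisson.
    """
    cmax = max(1, min(n_hap - 1, int(np.floor(max_af * n_hap))))
    support = np.arange(1, cmax + 1)
    if sfs == "neutral":
        w = 1.0 / support
    elif sfs == "uniform":
        w = np.ones_like(support, dtype=float)
    else:
        raise ValueError(f"unknown spectrum {sfs!r}")
    return support, w


def _spectrum_counts(n_sites: int, n_hap: int, sfs: str,
                     rng: np.random.Generator,
                     max_af: float = 1.0) -> np.ndarray:
    """Site allele counts composed from the requested frequency spectrum.

    The composition is *systematic* (mid-stratum points over the
    cumulative distribution, shuffled): the spectrum shape is preserved
    exactly up to rounding, and the realized total allele count — hence
    the cohort mean — does not inherit the enormous variance of iid draws
    from this heavy-tailed law. Randomness enters through genotype
    allocation and site placement, not the composition.
    """
    support, w = _spectrum_support(n_hap, sfs, max_af)
    cdf = np.cumsum(w) / w.sum()
    points = (np.arange(n_sites) + 0.5) / n_sites
    counts = support[np.searchsorted(cdf, points)]
    return rng.permutation(counts)


def expected_carrier_fraction(n_hap: int, sfs: str = "neutral",
                              max_af: float = 1.0) -> float:
    """Expected probability, under the spectrum, that one diploid founder
    carries a segregating site (used to calibrate sites-per-individual).

    For a site with allele count c distributed over n_hap haplotypes, an
    individual's two haplotypes both miss it with probability
    (n_hap - c)(n_hap - c - 1) / (n_hap (n_hap - 1)).
    """
    support, w = _spectrum_support(n_hap, sfs, max_af)
    p_carry = 1.0 - ((n_hap - support) * (n_hap - support - 1)
                     / (n_hap * (n_hap - 1)))
    return float(np.sum(w * p_carry) / np.sum(w))


def gen_mei_cohort(genome: ToyGenome,
                   n_individuals: int,
                   class_means: Optional[Mapping[str, float]] = None,
                   n_trios: int = 0,
                   n_denovo: int = 0,
                   sfs: str = "neutral",
                   seed: int = 0,
                   missing_rate: float = 0.0,
                   max_af: float = 1.0,
                   n_mosaic: int = 0,
                   mosaic_fraction: float = 0.5,
                   ) -> SimulatedCohort:
    """Simulated MEI cohort with per-individual Poisson site counts.

    Founders (parents and unrelated individuals) receive genotypes by
    distributing each site's allele count uniformly over founder
    haplotypes; trio probands inherit one haplotype from each parent, so
    Mendelian structure holds. Planted de novo sites are het in a single
    proband and absent from all other genotypes. ``class_means`` are mean
    sites per founder (defaults: Alu 23.6, L1 2.8, SVA 0.2); the number of
    sites per class is calibrated against the spectrum's expected carrier
    fraction so the realized per-founder mean matches the request.

    With the full neutral spectrum (``max_af=1.0``, the Watterson model's
    analytic truth) common variants make per-individual counts mildly
    underdispersed relative to Poisson; a truncated spectrum
    (e.g. ``max_af=0.05``), emulating a call set dominated by rare recent
    insertions, yields Poisson counts.
    """
    if class_means is None:
        class_means = DEFAULT_CLASS_MEANS
    if n_individuals < 0 or n_trios < 0 or n_denovo < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)

    probands = [f"P{i:04d}" for i in range(n_trios)]
    fathers = [f"F{i:04d}" for i in range(n_trios)]
    mothers = [f"M{i:04d}" for i in range(n_trios)]
    n_unrelated = max(0, n_individuals - 3 * n_trios)
    unrelated = [f"U{i:04d}" for i in range(n_unrelated)]
    samples = probands + fathers + mothers + unrelated
    founders = fathers + mothers + unrelated
    trios = list(zip(probands, fathers, mothers))

    cohort = SimulatedCohort(samples=samples, records=[], trios=trios,
                             class_means=dict(class_means))
    if not samples:
        if n_denovo:
            raise ValueError("cannot plant de novos in an empty cohort")
        return cohort
    n_founders = len(founders)
    if n_founders == 0:
        raise ValueError("cohort must contain founders")
    n_hap = 2 * n_founders
    if n_denovo > n_trios:
        raise ValueError("more planted de novos than trios")

    sample_index = {s: i for i, s in enumerate(samples)}
    founder_offset = len(probands)

    chroms = sorted(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    def random_position() -> Tuple[str, int]:
        ci = rng.choice(len(chroms), p=probs)
        return chroms[ci], int(rng.integers(0, genome.chrom_lengths[chroms[ci]]))

    site_counter = 0
    for cls in ME_CLASSES:
        mean = float(class_means.get(cls, 0.0))
        if mean <= 0:
            continue
        if n_hap < 2:
            raise ValueError("need >= 1 founder pair for polymorphic sites")
        # calibrate the site count against the realized composition: pick
        # the S whose systematic composition has expected carrier mean
        # closest to the requested per-founder mean
        p_carry = expected_carrier_fraction(n_hap, sfs, max_af)
        s_guess = max(1, int(round(mean / p_carry)))
        support, _w = _spectrum_support(n_hap, sfs, max_af)
        carry_of = 1.0 - ((n_hap - support) * (n_hap - support - 1)
                          / (n_hap * (n_hap - 1)))
        carry_lut = dict(zip(support.tolist(), carry_of.tolist()))
        best_s, best_err = s_guess, float("inf")
        for s_try in range(max(1, s_guess - 5), s_guess + 6):
            comp = _spectrum_counts(s_try, n_hap, sfs,
                                    np.random.default_rng(0), max_af)
            err = abs(sum(carry_lut[int(c)] for c in comp) - mean)
            if err < best_err:
                best_s, best_err = s_try, err
        n_sites = best_s
        counts = _spectrum_counts(n_sites, n_hap, sfs, rng, max_af)
        for c in counts:
            hap_carriers = set(int(h) for h in
                               rng.choice(n_hap, size=int(c), replace=False))
            founder_gt = np.zeros(n_founders, dtype=int)
            for h in hap_carriers:
                founder_gt[h // 2] += 1
            genotypes = np.zeros(len(samples), dtype=int)
            genotypes[founder_offset:] = founder_gt
            # probands inherit one random haplotype from each parent
            for t, (p, f, m) in enumerate(trios):
                hap_f = int(rng.integers(2))
                hap_m = int(rng.integers(2))
                fa = sample_index[f] - founder_offset
                mo = sample_index[m] - founder_offset
                carry = int(2 * fa + hap_f in hap_carriers)
                carry += int(2 * mo + hap_m in hap_carriers)
                genotypes[sample_index[p]] = carry
            if missing_rate > 0:
                miss = rng.random(len(samples)) < missing_rate
                genotypes[miss] = -1
            chrom, pos = random_position()
            site_counter += 1
            cohort.records.append(MeiRecord(
                site_id=f"{cls}_{site_counter:05d}", me_class=cls,
                chrom=chrom, pos=pos, genotypes=genotypes,
                filters={"PASS"}, split_reads=int(rng.integers(3, 12)),
                assess=5,
                insert_length=int(rng.integers(80, 6000))))

    # planted de novos: het in one proband, absent everywhere else.
    # The first n_mosaic of them additionally mark the trio's father as a
    # low-level mosaic carrier (truth only: his genotype stays hom-ref, as
    # for the apparent-de-novo / mosaic-parent scenario).
    if n_mosaic > n_denovo:
        raise ValueError("n_mosaic cannot exceed n_denovo")
    if n_denovo:
        chosen = rng.choice(n_trios, size=n_denovo, replace=False)
        for k, t in enumerate(chosen):
            genotypes = np.zeros(len(samples), dtype=int)
            genotypes[sample_index[probands[t]]] = GT_HET
            chrom, pos = random_position()
            site_counter += 1
            cls = str(rng.choice(["Alu", "Alu", "Alu", "L1"]))  # Alu-dominated
            rec = MeiRecord(site_id=f"DN_{cls}_{site_counter:05d}", me_class=cls,
                            chrom=chrom, pos=pos, genotypes=genotypes,
                            filters={"PASS"}, split_reads=int(rng.integers(3, 12)),
                            assess=5, insert_length=int(rng.integers(80, 6000)))
            cohort.records.append(rec)
            cohort.denovo_sites.append(rec.site_id)
            if k < n_mosaic:
                cohort.mosaic_parents[fathers[t]] = mosaic_fraction
    return cohort


def trio_calls_from_cohort(cohort: SimulatedCohort,
                           depth: int = 30,
                           seed: int = 0,
                           error_rate: float = 0.0) -> List[TrioCall]:
    """TrioCall objects (genotypes + binomial read counts) for every
    (site, trio) pair in a simulated cohort.

    Het genotypes draw alt reads Binomial(depth, 0.5); hom-ref genotypes
    Binomial(depth, error_rate); mosaic parents (cohort.mosaic_parents,
    sample -> cell fraction m) draw Binomial(depth, m / 2) at de novo
    sites while staying genotyped hom-ref.
    """
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(cohort.samples)}
    out: List[TrioCall] = []
    for rec in cohort.records:
        for t, (p, f, m) in enumerate(cohort.trios):
            alt: Dict[str, int] = {}
            ref: Dict[str, int] = {}
            for member in (p, f, m):
                gt = int(rec.genotypes[idx[member]])
                if gt == GT_HET:
                    a = int(rng.binomial(depth, 0.5))
                elif gt == GT_HOM:
                    a = int(rng.binomial(depth, 1 - error_rate))
                elif (member in cohort.mosaic_parents
                      and rec.site_id in cohort.denovo_sites):
                    a = int(rng.binomial(depth, cohort.mosaic_parents[member] / 2))
                else:
                    a = int(rng.binomial(depth, error_rate)) if error_rate else 0
                alt[member] = a
                ref[member] = depth - a
            out.append(TrioCall(rec.site_id, f"T{t:04d}",
                                proband_gt=int(rec.genotypes[idx[p]]),
                                father_gt=int(rec.genotypes[idx[f]]),
                                mother_gt=int(rec.genotypes[idx[m]]),
                                alt_reads=alt, ref_reads=ref))
    return out


def simulate_allelic_depths(n: int, depth: int, cell_fraction: float,
                            seed: int = 0) -> pd.DataFrame:
    """Alt/ref read counts for ``n`` observations of a mosaic carrier.

    A cell fraction m puts the insertion on one chromosome of a fraction m
    of cells, so the expected allelic proportion is m / 2.
    """
    rng = np.random.default_rng(seed)
    alt = rng.binomial(depth, cell_fraction / 2, size=n)
    return pd.DataFrame({"alt": alt, "ref": depth - alt})


# --------------------------------------------------------------------------
# Methylation beta matrices
# --------------------------------------------------------------------------

def gen_beta_matrix(n_cpg: int,
                    n_case: int,
                    n_control: int,
                    n_signature: int,
                    effect: float = 0.30,
                    noise_sd: float = 0.05,
                    seed: int = 0,
                    ) -> Tuple[pd.DataFrame, pd.Series, List[str]]:
    """Beta matrix (CpG x sample) with planted differential CpGs.

    Signature CpGs differ between groups by ``effect`` in expectation (sign
    chosen away from the [0, 1] boundary so clipping does not attenuate
    the planted effect); all other CpGs are exchangeable between groups.
    Returns (betas, labels, signature CpG ids).
    """
    if not 0 <= effect <= 1:
        raise ValueError("effect must be in [0, 1]")
    if n_signature > n_cpg:
        raise ValueError("more signature CpGs than CpGs")
    rng = np.random.default_rng(seed)
    cpgs = [f"cg{i:07d}" for i in range(n_cpg)]
    samples = ([f"case{i:03d}" for i in range(n_case)]
               + [f"ctrl{i:03d}" for i in range(n_control)])
    labels = pd.Series(["case"] * n_case + ["control"] * n_control,
                       index=samples)
    base = rng.uniform(0.15, 0.85, size=n_cpg)
    sig_idx = rng.choice(n_cpg, size=n_signature, replace=False)
    shift = np.zeros(n_cpg)
    # hypo- or hyper-methylate whichever direction has headroom
    shift[sig_idx] = np.where(base[sig_idx] < 0.5, effect, -effect)
    means = np.tile(base[:, None], (1, len(samples)))
    means[:, :n_case] += shift[:, None] @ np.ones((1, n_case))
    betas = means + rng.normal(0.0, noise_sd, size=means.shape)
    betas = np.clip(betas, 0.0, 1.0)
    df = pd.DataFrame(betas, index=cpgs, columns=samples)
    return df, labels, [cpgs[i] for i in sorted(sig_idx)]
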