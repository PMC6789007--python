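"""Mutation-rate estimation and genome-wide de novo burden simulation.

The insertion mutation rate per class (Alu, L1, SVA) is estimated with the
Watterson estimator: for n diploid individuals (2n haplotypes), S
segregating sites over L accessible bp,

    Theta = S / (a_{2n-1} * L),   a_k = sum_{i=1..k} 1/i

and, with effective population size Ne and the diploid-site normalisation,

    mu = Theta / (8 * Ne)

per bp per generation. Combined mu sums the per-class rates. The extra
factor of two relative to the textbook theta = 4*Ne*mu arises because S is
counted against diploid individuals' accessible territory; this
normalisation reproduces both published whole-cohort reconstructions from
their printed inputs, which was the criterion for adopting it.

Expected genome-wide de novo counts follow by extrapolation
(mu x 2 x haploid genome length x births), and compartment-level
expectations by placing that many events uniformly at random and
annotating each with the single-consequence rule (enhancer priority).
Poisson and exact binomial tail tests compare observed counts with the
simulated expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from . import intervals as iv
from .genome import COMPARTMENTS, ToyGenome

DEFAULT_NE = 10_000
#: ungapped GRCh37 primary-assembly haploid length (bp)
HAPLOID_GENOME_LENGTH = 2.8973e9
#: diploid-site Watterson normalisation: mu = Theta / (THETA_TO_MU_FACTOR * Ne)
THETA_TO_MU_FACTOR = 8


def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1..k} 1/i by direct summation."""
    if k < 1:
        raise ValueError("harmonic number defined for k >= 1")
    return float(np.sum(1.0 / np.arange(1, k + 1)))


@dataclass
class MaskSet:
    """Accessible-territory interval set (merged, half-open, 0-based)."""

    intervals: iv.IntervalDict
    classes: Tuple[str, ...] = ()     # ME classes this mask applies to

    def __post_init__(self) -> None:
        self.intervals = iv.merge_dict(self.intervals)

    @property
    def length(self) -> int:
        return iv.total_length(self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        look = iv.IntervalLookup(self.intervals.get(chrom, []))
        return pos in look


def build_mask(coverage_track: Mapping[str, np.ndarray],
               threshold: float = 10.0,
               classes: Tuple[str, ...] = ()) -> MaskSet:
    """Accessibility mask from a per-base mean-coverage track.

    Keeps maximal runs where mean cohort coverage >= ``threshold``
    (the >= 10x accessibility criterion).
    """
    out: iv.IntervalDict = {}
    for chrom, cov in coverage_track.items():
        cov = np.asarray(cov, dtype=float)
        ok = cov >= threshold
        if not ok.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], ok, [False]))))
        out[chrom] = [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]
    return MaskSet(out, classes=classes)


def combine_masks(masks: Sequence[MaskSet], mode: str) -> MaskSet:
    """Interval algebra over masks: ``intersect`` | ``subtract`` | ``union``.

    ``subtract`` removes every subsequent mask from the first.
    """
    if not masks:
        raise ValueError("no masks given")
    acc = masks[0].intervals
    for m in masks[1:]:
        if mode == "intersect":
            acc = iv.intersect(acc, m.intervals)
        elif mode == "union":
            acc = iv.union(acc, m.intervals)
        elif mode == "subtract":
            acc = iv.subtract(acc, m.intervals)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return MaskSet(acc, classes=masks[0].classes)


@dataclass
class RateEstimate:
    """Watterson Theta and mu with the inputs that produced them."""

    S: Dict[str, int]
    L: Dict[str, float]
    n_individuals: int
    Ne: int
    harmonic: float
    theta: Dict[str, float] = field(default_factory=dict)
    mu: Dict[str, float] = field(default_factory=dict)

    @property
    def combined_mu(self) -> float:
        return float(sum(self.mu.values()))


def watterson_mu(S_per_class: Mapping[str, int],
                 L_per_class: Mapping[str, float],
                 n_individuals: int,
                 Ne: int = DEFAULT_NE) -> RateEstimate:
    """Per-class and combined Watterson mutation-rate estimate.

    Theta_c = S_c / (a_{2n-1} * L_c) over 2n haplotypes;
    mu_c = Theta_c / (8 * Ne). Combined mu is the sum over classes.
    """
    if n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    a = harmonic_number(2 * n_individuals - 1)
    est = RateEstimate(S=dict(S_per_class), L=dict(L_per_class),
                       n_individuals=n_individuals, Ne=Ne, harmonic=a)
    for cls, S in S_per_class.items():
        L = float(L_per_class[cls])
        if L <= 0:
            if S > 0:
                raise ValueError(f"{cls}: S > 0 with zero accessible length")
            est.theta[cls] = 0.0
            est.mu[cls] = 0.0
            continue
        theta = S / (a * L)
        est.theta[cls] = theta
        est.mu[cls] = theta / (THETA_TO_MU_FACTOR * Ne)
    return est


def expected_denovo(mu: float, births: int,
                    haploid_genome_len: float = HAPLOID_GENOME_LENGTH,
                    ) -> Tuple[int, float]:
    """Expected genome-wide de novo insertions for a number of births.

    Each birth samples two haploid genomes, so the expectation is
    mu x 2 x haploid length x births (rounded to the nearest integer).
    Also returns births-per-event, 1 / (mu x 2 x haploid length); zero
    rate yields (0, inf).
    """
    if births <= 0 or haploid_genome_len <= 0:
        raise ValueError("births and genome length must be positive")
    per_birth = mu * 2 * haploid_genome_len
    if per_birth == 0:
        return 0, float("inf")
    return int(round(per_birth * births)), 1.0 / per_birth


@dataclass
class CompartmentExpectation:
    """Simulated Poisson expectation for one compartment / gene set."""

    compartment: str
    gene_set: str
    lam: float
    ci_low: float
    ci_high: float
    observed: Optional[int] = None
    poisson_p: Optional[float] = None


def lambda_interval(lam: float, alpha: float = 0.05,
                    method: str = "normal",
                    rep_counts: Optional[Sequence[int]] = None,
                    ) -> Tuple[float, float]:
    """95% interval on a simulated Poisson mean.

    ``normal``: lam +/- 1.96 * sqrt(lam) (the reconstruction used for the
    published interval); ``percentile``: empirical percentiles of the
    per-replicate counts.
    """
    if method == "normal":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(lam)
        return float(lam - half), float(lam + half)
    if method == "percentile":
        if rep_counts is None:
            raise ValueError("percentile method needs rep_counts")
        lo, hi = np.percentile(rep_counts, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(lo), float(hi)
    raise ValueError(f"unknown method {method!r}")


def simulate_denovo_placements(n_events: int,
                               reps: int,
                               genome: ToyGenome,
                               gene_sets: Optional[Mapping[str, Set[str]]] = None,
                               seed: int = 0,
                               observed: Optional[Mapping[Tuple[str, str], int]] = None,
                               ci_method: str = "normal",
                               ) -> List[CompartmentExpectation]:
    """Uniform random placement of ``n_events`` de novo insertions,
    ``reps`` times, annotated with the single-consequence rule.

    Returns one expectation per (gene set x compartment); gene set "all"
    counts every event, a named gene set counts only exonic/intronic
    events in its genes. ``observed`` maps (gene_set, compartment) to an
    observed count; a Poisson upper-tail p is then attached.
    """
    if n_events < 1 or reps < 1:
        raise ValueError("n_events and reps must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    cum = np.cumsum(lengths)
    total = cum[-1]
    sets = {"all": None, **(dict(gene_sets) if gene_sets else {})}
    counts = {(gs, comp): np.zeros(reps, dtype=int)
              for gs in sets for comp in COMPARTMENTS}
    for r in range(reps):
        flat = rng.uniform(0, total, size=n_events)
        idx = np.searchsorted(cum, flat, side="right")
        for f, i in zip(flat, idx):
            chrom = chroms[i]
            pos = int(f - (cum[i] - lengths[i]))
            comp, gene = genome.compartment_of(chrom, pos)
            counts[("all", comp)][r] += 1
            if gene is not None:
                for gs, members in sets.items():
                    if members is not None and gene.transcript_id in members:
                        counts[(gs, comp)][r] += 1
    out: List[CompartmentExpectation] = []
    for (gs, comp), reps_counts in counts.items():
        lam = float(reps_counts.mean())
        lo, hi = lambda_interval(lam, method=ci_method, rep_counts=reps_counts)
        exp = CompartmentExpectation(comp, gs, lam, lo, hi)
        if observed is not None and (gs, comp) in observed:
            exp.observed = int(observed[(gs, comp)])
            exp.poisson_p = poisson_upper_p(exp.observed, lam)
        out.append(exp)
    return out


def poisson_upper_p(observed: int, lam: float) -> float:
    """P(X >= observed) under Poisson(lam) — the upper-tail enrichment p."""
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))


def binomial_upper_p(k: int, n: int, p: float) -> float:
    """Exact P(X >= k | n, p) — e.g. the chance that k of n exonic de novo
    insertions land in a gene set covering fraction p of the exome."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))
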