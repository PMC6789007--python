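"""Selective-constraint metrics, enrichment tests and cohort QC statistics.

Two complementary constraint measures are used to compare insertion
classes against SNV consequence classes: the proportion of variants seen
in exactly one individual (singletons — enriched under purifying
selection) and the proportion of variants falling in loss-of-function-
intolerant genes (pLI > 0.9 — depleted under purifying selection).
Also here: Fisher's exact test for donor-gene enrichment, a chi-square
orientation-bias test, the SNV genotype "missingness" QC filter, the
downsampling z-score cohort comparison, and a median-expression filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

HIGH_PLI = 0.9
WALD_Z = 1.959963984540054  # two-sided 95%

# genotype missingness thresholds
MIN_GQ = 20
MIN_DP = 8
MIN_AD_P = 0.001
MAX_MISSING_FRACTION = 0.5   # "more than 50% ... filtered"
MIN_VQSLOD = -2.0


@dataclass
class ConstraintSummary:
    label: str
    count: int
    proportion: float
    ci_half_width: float

    @property
    def ci(self) -> Tuple[float, float]:
        return (self.proportion - self.ci_half_width,
                self.proportion + self.ci_half_width)


def proportion_ci(k: int, n: int, z: float = WALD_Z) -> Tuple[float, float]:
    """Wald (normal-approximation) proportion estimate and CI half-width."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = k / n
    return p, z * float(np.sqrt(p * (1 - p) / n))


def singleton_proportion(carrier_counts: Sequence[int],
                         label: str = "") -> ConstraintSummary:
    """Proportion of variants carried by exactly one individual, with a
    Wald 95% CI based on the population proportion."""
    counts = np.asarray(carrier_counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty variant set")
    k = int(np.sum(counts == 1))
    p, hw = proportion_ci(k, counts.size)
    return ConstraintSummary(label, counts.size, p, hw)


def pli_proportion(pli_values: Sequence[float],
                   label: str = "",
                   threshold: float = HIGH_PLI) -> Optional[ConstraintSummary]:
    """Proportion of variants inside LoF-intolerant (pLI > 0.9) genes.

    Input is the pLI of the containing gene for each variant (restricted
    beforehand to variants inside genes with a defined pLI). An empty set
    returns None with a warning.
    """
    vals = np.asarray([v for v in pli_values if v is not None and not np.isnan(v)])
    if vals.size == 0:
        warnings.warn(f"{label or 'variant set'}: no pLI-annotated variants")
        return None
    k = int(np.sum(vals > threshold))
    p, hw = proportion_ci(k, vals.size)
    return ConstraintSummary(label, vals.size, p, hw)


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]] by
    hypergeometric enumeration: the sum of probabilities of all tables
    with the same margins whose probability does not exceed the observed
    table's. A zero margin makes every table equally (certainly) likely;
    p = 1 with a warning."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 table (zero margin): p = 1")
        return 1.0
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    # relative tolerance guards against floating-point ties
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))
    return 1.0 if p > 1 - 1e-9 else p


def orientation_bias_test(sense: int, antisense: int) -> Tuple[float, float]:
    """Chi-square goodness of fit of sense/antisense counts against 50:50
    (1 df); tests insertion-orientation bias within genes."""
    if sense < 0 or antisense < 0:
        raise ValueError("counts must be >= 0")
    n = sense + antisense
    if n == 0:
        raise ValueError("no oriented insertions")
    chi2, p = stats.chisquare([sense, antisense], [n / 2, n / 2])
    return float(chi2), float(p)


def _binom_two_sided_half(alt: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial(0.5) p for alt successes out of total.

    With p = 0.5 the distribution is symmetric, so the two-sided p is
    min(1, 2 * min(lower tail, upper tail))."""
    lower = stats.binom.cdf(alt, total, 0.5)
    upper = stats.binom.sf(alt - 1, total, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def snv_missingness_filter(gq: np.ndarray,
                           dp: np.ndarray,
                           ad_alt: np.ndarray,
                           ad_ref: np.ndarray,
                           is_het: np.ndarray,
                           vqslod: Optional[np.ndarray] = None,
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """SNV genotype-level QC: per-genotype missing flags and variant keep mask.

    Arrays are (n_variants, n_samples); ``vqslod`` is per-variant. A
    genotype is missing if GQ < 20, DP < 8, or (for heterozygous calls)
    the exact two-sided binomial allele-balance p < 0.001. Homozygous
    calls are judged on GQ/DP only. A variant is dropped if more than 50%
    of genotypes are missing, or if it fails the site-level prefilter
    VQSLOD >= -2.0. Returns (variant_keep, genotype_missing).
    """
    gq = np.asarray(gq)
    dp = np.asarray(dp)
    ad_alt = np.asarray(ad_alt)
    ad_ref = np.asarray(ad_ref)
    is_het = np.asarray(is_het, dtype=bool)
    missing = (gq < MIN_GQ) | (dp < MIN_DP)
    total = ad_alt + ad_ref
    with np.errstate(invalid="ignore"):
        ad_p = _binom_two_sided_half(ad_alt, np.maximum(total, 1))
    missing |= is_het & (total > 0) & (ad_p < MIN_AD_P)
    keep = missing.mean(axis=1) <= MAX_MISSING_FRACTION
    if vqslod is not None:
        keep &= np.asarray(vqslod) >= MIN_VQSLOD
    return keep, missing


def downsample_zscore(observed_reference: Mapping[str, int],
                      carriers: Mapping[str, np.ndarray],
                      subset_size: int,
                      reps: int = 1000,
                      seed: int = 0) -> Dict[str, float]:
    """Cohort-downsampling z-score per ME class.

    ``carriers[cls]`` is a boolean (n_sites, n_samples) matrix. For each
    replicate, ``subset_size`` samples are drawn without replacement and
    the number of sites segregating in the subset is counted;
    z = (reference count - mean) / SD of the replicate distribution.
    Compares an external reference call set with the cohort's expectation
    at matched sample size.
    """
    rng = np.random.default_rng(seed)
    out: Dict[str, float] = {}
    for cls, mat in carriers.items():
        mat = np.asarray(mat, dtype=bool)
        n_samples = mat.shape[1]
        if subset_size > n_samples:
            raise ValueError("subset_size exceeds cohort size")
        counts = np.empty(reps, dtype=int)
        for r in range(reps):
            sel = rng.choice(n_samples, size=subset_size, replace=False)
            counts[r] = int(mat[:, sel].any(axis=1).sum())
        sd = float(np.std(counts, ddof=1))
        if sd == 0:
            raise ValueError(f"{cls}: degenerate downsampling distribution "
                             "(SD = 0); subset equals the full cohort?")
        out[cls] = (observed_reference[cls] - float(counts.mean())) / sd
    return out


def median_expression_filter(expression: pd.DataFrame,
                             threshold: float = 1.0) -> pd.Index:
    """Genes whose median expression across samples is >= ``threshold``
    (median RPKM >= 1 defines fetal-brain-expressed genes).

    Genes with no expression values are excluded with a warning.
    """
    if expression.empty:
        raise ValueError("empty expression matrix")
    medians = expression.median(axis=1, skipna=True)
    all_nan = expression.isna().all(axis=1)
    if all_nan.any():
        warnings.warn(f"{int(all_nan.sum())} genes with no expression values "
                      "excluded")
    return expression.index[(medians >= threshold) & ~all_nan]


# --- printed-summary arithmetic helpers -----------------------------------

def diagnostic_yield(diagnoses: int, births: int) -> Tuple[float, float, float]:
    """Diagnostic yield of a variant class in a cohort.

    Returns (cases-per-diagnosis, percent yield, Wald 95% CI half-width in
    percent): e.g. 4 diagnoses in 9738 probands is one per ~2434 cases,
    0.04% +/- 0.04%.
    """
    if diagnoses < 0 or births <= 0:
        raise ValueError("need diagnoses >= 0 and births > 0")
    p, hw = proportion_ci(diagnoses, births)
    return births / max(diagnoses, 1), 100 * p, 100 * hw


def combined_error_rate(*rates_per_n: float) -> float:
    """Combine per-patient error rates given as "1 in N" denominators.

    Independent error sources at 1/n_1, 1/n_2, ... combine to a single
    rate of 1 in 1/(sum 1/n_i): e.g. false positives at 1/649 and false-
    negative parental genotypes at 1/541 give one error per ~295 patients.
    Returns the combined denominator N.
    """
    total = sum(1.0 / n for n in rates_per_n)
    if total == 0:
        raise ValueError("no error sources")
    return 1.0 / total


def ascertained_fraction(mean_observed: float, genomewide_mean: float) -> float:
    """Percent of an individual's genome-wide variants ascertained by a
    targeted assay: e.g. 26.6 exome insertions of ~1200 genome-wide is
    ~2.2%."""
    if genomewide_mean <= 0:
        raise ValueError("genome-wide mean must be positive")
    return 100.0 * mean_observed / genomewide_mean
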