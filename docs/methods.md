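# Methods

This note documents the models behind each component, the parameter
defaults and why they hold their values, what the synthetic generators do
and do not emulate, and the numerical choices that matter for
reproducibility.

## Processed-pseudogene detection

A processed pseudogene retains the donor transcript's exon–exon junctions
but not its introns. In hybridisation-capture sequencing, fragments from
the retrocopy are pulled down by the donor gene's baits, so they align to
the donor with two signatures: mate pairs landing in *different exons of
the same transcript* with an apparent insert size inflated by the missing
intron (discordant read pairs, DRPs), and reads split across an exon–exon
boundary absent from the reference (split reads, SRPs).

Decision rules (all configurable, defaults in `PipelineConfig`):

* Step 1 flags a gene in an individual at **> 4** exon-linking DRPs whose
  insert size exceeds the sample's **99.5th-percentile** (nearest-rank)
  insert size. Only genes with a defined pLI annotation are iterated.
* Step 2 pools junction evidence across all step-1-positive individuals
  and genotypes everyone: positive at **DRP + SRP ≥ 5** with **≥ 1** of
  each.

*Insert-size null.* The percentile is estimated from the sample's
background pairs — pairs that do not themselves link two exons of one
transcript. On realistic read counts this is indistinguishable from the
all-pairs percentile (evidence pairs are a vanishing fraction); on small
simulated read sets it prevents the handful of evidence pairs from
inflating their own threshold, which would otherwise make the caller's
behaviour depend on fixture size rather than on the rules above.

Exon assignment uses any overlap (≥ 1 bp) between a mate's aligned span
and an exon. Duplicate fragments (identical coordinates, both mates) are
counted once. Fragments whose mates hit exons of two *different*
transcripts are not evidence for either. Insertion-site localisation is
not attempted: capture evidence identifies the donor gene, not the
integration point, so two independent retrocopies of the same donor are
indistinguishable here.

## MEI call-set filtering

Filters applied to MELT-style VCF records, in the fixed ledger order
lc → call rate → split reads → ASSESS → FILTER (each removed record is
attributed to its first failing criterion, making ledger counts
reproducible):

| filter | rule | default |
|---|---|---|
| lc | run of ≥ 15 bp with ≤ 2 distinct nucleotides within ± 50 bp | flagged |
| call rate | genotyped fraction of cohort ≥ 0.25 | drop below |
| split reads | ≥ 3 supporting split reads | drop ≤ 2 |
| ASSESS | caller assessment score ≥ 3 | drop < 3 |
| FILTER | subset of {PASS, rSD} | drop others |

The low-complexity scan covers the reference flank only (101 bp window);
whether the inserted element's own sequence should be scanned is exposed
as the window the caller passes in, not guessed. `N` is allowed in a
window but breaks runs. Call-rate denominators count all cohort samples,
missing genotypes included.

Consequence annotation retains a single consequence per variant with
priority **enhancer > exonic > intronic > intergenic**; gene id and pLI
ride along for genic hits. Recomputed allele frequencies divide the alt
allele count by 2 × (non-missing samples).

## Trio de novo and mosaicism

A candidate de novo insertion is heterozygous in exactly one proband,
homozygous reference in both parents, and carried by nobody else in the
cohort (the uniqueness requirement is configurable; genuinely recurrent
insertions would fail it). Sites with a missing parental genotype are
excluded rather than guessed.

An apparent de novo can instead be a parental mosaic missed by
genotyping. Three statistics assess this:

* **Allelic proportion** alt/(alt+ref) per site and member. A parent
  mosaic in a fraction *m* of cells has expectation *m*/2.
* **Locus z-test**: the mean allelic proportion among hom-ref genotypes
  at the locus is compared against the cohort distribution of per-locus
  hom-ref means (one-sample z, two-sided normal p; sample SD, ddof = 1).
  The underlying published analysis does not fully specify the test; the
  one-sample-against-cohort-distribution reading is implemented and
  frozen here.
* **Read-start KS**: two-sample Kolmogorov–Smirnov on read start
  positions within ± 250 bp of the insertion, asymptotic p (start counts
  are hundreds, where the asymptotic and exact distributions agree).

Phasing tallies, per long read, the four insertion × SNV-allele
configurations at the nearest heterozygous SNV. Parental origin is
assigned when ≥ 90 % of insertion-bearing reads carry one SNV allele and
that allele is unique to one parent. The 90 % consistency level is this
package's choice — it tolerates ~1 chimeric/error read in 10 while
refusing genuinely ambiguous phases.

## Mutation rate and burden

The Watterson estimator treats each insertion class as an infinite-sites
locus of length *L* (the accessible territory for that class):
θ̂ = S / (a₂ₙ₋₁·L) over 2n haplotypes, and μ̂ = θ̂ / (8Nₑ) with
Nₑ = 10,000. The conversion carries a factor 2 beyond the textbook
θ = 4Nₑμ because *S* is counted against diploid individuals' accessible
territory; this diploid-site normalisation is the convention that
reproduces both published whole-cohort rate reconstructions from their
printed inputs (verified independently before implementation — see
`THETA_TO_MU_FACTOR`), so it is fixed as a named constant rather than an
option.

The default haploid genome length is 2.8973 Gbp (ungapped GRCh37 primary
assembly), consistent with the published genome-wide extrapolation;
it is configurable. The SVA class reuses the *Alu* accessibility mask, as
its callable territory matches *Alu*'s.

Burden simulation places the extrapolated number of events uniformly at
random, annotates each with the single-consequence rule, and averages
compartment counts over replicates (default 100) to give Poisson λ per
compartment and gene set. The 95 % interval on λ defaults to the normal
approximation λ ± 1.96√λ — the reconstruction that matches the published
interval — with an empirical percentile-of-replicates alternative.
Uniform placement deliberately ignores local sequence preference
(endonuclease-motif hotspots); it is the neutral null, not an insertion
model. Enrichment uses exact tails: P(X ≥ k) under Poisson(λ), and an
exact binomial for "k of n exonic events in a gene set covering fraction
p of the exome".

## Constraint and QC statistics

Singleton proportion (carrier count = 1) and high-pLI proportion
(pLI > 0.9) carry Wald intervals p̂ ± 1.96·√(p̂(1−p̂)/N) — adequate at the
variant counts involved (hundreds), chosen over Wilson/Jeffreys to match
the published population-proportion intervals. Fisher's exact test is
computed by full hypergeometric enumeration (two-sided: sum of table
probabilities ≤ the observed one, with a 1 + 10⁻⁹ relative tolerance
against floating-point ties). Orientation bias is a 1-df χ² against
50:50.

SNV genotype "missingness" QC: a genotype is missing at GQ < 20, DP < 8,
or — for heterozygous calls — an exact two-sided binomial(0.5)
allele-balance p < 0.001; homozygous calls are judged on GQ/DP only
(balance testing against 0.5 is meaningless for them; an error-rate test
would need a calibrated error model, which is out of scope). Variants
drop at > 50 % missing genotypes or site-level VQSLOD < −2.0.

The downsampling z-score draws subsets of the cohort (default 1000
replicates) without replacement, counts segregating sites per subset, and
standardises an external reference count against that distribution.

## Methylation episignature

Per CpG: effect = mean(case β) − mean(control β) on a random 15 + 15
training subsample; p from a **Welch two-sample t-test** (the referenced
protocol does not name its test; Welch avoids the equal-variance
assumption and is swappable); Benjamini–Hochberg adjustment; signature
membership at |Δβ| ≥ 0.20 and adjusted p ≤ 0.01. Classification is the
larger Pearson correlation against the mean case/control profile over
signature CpGs; queries must cover ≥ 90 % of the signature; exact
correlation ties return "uncertain". Training samples are excluded from
evaluation. No array normalisation, batch correction, or probe QC is
performed — inputs are assumed to be curated beta matrices.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic for a fixed seed.

* **Toy genome**: non-overlapping genes (3–8 exons, 100–300 bp exons,
  0.5–3 kbp introns), enhancers in intergenic space, uniform random pLI
  per gene, optional iid random sequence. Compartment fractions partition
  the genome exactly.
* **Read sets**: evidence-level realism only — coordinates, insert sizes
  (Normal(350, 35) background), split flags. No base-level error model,
  no GC bias, no chimeras. Passing caller tests demonstrates the decision
  rules, not robustness to alignment artefacts.
* **Cohorts**: site allele counts follow the neutral 1/i spectrum by
  default (with a uniform alternative). The composition is *systematic*
  (mid-stratum points on the cumulative spectrum) rather than iid, and
  the per-class site count is calibrated against the composition's
  expected carrier fraction: iid draws of this heavy-tailed law would
  leave the realized cohort mean with a standard deviation of several
  sites per individual, swamping the requested per-class means. Founder
  genotypes distribute each site's copies uniformly over haplotypes;
  probands inherit Mendelian-consistently; planted de novos are
  proband-unique. Per-parent means default to *Alu* 23.6, L1 2.8, SVA
  0.2 — the modelled cohort's values.
  A `max_af` truncation emulates call sets dominated by rare, recent
  insertions: under the **full** neutral spectrum, common variants make
  per-individual counts underdispersed relative to Poisson
  (variance/mean ≈ 0.4–0.5), so Poisson behaviour of real insertion
  counts is reproduced with truncation (e.g. `max_af = 0.05`), while the
  full spectrum is kept as the default analytic truth for
  Watterson-estimator and singleton-proportion checks. Tests that target
  Poisson count behaviour use the truncated setting; tests that target
  frequency-spectrum theory use the full one.
* **Beta matrices**: baseline β ~ U(0.15, 0.85), planted |Δβ| with the
  sign chosen away from the [0, 1] boundary (so clipping cannot attenuate
  the planted effect), Gaussian noise (default SD 0.05). No probe-type
  structure, batch effects, or cell-composition variation.

## Problem sizes and numerics

Default verification scales (chosen so the full suite runs in seconds on
one CPU): toy genomes of 1–2 chromosomes × 0.4–1 Mbp, read sets of
300–500 background pairs per sample, cohorts of 300–1000 individuals,
100 burden replicates, 100 rate-recovery cohorts, 10⁴-CpG beta matrices.
Statistical assertions use 3–4 standard errors of their own Monte-Carlo
noise, never tuned tolerances.

Numerical details: harmonic numbers by direct summation (exact to float
precision at the sizes used); nearest-rank percentile (value at
⌈q·n⌉ of the sorted sample) rather than interpolation, so the threshold
is always an observed insert size; Poisson GOF bins merged from the tail
until every expected count ≥ 5, dof reduced by one when the mean is
estimated; interval arithmetic on half-open 0-based coordinates with
BED/VCF conversion confined to the I/O layer; exact binomial/Poisson
tails via scipy's stable implementations (brute-force pmf summation is
used as the oracle in tests, never as the implementation).

## Known limitations

* The PPG caller cannot localise insertion sites or separate multiple
  retrocopies of one donor; population-genetic statistics over PPGs are
  therefore limited to presence/absence per donor gene.
* Watterson estimation assumes neutrality and constant population size;
  rates for classes under strong selection are biased downward.
* Uniform placement is a null model; real insertion-site preference
  (e.g. L1 endonuclease motifs) is not modelled.
* The methylation classifier presumes the query was processed comparably
  to the training matrix; no cross-platform harmonisation is attempted.
* Synthetic fixtures validate decision rules and statistical behaviour,
  not robustness to alignment artefacts, sample contamination, or batch
  structure in real data.
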