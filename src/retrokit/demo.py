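"""Write a complete, self-consistent demo input set for the pipeline.

Everything is produced by the synthetic generators at a scale where the
full pipeline runs in seconds: a toy genome, read sets with planted
retroduplications, an MEI cohort VCF with trios and planted de novos, a
coverage-derived accessibility mask, and a beta matrix with a planted
methylation signature.
"""

from __future__ import annotations

import os
from typing import Dict

import numpy as np
import pandas as pd

from . import io, synthetic_data as syn
from .config import PipelineConfig
from .rates_burden import build_mask


def make_demo_inputs(outdir: str, seed: int = 0,
                     n_trios: int = 12,
                     n_unrelated: int = 24,
                     n_denovo: int = 3) -> PipelineConfig:
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)

    genome = syn.gen_toy_genome(n_chrom=2, chrom_len=400_000, n_genes=12,
                                seed=seed)
    paths: Dict[str, str] = {k: os.path.join(outdir, v) for k, v in {
        "chrom_sizes": "genome.chrom.sizes", "genes_bed": "genes.bed",
        "enhancers_bed": "enhancers.bed", "fasta": "genome.fa",
        "alignments_sam": "reads.sam", "mei_vcf": "cohort.vcf",
        "pedigree": "pedigree.tsv", "mask_bed": "mask.bed",
        "beta_matrix": "betas.tsv", "beta_labels": "beta_labels.tsv",
    }.items()}

    io.write_chrom_sizes(genome.chrom_lengths, paths["chrom_sizes"])
    io.write_genes_bed(genome, paths["genes_bed"])
    enh = {}
    for c, s, e in genome.enhancers:
        enh.setdefault(c, []).append((s, e))
    io.write_intervals_bed(enh, paths["enhancers_bed"])
    io.write_fasta(genome.sequence, paths["fasta"])

    # read sets: two carriers of one donor-gene retroduplication
    donor = sorted(genome.genes)[0]
    carriers = ["U0000", "U0001"]
    non_carriers = ["U0002", "U0003"]
    reads = syn.gen_ppg_cohort_readsets(genome, donor, carriers, non_carriers,
                                        seed=seed, n_background=300)
    io.write_readset_sam(reads, genome.chrom_lengths, paths["alignments_sam"])

    cohort = syn.gen_mei_cohort(genome, n_individuals=3 * n_trios + n_unrelated,
                                n_trios=n_trios, n_denovo=n_denovo,
                                seed=seed, max_af=0.2)
    io.write_mei_vcf(cohort.records, cohort.samples, genome.chrom_lengths,
                     paths["mei_vcf"])
    io.write_pedigree(cohort.trios, paths["pedigree"])

    # accessibility mask from a synthetic coverage track: high coverage
    # everywhere except a few random dropouts
    coverage = {}
    for c, n in genome.chrom_lengths.items():
        cov = np.full(n, 30.0)
        for _ in range(5):
            s = int(rng.integers(0, n - 2000))
            cov[s:s + 2000] = 4.0
        coverage[c] = cov
    io.write_mask_bed(build_mask(coverage, threshold=10.0), paths["mask_bed"])

    betas, labels, _sig = syn.gen_beta_matrix(4000, 20, 20, 40,
                                              effect=0.30, noise_sd=0.05,
                                              seed=seed)
    betas.to_csv(paths["beta_matrix"], sep="\t")
    pd.DataFrame({"label": labels}).rename_axis("sample").to_csv(
        paths["beta_labels"], sep="\t")

    return PipelineConfig(outdir=os.path.join(outdir, "out"), seed=seed,
                          **paths)
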