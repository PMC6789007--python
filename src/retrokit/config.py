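"""Pipeline configuration: paths plus every tunable threshold with its
published default. Round-trips losslessly through a flat YAML document."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    # --- paths -----------------------------------------------------------
    chrom_sizes: Optional[str] = None
    genes_bed: Optional[str] = None
    enhancers_bed: Optional[str] = None
    fasta: Optional[str] = None
    alignments_sam: Optional[str] = None
    mei_vcf: Optional[str] = None
    pedigree: Optional[str] = None
    mask_bed: Optional[str] = None
    beta_matrix: Optional[str] = None
    beta_labels: Optional[str] = None
    outdir: str = "retrokit_out"

    # --- retroduplication caller ----------------------------------------
    step1_min_drp: int = 5           # "more than four" exon-linking DRPs
    step2_min_total: int = 5         # "at least five total read pairs"
    step2_min_srp: int = 1
    step2_min_drp: int = 1
    insert_quantile: float = 0.995   # per-sample insert-size percentile

    # --- MEI call-set filters -------------------------------------------
    min_call_rate: float = 0.25
    min_split_reads: int = 3
    min_assess: int = 3
    lc_min_run: int = 15
    lc_max_distinct: int = 2
    lc_flank: int = 50
    assess_key: str = "ASSESS"
    sr_key: str = "SR"

    # --- rates & burden --------------------------------------------------
    ne: int = 10_000
    haploid_genome_len: float = 2.8973e9
    burden_reps: int = 100
    births: Optional[int] = None     # default: number of pedigree trios
    coverage_threshold: float = 10.0

    # --- constraint ------------------------------------------------------
    high_pli: float = 0.9

    # --- methylation ------------------------------------------------------
    effect_cutoff: float = 0.20
    fdr: float = 0.01
    n_train_per_group: int = 15

    # --- misc -------------------------------------------------------------
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
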