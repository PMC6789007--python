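"""Fixed-order pipeline tying the stages together, with a deterministic
summary report: retroduplication calling -> call-set filters -> trio de
novo -> mutation rate -> burden simulation -> constraint (and, when a beta
matrix is configured, methylation classification)."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import constraint_stats, io, mei_callset, ppg_caller, rates_burden, trio_denovo
from .config import PipelineConfig
from .genome import ToyGenome
from .mei_callset import ME_CLASSES

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all configured stages; returns the report dict and writes
    per-stage TSVs plus ``report.txt`` / ``report.json`` to the output
    directory. Identical config + seed produces byte-identical reports."""
    genome = _load_genome(config)
    os.makedirs(config.outdir, exist_ok=True)
    report: Dict = {"config": asdict(config), "stages": {}}

    alignments = None
    if config.alignments_sam:
        alignments = io.read_readset_sam(config.alignments_sam)

    # --- stage: ppg ------------------------------------------------------
    if alignments is not None:
        try:
            logger.info("stage ppg: %d read pairs", len(alignments))
            ppg_table = ppg_caller.call_ppgs(alignments, genome,
                                             step1_min_drp=config.step1_min_drp)
            ppg_table.to_csv(os.path.join(config.outdir, "ppg_calls.tsv"),
                             sep="\t", index=False)
            positives = ppg_table[ppg_table["positive"]]
            report["stages"]["ppg"] = {
                "genes": sorted(ppg_table["transcript_id"].unique().tolist()),
                "positive_calls": int(positives.shape[0]),
                "mean_per_individual": (float(positives.groupby("sample").size().reindex(
                    sorted({r.sample for r in alignments}), fill_value=0).mean())
                    if len(ppg_table) else 0.0),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("ppg", exc) from exc

    records: List[mei_callset.MeiRecord] = []
    samples: List[str] = []
    # --- stage: filter ---------------------------------------------------
    if config.mei_vcf:
        try:
            records, samples = io.read_mei_vcf(config.mei_vcf,
                                               assess_key=config.assess_key,
                                               sr_key=config.sr_key)
            if genome.sequence:
                mei_callset.apply_lc_filter(records, genome.sequence,
                                            flank=config.lc_flank)
            retained, ledger = mei_callset.apply_callset_filters(
                records, cohort_size=len(samples),
                min_call_rate=config.min_call_rate,
                min_split_reads=config.min_split_reads,
                min_assess=config.min_assess)
            io.write_mei_vcf(records, samples, genome.chrom_lengths,
                             os.path.join(config.outdir, "mei_flagged.vcf"),
                             assess_key=config.assess_key, sr_key=config.sr_key)
            io.write_mei_vcf(retained, samples, genome.chrom_lengths,
                             os.path.join(config.outdir, "mei_filtered.vcf"),
                             assess_key=config.assess_key, sr_key=config.sr_key)
            summary = mei_callset.per_individual_count_summary(retained, len(samples))
            summary.to_csv(os.path.join(config.outdir, "per_individual.tsv"),
                           sep="\t", index=False)
            ann = mei_callset.annotate_records(retained, genome)
            ann.to_csv(os.path.join(config.outdir, "consequences.tsv"),
                       sep="\t", index=False)
            report["stages"]["filter"] = {
                "ledger": ledger,
                "per_class_totals": {c: int(sum(r.me_class == c for r in retained))
                                     for c in ME_CLASSES},
                "total": len(retained),
            }
            report["stages"]["per_individual"] = json.loads(
                summary.round(6).to_json(orient="records"))
            records = retained
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("filter", exc) from exc

    # --- stage: denovo ---------------------------------------------------
    trios: List[Tuple[str, str, str]] = []
    denovo_sites: List[str] = []
    if config.pedigree and records:
        try:
            trios = io.read_pedigree(config.pedigree)
            calls, other_carriers = _trio_calls(records, samples, trios)
            candidates = trio_denovo.find_candidate_denovos(
                calls, other_carrier_sites=other_carriers)
            denovo_sites = [c.site_id for c in candidates]
            rows = []
            ann_by_site = {}
            for rec in records:
                ann_by_site[rec.site_id] = mei_callset.annotate_consequence(rec, genome)
            for c in candidates:
                rec = next(r for r in records if r.site_id == c.site_id)
                ann = ann_by_site[c.site_id]
                rows.append({"site_id": c.site_id, "trio_id": c.trio_id,
                             "chrom": rec.chrom, "pos": rec.pos,
                             "class": rec.me_class,
                             "compartment": ann.consequence,
                             "gene": ann.gene_id, "pli": ann.pli,
                             "origin": "unknown"})
            pd.DataFrame(rows, columns=["site_id", "trio_id", "chrom", "pos",
                                        "class", "compartment", "gene", "pli",
                                        "origin"]).to_csv(
                os.path.join(config.outdir, "denovo_candidates.tsv"),
                sep="\t", index=False)
            report["stages"]["denovo"] = {
                "candidates": len(candidates),
                "per_class": {c: int(sum(next(r for r in records if r.site_id == s).me_class == c
                                         for s in denovo_sites)) for c in ME_CLASSES},
            }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("denovo", exc) from exc

    # --- stage: rates ----------------------------------------------------
    if records:
        try:
            mask = io.read_mask_bed(config.mask_bed) if config.mask_bed else None
            in_mask = records
            if mask is not None:
                in_mask = [r for r in records if mask.contains(r.chrom, r.pos)]
                L = float(mask.length)
            else:
                L = float(genome.total_length)
            # rate estimation uses founders (parents) only where a pedigree
            # identifies them; probands are not independent chromosomes
            founders = samples
            if trios:
                children = {p for p, _, _ in trios}
                founders = [s for s in samples if s not in children]
            founder_idx = [samples.index(s) for s in founders]
            S = {c: 0 for c in ME_CLASSES}
            for r in in_mask:
                g = r.genotypes[founder_idx]
                if np.any(g > 0):
                    S[r.me_class] += 1
            est = rates_burden.watterson_mu(S, {c: L for c in ME_CLASSES},
                                            n_individuals=len(founders),
                                            Ne=config.ne)
            pd.DataFrame({"class": list(est.mu), "S": [est.S[c] for c in est.mu],
                          "L": [est.L[c] for c in est.mu],
                          "theta": [est.theta[c] for c in est.mu],
                          "mu": [est.mu[c] for c in est.mu]}).to_csv(
                os.path.join(config.outdir, "rates.tsv"), sep="\t", index=False)
            report["stages"]["rates"] = {
                "S": est.S, "L_bp": L, "n_founders": len(founders),
                "Ne": config.ne,
                "mu_per_class": {c: float(f"{v:.6g}") for c, v in est.mu.items()},
                "combined_mu": float(f"{est.combined_mu:.6g}"),
            }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("rates", exc) from exc

        # --- stage: burden ----------------------------------------------
        try:
            births = config.births or max(len(trios), 1)
            n_events, per_event = rates_burden.expected_denovo(
                est.combined_mu, births,
                haploid_genome_len=float(genome.total_length))
            n_events = max(n_events, 1)
            observed = {}
            for s in denovo_sites:
                rec = next(r for r in records if r.site_id == s)
                comp, _ = genome.compartment_of(rec.chrom, rec.pos)
                observed[("all", comp)] = observed.get(("all", comp), 0) + 1
            expectations = rates_burden.simulate_denovo_placements(
                n_events, config.burden_reps, genome, seed=config.seed,
                observed=observed)
            pd.DataFrame([{"gene_set": e.gene_set, "compartment": e.compartment,
                           "lambda": e.lam, "ci_low": e.ci_low,
                           "ci_high": e.ci_high, "observed": e.observed,
                           "poisson_p": e.poisson_p} for e in expectations]
                         ).to_csv(os.path.join(config.outdir, "burden.tsv"),
                                  sep="\t", index=False)
            report["stages"]["burden"] = {
                "expected_genomewide": n_events,
                "births_per_event": float(f"{per_event:.4g}"),
                "lambda": {f"{e.gene_set}:{e.compartment}": float(f"{e.lam:.6g}")
                           for e in expectations},
            }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("burden", exc) from exc

        # --- stage: constraint ------------------------------------------
        try:
            carrier_counts = [r.carrier_count for r in records]
            sing = constraint_stats.singleton_proportion(carrier_counts, "all MEI")
            plis = []
            for r in records:
                ann = mei_callset.annotate_consequence(r, genome)
                if ann.pli is not None:
                    plis.append(ann.pli)
            pli_sum = constraint_stats.pli_proportion(plis, "all MEI",
                                                      threshold=config.high_pli)
            report["stages"]["constraint"] = {
                "singleton_proportion": float(f"{sing.proportion:.6g}"),
                "singleton_ci_half_width": float(f"{sing.ci_half_width:.6g}"),
                "high_pli_proportion": (float(f"{pli_sum.proportion:.6g}")
                                        if pli_sum else None),
            }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("constraint", exc) from exc

    # --- stage: methyl ---------------------------------------------------
    if config.beta_matrix and config.beta_labels:
        try:
            from .methylation import build_signature, classify_by_correlation
            betas = pd.read_csv(config.beta_matrix, sep="\t", index_col=0)
            labels = pd.read_csv(config.beta_labels, sep="\t", index_col=0)["label"]
            signature, clf = build_signature(
                betas, labels, effect_cutoff=config.effect_cutoff,
                fdr=config.fdr, n_per_group=config.n_train_per_group,
                seed=config.seed)
            signature.to_frame().to_csv(
                os.path.join(config.outdir, "signature.tsv"), sep="\t", index=False)
            train_samples = set(np.array([s for s in betas.columns
                                          if labels.get(s) in ("case", "control")]
                                         )[clf.train_mask_])
            rows = []
            for s in betas.columns:
                if s in train_samples:
                    continue
                label, rc, rk = classify_by_correlation(betas[s], signature)
                rows.append({"sample": s, "label": label,
                             "r_case": round(rc, 6), "r_control": round(rk, 6)})
            pd.DataFrame(rows).to_csv(
                os.path.join(config.outdir, "methyl_classification.tsv"),
                sep="\t", index=False)
            report["stages"]["methyl"] = {
                "signature_size": len(signature),
                "classified": len(rows),
            }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("methyl", exc) from exc

    _write_report(report, config.outdir)
    return report


def _load_genome(config: PipelineConfig) -> ToyGenome:
    if not config.chrom_sizes:
        raise StageError("config", ValueError("chrom_sizes path is required"))
    return io.load_genome(config.chrom_sizes, config.genes_bed,
                          config.enhancers_bed, config.fasta)


def _trio_calls(records, samples, trios):
    idx = {s: i for i, s in enumerate(samples)}
    calls = []
    for rec in records:
        for t, (p, f, m) in enumerate(trios):
            calls.append(trio_denovo.TrioCall(
                rec.site_id, f"T{t:04d}",
                proband_gt=int(rec.genotypes[idx[p]]),
                father_gt=int(rec.genotypes[idx[f]]),
                mother_gt=int(rec.genotypes[idx[m]])))
    # carriers outside the pedigree count against cohort-uniqueness
    ped_members = {s for trio in trios for s in trio}
    outside = [i for i, s in enumerate(samples) if s not in ped_members]
    other_carriers = {rec.site_id for rec in records
                      if np.any(rec.genotypes[outside] > 0)}
    return calls, other_carriers


def _write_report(report: Dict, outdir: str) -> None:
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    lines = ["retrokit pipeline report", "========================", ""]
    stages = report["stages"]
    if "filter" in stages:
        lines.append("Call-set totals (post-filter):")
        totals = stages["filter"]["per_class_totals"]
        for c in ME_CLASSES:
            lines.append(f"  {c:<4} {totals.get(c, 0)}")
        lines.append(f"  Total - MEI  {stages['filter']['total']}")
        lines.append(f"  Filter ledger: {stages['filter']['ledger']}")
        lines.append("")
    if "per_individual" in stages:
        lines.append("Sites per individual (mean +/- SD, Poisson GOF p):")
        for row in stages["per_individual"]:
            lines.append(f"  {row['class']:<6} {row['mean_per_individual']:.2f} "
                         f"+/- {row['sd_per_individual']:.2f} "
                         f"(p={row['poisson_gof_p']:.3f})")
        lines.append("")
    if "denovo" in stages:
        lines.append(f"De novo candidates: {stages['denovo']['candidates']} "
                     f"({stages['denovo']['per_class']})")
        lines.append("")
    if "rates" in stages:
        r = stages["rates"]
        lines.append(f"Watterson rate: combined mu = {r['combined_mu']} "
                     f"(S={r['S']}, L={r['L_bp']:.0f} bp, "
                     f"n={r['n_founders']}, Ne={r['Ne']})")
        lines.append("")
    if "burden" in stages:
        b = stages["burden"]
        lines.append(f"Burden: expected genome-wide de novos = "
                     f"{b['expected_genomewide']} "
                     f"(1 per {b['births_per_event']} births)")
        lines.append("")
    if "constraint" in stages:
        c = stages["constraint"]
        lines.append(f"Constraint: singleton proportion = "
                     f"{c['singleton_proportion']} +/- {c['singleton_ci_half_width']}; "
                     f"high-pLI proportion = {c['high_pli_proportion']}")
        lines.append("")
    if "methyl" in stages:
        m = stages["methyl"]
        lines.append(f"Methylation: signature of {m['signature_size']} CpGs; "
                     f"{m['classified']} samples classified")
        lines.append("")
    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
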