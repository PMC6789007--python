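"""File formats: VCF, SAM, BED, FASTA and TSV readers/writers.

Conventions: BED is 0-based half-open, VCF is 1-based; the in-memory model
is 0-based half-open everywhere, so conversion happens exactly here.
"""

from __future__ import annotations

import os
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from . import intervals as iv
from .genome import GeneModel, ToyGenome
from .mei_callset import GT_MISSING, MeiRecord
from .ppg_caller import ReadPairObservation
from .rates_burden import MaskSet


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def write_fasta(sequence: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequence):
            fh.write(f">{chrom}\n")
            seq = sequence[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    with pysam.FastxFile(path) as fh:
        return {entry.name: entry.sequence for entry in fh}


# --------------------------------------------------------------------------
# BED (genes exon-per-row, enhancers, masks)
# --------------------------------------------------------------------------

def write_genes_bed(genome: ToyGenome, path: str) -> None:
    """One record per exon: chrom, start, end, transcript|exon_idx, pLI, strand."""
    rows = []
    for tid in sorted(genome.genes):
        g = genome.genes[tid]
        for i, (s, e) in enumerate(g.exons):
            pli = "." if g.pli is None else f"{g.pli:.4f}"
            rows.append((g.chrom, s, e, f"{tid}|{i}", pli, g.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path: str, chrom_lengths: Mapping[str, int]) -> Dict[str, GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "pli", "strand"])
    genes: Dict[str, dict] = {}
    for row in df.itertuples():
        tid, _idx = row.name.rsplit("|", 1)
        info = genes.setdefault(tid, {"chrom": row.chrom, "exons": [],
                                      "strand": row.strand,
                                      "pli": None if row.pli == "." else float(row.pli)})
        info["exons"].append((int(row.start), int(row.end)))
    return {tid: GeneModel(tid, d["chrom"], d["exons"], d["strand"], d["pli"])
            for tid, d in genes.items()}


def write_intervals_bed(intervals: iv.IntervalDict, path: str) -> None:
    rows = [(c, s, e) for c in sorted(intervals) for s, e in intervals[c]]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_intervals_bed(path: str) -> iv.IntervalDict:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    out: iv.IntervalDict = {}
    for row in df.itertuples():
        out.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    return iv.merge_dict(out)


def write_mask_bed(mask: MaskSet, path: str) -> None:
    write_intervals_bed(mask.intervals, path)


def read_mask_bed(path: str, classes: Tuple[str, ...] = ()) -> MaskSet:
    return MaskSet(read_intervals_bed(path), classes=classes)


def write_chrom_sizes(chrom_lengths: Mapping[str, int], path: str) -> None:
    pd.DataFrame(sorted(chrom_lengths.items())).to_csv(
        path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return {str(r.chrom): int(r.length) for r in df.itertuples()}


def load_genome(chrom_sizes_path: str,
                genes_bed: Optional[str] = None,
                enhancers_bed: Optional[str] = None,
                fasta: Optional[str] = None) -> ToyGenome:
    chrom_lengths = read_chrom_sizes(chrom_sizes_path)
    genes = read_genes_bed(genes_bed, chrom_lengths) if genes_bed else {}
    enhancers: List[Tuple[str, int, int]] = []
    if enhancers_bed:
        for c, ivs in read_intervals_bed(enhancers_bed).items():
            enhancers.extend((c, s, e) for s, e in ivs)
    sequence = read_fasta(fasta) if fasta else None
    return ToyGenome(chrom_lengths, genes, enhancers, sequence)


# --------------------------------------------------------------------------
# SAM read pairs
# --------------------------------------------------------------------------

_SPLIT_TAG = "ZS"  # 1 marks a split-read pair of segments


def write_readset_sam(reads: Sequence[ReadPairObservation],
                      chrom_lengths: Mapping[str, int],
                      path: str) -> None:
    """Each ReadPairObservation becomes a proper read pair; split reads
    carry the ZS:i:1 tag on both segments. Base qualities are constant
    (coordinate/flag evidence only). Records are coordinate-sorted."""
    chroms = sorted(chrom_lengths)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms]}
    tid_of = {c: i for i, c in enumerate(chroms)}
    segs = []
    for k, r in enumerate(reads):
        name = r.name or f"pair{k}"
        qname = f"{r.sample}:{name}"
        for which, (chrom, start, end, mchrom, mstart) in enumerate(
                [(r.chrom1, r.start1, r.end1, r.chrom2, r.start2),
                 (r.chrom2, r.start2, r.end2, r.chrom1, r.start1)]):
            a = pysam.AlignedSegment()
            a.query_name = qname
            a.query_sequence = "A" * (end - start)
            a.query_qualities = pysam.qualitystring_to_array("I" * (end - start))
            a.reference_id = tid_of[chrom]
            a.reference_start = start
            a.cigarstring = f"{end - start}M"
            a.flag = (0x1 | 0x2
                      | (0x40 if which == 0 else 0x80)
                      | (0x20 if which == 0 else 0x10))
            a.next_reference_id = tid_of[mchrom]
            a.next_reference_start = mstart
            a.template_length = (r.insert_size if which == 0 else -r.insert_size)
            a.set_tag(_SPLIT_TAG, 1 if r.is_split else 0)
            a.set_tag("RG", r.sample)
            segs.append(a)
    segs.sort(key=lambda a: (a.reference_id, a.reference_start))
    header["RG"] = [{"ID": s} for s in sorted({r.sample for r in reads})]
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for a in segs:
            out.write(a)


def read_readset_sam(path: str) -> List[ReadPairObservation]:
    """Reconstruct read-pair observations from a SAM written by
    :func:`write_readset_sam` (or any name-paired SAM with RG tags)."""
    firsts: Dict[str, pysam.AlignedSegment] = {}
    out: List[ReadPairObservation] = []
    with pysam.AlignmentFile(path, "r") as fh:
        chroms = list(fh.references)
        for a in fh:
            if a.is_secondary or a.is_supplementary or a.is_unmapped:
                continue
            if a.query_name in firsts:
                b = firsts.pop(a.query_name)
                r1, r2 = (b, a) if b.is_read1 else (a, b)
                sample = r1.get_tag("RG") if r1.has_tag("RG") else "S0"
                qname = r1.query_name
                name = qname.split(":", 1)[1] if ":" in qname else qname
                out.append(ReadPairObservation(
                    sample=str(sample),
                    chrom1=chroms[r1.reference_id],
                    start1=r1.reference_start,
                    end1=r1.reference_end,
                    chrom2=chroms[r2.reference_id],
                    start2=r2.reference_start,
                    end2=r2.reference_end,
                    insert_size=abs(r1.template_length),
                    is_split=bool(r1.get_tag(_SPLIT_TAG)) if r1.has_tag(_SPLIT_TAG) else False,
                    name=name))
            else:
                firsts[a.query_name] = a
    return out


# --------------------------------------------------------------------------
# MEI VCF
# --------------------------------------------------------------------------

_GT_TO_VCF = {0: (0, 0), 1: (0, 1), 2: (1, 1), GT_MISSING: (None, None)}


def write_mei_vcf(records: Sequence[MeiRecord],
                  samples: Sequence[str],
                  chrom_lengths: Mapping[str, int],
                  path: str,
                  assess_key: str = "ASSESS",
                  sr_key: str = "SR") -> None:
    """Write MEI records as a VCF with symbolic insertion ALTs.

    Internal 0-based positions become 1-based VCF POS. FILTER holds the
    record's filter set; INFO carries the ME class (METYPE), ASSESS score,
    split-read support and insert-length estimate.
    """
    header = pysam.VariantHeader()
    for c in sorted(chrom_lengths):
        header.contigs.add(c, length=int(chrom_lengths[c]))
    header.filters.add("rSD", None, None, "ratio of split to discordant evidence")
    header.filters.add("lc", None, None, "low-complexity context (+/-50 bp)")
    header.filters.add("ac0", None, None, "no alternate allele")
    header.info.add("METYPE", 1, "String", "Mobile element class (Alu/L1/SVA)")
    header.info.add(assess_key, 1, "Integer", "Caller assessment score (0-5)")
    header.info.add(sr_key, 1, "Integer", "Split reads supporting the insertion")
    header.info.add("INSLEN", 1, "Integer", "Estimated insertion length (bp)")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.site_id))
    with pysam.VariantFile(path, "w", header=header) as out:
        for r in recs:
            v = out.new_record()
            v.chrom = r.chrom
            v.start = r.pos          # pysam start is 0-based; POS printed 1-based
            v.stop = r.pos + 1
            v.id = r.site_id
            v.ref = "N"
            v.alts = (f"<INS:ME:{r.me_class.upper()}>",)
            for f in sorted(r.filters):
                v.filter.add(f)
            v.info["METYPE"] = r.me_class
            v.info[assess_key] = int(r.assess)
            v.info[sr_key] = int(r.split_reads)
            if r.insert_length is not None:
                v.info["INSLEN"] = int(r.insert_length)
            for s, gt in zip(samples, r.genotypes):
                v.samples[s]["GT"] = _GT_TO_VCF[int(gt)]
                v.samples[s].phased = False
            out.write(v)


_ALT_TO_CLASS = {"ALU": "Alu", "L1": "L1", "LINE1": "L1", "SVA": "SVA"}


def read_mei_vcf(path: str,
                 assess_key: str = "ASSESS",
                 sr_key: str = "SR") -> Tuple[List[MeiRecord], List[str]]:
    """Parse an MEI VCF into records (0-based positions) and sample order.

    Strict about required INFO keys: a record without the configured
    ASSESS or split-read key raises with the record's location.
    """
    records: List[MeiRecord] = []
    with pysam.VariantFile(path) as fh:
        samples = list(fh.header.samples)
        for v in fh:
            where = f"{os.path.basename(path)}:{v.chrom}:{v.pos}"
            if assess_key not in v.info:
                raise ValueError(f"{where}: missing INFO key {assess_key!r}")
            if sr_key not in v.info:
                raise ValueError(f"{where}: missing INFO key {sr_key!r}")
            if "METYPE" in v.info:
                cls = str(v.info["METYPE"])
            else:
                alt = (v.alts or ("",))[0].strip("<>").split(":")[-1].upper()
                if alt not in _ALT_TO_CLASS:
                    raise ValueError(f"{where}: cannot determine ME class")
                cls = _ALT_TO_CLASS[alt]
            gts = []
            for s in samples:
                gt = v.samples[s].get("GT", (None, None))
                if gt is None or any(a is None for a in gt):
                    gts.append(GT_MISSING)
                else:
                    gts.append(int(sum(gt)))
            filters = set(v.filter.keys()) or {"PASS"}
            records.append(MeiRecord(
                site_id=v.id or f"{v.chrom}_{v.pos}",
                me_class=cls, chrom=v.chrom, pos=v.start,
                genotypes=np.array(gts),
                filters=filters,
                split_reads=int(v.info[sr_key]),
                assess=int(v.info[assess_key]),
                insert_length=(int(v.info["INSLEN"]) if "INSLEN" in v.info else None)))
    return records, samples


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------

def write_pedigree(trios: Sequence[Tuple[str, str, str]], path: str) -> None:
    pd.DataFrame(trios, columns=["proband", "father", "mother"]).to_csv(
        path, sep="\t", index=False)


def read_pedigree(path: str) -> List[Tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(r.proband, r.father, r.mother) for r in df.itertuples()]


def write_pli_table(pli: Mapping[str, float], path: str) -> None:
    pd.DataFrame(sorted(pli.items()), columns=["gene_id", "pli"]).to_csv(
        path, sep="\t", index=False)


def read_pli_table(path: str) -> Dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"], df["pli"].astype(float)))
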