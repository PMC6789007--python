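"""Toy genome container: chromosomes, gene models, enhancers, sequence.

Coordinates are 0-based half-open throughout the in-memory model; file
formats convert at the I/O boundary (VCF is 1-based, BED is 0-based).

The compartment partition follows single-consequence priority used for
insertion annotation: enhancer > exonic > intronic > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import intervals as iv

COMPARTMENTS = ("enhancer", "exonic", "intronic", "intergenic")


@dataclass
class GeneModel:
    """One transcript: ordered, non-overlapping exons on one chromosome."""

    transcript_id: str
    chrom: str
    exons: List[Tuple[int, int]]
    strand: str = "+"
    pli: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> List[Tuple[int, int]]:
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])]

    def exon_index_overlapping(self, start: int, end: int) -> Optional[int]:
        """Index of the first exon overlapping [start, end) by >=1 bp."""
        for i, (s, e) in enumerate(self.exons):
            if start < e and end > s:
                return i
        return None


@dataclass
class ToyGenome:
    """Chromosome lengths plus gene/enhancer annotation and optional sequence."""

    chrom_lengths: Dict[str, int]
    genes: Dict[str, GeneModel] = field(default_factory=dict)
    enhancers: List[Tuple[str, int, int]] = field(default_factory=list)
    sequence: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        for g in self.genes.values():
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"{g.transcript_id}: unknown chrom {g.chrom}")
            if g.start < 0 or g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(f"{g.transcript_id}: exons outside chromosome")
        for c, s, e in self.enhancers:
            if c not in self.chrom_lengths or s < 0 or e > self.chrom_lengths[c]:
                raise ValueError(f"enhancer ({c},{s},{e}) outside chromosome")
        self._index()

    def _index(self) -> None:
        self._enh = {c: iv.IntervalLookup([(s, e) for cc, s, e in self.enhancers if cc == c])
                     for c in self.chrom_lengths}
        # per-chromosome gene list sorted by start, for point queries
        self._genes_by_chrom: Dict[str, List[GeneModel]] = {c: [] for c in self.chrom_lengths}
        for g in self.genes.values():
            self._genes_by_chrom[g.chrom].append(g)
        for lst in self._genes_by_chrom.values():
            lst.sort(key=lambda g: g.start)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def genes_overlapping(self, chrom: str, start: int, end: int) -> List[GeneModel]:
        return [g for g in self._genes_by_chrom.get(chrom, ())
                if start < g.end and end > g.start]

    def compartment_of(self, chrom: str, pos: int) -> Tuple[str, Optional[GeneModel]]:
        """Single-consequence compartment of a point, with priority
        enhancer > exonic > intronic > intergenic. Returns the containing
        gene for genic (exonic/intronic) hits, else None."""
        if chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        if pos in self._enh[chrom]:
            return "enhancer", None
        hit_gene = None
        for g in self._genes_by_chrom[chrom]:
            if g.start <= pos < g.end:
                hit_gene = g
                for s, e in g.exons:
                    if s <= pos < e:
                        return "exonic", g
        if hit_gene is not None:
            return "intronic", hit_gene
        return "intergenic", None

    def compartment_intervals(self) -> Dict[str, iv.IntervalDict]:
        """Disjoint interval sets per compartment under the priority rule."""
        whole: iv.IntervalDict = {c: [(0, n)] for c, n in self.chrom_lengths.items()}
        enh: iv.IntervalDict = {}
        for c, s, e in self.enhancers:
            enh.setdefault(c, []).append((s, e))
        enh = iv.merge_dict(enh)
        raw_exon: iv.IntervalDict = {}
        body: iv.IntervalDict = {}
        for g in self.genes.values():
            raw_exon.setdefault(g.chrom, []).extend(g.exons)
            body.setdefault(g.chrom, []).append((g.start, g.end))
        raw_exon = iv.merge_dict(raw_exon)
        body = iv.merge_dict(body)
        exon = iv.subtract(raw_exon, enh)
        intron = iv.subtract(iv.subtract(body, raw_exon), enh)
        inter = iv.subtract(iv.subtract(whole, enh), body)
        return {"enhancer": enh, "exonic": exon, "intronic": intron, "intergenic": inter}

    def compartment_fractions(self) -> Dict[str, float]:
        """Fraction of genome bp per compartment; sums to 1."""
        comp = self.compartment_intervals()
        total = self.total_length
        return {k: iv.total_length(v) / total for k, v in comp.items()}
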