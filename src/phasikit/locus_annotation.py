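"""Locus classification against gene and repeat annotation.

A locus is *genic* when it shares at least one base with an annotated gene
(strand-agnostic), otherwise *intergenic* (reported with the literal token
"Intergenic").  Repeat overlap is reported as the covered fraction of the
locus, with a summary share of loci majority-covered (> 0.5) by repeats.
Putative-function labels come from the overlapping gene's product string,
from configured ncRNA intervals ("ncRNA"), or default to "NULL".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .phas_detection import PhasLocus
from .sequence_io import GeneFeature, GenomeAnnotation, Interval

INTERGENIC = "Intergenic"


@dataclass
class AnnotationOverlap:
    locus_id: str
    gene_ids: list[str]
    products: list[str]
    genic: bool
    repeat_fraction: float

    @property
    def gene_label(self) -> str:
        if not self.gene_ids:
            return INTERGENIC
        parts = []
        for gid, product in zip(self.gene_ids, self.products):
            parts.append(f"{gid} ({product})" if product else gid)
        return "; ".join(parts)


def _trees(intervals: Sequence[Interval]) -> dict[str, IntervalTree]:
    out: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        out[iv.chrom].addi(iv.start, iv.end)
    return dict(out)


def overlap_genes(
    loci: Sequence[PhasLocus], genes: Sequence[GeneFeature]
) -> list[AnnotationOverlap]:
    """Strand-agnostic >= 1 nt interval intersection of loci with genes."""
    by_chrom: dict[str, list[GeneFeature]] = defaultdict(list)
    for g in genes:
        by_chrom[g.interval.chrom].append(g)
    out = []
    for locus in loci:
        iv = locus.interval
        hits = [
            g for g in by_chrom.get(iv.chrom, [])
            if g.interval.start < iv.end and iv.start < g.interval.end
        ]
        hits.sort(key=lambda g: (g.interval.start, g.gene_id))
        out.append(
            AnnotationOverlap(
                locus.id,
                [g.gene_id for g in hits],
                [g.product for g in hits],
                genic=bool(hits),
                repeat_fraction=0.0,
            )
        )
    return out


def repeat_overlap(
    loci: Sequence[PhasLocus], repeats: Sequence[Interval]
) -> tuple[dict[str, float], float]:
    """Per-locus repeat-covered fraction and the share of loci with > 0.5.

    With no repeat annotation, all fractions are 0 and a warning is issued.
    """
    if not repeats:
        import warnings

        warnings.warn("no repeat annotation: repeat fractions all 0")
        return {l.id: 0.0 for l in loci}, 0.0
    trees = _trees(repeats)
    fractions = {}
    for locus in loci:
        iv = locus.interval
        tree = trees.get(iv.chrom)
        covered = 0
        if tree is not None:
            # merge overlapping repeat pieces within the locus
            pieces = sorted(
                (max(h.begin, iv.start), min(h.end, iv.end))
                for h in tree.overlap(iv.start, iv.end)
            )
            cur_lo = cur_hi = None
            for lo, hi in pieces:
                if cur_hi is None or lo > cur_hi:
                    if cur_hi is not None:
                        covered += cur_hi - cur_lo
                    cur_lo, cur_hi = lo, hi
                else:
                    cur_hi = max(cur_hi, hi)
            if cur_hi is not None:
                covered += cur_hi - cur_lo
        fractions[locus.id] = covered / len(iv)
    share = sum(f > 0.5 for f in fractions.values()) / len(loci) if loci else 0.0
    return fractions, share


def classify_putative_function(
    locus: PhasLocus,
    annotation: GenomeAnnotation,
    overlap: AnnotationOverlap | None = None,
) -> str:
    """Product of the overlapping gene, "ncRNA" for configured ncRNA
    intervals, else the literal "NULL"."""
    if overlap is None:
        overlap = overlap_genes([locus], annotation.genes)[0]
    for product in overlap.products:
        if product:
            return product
    iv = locus.interval
    for nc in annotation.ncrnas:
        if nc.overlaps(iv):
            return "ncRNA"
    if overlap.genic:
        return "uncharacterized mRNA"
    return "NULL"


def annotate_loci(
    loci: Sequence[PhasLocus], annotation: GenomeAnnotation
) -> list[AnnotationOverlap]:
    """Full annotation pass; genic/intergenic partition is checked."""
    overlaps = overlap_genes(loci, annotation.genes)
    fractions, _ = (
        repeat_overlap(loci, annotation.repeats)
        if annotation.repeats
        else ({l.id: 0.0 for l in loci}, 0.0)
    )
    for ov in overlaps:
        ov.repeat_fraction = fractions[ov.locus_id]
    n_genic = sum(ov.genic for ov in overlaps)
    n_inter = sum(not ov.genic for ov in overlaps)
    assert n_genic + n_inter == len(loci), "genic/intergenic must partition the loci"
    return overlaps
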