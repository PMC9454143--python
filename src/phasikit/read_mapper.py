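"""Exact-match placement of sRNA sequences on a genome.

Mapping is zero-mismatch by design: only reads that perfectly match the
genome (either strand) enter downstream analysis.  A k-mer seed index over
the plus strand finds candidate positions; every hit is verified by full
substring comparison, so the result is identical to a naive all-positions
scan (property-tested against one).

Multi-mapping reads are retained — phased-siRNA loci frequently sit in
repeats — with their counts split equally across hits by the locus callers;
they are excluded from novel-miRNA candidacy upstream.  Removal of reads
overlapping mRNA exons/introns or repeats (to avoid degradation products)
applies only on the miRNA-identification branch.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .sequence_io import GenomeAnnotation, Interval, revcomp


@dataclass(frozen=True)
class AlignmentHit:
    """A perfect-match placement of a read on the genome."""

    seq: str
    interval: Interval

    @property
    def strand(self) -> str:
        return self.interval.strand


class KmerIndex:
    """Plus-strand k-mer position index over a genome.

    Minus-strand hits are found by searching the reverse complement of the
    query against the plus strand.  k-mers containing N are not indexed.
    """

    def __init__(self, genome: Mapping[str, str], k: int = 12):
        if k < 1:
            raise ValueError("k must be positive")
        if genome and k > min(len(s) for s in genome.values()):
            raise ValueError("k exceeds the shortest chromosome length")
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in sorted(self.genome.items()):
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self._index[kmer].append((chrom, i))
        self._index = dict(self._index)

    def positions(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    # -- queries ------------------------------------------------------------

    def _scan_plus(self, query: str) -> list[tuple[str, int]]:
        """All plus-strand occurrences of ``query``; seeded when possible."""
        L = len(query)
        if L < self.k:
            # fall back to a naive scan for sub-seed queries
            out = []
            for chrom, seq in sorted(self.genome.items()):
                start = seq.find(query)
                while start != -1:
                    out.append((chrom, start))
                    start = seq.find(query, start + 1)
            return out
        hits = []
        for chrom, i in self.positions(query[: self.k]):
            if self.genome[chrom][i : i + L] == query:
                hits.append((chrom, i))
        return hits

    def map_read(self, read: str) -> list[AlignmentHit]:
        """All 0-mismatch placements of ``read`` on both strands.

        Sorted by (chrom, start, strand).
        """
        read = read.upper()
        hits = [
            AlignmentHit(read, Interval(c, p, p + len(read), "+"))
            for c, p in self._scan_plus(read)
        ]
        rc = revcomp(read)
        hits += [
            AlignmentHit(read, Interval(c, p, p + len(read), "-"))
            for c, p in self._scan_plus(rc)
        ]
        hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
        return hits


def build_index(genome: Mapping[str, str], k: int = 12) -> KmerIndex:
    return KmerIndex(genome, k=k)


def naive_map(genome: Mapping[str, str], read: str) -> list[AlignmentHit]:
    """Reference brute-force mapper: scan every position on both strands."""
    read = read.upper()
    rc = revcomp(read)
    hits = []
    for chrom, seq in sorted(genome.items()):
        seq = seq.upper()
        for query, strand in ((read, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                hits.append(AlignmentHit(read, Interval(chrom, start, start + len(read), strand)))
                start = seq.find(query, start + 1)
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    return hits


def verify_hit(genome: Mapping[str, str], hit: AlignmentHit) -> bool:
    """Check the substring-equality invariant of an alignment hit."""
    sub = genome[hit.interval.chrom][hit.interval.start : hit.interval.end].upper()
    return sub == (hit.seq if hit.strand == "+" else revcomp(hit.seq))


def remove_annotation_overlaps(
    hits: Sequence[AlignmentHit],
    annotation: GenomeAnnotation,
    classes: Iterable[str] = ("gene", "repeat"),
) -> tuple[list[AlignmentHit], dict[str, int]]:
    """Drop hits overlapping annotated mRNA or repeat intervals by >= 1 nt.

    Used only on the miRNA-identification branch: phased-siRNA loci are
    detected without this filter so repeat-resident loci stay visible.
    Returns (retained hits, per-class removed counts).
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    classes = set(classes)
    sources: dict[str, list[Interval]] = {}
    if "gene" in classes:
        sources["gene"] = [g.interval for g in annotation.genes]
    if "repeat" in classes:
        sources["repeat"] = list(annotation.repeats)
    for cls, ivs in sources.items():
        per_chrom: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for iv in ivs:
            per_chrom[iv.chrom].addi(iv.start, iv.end)
        trees[cls] = dict(per_chrom)

    retained = []
    removed = {cls: 0 for cls in sources}
    for hit in hits:
        iv = hit.interval
        hit_cls = None
        for cls in sources:  # fixed order: gene before repeat
            tree = trees[cls].get(iv.chrom)
            if tree is not None and tree.overlap(iv.start, iv.end):
                hit_cls = cls
                break
        if hit_cls is None:
            retained.append(hit)
        else:
            removed[hit_cls] += 1
    return retained, removed
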