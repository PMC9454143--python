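"""Known-miRNA matching, novel-miRNA hairpin evaluation and family assignment.

Known miRNAs are called by exact (U/T-insensitive) sequence identity between
a genome-matched read and a mature catalog entry; the family is inherited
from the catalog.

Novel candidates are uniquely mapped, abundant reads absent from the
catalog.  For each candidate two precursor windows are cut around the
mapped position, folded, and evaluated against plant-miRNA annotation
criteria:

(a) the candidate folds into a stem-loop with the mature entirely on one
    arm of the stem;
(b) at most 5 unpaired mature positions in the mature/star duplex and no
    asymmetric bulge larger than 3 nt;
(c) the (observed or inferred) star forms a duplex with 2-nt 3' overhangs —
    the star 5' end is the pairing partner of the 3rd-from-last mature
    position, and the star 3' end extends 2 nt past the partner of the
    mature 5' end;
(d) mature + star reads account for >= 75% of all read mass in the
    precursor window (this criterion separates hairpins from phased loci,
    whose mass is spread over many registers);
(e) mature length 20-22 nt.

Novel families are single-linkage clusters of mature sequences at <= 2
mismatches (equal length only) and are numbered miRN1, miRN2, ... by
descending total abundance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .read_mapper import AlignmentHit
from .rna_thermo import fold
from .sequence_io import CollapsedRead, Interval, read_fasta, revcomp

MIN_MATURE_LEN = 20
MAX_MATURE_LEN = 22
MAX_UNPAIRED_MATURE = 5
MAX_ASYM_BULGE = 3
MIN_DUPLEX_MASS_FRACTION = 0.75
WINDOW_UP = 20
WINDOW_DOWN = 150
DEFAULT_MIN_READS = 20


@dataclass(frozen=True)
class MirnaCatalogEntry:
    id: str
    family: str
    mature: str
    species: str = ""


@dataclass
class MirnaRecord:
    """A mature miRNA call with optional star and precursor geometry."""

    id: str
    status: str  # "known" | "novel"
    mature: str
    family: str = ""
    star: str | None = None
    precursor: Interval | None = None
    mature_counts: dict[str, int] = field(default_factory=dict)
    star_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.mature_counts.values())


def read_catalog(path: str | Path) -> list[MirnaCatalogEntry]:
    """Load a mature-miRNA catalog FASTA with ``family=`` description tags."""
    entries = []
    for rec in read_fasta(path):
        parts = rec.id.split()
        name = parts[0]
        m = re.search(r"family=(\S+)", rec.id)
        family = m.group(1) if m else re.sub(r"^\D*?(miR[N]?\d+).*$", r"\1", name)
        sp = re.search(r"species=(\S+)", rec.id)
        entries.append(
            MirnaCatalogEntry(name, family, rec.seq, sp.group(1) if sp else "")
        )
    return entries


def match_known(
    reads: Sequence[CollapsedRead], catalog: Sequence[MirnaCatalogEntry]
) -> list[MirnaRecord]:
    """Exact-identity matching of reads against catalog matures.

    One record per distinct mature sequence; when several catalog entries
    share the sequence, the lexicographically first id wins.
    """
    by_seq: dict[str, list[MirnaCatalogEntry]] = {}
    for e in catalog:
        by_seq.setdefault(e.mature, []).append(e)
    records = []
    for read in reads:
        entries = by_seq.get(read.seq)
        if entries:
            best = min(entries, key=lambda e: e.id)
            records.append(
                MirnaRecord(
                    best.id, "known", read.seq, family=best.family,
                    mature_counts=dict(read.counts),
                )
            )
    return records


@dataclass
class PrecursorCandidate:
    mature_read: CollapsedRead
    hit: AlignmentHit
    windows: list[Interval]


def _eligible_hits(reads, hits_by_seq, known_seqs, min_reads):
    """Yield (read, representative hit) for candidacy-eligible reads."""
    for read in reads:
        if read.seq in known_seqs or read.total < min_reads:
            continue
        hits = list(hits_by_seq.get(read.seq, []))
        if not hits:
            continue
        if len(hits) == 1:
            yield read, hits[0]
        elif len(hits) == 2 and hits[0].interval.chrom == hits[1].interval.chrom and (
            hits[1].interval.end - hits[0].interval.start <= 300
        ):
            # both arms of a near-palindromic hairpin: one locus, not a repeat
            plus = [h for h in hits if h.strand == "+"]
            yield read, (plus[0] if plus else hits[0])


def propose_novel(
    reads: Sequence[CollapsedRead],
    hits_by_seq: Mapping[str, Sequence[AlignmentHit]],
    known_seqs: set[str],
    chrom_lengths: Mapping[str, int],
    min_reads: int = DEFAULT_MIN_READS,
    known_anchors: Sequence[Interval] = (),
) -> list[PrecursorCandidate]:
    """Select uniquely mapped, abundant, non-catalog reads as candidates.

    A read whose two hits lie within one precursor-scale span (300 nt, the
    mature matching both arms of a near-palindromic hairpin) still counts
    as uniquely placed; genuinely multi-mapped reads are excluded.  Reads
    landing within 200 nt of a known mature (``known_anchors``) are its
    star/processing variants, not novel candidates.

    For each candidate two precursor windows are proposed: mature near the
    5' end ([start-20, end+150)) and mature near the 3' end
    ([start-150, end+20)), clipped to the chromosome.  Candidates within
    200 nt of a more abundant candidate are absorbed into it.
    """
    eligible = []
    for read, hit in _eligible_hits(reads, hits_by_seq, known_seqs, min_reads):
        iv = hit.interval
        if any(
            a.chrom == iv.chrom and abs(a.start - iv.start) <= 200
            for a in known_anchors
        ):
            continue
        eligible.append((read, hit))
    eligible.sort(key=lambda rh: (-rh[0].total, rh[0].seq))

    candidates: list[PrecursorCandidate] = []
    for read, hit in eligible:
        iv = hit.interval
        absorbed = False
        for c in candidates:
            civ = c.hit.interval
            if civ.chrom == iv.chrom and abs(civ.start - iv.start) <= 200:
                absorbed = True
                break
        if absorbed:
            continue
        clen = chrom_lengths[iv.chrom]
        windows = [
            Interval(iv.chrom, max(0, iv.start - WINDOW_UP),
                     min(clen, iv.end + WINDOW_DOWN), iv.strand),
            Interval(iv.chrom, max(0, iv.start - WINDOW_DOWN),
                     min(clen, iv.end + WINDOW_UP), iv.strand),
        ]
        candidates.append(PrecursorCandidate(read, hit, windows))
    return candidates


@dataclass
class HairpinEvaluation:
    passed: bool
    failures: list[str]
    record: MirnaRecord | None = None


def _window_mass(
    window: Interval,
    reads: Sequence[CollapsedRead],
    hits_by_seq: Mapping[str, Sequence[AlignmentHit]],
) -> float:
    mass = 0.0
    for read in reads:
        for h in hits_by_seq.get(read.seq, []):
            if h.interval.overlaps(window):
                mass += read.total / max(1, len(hits_by_seq[read.seq]))
    return mass


def evaluate_hairpin(
    candidate: PrecursorCandidate,
    genome: Mapping[str, str],
    reads: Sequence[CollapsedRead],
    hits_by_seq: Mapping[str, Sequence[AlignmentHit]],
    min_mass_fraction: float = MIN_DUPLEX_MASS_FRACTION,
) -> HairpinEvaluation:
    """Evaluate precursor windows against the hairpin criteria (a)-(e).

    The candidate passes if either window passes; failures list the
    criteria violated by the best window.
    """
    mature = candidate.mature_read.seq
    L = len(mature)
    failures_best: list[str] | None = None
    if not (MIN_MATURE_LEN <= L <= MAX_MATURE_LEN):
        return HairpinEvaluation(False, ["e:mature-length"])

    for window in candidate.windows:
        failures: list[str] = []
        seq = genome[window.chrom][window.start : window.end]
        if candidate.hit.strand == "-":
            seq = revcomp(seq)
            mo = window.end - candidate.hit.interval.end
        else:
            mo = candidate.hit.interval.start - window.start
        structure = fold(seq)
        partner = structure.partner_map()
        mat_pos = list(range(mo, mo + L))

        # the mature/star duplex is the dominant helix.  Along a clean
        # antiparallel helix i + partner(i) is constant (bulges shift it by
        # their asymmetry), so pairs whose diagonal i + partner(i) strays
        # far from the consensus are sporadic off-helix pairs picked up by
        # the pair-maximizing fold, not duplex pairs.
        raw_pairs = [(i, partner[i]) for i in mat_pos if i in partner]
        if not raw_pairs:
            failures_best = ["a:not-on-one-arm", "c:star-anchors-unpaired"]
            continue
        diags = sorted(i + p for i, p in raw_pairs)
        med_c = diags[len(diags) // 2]
        duplex_pairs = {
            i: p for i, p in raw_pairs if abs((i + p) - med_c) <= MAX_ASYM_BULGE
        }

        # (a) mature on one arm, inside the stem (no intra-mature pairs)
        paired = list(duplex_pairs.values())
        intra = [p for p in paired if mo <= p < mo + L]
        one_side = paired and (all(p >= mo + L for p in paired) or all(p < mo for p in paired))
        if intra or not one_side:
            failures.append("a:not-on-one-arm")

        # (b) unpaired mature positions and asymmetric bulges within the duplex
        n_unpaired = L - len(duplex_pairs)
        if n_unpaired > MAX_UNPAIRED_MATURE:
            failures.append("b:unpaired>5")
        paired_idx = sorted(duplex_pairs)
        max_bulge = 0
        for i1, i2 in zip(paired_idx, paired_idx[1:]):
            gap_m = i2 - i1 - 1
            gap_s = abs(duplex_pairs[i1] - duplex_pairs[i2]) - 1
            max_bulge = max(max_bulge, abs(gap_m - gap_s))
        if max_bulge > MAX_ASYM_BULGE:
            failures.append("b:bulge>3")

        # (c) star geometry: 2-nt 3' overhangs.  The star 5' end pairs the
        # 3rd-from-last mature base and the star 3' end extends 2 nt past
        # the partner of the mature 5' end; when those exact bases sit in a
        # terminal bulge the ends are extrapolated along the helix
        # (partners decrease by 1 per mature base in a clean duplex).
        star_iv = None
        if not paired_idx:
            failures.append("c:star-anchors-unpaired")
        else:
            j_anchor = min(paired_idx, key=lambda i: abs(i - (mo + L - 3)))
            j_five = min(paired_idx, key=lambda i: abs(i - mo))
            star_start = duplex_pairs[j_anchor] - ((mo + L - 3) - j_anchor)
            star_end = duplex_pairs[j_five] + (j_five - mo) + 3
            if not (L - 3 <= star_end - star_start <= L + 3) or star_start < 0 or star_end > len(seq):
                failures.append("c:star-geometry")
            else:
                star_iv = (star_start, star_end)

        # (d) mature+star mass fraction in the window
        star_seq = seq[star_iv[0] : star_iv[1]] if star_iv else None
        total_mass = _window_mass(window, reads, hits_by_seq)
        duplex_mass = candidate.mature_read.total
        star_counts: dict[str, int] = {}
        if star_seq:
            for read in reads:
                if read.seq == star_seq:
                    duplex_mass += read.total
                    star_counts = dict(read.counts)
        if total_mass > 0 and duplex_mass / total_mass < min_mass_fraction:
            failures.append("d:duplex-mass<75%")

        if not failures:
            record = MirnaRecord(
                id="",  # assigned with the family label
                status="novel",
                mature=mature,
                star=star_seq,
                precursor=window,
                mature_counts=dict(candidate.mature_read.counts),
                star_counts=star_counts,
            )
            return HairpinEvaluation(True, [], record)
        if failures_best is None or len(failures) < len(failures_best):
            failures_best = failures
    return HairpinEvaluation(False, failures_best or ["no-window"])


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_family(records: Sequence[MirnaRecord], max_mismatch: int = 2) -> list[MirnaRecord]:
    """Cluster novel matures into families and assign miRN ids.

    Single-linkage at <= ``max_mismatch`` mismatches between equal-length
    matures (different lengths never join).  Families are numbered by
    descending total abundance (ties broken by smallest mature sequence);
    members get letter suffixes a, b, ... by descending abundance.
    """
    records = list(records)
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i].mature, records[j].mature
            if len(a) == len(b) and _hamming(a, b) <= max_mismatch:
                parent[find(i)] = find(j)

    clusters: dict[int, list[MirnaRecord]] = {}
    for i, rec in enumerate(records):
        clusters.setdefault(find(i), []).append(rec)
    ordered = sorted(
        clusters.values(),
        key=lambda c: (-sum(r.total for r in c), min(r.mature for r in c)),
    )
    out = []
    for fam_idx, members in enumerate(ordered, start=1):
        family = f"miRN{fam_idx}"
        members = sorted(members, key=lambda r: (-r.total, r.mature))
        for m_idx, rec in enumerate(members):
            rec.family = family
            suffix = chr(ord("a") + m_idx) if len(members) > 1 else "a"
            rec.id = f"fan-{family}{suffix}"
            out.append(rec)
    return out
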