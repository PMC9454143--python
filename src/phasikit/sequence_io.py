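"""Readers/writers for on-disk formats and sRNA read collapsing.

Internal conventions
--------------------
* All sequences are stored uppercase in the DNA alphabet; ``U`` is
  normalized to ``T`` at ingest (RNA-ness is implicit).
* Genomic coordinates are 0-based half-open internally.  Human-facing
  tables exported by the reporting layer use 1-based inclusive coordinates.
* FASTQ qualities are parsed but ignored; quality control is delegated to
  length/composition filters in :mod:`phasikit.preprocess`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an on-disk record cannot be interpreted."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA-alphabet sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and map U->T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class FastaRecord:
    """A named nucleotide sequence (U already normalized to T)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ParseError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r} contains non-IUPAC characters {sorted(bad)}"
            )


@dataclass
class CollapsedRead:
    """A unique sRNA sequence with per-library read counts."""

    seq: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval with identifier and free-text product annotation."""

    interval: Interval
    gene_id: str
    product: str = ""


@dataclass
class GenomeAnnotation:
    """Gene features plus repeat intervals for a genome."""

    genes: list[GeneFeature] = field(default_factory=list)
    repeats: list[Interval] = field(default_factory=list)
    # optional ncRNA intervals used for putative-function labelling
    ncrnas: list[Interval] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a FASTA file, preserving order, normalizing U->T.

    Raises :class:`ParseError` for empty sequences or invalid characters.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(FastaRecord(rec.description or rec.id, normalize_seq(str(rec.seq))))
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _iter_fastq_seqs(path: str | Path):
    """Yield sequences from a 4-line FASTQ, raising on truncation."""
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lines = [fh.readline() for _ in range(3)]
            if not header.startswith("@") or any(not ln for ln in lines):
                raise ParseError(f"truncated/malformed FASTQ record {idx} in {path}")
            yield normalize_seq(lines[0].strip())
            idx += 1


def collapse_reads(fastq_paths: Mapping[str, str | Path]) -> list[CollapsedRead]:
    """Collapse FASTQ reads into unique sequences with per-library counts.

    Parameters
    ----------
    fastq_paths
        Map of library id -> FASTQ path.

    Returns
    -------
    list of CollapsedRead, sorted lexicographically by sequence.
    """
    table: dict[str, dict[str, int]] = {}
    for lib, path in fastq_paths.items():
        for seq in _iter_fastq_seqs(path):
            counts = table.setdefault(seq, {})
            counts[lib] = counts.get(lib, 0) + 1
    return [CollapsedRead(seq, table[seq]) for seq in sorted(table)]


def collapse_sequences(seq_lists: Mapping[str, Sequence[str]]) -> list[CollapsedRead]:
    """Collapse in-memory per-library sequence lists (same contract as
    :func:`collapse_reads`, without the FASTQ round trip)."""
    table: dict[str, dict[str, int]] = {}
    for lib, seqs in seq_lists.items():
        for seq in seqs:
            counts = table.setdefault(normalize_seq(seq), {})
            counts[lib] = counts.get(lib, 0) + 1
    return [CollapsedRead(seq, table[seq]) for seq in sorted(table)]


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Sequence[Interval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED6 (0-based half-open) lines."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[Interval, str, float]]:
    """Read BED (3-6 columns) into (Interval, name, score) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((Interval(chrom, start, end, strand), name, score))
    return out


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, feature_types: Sequence[str] = ("gene",)) -> list[GeneFeature]:
    """Read gene-level features from a GFF3 file via gffutils.

    Only the ``ID`` and optional ``product`` attributes are retained.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
            strand = feat.strand if feat.strand in {"+", "-"} else "+"
            product = feat.attributes.get("product", [""])[0]
            genes.append(
                GeneFeature(
                    Interval(feat.seqid, feat.start - 1, feat.end, strand),
                    feat.id,
                    product,
                )
            )
    return genes


def write_gff3(features: Sequence[GeneFeature], path: str | Path, source: str = "phasikit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            iv = f.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
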