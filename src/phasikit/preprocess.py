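"""Clean-read production: length/composition filters and ncRNA removal.

The filters mirror standard sRNA-seq practice: reads outside the 16-30 nt
enrichment window are dropped, polyA-dominated fragments (adapter/tailing
artifacts) are removed, and reads matching structural ncRNAs (rRNA, tRNA,
snRNA, snoRNA, scRNA) are subtracted before miRNA/phasiRNA analysis.

All filters operate on collapsed reads and conserve read mass: for every
library, raw = retained + sum(removed), asserted on each run.  Filters are
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .sequence_io import CollapsedRead, FastaRecord, revcomp

NCRNA_CLASS_ORDER = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA")

DEFAULT_MIN_LEN = 16
DEFAULT_MAX_LEN = 30
POLYA_FRACTION = 0.8
POLYA_RUN = 8


@dataclass
class FilterReport:
    """Per-library read-mass accounting through the preprocessing filters."""

    raw: dict[str, int] = field(default_factory=dict)
    removed_length: dict[str, int] = field(default_factory=dict)
    removed_polya: dict[str, int] = field(default_factory=dict)
    removed_ncrna: dict[str, dict[str, int]] = field(default_factory=dict)  # class -> lib -> n
    retained: dict[str, int] = field(default_factory=dict)

    def libraries(self) -> list[str]:
        return sorted(self.raw)

    def assert_mass_conserved(self) -> None:
        for lib in self.raw:
            removed = (
                self.removed_length.get(lib, 0)
                + self.removed_polya.get(lib, 0)
                + sum(cls.get(lib, 0) for cls in self.removed_ncrna.values())
            )
            assert self.raw[lib] == self.retained.get(lib, 0) + removed, (
                f"mass not conserved in library {lib}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lib in self.libraries():
            row = {
                "library": lib,
                "raw": self.raw.get(lib, 0),
                "removed_length": self.removed_length.get(lib, 0),
                "removed_polyA": self.removed_polya.get(lib, 0),
            }
            for cls in NCRNA_CLASS_ORDER:
                row[f"removed_{cls}"] = self.removed_ncrna.get(cls, {}).get(lib, 0)
            row["retained"] = self.retained.get(lib, 0)
            rows.append(row)
        return pd.DataFrame(rows)


def is_polya(seq: str, fraction: float = POLYA_FRACTION, run: int = POLYA_RUN) -> bool:
    """Flag polyA artifacts: >= ``fraction`` A overall or a run of >= ``run`` A."""
    if not seq:
        return False
    if seq.count("A") / len(seq) >= fraction:
        return True
    return "A" * run in seq


def _add_mass(target: dict[str, int], read: CollapsedRead) -> None:
    for lib, n in read.counts.items():
        target[lib] = target.get(lib, 0) + n


def quality_filter(
    reads: Sequence[CollapsedRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    polya_fraction: float = POLYA_FRACTION,
    polya_run: int = POLYA_RUN,
) -> tuple[list[CollapsedRead], FilterReport]:
    """Retain reads with min_len <= length <= max_len and no polyA flag."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    report = FilterReport()
    retained = []
    for read in reads:
        _add_mass(report.raw, read)
        if not (min_len <= len(read) <= max_len):
            _add_mass(report.removed_length, read)
        elif is_polya(read.seq, polya_fraction, polya_run):
            _add_mass(report.removed_polya, read)
        else:
            retained.append(read)
            _add_mass(report.retained, read)
    report.assert_mass_conserved()
    return retained, report


def filter_ncrna(
    reads: Sequence[CollapsedRead],
    contaminants: Sequence[tuple[FastaRecord, str]],
) -> tuple[list[CollapsedRead], dict[str, dict[str, int]]]:
    """Remove reads that are exact substrings (either strand) of a contaminant.

    ``contaminants`` pairs each reference record with its ncRNA class label.
    A read's class attribution is the first matching class in the fixed
    order rRNA -> tRNA -> snRNA -> snoRNA -> scRNA.  Matching is exact
    substring only, consistent with the perfect-match standard used for
    genome mapping.
    """
    if not contaminants:
        import warnings

        warnings.warn("empty contaminant reference: all reads retained")
        return list(reads), {}
    by_class: dict[str, list[str]] = {}
    for rec, cls in contaminants:
        by_class.setdefault(cls, []).append(rec.seq)
    ordered = [c for c in NCRNA_CLASS_ORDER if c in by_class] + [
        c for c in by_class if c not in NCRNA_CLASS_ORDER
    ]

    removed: dict[str, dict[str, int]] = {}
    retained = []
    for read in reads:
        rc = revcomp(read.seq)
        hit_cls = None
        for cls in ordered:
            if any(read.seq in ref or rc in ref for ref in by_class[cls]):
                hit_cls = cls
                break
        if hit_cls is None:
            retained.append(read)
        else:
            _add_mass(removed.setdefault(hit_cls, {}), read)
    return retained, removed


def length_distribution(
    reads: Sequence[CollapsedRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> pd.DataFrame:
    """Per-library length histogram by read mass (not unique sequences).

    Rows are lengths min_len..max_len; columns are libraries; each column
    sums to the library's read mass within the length window.
    """
    libs = sorted({lib for r in reads for lib in r.counts})
    hist = pd.DataFrame(
        0, index=range(min_len, max_len + 1), columns=libs, dtype=int
    )
    for read in reads:
        L = len(read)
        if min_len <= L <= max_len:
            for lib, n in read.counts.items():
                hist.loc[L, lib] += n
    hist.index.name = "length"
    return hist
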