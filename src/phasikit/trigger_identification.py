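"""miRNA triggers of phased loci: one-hit and two-hit configurations.

A miRNA *triggers* a phased locus when its cleavage of the precursor
transcript sets the phase register: phasiRNA 5' ends run in period-length
steps from the cut between the target bases pairing miRNA positions 10-11.
Candidate sites are found by the four target-prediction rules on the locus
sequence +- a flank, on both strands; a site becomes a trigger when its
cleavage point is in register with the locus (distance to the nearest
phased position congruent to 0 mod period, within a +-1 nt tolerance).

The two-hit configuration (the miR390/TAS3 archetype) is recognized when
two sites of one family flank at least 3 phased cycles and the 3' site's
cleavage sets the register; the 5' site is a non-cleavable anchor and is
exempt from the positions-10-11 rule.

This module also ships a curated table of published trigger-locus pairs
from a cultivated-strawberry embryo/endosperm study, used as a reference
input for the summary/reporting operations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .mirna_identification import MirnaRecord
from .phas_detection import PhasLocus
from .sequence_io import Interval, revcomp
from .target_prediction import evaluate_site

DEFAULT_FLANK = 200
REGISTER_TOLERANCE = 1
MIN_TWO_HIT_CYCLES = 3


@dataclass(frozen=True)
class TriggerPair:
    phas_id: str
    family: str
    member_ids: tuple[str, ...]
    mirna_lengths: tuple[int, ...]
    site: Interval                      # genomic coordinates of the cleavable site
    model: str                          # "ONE_HIT" | "TWO_HIT"
    register_offset: int                # nt from perfect register (0 = exact)
    anchor_site: Interval | None = None  # 5' site of a two-hit pair


@dataclass(frozen=True)
class _Site:
    interval: Interval
    cleavage_register: int   # registers-space position implied by cleavage
    cleavable: bool


def _scan_sites(
    mirna: str, genome: Mapping[str, str], region: Interval, protect_10_11: bool
) -> list[_Site]:
    """All rule-passing sites of one miRNA in a genomic region, both strands.

    ``cleavage_register`` is the strand-adjusted position comparable to
    locus registers: for a plus-strand target it is the cleavage point
    itself; for a minus-strand target the 2-nt duplex-overhang shift of
    minus reads adds 3 (end+2 convention on a 1-length slice).
    """
    seq = genome[region.chrom][region.start : region.end]
    L = len(mirna)
    sites = []
    for s in range(len(seq) - L + 1):
        ok, _, _, _ = evaluate_site(mirna, seq[s : s + L], protect_10_11=protect_10_11)
        if ok:
            g = region.start + s
            sites.append(
                _Site(Interval(region.chrom, g, g + L, "+"), g + L - 10, True)
            )
    rc = revcomp(seq)
    for s in range(len(rc) - L + 1):
        ok, _, _, _ = evaluate_site(mirna, rc[s : s + L], protect_10_11=protect_10_11)
        if ok:
            g = region.end - s - L  # genomic start of the minus-strand site
            # cleavage base pairs miRNA position 10: genomic g + 9; the
            # minus-strand 3' fragment phases leftward from there
            sites.append(
                _Site(Interval(region.chrom, g, g + L, "-"), g + 9 + 3, True)
            )
    return sites


def _register_offset(pos: int, locus: PhasLocus) -> int:
    """Signed minimal distance (mod period) from pos to the locus register."""
    period = locus.period
    ref = locus.registers[0]
    return ((pos - ref) + period // 2) % period - period // 2


def _phased_cycles_between(locus: PhasLocus, lo: int, hi: int) -> int:
    return sum(lo < r < hi for r in locus.registers)


def find_triggers(
    locus: PhasLocus,
    mirnas: Sequence[MirnaRecord],
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    tolerance: int = REGISTER_TOLERANCE,
) -> list[TriggerPair]:
    """One-hit and two-hit triggers of one locus.

    For each miRNA family, a two-hit configuration is reported when found;
    otherwise every in-register cleavable site yields a ONE_HIT pair.
    Family members hitting the same site are merged onto one pair.
    """
    chrom_len = len(genome[locus.interval.chrom])
    region = Interval(
        locus.interval.chrom,
        max(0, locus.interval.start - flank),
        min(chrom_len, locus.interval.end + flank),
        "+",
    )
    by_family: dict[str, list[MirnaRecord]] = {}
    for rec in mirnas:
        by_family.setdefault(rec.family or rec.id, []).append(rec)

    pairs: list[TriggerPair] = []
    for family in sorted(by_family):
        members = by_family[family]
        # site -> (member ids, lengths) for cleavable, rule-passing sites
        cleavable: dict[tuple[Interval, int], tuple[set[str], set[int]]] = {}
        anchors: dict[Interval, set[str]] = {}
        for rec in members:
            for site in _scan_sites(rec.mature, genome, region, protect_10_11=True):
                key = (site.interval, site.cleavage_register)
                ids, lens = cleavable.setdefault(key, (set(), set()))
                ids.add(rec.id)
                lens.add(len(rec.mature))
            for site in _scan_sites(rec.mature, genome, region, protect_10_11=False):
                anchors.setdefault(site.interval, set()).add(rec.id)

        two_hit_found = False
        for (iv, creg), (ids, lens) in sorted(cleavable.items()):
            offset = _register_offset(creg, locus)
            if abs(offset) > tolerance:
                continue
            # look for a second same-family site 5' of >= 3 phased cycles
            for anchor_iv in sorted(anchors):
                if anchor_iv == iv:
                    continue
                lo, hi = sorted((anchor_iv.end, iv.start))
                if _phased_cycles_between(locus, lo, hi) >= MIN_TWO_HIT_CYCLES:
                    pairs.append(
                        TriggerPair(
                            locus.id, family, tuple(sorted(ids)),
                            tuple(sorted(lens)), iv, "TWO_HIT", offset,
                            anchor_site=anchor_iv,
                        )
                    )
                    two_hit_found = True
                    break
            if two_hit_found:
                break
        if two_hit_found:
            continue
        for (iv, creg), (ids, lens) in sorted(cleavable.items()):
            offset = _register_offset(creg, locus)
            if abs(offset) <= tolerance:
                pairs.append(
                    TriggerPair(
                        locus.id, family, tuple(sorted(ids)),
                        tuple(sorted(lens)), iv, "ONE_HIT", offset,
                    )
                )
    return pairs


def detect_two_hit(
    locus: PhasLocus,
    family_records: Sequence[MirnaRecord],
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    tolerance: int = REGISTER_TOLERANCE,
) -> TriggerPair | None:
    """Two-hit trigger of one family for one locus, if present."""
    pairs = find_triggers(locus, family_records, genome, flank, tolerance)
    for pair in pairs:
        if pair.model == "TWO_HIT":
            return pair
    return None


# ---------------------------------------------------------------------------
# summaries and the curated reference table
# ---------------------------------------------------------------------------

FAMILY_RE = re.compile(r"^(miRN?\d+)")


def trigger_family(member_label: str) -> str:
    """Family name from a member label: 'miR482a/b/y' -> 'miR482'."""
    m = FAMILY_RE.match(member_label.strip())
    if not m:
        raise ValueError(f"unrecognized miRNA label {member_label!r}")
    return m.group(1)


def is_novel_family(family: str) -> bool:
    return family.startswith("miRN")


def summarize_triggers(
    pairs: Sequence[TriggerPair],
    functions: Mapping[str, str] | None = None,
    genes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row per triggered locus, in the curated-table column layout.

    ``functions``/``genes`` map locus id -> putative function / overlapping
    gene label ("Intergenic" when none).
    """
    functions = functions or {}
    genes = genes or {}
    rows: dict[str, dict] = {}
    for pair in pairs:
        row = rows.setdefault(
            pair.phas_id,
            {
                "phas_id": pair.phas_id,
                "putative_function": functions.get(pair.phas_id, "NULL"),
                "overlapping_gene": genes.get(pair.phas_id, "Intergenic"),
                "trigger": [],
                "mirna_length": [],
            },
        )
        # compact member notation: family + joined member suffixes
        suffixes = [m.replace("fan-", "").replace(pair.family, "") for m in pair.member_ids]
        label = pair.family + "/".join(s for s in suffixes if s)
        row["trigger"].append(label)
        row["mirna_length"].append("/".join(str(n) for n in sorted(set(pair.mirna_lengths))))
    out = []
    for phas_id in sorted(rows, key=_phas_sort_key):
        row = rows[phas_id]
        row["trigger"] = "; ".join(row["trigger"])
        row["mirna_length"] = "; ".join(row["mirna_length"])
        out.append(row)
    return pd.DataFrame(
        out, columns=["phas_id", "putative_function", "overlapping_gene", "trigger", "mirna_length"]
    )


def _phas_sort_key(phas_id: str):
    m = re.match(r"PHAS(\d+)-(\d+)", phas_id)
    return (int(m.group(1)), int(m.group(2))) if m else (99, 0, phas_id)


def load_reference_pairs() -> pd.DataFrame:
    """Curated published trigger-locus pairs for cultivated strawberry."""
    path = resources.files("phasikit.data").joinpath("fragaria_trigger_pairs.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def trigger_table_summary(table: pd.DataFrame) -> dict[str, object]:
    """Counts over a trigger table (computed or curated).

    Returns triggered-locus counts per period, the genic split, distinct
    trigger families per period split known/novel, and the number of
    TAS3-like loci.
    """
    def period_of(phas_id: str) -> int:
        return int(re.match(r"PHAS(\d+)-", phas_id).group(1))

    out: dict[str, object] = {}
    for period in (21, 24):
        sub = table[table["phas_id"].map(period_of) == period]
        families: set[str] = set()
        for cell in sub["trigger"]:
            for member in str(cell).split(";"):
                families.add(trigger_family(member))
        out[f"loci_{period}"] = int(len(sub))
        out[f"genic_{period}"] = int((sub["overlapping_gene"] != "Intergenic").sum())
        out[f"families_{period}"] = len(families)
        out[f"known_families_{period}"] = sum(not is_novel_family(f) for f in families)
        out[f"novel_families_{period}"] = sum(is_novel_family(f) for f in families)
    out["tas3_like"] = int((table["putative_function"] == "TAS3-like").sum())
    return out
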