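"""Rule-based miRNA target-site discovery on transcript sequences.

A site is an ungapped antiparallel window of the transcript, scored against
four criteria (positions are 1-based from the miRNA 5' end):

1. no more than four mismatches in the miRNA/target duplex;
2. no more than two adjacent mismatches (maximal mismatch run <= 2);
3. no mismatches at positions 10-11 (the cleavage register);
4. duplex free energy >= 74% of the energy of the miRNA bound to its
   perfect complement.

G:U wobbles count as mismatches for rules 1-3 by default (pattern matching
is sequence-literal) while still pairing for the energy term; set
``gu_is_mismatch=False`` to treat wobbles as matches throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .rna_thermo import duplex_energy, pair_state, perfect_complement_energy
from .sequence_io import FastaRecord

MAX_MISMATCHES = 4
MAX_ADJACENT = 2
PROTECTED_POSITIONS = (10, 11)
MIN_MFE_RATIO = 0.74
MIRNA_MIN_LEN = 20
MIRNA_MAX_LEN = 24


@dataclass(frozen=True)
class TargetSite:
    """An accepted miRNA target site on a transcript.

    ``start``/``end`` are 1-based inclusive transcript coordinates of the
    site; ``cleavage`` is the transcript coordinate of the base pairing
    miRNA position 10 (cleavage occurs between the bases pairing positions
    10 and 11).
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    mismatches: tuple[int, ...]
    max_run: int
    ratio: float
    cleavage: int


def _max_run(positions: Sequence[int]) -> int:
    best = run = 0
    prev = None
    for p in positions:
        run = run + 1 if prev is not None and p == prev + 1 else 1
        best = max(best, run)
        prev = p
    return best


def evaluate_site(
    mirna: str,
    site_seq: str,
    gu_is_mismatch: bool = True,
    protect_10_11: bool = True,
) -> tuple[bool, tuple[int, ...], int, float]:
    """Apply the four criteria to one miRNA/site duplex.

    Returns (accepted, mismatch positions, max mismatch run, energy ratio).
    ``protect_10_11=False`` relaxes rule 3 (used for the non-cleavable 5'
    anchor of two-hit triggers).  The energy ratio is only computed once
    the sequence rules pass (and is reported as nan otherwise).
    """
    bad = {"mismatch", "wobble"} if gu_is_mismatch else {"mismatch"}
    opposite = site_seq[::-1]
    mismatches = tuple(
        i + 1
        for i in range(len(mirna))
        if pair_state(mirna[i], opposite[i]) in bad
    )
    run = _max_run(mismatches)
    ok = (
        len(mismatches) <= MAX_MISMATCHES
        and run <= MAX_ADJACENT
        and (not protect_10_11 or not (set(PROTECTED_POSITIONS) & set(mismatches)))
    )
    if not ok:
        return False, mismatches, run, float("nan")
    ratio = duplex_energy(mirna, site_seq).energy / perfect_complement_energy(mirna)
    return ratio >= MIN_MFE_RATIO, mismatches, run, ratio


def predict_targets(
    mirna_id: str,
    mirna: str,
    transcripts: Sequence[FastaRecord] | Mapping[str, str],
    gu_is_mismatch: bool = True,
    protect_10_11: bool = True,
) -> list[TargetSite]:
    """Scan every transcript window for sites satisfying all four criteria.

    Results are sorted by (transcript, site start).  Site coordinates are
    1-based inclusive; the site is antisense to the miRNA.
    """
    if not (MIRNA_MIN_LEN <= len(mirna) <= MIRNA_MAX_LEN):
        raise ValueError(f"miRNA length {len(mirna)} outside {MIRNA_MIN_LEN}-{MIRNA_MAX_LEN}")
    if isinstance(transcripts, Mapping):
        items = sorted(transcripts.items())
    else:
        items = [(t.id.split()[0], t.seq) for t in transcripts]
    L = len(mirna)
    sites = []
    for tid, seq in items:
        for s in range(len(seq) - L + 1):
            window = seq[s : s + L]
            ok, mism, run, ratio = evaluate_site(mirna, window, gu_is_mismatch, protect_10_11)
            if ok:
                sites.append(
                    TargetSite(
                        mirna_id, tid,
                        start=s + 1, end=s + L,
                        mismatches=mism, max_run=run, ratio=round(ratio, 4),
                        cleavage=s + 1 + (L - 10),
                    )
                )
    sites.sort(key=lambda t: (t.transcript_id, t.start))
    return sites


def cleavage_position(site: TargetSite) -> int:
    """Transcript coordinate of the base pairing miRNA position 10.

    The guided cut falls between this base and the next one toward the
    transcript 5' end (pairing position 11).
    """
    return site.cleavage
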