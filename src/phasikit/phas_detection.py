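"""Detection of 21-nt and 24-nt phased siRNA (PHAS) loci.

Phased siRNAs are diced in fixed-length increments from a double-stranded
precursor, so their 5' ends fall into a single congruence class
("register") modulo the period.  Because phasiRNA duplexes carry 2-nt 3'
overhangs, a minus-strand read belongs to the same register as its
plus-strand partner after shifting: the adjusted position of a minus read
is its interval end + 2 (0-based half-open coordinates).

For a 9-cycle sliding window starting at s (register = s mod period):

* ``n`` — occupied phased positions: distinct (position, strand) slots with
  a period-length read 5' end at a register position;
* ``P`` / ``U`` — read mass at phased positions (period-length reads only)
  and everywhere else (including all reads of other lengths);
* phase score = (n - 2) * ln(1 + 10 P / (1 + U)), 0 when n < 3;
* P value = hypergeometric upper tail of drawing >= n phased positions when
  q occupied positions are placed among N = 2 x span slots of which
  m = 2 x cycles are phased.

Loci are windows passing both the score threshold (>= 10 for 21-nt, >= 5
for 24-nt) and P < 0.001, merged when overlapping and trimmed to the
outermost phased read.  Multi-mapped reads contribute fractional mass
(1 / number of hits) so repeat-resident loci remain detectable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .read_mapper import AlignmentHit
from .sequence_io import CollapsedRead, Interval

DEFAULT_CYCLES = 9
MAX_P_VALUE = 1e-3
MIN_SCORE = {21: 10.0, 24: 5.0}


@dataclass
class PhaseWindow:
    """One scored sliding window (span = cycles x period)."""

    chrom: str
    start: int
    period: int
    cycles: int
    n: int
    P: float
    U: float
    q: int

    @property
    def span(self) -> int:
        return self.cycles * self.period

    @property
    def N(self) -> int:
        return 2 * self.span

    @property
    def m(self) -> int:
        return 2 * self.cycles


@dataclass
class PhasLocus:
    id: str
    interval: Interval
    period: int
    score: float
    p_value: float
    registers: list[int]                      # phased (occupied) positions
    lib_abundance: dict[str, float] = field(default_factory=dict)


def phase_score(n: int, P: float, U: float) -> float:
    """(n-2) * ln(1 + 10P/(1+U)); 0 below the 3-position occupancy floor."""
    if n < 3:
        return 0.0
    return float((n - 2) * np.log1p(10.0 * P / (1.0 + U)))


def phase_pvalue(n: int, N: int, m: int, q: int) -> float:
    """Upper-tail hypergeometric probability of >= n phased occupied positions."""
    if q > N:
        raise ValueError(f"occupied positions q={q} exceed total positions N={N}")
    return float(stats.hypergeom.sf(n - 1, N, m, q))


def window_score(window: PhaseWindow) -> float:
    return phase_score(window.n, window.P, window.U)


def window_pvalue(window: PhaseWindow) -> float:
    return phase_pvalue(window.n, window.N, window.m, window.q)


# ---------------------------------------------------------------------------
# position tables
# ---------------------------------------------------------------------------

@dataclass
class _ChromPositions:
    # one entry per occupied (adjusted position, strand) slot, period-length reads
    occ_pos: np.ndarray          # sorted adjusted positions (ties allowed across strands)
    occ_mass: np.ndarray         # aligned fractional mass
    occ_libs: list[dict[str, float]]
    all_pos: np.ndarray          # sorted adjusted positions, every read length
    all_mass: np.ndarray


class PositionTable:
    """Strand-adjusted 5'-position abundance table for one period."""

    def __init__(self, period: int):
        self.period = period
        self.chroms: dict[str, _ChromPositions] = {}

    @property
    def total_occupied(self) -> int:
        return sum(len(c.occ_pos) for c in self.chroms.values())


def adjusted_position(hit: AlignmentHit) -> int:
    """Register-space 5' position: start for plus reads, end + 2 for minus."""
    iv = hit.interval
    return iv.start if iv.strand == "+" else iv.end + 2


def phase_registers(
    reads: Sequence[CollapsedRead],
    hits_by_seq: Mapping[str, Sequence[AlignmentHit]],
    period: int,
) -> PositionTable:
    """Aggregate read mass by adjusted 5' position.

    Period-length reads define occupied phased-candidate slots; reads of
    any other length contribute unphased mass only.  Multi-mapped reads are
    down-weighted by their hit count.
    """
    occ: dict[str, dict[tuple[int, str], tuple[float, dict[str, float]]]] = defaultdict(dict)
    allm: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for read in reads:
        hits = hits_by_seq.get(read.seq, [])
        if not hits:
            continue
        frac = 1.0 / len(hits)
        for hit in hits:
            pos = adjusted_position(hit)
            chrom = hit.interval.chrom
            mass = read.total * frac
            allm[chrom][pos] += mass
            if len(read.seq) == period:
                key = (pos, hit.interval.strand)
                prev_mass, prev_libs = occ[chrom].get(key, (0.0, {}))
                libs = dict(prev_libs)
                for lib, n in read.counts.items():
                    libs[lib] = libs.get(lib, 0.0) + n * frac
                occ[chrom][key] = (prev_mass + mass, libs)

    table = PositionTable(period)
    for chrom in sorted(set(occ) | set(allm)):
        entries = sorted(occ.get(chrom, {}).items())
        occ_pos = np.array([pos for (pos, _), _ in entries], dtype=np.int64)
        occ_mass = np.array([m for _, (m, _) in entries], dtype=float)
        occ_libs = [libs for _, (_, libs) in entries]
        apos = np.array(sorted(allm[chrom]), dtype=np.int64)
        amass = np.array([allm[chrom][p] for p in sorted(allm[chrom])], dtype=float)
        table.chroms[chrom] = _ChromPositions(occ_pos, occ_mass, occ_libs, apos, amass)
    return table


# ---------------------------------------------------------------------------
# locus calling
# ---------------------------------------------------------------------------

def _window_stats(
    cp: _ChromPositions, starts: np.ndarray, period: int, cycles: int,
    register_tolerance: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (n, P, U, q) for an array of window starts."""
    span = period * cycles
    ends = starts + span
    # q and total mass from the all-position arrays
    occ_lo = np.searchsorted(cp.occ_pos, starts, side="left")
    occ_hi = np.searchsorted(cp.occ_pos, ends, side="left")
    q = occ_hi - occ_lo
    acum = np.concatenate([[0.0], np.cumsum(cp.all_mass)])
    alo = np.searchsorted(cp.all_pos, starts, side="left")
    ahi = np.searchsorted(cp.all_pos, ends, side="left")
    total_mass = acum[ahi] - acum[alo]

    # per-residue-class occupied slots
    res = cp.occ_pos % period
    n = np.zeros(len(starts), dtype=np.int64)
    P = np.zeros(len(starts), dtype=float)
    reg = starts % period
    for dr in range(-register_tolerance, register_tolerance + 1):
        want = (reg + dr) % period
        for r in np.unique(want):
            sel = res == r
            if not sel.any():
                continue
            cls_pos = cp.occ_pos[sel]
            cls_cum = np.concatenate([[0.0], np.cumsum(cp.occ_mass[sel])])
            idx = np.nonzero(want == r)[0]
            lo = np.searchsorted(cls_pos, starts[idx], side="left")
            hi = np.searchsorted(cls_pos, ends[idx], side="left")
            n[idx] += hi - lo
            P[idx] += cls_cum[hi] - cls_cum[lo]
    U = np.maximum(total_mass - P, 0.0)
    return n, P, U, q


def call_phas_loci(
    table: PositionTable,
    min_score: float | None = None,
    max_p: float = MAX_P_VALUE,
    cycles: int = DEFAULT_CYCLES,
    register_tolerance: int = 0,
) -> list[PhasLocus]:
    """Call phased loci from a position table.

    Every window start for which some occupied slot is in register is
    scored (equivalent to sliding by 1 position: windows without an
    in-register occupied slot have n = 0 and cannot pass).  Windows passing
    both thresholds are merged when overlapping; locus boundaries are the
    union of passing windows trimmed to the outermost phased read.  IDs are
    PHAS{period}-i in (chrom, start) order.
    """
    period = table.period
    if min_score is None:
        min_score = MIN_SCORE.get(period, 5.0)
    span = period * cycles
    loci: list[PhasLocus] = []

    for chrom in sorted(table.chroms):
        cp = table.chroms[chrom]
        if len(cp.occ_pos) == 0:
            continue
        # candidate starts: each occupied slot can anchor cycles windows
        cand = (cp.occ_pos[:, None] - np.arange(cycles)[None, :] * period).ravel()
        cand = np.unique(cand[cand >= 0])
        n, P, U, q = _window_stats(cp, cand, period, cycles, register_tolerance)
        mask = n >= 3
        if not mask.any():
            continue
        cand, n, P, U, q = cand[mask], n[mask], P[mask], U[mask], q[mask]
        with np.errstate(divide="ignore"):
            scores = (n - 2) * np.log1p(10.0 * P / (1.0 + U))
        pvals = stats.hypergeom.sf(n - 1, 2 * span, 2 * cycles, q)
        passing = (scores >= min_score) & (pvals < max_p)
        if not passing.any():
            continue

        # merge overlapping passing windows into loci
        order = np.argsort(cand[passing])
        starts = cand[passing][order]
        sc = scores[passing][order]
        pv = pvals[passing][order]
        clusters: list[list[int]] = [[0]]
        for i in range(1, len(starts)):
            if starts[i] <= starts[clusters[-1][-1]] + span:
                clusters[-1].append(i)
            else:
                clusters.append([i])
        for cluster in clusters:
            cl_starts = starts[cluster]
            best_score = float(sc[cluster].max())
            best_p = float(pv[cluster].min())
            # phased positions: occupied slots in register for some passing window
            phased_idx: set[int] = set()
            for s in cl_starts:
                sel = np.nonzero(
                    (cp.occ_pos >= s) & (cp.occ_pos < s + span)
                    & (np.abs((cp.occ_pos - s) % period - 0)
                       <= register_tolerance)
                )[0]
                # include wrap-around tolerance (period-1 counts as -1)
                sel2 = np.nonzero(
                    (cp.occ_pos >= s) & (cp.occ_pos < s + span)
                    & ((cp.occ_pos - s) % period >= period - register_tolerance)
                )[0] if register_tolerance else np.array([], dtype=int)
                phased_idx.update(sel.tolist())
                phased_idx.update(sel2.tolist())
            phased_idx = sorted(phased_idx)
            positions = [int(cp.occ_pos[i]) for i in phased_idx]
            lo, hi = min(positions), max(positions) + period
            lib_ab: dict[str, float] = defaultdict(float)
            for i in phased_idx:
                for lib, mass in cp.occ_libs[i].items():
                    lib_ab[lib] += mass
            loci.append(
                PhasLocus(
                    id="",
                    interval=Interval(chrom, lo, hi, "+"),
                    period=period,
                    score=best_score,
                    p_value=best_p,
                    registers=positions,
                    lib_abundance=dict(lib_ab),
                )
            )

    loci.sort(key=lambda l: (l.interval.chrom, l.interval.start))
    for i, locus in enumerate(loci, start=1):
        locus.id = f"PHAS{period}-{i}"
    return loci
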