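"""Secondary-structure prediction and duplex free-energy scoring.

Two independent primitives live here:

* :func:`fold` — hairpin-shape prediction used to evaluate miRNA precursor
  candidates.  The default backend is a weighted Nussinov base-pair
  maximization (G:U allowed, minimum hairpin loop 3 nt, traceback
  tie-broken toward 5'-most pairs).  Any conforming folder — e.g. a
  ViennaRNA wrapper — may be registered as an alternative backend; the
  downstream hairpin criteria only consume the pair list.

* :func:`duplex_energy` / :func:`mfe_ratio` — ungapped miRNA/target-site
  duplex scoring with a bundled nearest-neighbor stack table.  Energies are
  sums of stack terms over maximal runs of consecutive pairs (Watson-Crick
  and G:U); each mismatch contributes a fixed destabilizing penalty and
  breaks stacking.  The target-acceptance criterion downstream is a *ratio*
  of duplex energy to the perfect-complement energy, which is robust to
  affine rescaling of the table.

Sequences are DNA-alphabet internally (T for U).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Callable, Literal

import numpy as np

from .sequence_io import revcomp

MIN_LOOP = 3
MISMATCH_PENALTY = 1.0  # kcal/mol per mismatched position

# pair weights for the Nussinov objective (pseudo-stability units)
_PAIR_WEIGHT = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}

PairState = Literal["pair", "wobble", "mismatch"]


def pair_state(m: str, t: str) -> PairState:
    """Classify one duplex position: Watson-Crick pair, G:U wobble, or mismatch."""
    if (m, t) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
        return "pair"
    if (m, t) in {("G", "T"), ("T", "G")}:
        return "wobble"
    return "mismatch"


@dataclass
class SecondaryStructure:
    """Nested secondary structure: dot-bracket, pair list and pseudo-energy."""

    dotbracket: str
    pairs: list[tuple[int, int]]
    energy: float

    def partner_map(self) -> dict[int, int]:
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def validate(self) -> None:
        """Assert balanced brackets, nesting, and the minimum-loop rule."""
        stack = []
        for i, c in enumerate(self.dotbracket):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                assert i - j > MIN_LOOP, f"loop below minimum at pair ({j},{i})"
        assert not stack, "unbalanced brackets"
        for (i1, j1) in self.pairs:
            for (i2, j2) in self.pairs:
                # nested or disjoint, never crossing
                assert not (i1 < i2 < j1 < j2), f"pseudoknot {i1},{j1} x {i2},{j2}"


@dataclass
class DuplexAlignment:
    """Ungapped antiparallel miRNA/target duplex.

    ``states[i]`` describes miRNA position ``i+1`` (1-based from the miRNA
    5' end); the site sequence is given 5'->3' as it reads on the target.
    """

    mirna: str
    site: str
    states: list[PairState]
    energy: float

    def mismatch_positions(self, gu_is_mismatch: bool = True) -> list[int]:
        """1-based miRNA positions counted as mismatches by the rule engine."""
        bad = {"mismatch", "wobble"} if gu_is_mismatch else {"mismatch"}
        return [i + 1 for i, s in enumerate(self.states) if s in bad]


# ---------------------------------------------------------------------------
# Nussinov folding backend
# ---------------------------------------------------------------------------

def _nussinov_fold(seq: str) -> SecondaryStructure:
    n = len(seq)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            w[i, j] = _PAIR_WEIGHT.get((seq[i], seq[j]), -np.inf)
    # dp over diagonals; D[l][i] = best score of seq[i..i+l]
    diags = [np.zeros(n), np.zeros(n - 1) if n > 1 else np.zeros(0)]
    for l in range(2, n):
        m = n - l
        best = diags[l - 1][1 : m + 1].copy()            # i unpaired
        np.maximum(best, diags[l - 1][:m], out=best)     # j unpaired
        if l > MIN_LOOP:                                  # i pairs j
            pairij = diags[l - 2][1 : m + 1] + w[np.arange(m), np.arange(m) + l]
            np.maximum(best, pairij, out=best)
        for k in range(1, l):                             # bifurcation at i+k
            np.maximum(best, diags[k][:m] + diags[l - k - 1][k + 1 : k + 1 + m], out=best)
        diags.append(best)
    dp = np.full((n, n), 0.0)
    for l in range(1, n):
        for i in range(n - l):
            dp[i, i + l] = diags[l][i]

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        v = dp[i, j]
        if w[i, j] > -np.inf and np.isclose(v, dp[i + 1, j - 1] + w[i, j]):
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        elif np.isclose(v, dp[i + 1, j]):
            stack.append((i + 1, j))
        elif np.isclose(v, dp[i, j - 1]):
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if np.isclose(v, dp[i, k] + dp[k + 1, j]):
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    energy = -sum(_PAIR_WEIGHT[(seq[i], seq[j])] for i, j in pairs)
    return SecondaryStructure("".join(db), pairs, energy)


FOLD_BACKENDS: dict[str, Callable[[str], SecondaryStructure]] = {
    "nussinov": _nussinov_fold,
}


def fold(seq: str, backend: str = "nussinov") -> SecondaryStructure:
    """Predict a nested secondary structure for ``seq``.

    Raises ``ValueError`` when more than 5% of positions are outside ACGT.
    """
    seq = seq.upper().replace("U", "T")
    n_bad = sum(c not in "ACGT" for c in seq)
    if seq and n_bad / len(seq) > 0.05:
        raise ValueError(f"sequence has {n_bad}/{len(seq)} non-ACGT characters")
    return FOLD_BACKENDS[backend](seq)


# ---------------------------------------------------------------------------
# Duplex energies
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def load_stack_table() -> dict[tuple[str, str], float]:
    """Bundled nearest-neighbor stack table, keyed by (pair1, pair2).

    Each pair is a two-character string (first-strand base, second-strand
    base) in RNA letters; lookups here use the DNA alphabet and convert.
    """
    table = {}
    text = resources.files("phasikit.data").joinpath("duplex_stacks.tsv").read_text()
    for line in text.splitlines():
        if line.startswith("#") or line.startswith("pair1") or not line.strip():
            continue
        p1, p2, dg = line.split("\t")
        table[(p1.replace("U", "T"), p2.replace("U", "T"))] = float(dg)
    return table


def duplex_energy(
    mirna: str, site: str, mismatch_penalty: float = MISMATCH_PENALTY
) -> DuplexAlignment:
    """Score the ungapped antiparallel duplex of a miRNA and a target site.

    ``site`` is the target subsequence 5'->3'; miRNA position ``i`` (0-based)
    faces site position ``L-1-i``.  Energy = sum of stack terms over maximal
    runs of consecutive pairs (WC or G:U) + ``mismatch_penalty`` per mismatch.
    """
    if len(mirna) != len(site):
        raise ValueError(f"duplex length mismatch: {len(mirna)} vs {len(site)}")
    L = len(mirna)
    opposite = site[::-1]  # opposite[i] faces mirna[i]
    states = [pair_state(mirna[i], opposite[i]) for i in range(L)]
    table = load_stack_table()
    energy = mismatch_penalty * sum(s == "mismatch" for s in states)
    for i in range(L - 1):
        if states[i] != "mismatch" and states[i + 1] != "mismatch":
            key = (mirna[i] + opposite[i], mirna[i + 1] + opposite[i + 1])
            energy += table[key]
    return DuplexAlignment(mirna, site, states, energy)


@lru_cache(maxsize=4096)
def perfect_complement_energy(mirna: str) -> float:
    return duplex_energy(mirna, revcomp(mirna)).energy


def mfe_ratio(mirna: str, site: str) -> float:
    """Duplex energy relative to the perfect-complement duplex.

    1.0 for the exact complement; decreases (possibly below 0) with
    mismatches.  Raises for degenerate sequences whose perfect-complement
    energy is 0.
    """
    perfect = perfect_complement_energy(mirna)
    if perfect == 0:
        raise ValueError("degenerate sequence: perfect-complement energy is 0")
    return duplex_energy(mirna, site).energy / perfect
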