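"""Independent brute-force oracle for the four target-site rules.

Kept separate from the implementation: literal rule application per
window, with its own run-length logic.
"""

from phasikit.rna_thermo import duplex_energy, pair_state, perfect_complement_energy


def brute_force_accept(mirna, window, gu_is_mismatch=True, protect=True):
    opposite = window[::-1]
    bad = {"mismatch", "wobble"} if gu_is_mismatch else {"mismatch"}
    mism = [
        i + 1 for i in range(len(mirna)) if pair_state(mirna[i], opposite[i]) in bad
    ]
    if len(mism) > 4:
        return False
    best, run, prev = 0, 0, None
    for p in mism:
        run = run + 1 if prev == p - 1 else 1
        best = max(best, run)
        prev = p
    if best > 2:
        return False
    if protect and ({10, 11} & set(mism)):
        return False
    ratio = duplex_energy(mirna, window).energy / perfect_complement_energy(mirna)
    return ratio >= 0.74
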