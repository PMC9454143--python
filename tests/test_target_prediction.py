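import numpy as np
import pytest

from phasikit import target_prediction as tp
from phasikit.rna_thermo import duplex_energy, pair_state, perfect_complement_energy
from phasikit.sequence_io import revcomp

MIR = "TCGGACCAGGCTTCATTCCCC"  # 21 nt


def brute_force_accept(mirna, window, gu_is_mismatch=True, protect=True):
    """Independent literal application of the four rules."""
    opposite = window[::-1]
    bad = {"mismatch", "wobble"} if gu_is_mismatch else {"mismatch"}
    mism = [i + 1 for i in range(len(mirna))
            if pair_state(mirna[i], opposite[i]) in bad]
    if len(mism) > 4:
        return False
    run, best = 0, 0
    prev = None
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


def mutate(site, pos_1based, mirna):
    """Force a mismatch opposite the given miRNA position."""
    site = list(site)
    idx = len(site) - pos_1based
    m_base = mirna[pos_1based - 1]
    site[idx] = next(b for b in "ACGT" if pair_state(m_base, b) == "mismatch")
    return "".join(site)


class TestPredictTargets:
    def test_exact_complement_accepted(self):
        site = revcomp(MIR)
        hits = tp.predict_targets("m", MIR, {"t": "GGG" + site + "AAA"})
        assert len(hits) == 1
        h = hits[0]
        assert h.start == 4 and h.end == 24
        assert h.mismatches == () and h.ratio == pytest.approx(1.0)

    def test_mismatch_at_position_10_rejected(self):
        site = mutate(revcomp(MIR), 10, MIR)
        assert tp.predict_targets("m", MIR, {"t": site}) == []

    def test_five_scattered_mismatches_rejected(self):
        site = revcomp(MIR)
        for p in (1, 3, 5, 7, 14):
            site = mutate(site, p, MIR)
        assert tp.predict_targets("m", MIR, {"t": site}) == []

    def test_three_adjacent_mismatches_rejected(self):
        site = revcomp(MIR)
        for p in (4, 5, 6):
            site = mutate(site, p, MIR)
        assert tp.predict_targets("m", MIR, {"t": site}) == []

    def test_exhaustive_single_and_double_mismatch_oracle(self):
        perfect = revcomp(MIR)
        windows = [perfect]
        for p in range(1, 22):
            windows.append(mutate(perfect, p, MIR))
        for p in range(1, 22):
            for q in range(p + 1, 22):
                windows.append(mutate(mutate(perfect, p, MIR), q, MIR))
        for w in windows:
            got = bool(tp.predict_targets("m", MIR, {"t": w}))
            assert got == brute_force_accept(MIR, w), w

    def test_acceptance_invariant_under_translation(self):
        site = mutate(revcomp(MIR), 3, MIR)
        for pad in (0, 7, 40):
            t = "G" * pad + site + "C" * pad
            hits = tp.predict_targets("m", MIR, {"t": t})
            assert len(hits) == 1 and hits[0].start == pad + 1

    def test_equals_bruteforce_on_random_transcripts(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            mirna = "".join(rng.choice(list("ACGT"), 21))
            transcript = "".join(rng.choice(list("ACGT"), 200))
            got = {
                (h.start, h.end)
                for h in tp.predict_targets("m", mirna, {"t": transcript})
            }
            want = {
                (s + 1, s + 21)
                for s in range(len(transcript) - 20)
                if brute_force_accept(mirna, transcript[s : s + 21])
            }
            assert got == want

    def test_mirna_length_bounds(self):
        with pytest.raises(ValueError):
            tp.predict_targets("m", "ACGT" * 5 + "ACGTT", {"t": "A" * 30})  # 25 nt


class TestCleavagePosition:
    def test_site_at_100_cleaves_at_111(self):
        # 21-nt site occupying transcript 100..120 (1-based)
        t = "A" * 99 + revcomp(MIR) + "A" * 30
        # make flanks non-matching: perfect window only at 100
        hits = [h for h in tp.predict_targets("m", MIR, {"t": t}) if h.start == 100]
        assert hits and hits[0].cleavage == 100 + (21 - 10)
        assert tp.cleavage_position(hits[0]) == 111

    def test_adjacent_sites_shift_cleavage_equally(self):
        t = "GG" + revcomp(MIR) + revcomp(MIR) + "GG"
        hits = tp.predict_targets("m", MIR, {"t": t})
        starts = sorted(h.start for h in hits)
        cleaves = sorted(h.cleavage for h in hits)
        assert cleaves[1] - cleaves[0] == starts[1] - starts[0]

    def test_minus_strand_site_mirrors_plus_arithmetic(self):
        # a genomic region carrying the site on the minus strand: scanning
        # the reverse complement must find the mirrored window
        region = "T" * 50 + revcomp(revcomp(MIR)) + "T" * 50  # miRNA itself
        rc = revcomp(region)
        hits = tp.predict_targets("m", MIR, {"t": rc})
        assert len(hits) == 1
        h = hits[0]
        # mirrored site start: len(region) - (plus-strand end of the site)
        assert h.start == len(region) - (50 + 21) + 1
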