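import itertools
import math

import numpy as np
import pytest

from phasikit import phas_detection as pd_
from phasikit import synthetic_data as sd
from phasikit.read_mapper import AlignmentHit, build_index
from phasikit.sequence_io import CollapsedRead, Interval, collapse_sequences


class TestPhaseScore:
    def test_formula_ln31(self):
        assert pd_.phase_score(3, 3, 0) == pytest.approx(math.log(31), abs=1e-9)

    def test_formula_3ln21(self):
        assert pd_.phase_score(5, 10, 4) == pytest.approx(3 * math.log(21), abs=1e-9)

    def test_occupancy_floor(self):
        assert pd_.phase_score(2, 100, 0) == 0.0
        assert pd_.phase_score(0, 0, 0) == 0.0

    def test_monotone_in_phased_mass_and_occupancy(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 15))
            P = float(rng.uniform(0, 50))
            U = float(rng.uniform(0, 50))
            s = pd_.phase_score(n, P, U)
            assert pd_.phase_score(n + 1, P + 1, U) >= s       # one more phased read
            assert pd_.phase_score(n, P, U + 1) <= s           # one more unphased read
            assert s >= 0


class TestPhasePValue:
    def test_fully_phased_example(self):
        # all 4 occupied positions phased among N=20, m=4: 1/C(20,4)
        assert pd_.phase_pvalue(4, 20, 4, 4) == pytest.approx(1 / 4845, rel=1e-9)

    def test_n_zero_is_one(self):
        assert pd_.phase_pvalue(0, 20, 4, 4) == pytest.approx(1.0)

    def test_exhaustive_enumeration_small_n(self):
        # brute force over all C(N, q) placements for every N <= 12
        for N in range(2, 13):
            for m in range(1, N + 1):
                for q in range(0, N + 1):
                    placements = list(itertools.combinations(range(N), q))
                    for n in range(0, min(m, q) + 1):
                        count = sum(
                            1 for pl in placements
                            if sum(p < m for p in pl) >= n
                        )
                        expected = count / len(placements)
                        got = pd_.phase_pvalue(n, N, m, q)
                        assert got == pytest.approx(expected, abs=1e-12), (N, m, q, n)

    def test_q_exceeding_N_rejected(self):
        with pytest.raises(ValueError):
            pd_.phase_pvalue(1, 10, 2, 11)


def make_hit(chrom, start, length, strand):
    return AlignmentHit("N" * length, Interval(chrom, start, start + length, strand))


class TestPhaseRegisters:
    def test_minus_strand_duplex_partner_shares_register(self):
        # plus read 5' at 100; its duplex partner spans [98, 119): end+2 = 121
        plus = CollapsedRead("A" * 21, {"L": 1})
        minus = CollapsedRead("C" * 21, {"L": 1})
        hits = {
            plus.seq: [make_hit("c", 100, 21, "+")],
            minus.seq: [make_hit("c", 98, 21, "-")],
        }
        assert pd_.adjusted_position(hits[plus.seq][0]) % 21 == \
            pd_.adjusted_position(hits[minus.seq][0]) % 21

    def test_three_reads_one_register_class(self):
        reads = [CollapsedRead(b * 21, {"L": 1}) for b in "ACG"]
        hits = {r.seq: [make_hit("c", 21 * i, 21, "+")] for i, r in enumerate(reads)}
        table = pd_.phase_registers(reads, hits, 21)
        cp = table.chroms["c"]
        assert len(cp.occ_pos) == 3
        assert len(set(cp.occ_pos % 21)) == 1

    def test_wrong_length_contributes_unphased_only(self):
        r = CollapsedRead("A" * 22, {"L": 5})
        hits = {r.seq: [make_hit("c", 0, 22, "+")]}
        table = pd_.phase_registers([r], hits, 21)
        cp = table.chroms["c"]
        assert len(cp.occ_pos) == 0
        assert cp.all_mass.sum() == 5


class TestCallPhasLoci:
    def _planted_table(self, seed=2, period=21):
        kind = "PHAS21" if period == 21 else "PHAS24"
        feats = [sd.PlantedFeature(kind, "chr1", 50_000, {"n_cycles": 9})]
        g = sd.generate_genome(
            sd.SyntheticGenomeSpec(chrom_lengths={"chr1": 60_000}, seed=seed), feats
        )
        cfg = sd.ReadSimConfig(depth=480, noise_fraction=0.0,
                               polya_rate=0.0, short_rate=0.0, seed=seed)
        reads, _ = sd.simulate_reads(g, cfg)
        collapsed = collapse_sequences(reads)
        idx = build_index(g.genome)
        hits = {r.seq: idx.map_read(r.seq) for r in collapsed}
        return g, pd_.phase_registers(collapsed, hits, period)

    def test_planted_locus_called_once_within_one_cycle(self):
        g, table = self._planted_table()
        loci = pd_.call_phas_loci(table)
        assert len(loci) == 1
        locus = loci[0]
        f = g.features[0]
        planted_lo, planted_hi = f.registers[0], f.registers[-1] + 21
        assert locus.score >= 10 and locus.p_value < 1e-3
        assert abs(locus.interval.start - planted_lo) <= 21
        assert abs(locus.interval.end - planted_hi) <= 21

    def test_two_loci_ordered_by_start(self):
        feats = [sd.PlantedFeature("PHAS21", "chr1", 40_000, {"n_cycles": 9}),
                 sd.PlantedFeature("PHAS21", "chr1", 42_300, {"n_cycles": 9})]
        g = sd.generate_genome(
            sd.SyntheticGenomeSpec(chrom_lengths={"chr1": 60_000}, seed=3), feats
        )
        cfg = sd.ReadSimConfig(depth=960, noise_fraction=0.0,
                               polya_rate=0.0, short_rate=0.0, seed=3)
        reads, _ = sd.simulate_reads(g, cfg)
        collapsed = collapse_sequences(reads)
        idx = build_index(g.genome)
        hits = {r.seq: idx.map_read(r.seq) for r in collapsed}
        loci = pd_.call_phas_loci(pd_.phase_registers(collapsed, hits, 21))
        assert [l.id for l in loci] == ["PHAS21-1", "PHAS21-2"]
        assert loci[0].interval.start < loci[1].interval.start

    def test_no_reads_empty(self):
        table = pd_.phase_registers([], {}, 21)
        assert pd_.call_phas_loci(table) == []

    def test_strand_symmetry_under_reverse_complement(self):
        # reverse-complementing the genome mirrors the locus with equal score
        g, table = self._planted_table(seed=4)
        loci = pd_.call_phas_loci(table)
        from phasikit.sequence_io import revcomp

        rc_genome = {"chr1": revcomp(g.genome["chr1"])}
        cfg = sd.ReadSimConfig(depth=480, noise_fraction=0.0,
                               polya_rate=0.0, short_rate=0.0, seed=4)
        reads, _ = sd.simulate_reads(g, cfg)
        collapsed = collapse_sequences(reads)
        idx = build_index(rc_genome)
        hits = {r.seq: idx.map_read(r.seq) for r in collapsed}
        rc_loci = pd_.call_phas_loci(pd_.phase_registers(collapsed, hits, 21))
        assert len(rc_loci) == len(loci) == 1
        assert rc_loci[0].score == pytest.approx(loci[0].score)
        # mirrored boundaries: the strand-adjustment (+2 overhang shift and
        # the 21-nt right-extension of register positions) moves the
        # interval by a fixed 23-nt offset under reverse complement
        L = len(g.genome["chr1"])
        assert rc_loci[0].interval.start == L - loci[0].interval.end + 23
        assert rc_loci[0].interval.end == L - loci[0].interval.start + 23
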