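import pandas as pd
import pytest

from phasikit import trigger_identification as ti
from phasikit.mirna_identification import MirnaRecord
from phasikit.phas_detection import PhasLocus
from phasikit.sequence_io import Interval, revcomp

MIR390 = "AAGCTCAGGAGGGATAGCGCC"


def locus(chrom="c", start=1000, period=21, cycles=9, id="PHAS21-1"):
    regs = [start + k * period for k in range(cycles)]
    return PhasLocus(id, Interval(chrom, start, regs[-1] + period), period,
                     50.0, 1e-9, regs)


def mir390_record():
    return MirnaRecord("fan-miR390a", "known", MIR390, family="miR390")


class TestFindTriggers:
    def _genome_with_site(self, register_shift=0):
        import numpy as np

        rng = np.random.default_rng(6)
        seq = list("".join(rng.choice(list("ACGT"), 2000)))
        # cleavage c = s + L - 10 must hit the register (1000) + shift
        s = 1000 + 10 - 21 + register_shift
        seq[s : s + 21] = revcomp(MIR390)
        return {"c": "".join(seq)}

    def test_in_register_site_reported_one_hit(self):
        genome = self._genome_with_site()
        pairs = ti.find_triggers(locus(), [mir390_record()], genome)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.model == "ONE_HIT" and p.family == "miR390"
        assert p.register_offset == 0

    def test_out_of_register_site_not_a_trigger(self):
        genome = self._genome_with_site(register_shift=5)
        assert ti.find_triggers(locus(), [mir390_record()], genome) == []

    def test_one_off_register_within_tolerance(self):
        genome = self._genome_with_site(register_shift=1)
        pairs = ti.find_triggers(locus(), [mir390_record()], genome)
        assert len(pairs) == 1 and pairs[0].register_offset == 1

    def test_no_site_empty(self):
        import numpy as np

        rng = np.random.default_rng(8)
        genome = {"c": "".join(rng.choice(list("ACGT"), 2000))}
        assert ti.find_triggers(locus(), [mir390_record()], genome) == []

    def test_planted_one_hit_triggers_recovered(self, recovery_seed1):
        r = recovery_seed1
        assert r.trigger_recall == 1.0
        for pair in r.bundle.trigger_pairs:
            assert pair.register_offset == 0


class TestTwoHit:
    def test_planted_two_hit_recovered(self, recovery_seed1):
        r = recovery_seed1
        two_hits = [p for p in r.bundle.trigger_pairs if p.model == "TWO_HIT"]
        assert len(two_hits) == 1
        pair = two_hits[0]
        assert pair.family == "miR390"
        assert pair.anchor_site is not None
        # the cleavable 3' site lies downstream of the anchor
        assert pair.anchor_site.start < pair.site.start

    def test_single_site_is_not_two_hit(self):
        import numpy as np

        rng = np.random.default_rng(9)
        seq = list("".join(rng.choice(list("ACGT"), 2000)))
        s = 1000 + 10 - 21
        seq[s : s + 21] = revcomp(MIR390)
        genome = {"c": "".join(seq)}
        assert ti.detect_two_hit(locus(), [mir390_record()], genome) is None


class TestSummaries:
    def test_family_extraction(self):
        assert ti.trigger_family("miR482a/b/y") == "miR482"
        assert ti.trigger_family(" miRN14") == "miRN14"
        assert ti.trigger_family("miR11288b/e/i/l/n") == "miR11288"
        assert ti.is_novel_family("miRN3") and not ti.is_novel_family("miR390")

    def test_reference_table_counts(self):
        table = ti.load_reference_pairs()
        s = ti.trigger_table_summary(table)
        assert s["loci_21"] == 40
        assert s["loci_24"] == 12
        assert s["genic_21"] == 22
        assert s["known_families_21"] == 14
        assert s["novel_families_21"] == 3
        assert s["families_21"] == 17
        assert s["known_families_24"] == 7
        assert s["tas3_like"] == 2

    def test_summarize_empty(self):
        out = ti.summarize_triggers([])
        assert out.empty

    def test_summarize_merges_members_per_locus(self):
        pairs = [
            ti.TriggerPair("PHAS21-1", "miR390", ("fan-miR390a", "fan-miR390b"),
                           (21,), Interval("c", 0, 21), "ONE_HIT", 0),
            ti.TriggerPair("PHAS21-1", "miRN2", ("fan-miRN2a",),
                           (22,), Interval("c", 100, 122), "ONE_HIT", 0),
        ]
        out = ti.summarize_triggers(pairs, {"PHAS21-1": "TAS3-like"}, {})
        assert len(out) == 1
        row = out.iloc[0]
        assert row["putative_function"] == "TAS3-like"
        assert "miR390" in row["trigger"] and "miRN2" in row["trigger"]
        s = ti.trigger_table_summary(out)
        assert s["loci_21"] == 1 and s["families_21"] == 2
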