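import pytest

from phasikit import mirna_identification as mi
from phasikit import synthetic_data as sd
from phasikit.read_mapper import AlignmentHit
from phasikit.sequence_io import CollapsedRead, Interval


def cread(seq, total=100):
    return CollapsedRead(seq, {"L": total})


class TestCatalog:
    def test_read_catalog_family_tags(self, tmp_path):
        p = tmp_path / "cat.fa"
        p.write_text(">fan-miR166a family=miR166\nUCGGACCAGGCUUCAUUCCCC\n")
        entries = mi.read_catalog(p)
        assert entries[0].family == "miR166"
        assert entries[0].mature == "TCGGACCAGGCTTCATTCCCC"


class TestMatchKnown:
    CAT = [
        mi.MirnaCatalogEntry("fan-miR166a", "miR166", "TCGGACCAGGCTTCATTCCCC"),
        mi.MirnaCatalogEntry("fan-miR166b", "miR166", "TCGGACCAGGCTTCATTCCCC"),
        mi.MirnaCatalogEntry("fan-miR390a", "miR390", "AAGCTCAGGAGGGATAGCGCC"),
    ]

    def test_exact_match_inherits_family(self):
        recs = mi.match_known([cread("TCGGACCAGGCTTCATTCCCC")], self.CAT)
        assert len(recs) == 1 and recs[0].family == "miR166"
        assert recs[0].status == "known"

    def test_one_mismatch_not_known(self):
        recs = mi.match_known([cread("TCGGACCAGGCTTCATTCCCA")], self.CAT)
        assert recs == []

    def test_duplicate_entries_take_lexicographic_first_id(self):
        recs = mi.match_known([cread("TCGGACCAGGCTTCATTCCCC")], self.CAT)
        assert recs[0].id == "fan-miR166a"


class TestProposeNovel:
    def _hit(self, seq, chrom, start, strand="+"):
        return AlignmentHit(seq, Interval(chrom, start, start + len(seq), strand))

    def test_window_arithmetic(self):
        seq = "A" * 21
        r = cread(seq)
        hits = {seq: [self._hit(seq, "c", 5000)]}
        cands = mi.propose_novel([r], hits, set(), {"c": 100_000})
        w1, w2 = cands[0].windows
        assert (w1.start, w1.end) == (4980, 5171)
        assert (w2.start, w2.end) == (4850, 5041)
        assert all(len(w) <= 191 for w in (w1, w2))

    def test_window_clipped_at_chromosome_start(self):
        seq = "A" * 21
        hits = {seq: [self._hit(seq, "c", 10)]}
        cands = mi.propose_novel([cread(seq)], hits, set(), {"c": 100_000})
        assert cands[0].windows[1].start == 0

    def test_multimapped_read_excluded(self):
        seq = "A" * 21
        hits = {seq: [self._hit(seq, "c", 100), self._hit(seq, "c", 50_000)]}
        assert mi.propose_novel([cread(seq)], hits, set(), {"c": 100_000}) == []

    def test_low_abundance_excluded(self):
        seq = "A" * 21
        hits = {seq: [self._hit(seq, "c", 100)]}
        assert mi.propose_novel([cread(seq, total=5)], hits, set(), {"c": 100_000}) == []

    def test_read_near_known_mature_absorbed(self):
        seq = "A" * 21
        hits = {seq: [self._hit(seq, "c", 100)]}
        anchors = [Interval("c", 60, 81, "+")]
        assert mi.propose_novel([cread(seq)], hits, set(), {"c": 100_000},
                                known_anchors=anchors) == []


class TestEvaluateHairpin:
    def test_planted_hairpin_passes_with_star(self, recovery_seed1):
        bundle = recovery_seed1.bundle
        novel = bundle.novel_mirnas
        assert {r.mature for r in novel} == set(sd.NOVEL_MATURES)
        for rec in novel:
            assert rec.star is not None
            assert rec.precursor is not None

    def test_phased_window_fails_duplex_mass(self, recovery_seed1):
        # a phased read evaluated as a hairpin candidate must fail (d):
        # read mass at a phased locus is spread over many registers
        bundle = recovery_seed1.bundle
        g = recovery_seed1.synthetic
        phas = next(f for f in g.features if f.kind == "PHAS21")
        reg = phas.registers[0]
        seq = g.genome[phas.chrom][reg : reg + 21]
        read = next(r for r in bundle.clean_reads if r.seq == seq)
        hit = next(
            h for h in bundle.hits_by_seq[seq]
            if h.interval.start == reg and h.strand == "+"
        )
        cand = mi.PrecursorCandidate(
            read, hit,
            [Interval(phas.chrom, reg - 20, reg + 171, "+"),
             Interval(phas.chrom, reg - 150, reg + 41, "+")],
        )
        ev = mi.evaluate_hairpin(cand, g.genome, bundle.clean_reads, bundle.hits_by_seq)
        assert not ev.passed
        assert any(f.startswith("d:") for f in ev.failures)

    def test_mature_in_loop_fails_arm_criterion(self):
        # construct a hairpin whose "mature" candidate sits in the loop
        from phasikit.sequence_io import revcomp
        import numpy as np

        rng = np.random.default_rng(8)
        stem = "".join(rng.choice(list("ACGT"), 40))
        loop = "".join(rng.choice(list("ACGT"), 24))
        genome = {"c": "".join(rng.choice(list("ACGT"), 50)) + stem + loop
                  + revcomp(stem) + "".join(rng.choice(list("ACGT"), 50))}
        mature = loop[1:22]
        start = genome["c"].find(mature)
        read = cread(mature)
        hit = AlignmentHit(mature, Interval("c", start, start + 21, "+"))
        cand = mi.PrecursorCandidate(
            read, hit,
            [Interval("c", max(0, start - 60), min(len(genome["c"]), start + 81), "+")],
        )
        ev = mi.evaluate_hairpin(cand, genome, [read], {mature: [hit]})
        assert not ev.passed

    def test_bad_mature_length_fails(self):
        seq = "A" * 25
        cand = mi.PrecursorCandidate(
            cread(seq), AlignmentHit(seq, Interval("c", 0, 25, "+")), []
        )
        ev = mi.evaluate_hairpin(cand, {"c": "A" * 100}, [], {})
        assert ev.failures == ["e:mature-length"]


class TestAssignFamily:
    def rec(self, mature, total):
        return mi.MirnaRecord("", "novel", mature, mature_counts={"L": total})

    def test_one_mismatch_same_family(self):
        recs = mi.assign_family([self.rec("ACGTACGTACGTACGTACGTA", 10),
                                 self.rec("ACGTACGTACCTACGTACGTA", 5)])
        assert recs[0].family == recs[1].family == "miRN1"
        assert {r.id for r in recs} == {"fan-miRN1a", "fan-miRN1b"}

    def test_three_mismatches_different_families(self):
        recs = mi.assign_family([self.rec("ACGTACGTACGTACGTACGTA", 10),
                                 self.rec("TGCTACGTACCTACGTACGTA", 5)])
        assert recs[0].family != recs[1].family

    def test_different_lengths_never_join(self):
        recs = mi.assign_family([self.rec("ACGTACGTACGTACGTACGTA", 10),
                                 self.rec("ACGTACGTACGTACGTACGT", 9)])
        assert recs[0].family != recs[1].family

    def test_numbering_by_descending_abundance_and_stable(self):
        records = [self.rec("ACGTACGTACGTACGTACGTA", 5),
                   self.rec("TTTTGGGGCCCCAAAATTTTT", 50)]
        out1 = mi.assign_family([*records])
        out2 = mi.assign_family([*records])
        top = next(r for r in out1 if r.total == 50)
        assert top.family == "miRN1"
        assert [(r.id, r.family) for r in out1] == [(r.id, r.family) for r in out2]
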