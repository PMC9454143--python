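import numpy as np
import pytest
from scipy import stats

from phasikit import synthetic_data as sd
from phasikit.sequence_io import revcomp


class TestGenerateGenome:
    def test_determinism_byte_identical(self, tmp_path):
        a = sd.generate_genome(sd.SyntheticGenomeSpec(seed=7))
        b = sd.generate_genome(sd.SyntheticGenomeSpec(seed=7))
        assert a.genome == b.genome

    def test_hairpin_contains_mature_and_revcomp_nearby(self, synthetic_seed1):
        g = synthetic_seed1
        for f in g.features:
            if f.kind != "MIRNA_HAIRPIN":
                continue
            m = f.params["mature"]
            chrom = g.genome[f.chrom]
            pm = chrom.find(m, f.interval.start)
            ps = chrom.find(revcomp(m), f.interval.start)
            assert f.interval.start <= pm < f.interval.end
            assert 0 < ps - pm < 300

    def test_phas_registers_spacing(self, synthetic_seed1):
        for f in synthetic_seed1.features:
            if f.period:
                diffs = np.diff(f.registers)
                assert (diffs == f.period).all()
                assert len(f.registers) == f.params.get("n_cycles", 9)

    def test_trigger_site_is_revcomp_of_mirna(self, synthetic_seed1):
        g = synthetic_seed1
        for f in g.features:
            for iv, model in f.trigger_sites:
                site = g.genome[iv.chrom][iv.start : iv.end]
                if model in ("ONE_HIT", "THREE_PRIME"):
                    assert site == revcomp(f.params["trigger"])

    def test_overlapping_features_rejected(self):
        feats = [
            sd.PlantedFeature("MIRNA_HAIRPIN", "chr1", 20_000,
                              {"mature": sd.NOVEL_MATURES[0]}),
            sd.PlantedFeature("MIRNA_HAIRPIN", "chr1", 20_030,
                              {"mature": sd.NOVEL_MATURES[1]}),
        ]
        with pytest.raises(ValueError, match="overlap"):
            sd.generate_genome(sd.SyntheticGenomeSpec(seed=1), feats)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            sd.SyntheticGenomeSpec(chrom_lengths={"c": 5_000})
        with pytest.raises(ValueError):
            sd.SyntheticGenomeSpec(gc=1.2)


class TestSimulateReads:
    def test_noise_free_phas_reads_are_in_register(self):
        feats = [sd.PlantedFeature("PHAS21", "chr1", 50_000,
                                   {"n_cycles": 9, "trigger": None})]
        spec = sd.SyntheticGenomeSpec(chrom_lengths={"chr1": 60_000}, seed=2)
        g = sd.generate_genome(spec, feats)
        cfg = sd.ReadSimConfig(depth=500, noise_fraction=0.0,
                               polya_rate=0.0, short_rate=0.0, seed=2)
        reads, _ = sd.simulate_reads(g, cfg)
        f = g.features[0]
        registers = set(f.registers)
        chrom = g.genome["chr1"]
        for lib_reads in reads.values():
            for seq in lib_reads:
                if seq in chrom:  # plus-strand read: starts at a register
                    assert chrom.find(seq) in registers
                else:  # minus-strand duplex partner, 2-nt 3' overhang
                    s = chrom.find(revcomp(seq))
                    assert (s + 2) in registers

    def test_tissue_multiplier_ratio_within_binomial_error(self):
        # two symmetric features (em:4/en:1 vs em:1/en:4) keep per-library
        # normalization balanced, so the em:en count ratio of the first
        # feature is exactly 4:1 in expectation
        feats = [
            sd.PlantedFeature("MIRNA_HAIRPIN", "chr1", 20_000,
                              {"mature": sd.NOVEL_MATURES[0]},
                              multipliers={"em": 4.0, "en": 1.0}),
            sd.PlantedFeature("MIRNA_HAIRPIN", "chr1", 30_000,
                              {"mature": sd.NOVEL_MATURES[1]},
                              multipliers={"em": 1.0, "en": 4.0}),
        ]
        g = sd.generate_genome(
            sd.SyntheticGenomeSpec(chrom_lengths={"chr1": 50_000}, seed=3), feats
        )
        cfg = sd.ReadSimConfig(depth=20_000, seed=3)
        _, truth = sd.simulate_reads(g, cfg)
        t = truth[truth["feature"] == g.features[0].name]
        em = t[t["library"].str.contains("_em")]["count"].sum()
        en = t[t["library"].str.contains("_en")]["count"].sum()
        n, p = em + en, 4.0 / 5.0
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(em - n * p) < 3 * sigma

    def test_seed_reproducibility_identical_fastq(self, tmp_path):
        g = sd.generate_genome(sd.SyntheticGenomeSpec(seed=4))
        cfg = sd.ReadSimConfig(depth=2_000, seed=4)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.simulate_reads(g, cfg, out_dir=d1)
        sd.simulate_reads(g, cfg, out_dir=d2)
        for lib in sd.library_ids():
            assert (d1 / f"{lib}.fastq").read_bytes() == (d2 / f"{lib}.fastq").read_bytes()

    def test_depth_zero_rejected(self):
        with pytest.raises(ValueError):
            sd.ReadSimConfig(depth=0)

    def test_length_histogram_matches_weights_chi2(self):
        # background-only libraries vs the configured length distribution
        spec = sd.SyntheticGenomeSpec(chrom_lengths={"chr1": 20_000}, seed=0)
        failures = 0
        for seed in range(1, 11):
            g = sd.generate_genome(spec, features=[])
            cfg = sd.ReadSimConfig(depth=3_000, noise_fraction=0.99,
                                   polya_rate=0.0, short_rate=0.0, seed=seed)
            reads, _ = sd.simulate_reads(g, cfg)
            lengths = [len(s) for lib in sorted(reads) for s in reads[lib]]
            obs = np.array([lengths.count(k) for k in sorted(cfg.length_weights)])
            exp = np.array([cfg.length_weights[k] for k in sorted(cfg.length_weights)])
            exp = exp / exp.sum() * obs.sum()
            _, p = stats.chisquare(obs, exp)
            if p < 0.001:
                failures += 1
        assert failures == 0
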