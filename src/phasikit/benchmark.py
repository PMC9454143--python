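"""Planted-feature recovery benchmarks on synthetic data.

These helpers run the whole pipeline on a synthetic genome and score every
caller against the generator's truth tables: hairpin-miRNA recall, phased-
locus recall per period, trigger recall (including the two-hit
configuration), and false loci on register-free null genomes.  They are
used by the test suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import phas_detection, read_mapper, synthetic_data as sd
from .pipeline import PipelineBundle, PipelineConfig, run_pipeline
from .sequence_io import collapse_sequences


@dataclass
class RecoveryResult:
    bundle: PipelineBundle
    synthetic: sd.SyntheticGenome
    hairpin_total: int
    hairpin_recovered: int
    phas21_total: int
    phas21_recovered: int
    phas24_total: int
    phas24_recovered: int
    trigger_total: int
    trigger_recovered: int
    two_hit_expected: int
    two_hit_recovered: int

    @property
    def hairpin_recall(self) -> float:
        return self.hairpin_recovered / self.hairpin_total if self.hairpin_total else 1.0

    @property
    def phas21_recall(self) -> float:
        return self.phas21_recovered / self.phas21_total if self.phas21_total else 1.0

    @property
    def phas24_recall(self) -> float:
        return self.phas24_recovered / self.phas24_total if self.phas24_total else 1.0

    @property
    def trigger_recall(self) -> float:
        return self.trigger_recovered / self.trigger_total if self.trigger_total else 1.0


def _locus_for_feature(feature: sd.PlantedFeature, loci) -> object | None:
    for locus in loci:
        if locus.interval.overlaps(feature.interval):
            return locus
    return None


def run_recovery(
    seed: int,
    depth: int = 20_000,
    noise_fraction: float | None = None,
    min_hairpin_reads: int = 50,
) -> RecoveryResult:
    """Simulate the default feature layout and score all callers."""
    genome = sd.generate_genome(sd.SyntheticGenomeSpec(seed=seed))
    cfg = sd.ReadSimConfig(depth=depth, seed=seed)
    if noise_fraction is not None:
        cfg = sd.ReadSimConfig(depth=depth, noise_fraction=noise_fraction, seed=seed)
    reads, truth = sd.simulate_reads(genome, cfg)
    collapsed = collapse_sequences(reads)
    pconfig = PipelineConfig(catalog=str(sd.bundled_catalog_path()), seed=seed)
    bundle = run_pipeline(
        pconfig, annotation=genome.annotation, genome=genome.genome,
        reads=collapsed, contaminants=genome.contaminants,
    )

    feature_counts = truth.groupby("feature")["count"].sum().to_dict()
    recovered_matures = {r.mature for r in bundle.mirna_records()}

    hp_total = hp_found = 0
    for f in genome.features:
        if f.kind != "MIRNA_HAIRPIN":
            continue
        if feature_counts.get(f.name, 0) < min_hairpin_reads:
            continue
        hp_total += 1
        if f.params["mature"] in recovered_matures:
            hp_found += 1

    p21_total = p21_found = p24_total = p24_found = 0
    trig_total = trig_found = th_exp = th_found = 0
    for f in genome.features:
        if f.kind in {"PHAS21", "TAS3_TWO_HIT"}:
            p21_total += 1
            locus = _locus_for_feature(f, bundle.loci[21])
            if locus is not None:
                p21_found += 1
        elif f.kind == "PHAS24":
            p24_total += 1
            locus = _locus_for_feature(f, bundle.loci[24])
            if locus is not None:
                p24_found += 1
        else:
            continue
        if not f.trigger_sites:
            continue
        trig_total += 1
        expected_model = "TWO_HIT" if f.kind == "TAS3_TWO_HIT" else "ONE_HIT"
        if expected_model == "TWO_HIT":
            th_exp += 1
        if locus is None:
            continue
        for pair in bundle.trigger_pairs:
            if (
                pair.phas_id == locus.id
                and pair.family == f.params.get("trigger_family")
                and pair.model == expected_model
            ):
                trig_found += 1
                if expected_model == "TWO_HIT":
                    th_found += 1
                break

    return RecoveryResult(
        bundle, genome, hp_total, hp_found, p21_total, p21_found,
        p24_total, p24_found, trig_total, trig_found, th_exp, th_found,
    )


def run_null(seed: int, chrom_length: int = 20_000, depth: int = 2_000) -> dict[int, int]:
    """Loci called on a register-free genome (uniform background reads).

    The per-bp read density matches the default recovery configuration.
    """
    spec = sd.SyntheticGenomeSpec(chrom_lengths={"chr1": chrom_length}, seed=seed)
    genome = sd.generate_genome(spec, features=[])
    cfg = sd.ReadSimConfig(
        depth=depth, noise_fraction=0.99, polya_rate=0.0, short_rate=0.0, seed=seed
    )
    reads, _ = sd.simulate_reads(genome, cfg)
    collapsed = collapse_sequences(reads)
    index = read_mapper.build_index(genome.genome)
    hits = {r.seq: index.map_read(r.seq) for r in collapsed}
    out = {}
    for period in (21, 24):
        table = phas_detection.phase_registers(collapsed, hits, period)
        out[period] = len(phas_detection.call_phas_loci(table))
    return out
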