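"""Synthetic genomes with planted sRNA features and simulated read libraries.

The generator emulates the statistical structure of an embryo/endosperm
sRNA-seq experiment: 12 libraries (2 reciprocal crosses x 2 tissues x 3
replicates), 16-30 nt reads with a length distribution peaking at 24 nt,
planted miRNA hairpins (mature >> star), planted 21-nt and 24-nt phased
loci whose registers are set by miRNA cleavage sites, a TAS3-like two-hit
locus, structural-ncRNA contamination, mRNA degradation fragments, and
tissue-specific abundance multipliers.

Planted-feature geometry
------------------------
* Hairpins embed the mature sequence and its reverse complement separated
  by a >= 15-nt loop; the star *read* is offset so the mature/star duplex
  carries 2-nt 3' overhangs.
* Phased loci embed a 5' trigger site whose cleavage point (between the
  target bases pairing miRNA positions 10-11) coincides with the first
  phase register.
* The two-hit locus carries two miR390-family sites flanking the phased
  cycles; the 3' site is cleavable and in register, the 5' site carries
  mismatches at miRNA positions 10-11 (a non-cleavable anchor).
* Minus-strand phased reads start 2 nt before the register so that
  sense/antisense duplexes have 2-nt 3' overhangs.

Truth tables record every planted register, site and per-library expected
abundance, sufficient to score recall/precision of all downstream callers
without re-reading the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import (
    FastaRecord,
    GeneFeature,
    GenomeAnnotation,
    Interval,
    revcomp,
    write_fasta,
)

BASES = np.array(list("ACGT"))

CROSSES = ("BS", "SB")
TISSUES = ("em", "en")
N_REPS = 3

# default length distribution for background/degradation reads, peaking at
# 24 nt with 23 and 22 nt as the next most abundant classes
DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {
    16: 0.010, 17: 0.010, 18: 0.015, 19: 0.020, 20: 0.050,
    21: 0.100, 22: 0.120, 23: 0.150, 24: 0.300, 25: 0.100,
    26: 0.050, 27: 0.030, 28: 0.020, 29: 0.015, 30: 0.010,
}

# mature sequences (DNA alphabet) for planted novel hairpins; arbitrary
# 21-mers that match no catalog entry
NOVEL_MATURES = (
    "TACGATTGGCACTTGAACGTC",
    "GCTTAGACCTTGCAACGGTAT",
)


def library_ids() -> list[str]:
    return [
        f"{cross}_{tissue}{rep}"
        for cross in CROSSES
        for tissue in TISSUES
        for rep in range(1, N_REPS + 1)
    ]


def tissue_of(lib: str) -> str:
    return "em" if "_em" in lib else "en"


def bundled_catalog_path() -> Path:
    """Path to the bundled known-mature-miRNA catalog FASTA."""
    return Path(str(resources.files("phasikit.data").joinpath("known_mirnas.fa")))


@dataclass
class SyntheticGenomeSpec:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100_000, "chr2": 100_000}
    )
    gc: float = 0.40
    seed: int = 1

    def __post_init__(self) -> None:
        if any(n < 10_000 for n in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be >= 10 kb")
        if not 0 < self.gc < 1:
            raise ValueError("GC fraction must be in (0, 1)")


@dataclass
class PlantedFeature:
    """A feature to embed in the synthetic genome.

    ``params`` keys by kind:
      MIRNA_HAIRPIN: mature, star_ratio (star:mature, default 0.1)
      PHAS21/PHAS24: n_cycles, trigger (mature seq or None), trigger_family
      TAS3_TWO_HIT: n_cycles, trigger, trigger_family
      NCRNA: length, ncrna_class
      MRNA_DEGRADATION: (none)
    Common: abundance (relative weight), multipliers {tissue: factor}.
    """

    kind: str
    chrom: str
    start: int
    params: dict = field(default_factory=dict)
    abundance: float = 1.0
    multipliers: dict[str, float] = field(default_factory=lambda: {"em": 1.0, "en": 1.0})

    # resolved at generation time
    interval: Interval | None = None
    registers: list[int] = field(default_factory=list)
    period: int | None = None
    mature_interval: Interval | None = None
    star_interval: Interval | None = None
    star_seq: str | None = None
    trigger_sites: list[tuple[Interval, str]] = field(default_factory=list)  # (site, model)
    name: str = ""


@dataclass
class ReadSimConfig:
    depth: int = 20_000                # reads per library
    # genomic background reads (the hc-siRNA-like majority of real
    # embryo/endosperm libraries, with the 24-nt-peaked length profile)
    noise_fraction: float = 0.75
    polya_rate: float = 0.01           # polyA artifact reads
    short_rate: float = 0.01           # <16-nt fragments
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    dirichlet_concentration: float = 3.0  # unevenness of per-cycle abundance
    star_ratio: float = 0.10           # default star:mature read ratio
    seed: int = 1

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise fraction must be in [0, 1)")
        total = sum(self.length_weights.values())
        if abs(total - 1.0) > 1e-6:
            self.length_weights = {k: v / total for k, v in self.length_weights.items()}


@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    features: list[PlantedFeature]
    annotation: GenomeAnnotation
    contaminants: list[tuple[FastaRecord, str]]
    spec: SyntheticGenomeSpec

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write genome FASTA plus truth GFF3/BED files; returns path map."""
        from .sequence_io import write_bed, write_gff3

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "genes": out / "genes.gff3",
            "repeats": out / "repeats.bed",
            "contaminants": out / "contaminants.fa",
            "truth": out / "truth_features.tsv",
        }
        write_fasta(
            [FastaRecord(c, s) for c, s in sorted(self.genome.items())], paths["genome"]
        )
        write_gff3(self.annotation.genes, paths["genes"])
        write_bed(self.annotation.repeats, paths["repeats"])
        write_fasta(
            [FastaRecord(f"{rec.id} class={cls}", rec.seq) for rec, cls in self.contaminants],
            paths["contaminants"],
        )
        truth_table(self.features).to_csv(paths["truth"], sep="\t", index=False)
        return paths


def truth_table(features: Sequence[PlantedFeature]) -> pd.DataFrame:
    rows = []
    for f in features:
        rows.append(
            {
                "name": f.name,
                "kind": f.kind,
                "chrom": f.chrom,
                "start": f.interval.start if f.interval else f.start,
                "end": f.interval.end if f.interval else "",
                "period": f.period or "",
                "registers": ",".join(map(str, f.registers)),
                "trigger_family": f.params.get("trigger_family", ""),
                "abundance": f.abundance,
                "mult_em": f.multipliers.get("em", 1.0),
                "mult_en": f.multipliers.get("en", 1.0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

_HAIRPIN_FLANK = 10
_HAIRPIN_LOOP = 15


def _mutate_non_pairing(site: list[str], idx: int, mirna_base: str) -> None:
    """Set site[idx] to a base that neither WC-pairs nor wobbles with mirna_base."""
    from .rna_thermo import pair_state

    for b in "ACGT":
        if pair_state(mirna_base, b) == "mismatch":
            site[idx] = b
            return


def _build_hairpin(f: PlantedFeature, genome: np.ndarray, offset: int) -> None:
    mature = f.params["mature"]
    L = len(mature)
    arm2 = revcomp(mature)
    layout = (
        "N" * _HAIRPIN_FLANK + mature + "N" * _HAIRPIN_LOOP + arm2 + "N" * _HAIRPIN_FLANK
    )
    pm = offset + _HAIRPIN_FLANK
    ps = pm + L + _HAIRPIN_LOOP
    for i, c in enumerate(layout):
        if c != "N":
            genome[offset + i] = c
    f.interval = Interval(f.chrom, offset, offset + len(layout), "+")
    f.mature_interval = Interval(f.chrom, pm, pm + L, "+")
    # star read shifted +2 so the mature/star duplex has 2-nt 3' overhangs
    f.star_interval = Interval(f.chrom, ps + 2, ps + L + 2, "+")


def _build_phas(f: PlantedFeature, genome: np.ndarray, offset: int) -> None:
    period = 21 if f.kind in {"PHAS21", "TAS3_TWO_HIT"} else 24
    n_cycles = f.params.get("n_cycles", 9)
    if n_cycles < 4:
        raise ValueError("PHAS features need n_cycles >= 4")
    trigger = f.params.get("trigger")
    two_hit = f.kind == "TAS3_TWO_HIT"

    a = offset + (50 if two_hit else 40)  # leave room for upstream site(s)
    f.period = period
    f.registers = [a + k * period for k in range(n_cycles)]
    region_end = a + n_cycles * period
    f.interval = Interval(f.chrom, offset, region_end + 24, "+")

    if trigger:
        L = len(trigger)
        site = list(revcomp(trigger))
        if two_hit:
            # cleavable 3' site sets the register: cleavage at region_end == a (mod period)
            s3 = region_end + 10 - L
            for i, c in enumerate(site):
                genome[s3 + i] = c
            f.trigger_sites.append((Interval(f.chrom, s3, s3 + L, "+"), "THREE_PRIME"))
            # non-cleavable 5' anchor: mismatches at miRNA positions 10-11
            anchor = list(revcomp(trigger))
            _mutate_non_pairing(anchor, L - 10, trigger[9])
            _mutate_non_pairing(anchor, L - 11, trigger[10])
            s5 = offset + 4
            for i, c in enumerate(anchor):
                genome[s5 + i] = c
            f.trigger_sites.append((Interval(f.chrom, s5, s5 + L, "+"), "FIVE_PRIME"))
        else:
            # one-hit: cleavage between bases pairing miRNA 10-11 lands on register a
            s = a + 10 - L
            for i, c in enumerate(site):
                genome[s + i] = c
            f.trigger_sites.append((Interval(f.chrom, s, s + L, "+"), "ONE_HIT"))


def _build_ncrna(f: PlantedFeature, genome: np.ndarray, offset: int, rng) -> str:
    length = f.params.get("length", 120)
    seq = "".join(rng.choice(BASES, size=length))
    for i, c in enumerate(seq):
        genome[offset + i] = c
    f.interval = Interval(f.chrom, offset, offset + length, "+")
    return seq


def default_features() -> list[PlantedFeature]:
    """The default planted-feature layout used by tests and the pipeline demo."""
    from .mirna_identification import read_catalog

    catalog = read_catalog(bundled_catalog_path())
    by_family = {e.family: e.mature for e in catalog}
    mir390 = by_family["miR390"]
    mir482 = by_family["miR482"]
    mir172 = by_family["miR172"]

    feats = [
        # two hairpins carrying catalog (known) matures
        PlantedFeature("MIRNA_HAIRPIN", "chr1", 5_000,
                       {"mature": by_family["miR166"]},
                       abundance=2.0, multipliers={"em": 4.0, "en": 1.0}),
        PlantedFeature("MIRNA_HAIRPIN", "chr1", 15_000,
                       {"mature": by_family["miR159"]},
                       abundance=2.0, multipliers={"em": 1.0, "en": 4.0}),
        # two novel hairpins
        PlantedFeature("MIRNA_HAIRPIN", "chr1", 25_000,
                       {"mature": NOVEL_MATURES[0]}, abundance=1.5),
        PlantedFeature("MIRNA_HAIRPIN", "chr1", 35_000,
                       {"mature": NOVEL_MATURES[1]}, abundance=1.5,
                       multipliers={"em": 4.0, "en": 1.0}),
        # hairpins expressing the trigger miRNAs of the phased loci below
        PlantedFeature("MIRNA_HAIRPIN", "chr2", 44_000, {"mature": mir390},
                       abundance=1.5),
        PlantedFeature("MIRNA_HAIRPIN", "chr2", 46_000, {"mature": mir482},
                       abundance=1.5),
        PlantedFeature("MIRNA_HAIRPIN", "chr2", 48_000, {"mature": mir172},
                       abundance=1.5),
        # 21-nt phased loci with one-hit triggers
        PlantedFeature("PHAS21", "chr1", 50_000,
                       {"n_cycles": 9, "trigger": mir390, "trigger_family": "miR390"},
                       abundance=3.0, multipliers={"em": 1.0, "en": 2.0}),
        PlantedFeature("PHAS21", "chr1", 60_000,
                       {"n_cycles": 9, "trigger": mir482, "trigger_family": "miR482"},
                       abundance=3.0),
        # TAS3-like two-hit locus
        PlantedFeature("TAS3_TWO_HIT", "chr1", 70_000,
                       {"n_cycles": 8, "trigger": mir390, "trigger_family": "miR390"},
                       abundance=3.0),
        # 24-nt phased loci: one triggered, one trigger-free (repeat-resident)
        PlantedFeature("PHAS24", "chr2", 10_000,
                       {"n_cycles": 9, "trigger": mir172, "trigger_family": "miR172"},
                       abundance=3.0, multipliers={"em": 2.0, "en": 1.0}),
        PlantedFeature("PHAS24", "chr2", 20_000, {"n_cycles": 9}, abundance=3.0),
        # contamination sources
        PlantedFeature("NCRNA", "chr2", 40_000, {"length": 120, "ncrna_class": "rRNA"},
                       abundance=2.0),
        PlantedFeature("MRNA_DEGRADATION", "chr2", 60_000, {"length": 1_000},
                       abundance=1.0),
    ]
    return feats


def generate_genome(
    spec: SyntheticGenomeSpec, features: Sequence[PlantedFeature] | None = None
) -> SyntheticGenome:
    """Generate a random-background genome and embed the planted features.

    Deterministic given ``spec.seed``.  Raises on overlapping features.
    """
    if features is None:
        features = default_features()
    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc / 2
    p_at = (1 - spec.gc) / 2
    genome_arr: dict[str, np.ndarray] = {}
    for chrom, length in sorted(spec.chrom_lengths.items()):
        genome_arr[chrom] = rng.choice(BASES, size=length, p=[p_at, p_gc, p_gc, p_at])

    contaminants: list[tuple[FastaRecord, str]] = []
    genes: list[GeneFeature] = []
    repeats: list[Interval] = []
    ncrna_ivs: list[Interval] = []

    features = list(features)
    for i, f in enumerate(features):
        f.name = f"{f.kind}_{i}"
        if f.chrom not in genome_arr:
            raise ValueError(f"unknown chromosome {f.chrom}")
        if f.kind == "MIRNA_HAIRPIN":
            _build_hairpin(f, genome_arr[f.chrom], f.start)
        elif f.kind in {"PHAS21", "PHAS24", "TAS3_TWO_HIT"}:
            _build_phas(f, genome_arr[f.chrom], f.start)
        elif f.kind == "NCRNA":
            seq = _build_ncrna(f, genome_arr[f.chrom], f.start, rng)
            contaminants.append(
                (FastaRecord(f"synthetic_{f.params.get('ncrna_class', 'rRNA')}_{i}", seq),
                 f.params.get("ncrna_class", "rRNA"))
            )
            ncrna_ivs.append(f.interval)
        elif f.kind == "MRNA_DEGRADATION":
            length = f.params.get("length", 1_000)
            f.interval = Interval(f.chrom, f.start, f.start + length, "+")
            genes.append(GeneFeature(f.interval, f"gene-deg-{i}", "uncharacterized mRNA"))
        else:
            raise ValueError(f"unknown feature kind {f.kind}")

    for i, f1 in enumerate(features):
        for f2 in features[i + 1 :]:
            if f1.interval.overlaps(f2.interval):
                raise ValueError(f"features overlap: {f1.name} and {f2.name}")

    # annotation truth: gene products over selected phased loci; one
    # repeat-resident 24-nt locus; ncRNA label over the two-hit locus target
    products = {"PHAS21": "PPR", "TAS3_TWO_HIT": "TAS3-like", "PHAS24": ""}
    seen_kind: dict[str, int] = {}
    for f in features:
        if f.kind in {"PHAS21", "TAS3_TWO_HIT", "PHAS24"}:
            n = seen_kind.get(f.kind, 0)
            seen_kind[f.kind] = n + 1
            if f.kind == "PHAS21" and n == 1:
                genes.append(GeneFeature(f.interval, f"gene-ppr-{f.start}", "PPR"))
            elif f.kind == "TAS3_TWO_HIT":
                genes.append(GeneFeature(f.interval, f"gene-tas3-{f.start}", "TAS3-like"))
            elif f.kind == "PHAS24" and n == 1:
                repeats.append(
                    Interval(f.chrom, f.interval.start - 100, f.interval.end + 100, "+")
                )

    genome = {c: "".join(arr) for c, arr in genome_arr.items()}
    annotation = GenomeAnnotation(genes=genes, repeats=repeats, ncrnas=ncrna_ivs)
    return SyntheticGenome(genome, features, annotation, contaminants, spec)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _sample_length(rng, weights: dict[int, float]) -> int:
    lengths = sorted(weights)
    probs = np.array([weights[k] for k in lengths])
    return int(rng.choice(lengths, p=probs / probs.sum()))


def _emit_feature_read(
    f: PlantedFeature,
    genome: Mapping[str, str],
    rng,
    config: ReadSimConfig,
    cycle_weights: Mapping[str, np.ndarray],
) -> str | None:
    chrom_seq = genome[f.chrom]
    if f.kind == "MIRNA_HAIRPIN":
        ratio = f.params.get("star_ratio", config.star_ratio)
        if rng.random() < ratio / (1.0 + ratio):
            iv = f.star_interval
        else:
            iv = f.mature_interval
        return chrom_seq[iv.start : iv.end]
    if f.kind in {"PHAS21", "PHAS24", "TAS3_TWO_HIT"}:
        w = cycle_weights[f.name]
        reg = f.registers[int(rng.choice(len(w), p=w))]
        p = f.period
        if rng.random() < 0.5:
            return chrom_seq[reg : reg + p]
        # minus-strand duplex partner: 2-nt 3' overhangs on both strands
        return revcomp(chrom_seq[reg - 2 : reg + p - 2])
    if f.kind == "NCRNA":
        iv = f.interval
        L = min(_sample_length(rng, config.length_weights), len(iv))
        s = iv.start + int(rng.integers(0, len(iv) - L + 1))
        return chrom_seq[s : s + L]
    if f.kind == "MRNA_DEGRADATION":
        iv = f.interval
        L = min(_sample_length(rng, config.length_weights), len(iv))
        s = iv.start + int(rng.integers(0, len(iv) - L + 1))
        frag = chrom_seq[s : s + L]
        return frag if rng.random() < 0.5 else revcomp(frag)
    raise ValueError(f.kind)


def simulate_reads(
    synthetic: SyntheticGenome,
    config: ReadSimConfig,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Simulate the 12-library read set.

    Returns (reads per library, truth count table).  If ``out_dir`` is
    given, also writes one FASTQ per library.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genome = synthetic.genome
    features = synthetic.features

    # per-feature cycle weights (Dirichlet, drawn once so loci are unevenly
    # but consistently covered across libraries)
    cycle_weights: dict[str, np.ndarray] = {}
    for f in features:
        if f.registers:
            w = rng.dirichlet([config.dirichlet_concentration] * len(f.registers))
            cycle_weights[f.name] = w

    reads: dict[str, list[str]] = {}
    truth_rows = []
    for lib in library_ids():
        tissue = tissue_of(lib)
        weights = np.array(
            [f.abundance * f.multipliers.get(tissue, 1.0) for f in features]
        )
        frac_special = config.polya_rate + config.short_rate
        frac_features = max(0.0, 1.0 - config.noise_fraction - frac_special)
        wsum = float(weights.sum())
        if wsum == 0:
            frac_features = 0.0
        categories = (
            [frac_features * w / wsum if wsum else 0.0 for w in weights]
            + [1.0 - frac_features - frac_special, config.polya_rate, config.short_rate]
        )
        counts = rng.multinomial(config.depth, np.array(categories) / sum(categories))
        lib_reads: list[str] = []
        for f, n in zip(features, counts[: len(features)]):
            for _ in range(int(n)):
                seq = _emit_feature_read(f, genome, rng, config, cycle_weights)
                if seq:
                    lib_reads.append(seq)
            truth_rows.append({"library": lib, "feature": f.name, "kind": f.kind,
                               "count": int(n)})
        # genomic background noise
        chroms = sorted(genome)
        chrom_lens = np.array([len(genome[c]) for c in chroms], dtype=float)
        for _ in range(int(counts[len(features)])):
            L = _sample_length(rng, config.length_weights)
            ci = int(rng.choice(len(chroms), p=chrom_lens / chrom_lens.sum()))
            chrom = chroms[ci]
            s = int(rng.integers(0, len(genome[chrom]) - L + 1))
            frag = genome[chrom][s : s + L]
            lib_reads.append(frag if rng.random() < 0.5 else revcomp(frag))
        truth_rows.append({"library": lib, "feature": "noise", "kind": "NOISE",
                           "count": int(counts[len(features)])})
        # polyA artifacts and sub-16-nt fragments (exercise preprocess filters)
        for _ in range(int(counts[len(features) + 1])):
            lib_reads.append("A" * _sample_length(rng, config.length_weights))
        for _ in range(int(counts[len(features) + 2])):
            L = int(rng.integers(12, 16))
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            s = int(rng.integers(0, len(genome[chrom]) - L + 1))
            lib_reads.append(genome[chrom][s : s + L])
        reads[lib] = lib_reads

    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for lib in library_ids():
            with open(out / f"{lib}.fastq", "w") as fh:
                for i, seq in enumerate(reads[lib]):
                    fh.write(f"@{lib}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        truth.to_csv(out / "truth_counts.tsv", sep="\t", index=False)
    return reads, truth
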