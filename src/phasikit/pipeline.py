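"""End-to-end orchestration: preprocess -> map -> {miRNA, PHAS} -> reports.

The pipeline mirrors a standard sRNA-seq workflow: reads are collapsed to
unique sequences, cleaned (length/polyA/ncRNA filters), perfectly matched
to the genome, then analysed along two branches.  The miRNA branch removes
reads overlapping annotated mRNA or repeats (degradation products), calls
known miRNAs against the mature catalog, evaluates novel hairpin
candidates, quantifies TPM and differential expression between tissues.
The PHAS branch keeps all mapped reads (repeat-resident phased loci are
real signal), calls 21-nt and 24-nt loci, assigns miRNA triggers, and
annotates loci against genes/repeats.

Every stage logs read-mass conservation; re-running with the same config
and seed reproduces the output bundle bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import (
    expression,
    locus_annotation,
    mirna_identification as mirna_id,
    phas_detection,
    preprocess,
    read_mapper,
    trigger_identification as triggers,
)
from .mirna_identification import MirnaRecord
from .phas_detection import PhasLocus
from .sequence_io import (
    CollapsedRead,
    GenomeAnnotation,
    Interval,
    collapse_reads,
    read_bed,
    read_fasta,
    read_gff3,
)


@dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run.

    Thresholds default to the workflow's standard screening values:
    16-30 nt read window, fold change >= 2 with P < 0.05 for differential
    expression, phase score >= 10 (21-nt) / >= 5 (24-nt) with P < 0.001
    for locus calling, and a duplex-energy ratio >= 0.74 for targets.
    """

    genome: str = ""
    annotation_gff: str | None = None
    repeats_bed: str | None = None
    catalog: str | None = None
    contaminants: str | None = None
    fastq: dict[str, str] = field(default_factory=dict)
    out_dir: str = "phasikit_out"
    seed: int = 1

    min_len: int = 16
    max_len: int = 30
    kmer: int = 12
    min_novel_reads: int = 20
    phas_cycles: int = 9
    phas_min_score_21: float = 10.0
    phas_min_score_24: float = 5.0
    phas_max_p: float = 1e-3
    trigger_flank: int = 200
    register_tolerance: int = 1
    known_groups_k: int = 5
    novel_groups_k: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        missing = [
            p for p in [cfg.genome, cfg.catalog, cfg.contaminants, *cfg.fastq.values()]
            if p and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"configured inputs do not exist: {missing}")
        return cfg


@dataclass
class PipelineBundle:
    """All per-stage outputs of one pipeline run."""

    config: PipelineConfig
    filter_report: preprocess.FilterReport
    clean_reads: list[CollapsedRead]
    hits_by_seq: dict[str, list]
    library_totals: dict[str, float]
    known_mirnas: list[MirnaRecord]
    novel_mirnas: list[MirnaRecord]
    de_results: dict[str, list[expression.DEResult]]
    loci: dict[int, list[PhasLocus]]
    trigger_pairs: list[triggers.TriggerPair]
    locus_overlaps: dict[int, list[locus_annotation.AnnotationOverlap]]
    locus_functions: dict[str, str]
    annotation: GenomeAnnotation

    def mirna_records(self) -> list[MirnaRecord]:
        return self.known_mirnas + self.novel_mirnas


def _mirna_count_matrix(records: Sequence[MirnaRecord], libraries: Sequence[str]) -> pd.DataFrame:
    rows = {
        rec.id: {lib: rec.mature_counts.get(lib, 0) for lib in libraries}
        for rec in records
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(libraries)).fillna(0)


def run_pipeline(
    config: PipelineConfig,
    annotation: GenomeAnnotation | None = None,
    genome: Mapping[str, str] | None = None,
    reads: list[CollapsedRead] | None = None,
    contaminants: list | None = None,
) -> PipelineBundle:
    """Execute all stages; in-memory genome/annotation/reads may override paths."""
    if genome is None:
        genome = {r.id.split()[0]: r.seq for r in read_fasta(config.genome)}
    if annotation is None:
        genes = read_gff3(config.annotation_gff) if config.annotation_gff else []
        repeats = (
            [iv for iv, _, _ in read_bed(config.repeats_bed)] if config.repeats_bed else []
        )
        annotation = GenomeAnnotation(genes=genes, repeats=repeats)

    # stage 1-2: collapse + clean
    raw = reads if reads is not None else collapse_reads(config.fastq)
    filtered, report = preprocess.quality_filter(raw, config.min_len, config.max_len)
    if contaminants is None:
        contaminants = []
        if config.contaminants:
            import re

            for rec in read_fasta(config.contaminants):
                m = re.search(r"class=(\S+)", rec.id)
                contaminants.append((rec, m.group(1) if m else "rRNA"))
    clean, removed_nc = preprocess.filter_ncrna(filtered, contaminants)
    report.removed_ncrna = {
        cls: dict(libcounts) for cls, libcounts in removed_nc.items()
    }
    report.retained = {}
    for read in clean:
        for lib, n in read.counts.items():
            report.retained[lib] = report.retained.get(lib, 0) + n
    report.assert_mass_conserved()

    # stage 3: perfect-match mapping
    index = read_mapper.build_index(genome, k=config.kmer)
    hits_by_seq = {r.seq: index.map_read(r.seq) for r in clean}
    mapped = [r for r in clean if hits_by_seq[r.seq]]
    library_totals: dict[str, float] = {}
    for read in mapped:
        for lib, n in read.counts.items():
            library_totals[lib] = library_totals.get(lib, 0) + n

    # stage 4: miRNA branch (degradation/repeat reads removed here only);
    # a read survives if at least one placement is outside mRNA/repeat
    # annotation — miRNAs legitimately match their own target transcripts
    mirna_reads = []
    for read in mapped:
        kept, _ = read_mapper.remove_annotation_overlaps(hits_by_seq[read.seq], annotation)
        if kept:
            mirna_reads.append(read)
    catalog = mirna_id.read_catalog(config.catalog) if config.catalog else []
    known = mirna_id.match_known(mirna_reads, catalog)
    known_seqs = {rec.mature for rec in known}
    known_anchors = [
        h.interval for seq in known_seqs for h in hits_by_seq.get(seq, [])
    ]
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    candidates = mirna_id.propose_novel(
        mirna_reads, hits_by_seq, known_seqs, chrom_lengths,
        config.min_novel_reads, known_anchors,
    )
    novel = []
    for cand in candidates:
        ev = mirna_id.evaluate_hairpin(cand, genome, mapped, hits_by_seq)
        if ev.passed:
            novel.append(ev.record)
    novel = mirna_id.assign_family(novel)

    # stage 5: expression / differential expression per cross (em vs en)
    libraries = sorted(library_totals)
    de_results: dict[str, list[expression.DEResult]] = {}
    records = known + novel
    if records and libraries:
        counts = _mirna_count_matrix(records, libraries)
        tpm = expression.tpm_normalize(counts, library_totals)
        crosses = sorted({lib.split("_")[0] for lib in libraries if "_" in lib})
        for cross in crosses:
            em = [l for l in libraries if l.startswith(f"{cross}_em")]
            en = [l for l in libraries if l.startswith(f"{cross}_en")]
            if len(em) >= 2 and len(en) >= 2:
                de_results[cross] = expression.differential_expression(tpm, em, en)

    # stage 6: PHAS branch on all mapped reads
    loci: dict[int, list[PhasLocus]] = {}
    for period, min_score in ((21, config.phas_min_score_21), (24, config.phas_min_score_24)):
        table = phas_detection.phase_registers(mapped, hits_by_seq, period)
        loci[period] = phas_detection.call_phas_loci(
            table, min_score=min_score, max_p=config.phas_max_p, cycles=config.phas_cycles
        )

    # stage 7: triggers
    trigger_pairs: list[triggers.TriggerPair] = []
    for period in (21, 24):
        for locus in loci[period]:
            trigger_pairs.extend(
                triggers.find_triggers(
                    locus, records, genome,
                    flank=config.trigger_flank, tolerance=config.register_tolerance,
                )
            )

    # stage 8: locus annotation
    locus_overlaps = {
        period: locus_annotation.annotate_loci(loci[period], annotation)
        for period in (21, 24)
    }
    locus_functions = {}
    for period in (21, 24):
        for locus, ov in zip(loci[period], locus_overlaps[period]):
            locus_functions[locus.id] = locus_annotation.classify_putative_function(
                locus, annotation, ov
            )

    return PipelineBundle(
        config, report, clean, hits_by_seq, library_totals,
        known, novel, de_results, loci, trigger_pairs, locus_overlaps,
        locus_functions, annotation,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def summary_report(bundle: PipelineBundle) -> dict:
    """Recountable summary of the bundle (no hidden state)."""
    known_fams = {r.family for r in bundle.known_mirnas}
    novel_fams = {r.family for r in bundle.novel_mirnas}
    summary = {
        "known_mirnas": len(bundle.known_mirnas),
        "novel_mirnas": len(bundle.novel_mirnas),
        "known_families": len(known_fams),
        "novel_families": len(novel_fams),
        "phas21_loci": len(bundle.loci.get(21, [])),
        "phas24_loci": len(bundle.loci.get(24, [])),
        "two_hit_loci": len({p.phas_id for p in bundle.trigger_pairs if p.model == "TWO_HIT"}),
    }
    for period in (21, 24):
        overlaps = bundle.locus_overlaps.get(period, [])
        summary[f"phas{period}_genic"] = sum(ov.genic for ov in overlaps)
        summary[f"phas{period}_intergenic"] = sum(not ov.genic for ov in overlaps)
        ids = {l.id for l in bundle.loci.get(period, [])}
        triggered = {p.phas_id for p in bundle.trigger_pairs if p.phas_id in ids}
        fams = {p.family for p in bundle.trigger_pairs if p.phas_id in ids}
        summary[f"phas{period}_triggered"] = len(triggered)
        summary[f"phas{period}_trigger_families_known"] = sum(
            not triggers.is_novel_family(f) for f in fams
        )
        summary[f"phas{period}_trigger_families_novel"] = sum(
            triggers.is_novel_family(f) for f in fams
        )
    for cross, results in bundle.de_results.items():
        summary[f"de_significant_{cross}"] = sum(r.significant for r in results)
    return summary


def export_locus_track(
    bundle: PipelineBundle, locus: PhasLocus, rp_norm: float = 1e7
) -> pd.DataFrame:
    """Per-position track for one locus (+- 1 cycle): position, strand,
    length class, abundance in RP10M, and the phase score at phased
    positions (0 elsewhere)."""
    iv = locus.interval
    lo, hi = iv.start - locus.period, iv.end + locus.period
    total = sum(bundle.library_totals.values()) or 1.0
    phased = set(locus.registers)
    rows = []
    for read in bundle.clean_reads:
        hits = bundle.hits_by_seq.get(read.seq, [])
        for hit in hits:
            hiv = hit.interval
            if hiv.chrom != iv.chrom or hiv.end <= lo or hiv.start >= hi:
                continue
            five_prime = hiv.start if hiv.strand == "+" else hiv.end - 1
            adj = phas_detection.adjusted_position(hit)
            rows.append(
                {
                    "position": five_prime,
                    "strand": hiv.strand,
                    "length": len(read.seq),
                    "rp10m": read.total / len(hits) / total * rp_norm,
                    "phase_score": locus.score if adj in phased else 0.0,
                }
            )
    track = pd.DataFrame(
        rows, columns=["position", "strand", "length", "rp10m", "phase_score"]
    )
    return track.sort_values(["position", "strand"]).reset_index(drop=True)


def write_bundle(bundle: PipelineBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write all human-facing tables (1-based inclusive coordinates)."""
    from .sequence_io import write_bed, write_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    mirna_rows = []
    for rec in bundle.mirna_records():
        mirna_rows.append(
            {
                "id": rec.id, "status": rec.status, "family": rec.family,
                "mature": rec.mature, "star": rec.star or "",
                "precursor": (
                    f"{rec.precursor.chrom}:{rec.precursor.start + 1}-{rec.precursor.end}"
                    if rec.precursor else ""
                ),
                "total": rec.total,
                **{f"count_{lib}": n for lib, n in sorted(rec.mature_counts.items())},
            }
        )
    paths["mirnas"] = out / "mirnas.tsv"
    write_tsv(pd.DataFrame(mirna_rows), paths["mirnas"])

    de_rows = [
        {"comparison": cross, "id": r.id, "log2_fc": r.log2_fc,
         "p_value": r.p_value, "significant": r.significant}
        for cross, results in sorted(bundle.de_results.items())
        for r in results
    ]
    paths["de"] = out / "differential_expression.tsv"
    write_tsv(pd.DataFrame(de_rows), paths["de"])

    all_loci = [l for period in (21, 24) for l in bundle.loci.get(period, [])]
    paths["loci_bed"] = out / "phas_loci.bed"
    write_bed(
        [l.interval for l in all_loci], paths["loci_bed"],
        names=[l.id for l in all_loci], scores=[round(l.score, 3) for l in all_loci],
    )
    locus_rows = [
        {
            "id": l.id, "chrom": l.interval.chrom,
            "start": l.interval.start + 1, "end": l.interval.end,
            "period": l.period, "score": round(l.score, 4), "p_value": l.p_value,
            "putative_function": bundle.locus_functions.get(l.id, "NULL"),
        }
        for l in all_loci
    ]
    paths["loci"] = out / "phas_loci.tsv"
    write_tsv(pd.DataFrame(locus_rows), paths["loci"])

    functions = bundle.locus_functions
    genes = {
        ov.locus_id: ov.gene_label
        for period in (21, 24)
        for ov in bundle.locus_overlaps.get(period, [])
    }
    trigger_table = triggers.summarize_triggers(bundle.trigger_pairs, functions, genes)
    paths["triggers"] = out / "triggers.tsv"
    write_tsv(trigger_table, paths["triggers"])

    paths["summary"] = out / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary_report(bundle), fh, indent=2, sort_keys=True)
    return paths


def bundle_digest(bundle: PipelineBundle) -> str:
    """Deterministic content hash of the bundle's summary-level output."""
    payload = json.dumps(
        {
            "summary": summary_report(bundle),
            "loci": [
                (l.id, l.interval.chrom, l.interval.start, l.interval.end,
                 round(l.score, 6))
                for period in (21, 24) for l in bundle.loci.get(period, [])
            ],
            "mirnas": sorted((r.id, r.mature) for r in bundle.mirna_records()),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()
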