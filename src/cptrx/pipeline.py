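"""End-to-end orchestration: classify → filter → scan → profile → TIS/TTS.

Every stage accounts for its inputs in an attrition table (input = passed +
dropped per reason code), mirroring the bookkeeping used when the method was
developed: aligned reads → reads with primers → transcripts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from . import classify as _classify
from . import profile as _profile
from . import sites as _sites
from . import tis as _tis
from . import tts as _tts
from .classify import (
    AlignedRead,
    ClassifiedRead,
    ClassifyParams,
    PrimerSet,
    ReadClass,
    aligned_reads_from_sam,
    class_counts,
    classify_read,
    filter_alignment,
)
from .core import (
    Genome,
    StrandAssignment,
    Transcript,
    assign_strands,
    load_annotations,
    load_genome,
    write_bed,
)

log = logging.getLogger("cptrx")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and counts so far."""

    def __init__(self, stage: str, message: str, counts: dict):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage
        self.counts = counts


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run.

    Threshold defaults are the documented package defaults; the config
    round-trips through YAML unchanged.
    """

    genome: str = ""
    annotations: str = ""
    reads: str = ""
    alignments: str = ""
    outdir: str = "cptrx_out"
    five_prime_primer: str = _classify.DEFAULT_P5
    three_prime_primer: str = _classify.DEFAULT_P3
    polyT_min: int = 8
    max_edit_frac: float = 0.10
    end_search_window: int = 100
    min_aligned: int = 200
    min_aligned_frac: float = 0.05
    p5_seed_len: int = 8
    p5_max_edits: int = 1
    min_t_run: int = 8
    polya_window: int = 25
    polya_min_a_frac: float = 0.7
    polya_min_a_run: int = 5
    tis_min_support: int = 10
    tis_merge_radius: int = 0
    splice_tol: int = 0
    tts_tol: int = 10
    trunc_tol: int = 10
    unit_min_len: int = 300
    unit_max_gap: int = 50
    unit_min_depth: Optional[float] = None  # default: half strand mean
    editing_min_depth: int = 10
    editing_min_alt_frac: float = 0.2
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def primers(self) -> PrimerSet:
        return PrimerSet(
            five_prime=self.five_prime_primer,
            three_prime=self.three_prime_primer,
            polyT_min=self.polyT_min,
        )

    @property
    def classify_params(self) -> ClassifyParams:
        return ClassifyParams(
            max_edit_frac=self.max_edit_frac,
            end_search_window=self.end_search_window,
            polyT_min=self.polyT_min,
        )


@dataclass
class PipelineResult:
    genome: Genome
    assignment: Optional[StrandAssignment]
    attrition: pd.DataFrame
    class_counts: dict
    transcripts: list[Transcript]
    tis_report: Optional[_tis.TisReport]
    tts_calls: list
    tts_unassigned: list
    units: list
    summary: dict
    junctions: list
    editing: list
    snp_like: list
    sites: list
    polya_sites: list


def build_transcript(
    classified: ClassifiedRead, aligned: AlignedRead
) -> Optional[Transcript]:
    """Join a FULL_LENGTH classification with its alignment.

    The transcribed strand combines the read's transcript sense (from primer
    topology) with the alignment orientation; the aligned blocks give the
    genomic coordinates and the aligned portion of the read gives the
    transcript sequence when available.
    """
    if classified.sense is None:
        return None
    fastq_is_ref_forward = aligned.strand == "+"
    strand = "+" if classified.sense == fastq_is_ref_forward else "-"
    from .core import revcomp

    seq = aligned.aligned_seq
    return Transcript(
        id=classified.read_id,
        strand=strand,
        blocks=list(aligned.spliced_blocks),
        seq=seq if strand == "+" else revcomp(seq),
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole analysis; deterministic given config + inputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    attrition_rows: list[dict] = []
    counts_so_far: dict = {}

    def attr(stage: str, input_n: int, passed: int, dropped: dict) -> None:
        total_dropped = sum(dropped.values())
        if input_n != passed + total_dropped:
            raise StageError(
                stage, "attrition does not conserve read count", counts_so_far
            )
        attrition_rows.append(
            {"stage": stage, "input": input_n, "passed": passed,
             **{f"dropped_{k}": v for k, v in dropped.items()}}
        )

    # --- load inputs -----------------------------------------------------
    try:
        genome = load_genome(config.genome)
    except Exception as exc:  # noqa: BLE001
        raise StageError("load_genome", str(exc), counts_so_far) from exc
    annotations = []
    assignment = None
    if config.annotations:
        annotations = load_annotations(config.annotations)
        if annotations:
            assignment = assign_strands(genome, annotations)
    reads = {}
    if config.reads:
        fmt = "fastq" if Path(config.reads).suffix.lower() in (
            ".fastq", ".fq"
        ) else "fasta"
        reads = {
            r.id: str(r.seq).upper()
            for r in SeqIO.parse(config.reads, fmt)
        }
    aligned = aligned_reads_from_sam(config.alignments) if config.alignments else []
    aligned_by_id = {a.read_id: a for a in aligned}
    counts_so_far["reads"] = len(reads)
    counts_so_far["alignments"] = len(aligned)

    # --- stage 1: alignment filters --------------------------------------
    kept_alignments: dict[str, AlignedRead] = {}
    drop_reasons = {"short_aligned": 0, "low_cov": 0}
    for a in aligned:
        keep, reason = filter_alignment(
            a, config.min_aligned, config.min_aligned_frac
        )
        if keep:
            kept_alignments[a.read_id] = a
        else:
            drop_reasons[reason] += 1
    attr("filter_alignment", len(aligned), len(kept_alignments), drop_reasons)

    # --- stage 2: classification -----------------------------------------
    primers = config.primers
    params = config.classify_params
    pool = (
        {rid: reads[rid] for rid in reads if rid in kept_alignments}
        if aligned
        else dict(reads)
    )
    unaligned_reads = len(reads) - len(pool)
    classified: dict[str, ClassifiedRead] = {
        rid: classify_read(seq, primers, params, read_id=rid)
        for rid, seq in sorted(pool.items())
    }
    ccounts = class_counts(classified.values())
    counts_so_far["classified"] = ccounts
    keep_classes = {ReadClass.FULL_LENGTH, ReadClass.FIVE_ONLY,
                    ReadClass.THREE_ONLY}
    kept_reads = [
        c for c in classified.values() if c.klass in keep_classes
    ]
    attr(
        "classify",
        len(reads),
        len(kept_reads),
        {
            "unaligned": unaligned_reads,
            **{
                k.value: ccounts[k.value]
                for k in ReadClass
                if k not in keep_classes and ccounts[k.value]
            },
        },
    )

    # --- stage 3: transcripts --------------------------------------------
    transcripts: list[Transcript] = []
    full_length: list[Transcript] = []
    no_coords = 0
    for c in kept_reads:
        a = kept_alignments.get(c.read_id)
        if a is None:
            no_coords += 1
            continue
        t = build_transcript(c, a)
        if t is None:
            no_coords += 1
            continue
        transcripts.append(t)
        if c.klass is ReadClass.FULL_LENGTH:
            full_length.append(t)
    attr("transcripts", len(kept_reads), len(transcripts),
         {"no_coordinates": no_coords})

    # --- stage 4: site scans ---------------------------------------------
    sites = _sites.scan_primer_match_sites(
        genome, primers, config.p5_seed_len, config.p5_max_edits,
        config.min_t_run,
    )
    polya = _sites.scan_polyA_like(
        genome, config.polya_window, config.polya_min_a_frac,
        config.polya_min_a_run,
    )

    # --- stage 5: profile -------------------------------------------------
    summary = _profile.summarize(transcripts, genome)
    units = []
    for strand in ("+", "-"):
        depth = _profile.depth_profile(transcripts, strand, genome)
        units.extend(
            _profile.call_units(
                depth, strand,
                min_depth=config.unit_min_depth,
                min_len=config.unit_min_len,
                max_gap=config.unit_max_gap,
                sites=polya,
            )
        )
        write_bed(
            outdir / f"depth_{'light' if strand == '+' else 'heavy'}.bedgraph",
            _profile.depth_to_bedgraph(depth, genome),
        )
    junctions = _profile.extract_junctions(transcripts, genome)

    # --- stage 6: TIS ------------------------------------------------------
    tis_counts = _tis.aggregate_five_prime_ends(full_length)
    tis_report = _tis.call_tis(
        tis_counts, genome,
        min_support=config.tis_min_support,
        p5_sites=sites,
        merge_radius=config.tis_merge_radius,
    )
    if annotations:
        tis_report = _tis.filter_splicing_intermediates(
            tis_report, annotations, tol=config.splice_tol
        )

    # --- stage 7: TTS ------------------------------------------------------
    tts_calls, tts_unassigned = _tts.assign_tts(
        full_length, polya, tol=config.tts_tol
    )

    # --- editing ----------------------------------------------------------
    pile = _profile.pileup_from_transcripts(transcripts)
    editing, snp_like = _profile.detect_editing(
        pile, genome, config.editing_min_depth, config.editing_min_alt_frac
    )

    # --- write outputs ----------------------------------------------------
    attrition = pd.DataFrame(attrition_rows).fillna(0)
    attrition.to_csv(outdir / "attrition.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"class": k, "count": v} for k, v in sorted(ccounts.items())]
    ).to_csv(outdir / "class_counts.tsv", sep="\t", index=False)
    _tis.report_to_frame(tis_report, assignment).to_csv(
        outdir / "tis.tsv", sep="\t", index=False
    )
    write_bed(outdir / "tis.bed", _tis.report_to_bed(tis_report, genome,
                                                     assignment))
    _tts.calls_to_frame(tts_calls).to_csv(
        outdir / "tts.tsv", sep="\t", index=False
    )
    write_bed(outdir / "tts.bed", _tts.calls_to_bed(tts_calls, genome))
    _profile.units_to_frame(units).to_csv(
        outdir / "units.tsv", sep="\t", index=False
    )
    write_bed(outdir / "units.bed", _profile.units_to_bed(units, genome))
    _profile.junctions_to_frame(junctions).to_csv(
        outdir / "junctions.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [dataclasses.asdict(e) for e in editing]
    ).to_csv(outdir / "editing.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    if not reads:
        log.warning("run_pipeline: empty read set; reports are empty")

    return PipelineResult(
        genome=genome,
        assignment=assignment,
        attrition=attrition,
        class_counts=ccounts,
        transcripts=transcripts,
        tis_report=tis_report,
        tts_calls=tts_calls,
        tts_unassigned=tts_unassigned,
        units=units,
        summary=summary,
        junctions=junctions,
        editing=editing,
        snp_like=snp_like,
        sites=sites,
        polya_sites=polya,
    )
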