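"""Transcription-initiation-site calling from full-length transcript 5' ends.

Full-length transcript 5' ends are aggregated per exact (strand, position);
each position becomes a +1 candidate carrying its 62-nt promoter window split
into regions I (−37..−13), II (−12..−1) and III (+1..+25).  Degraded-RNA
false positives are suppressed by a copy-number threshold (support >= 10 by
default); splicing intermediates — RNAs starting exactly at an intron 5'
boundary, typically GT — are flagged, as are remaining GT-start candidates
of unknown provenance and candidates sitting on 5'-primer-match sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import (
    GeneAnnotation,
    Genome,
    Strand,
    StrandAssignment,
    Transcript,
    extract_window,
    to_bed6,
)
from .sites import PrimerMatchSite, _dist_to_interval

# region boundaries inside the 62-nt window (0-based slices)
REGION_I = slice(0, 25)    # -37..-13
REGION_II = slice(25, 37)  # -12..-1
REGION_III = slice(37, 62)  # +1..+25


def at_content(seq: str) -> float:
    return (seq.count("A") + seq.count("T")) / len(seq) if seq else 0.0


@dataclass
class TisCandidate:
    strand: Strand
    plus1: int
    support: int
    first_nt: str
    window: str
    at_content: tuple[float, float, float]  # regions I, II, III
    dimer: str
    flags: set[str] = field(default_factory=set)

    @property
    def passing(self) -> bool:
        return "LOW_SUPPORT" not in self.flags

    def label(self, assignment: Optional[StrandAssignment] = None) -> str:
        suffix = assignment.label_suffix(self.strand) if assignment else (
            "-" if self.strand == "-" else ""
        )
        return f"TIS_{self.plus1}{suffix}"


@dataclass
class TisReport:
    candidates: list[TisCandidate]
    dimer_table: Counter
    region_at_summary: dict[str, float]

    def passing(self) -> list[TisCandidate]:
        return [c for c in self.candidates if c.passing]


def aggregate_five_prime_ends(
    transcripts: Iterable[Transcript],
) -> dict[tuple[Strand, int], int]:
    """Exact-position support counts of transcript 5' ends (no clustering)."""
    counts: Counter = Counter()
    skipped = 0
    for t in transcripts:
        try:
            counts[(t.strand, t.five_prime)] += 1
        except (AttributeError, IndexError):
            skipped += 1
    if skipped:
        import logging

        logging.getLogger("cptrx").warning(
            "aggregate_five_prime_ends: skipped %d transcripts without "
            "coordinates", skipped,
        )
    return dict(counts)


def call_tis(
    counts: Mapping[tuple[Strand, int], int],
    genome: Genome,
    min_support: int = 10,
    p5_sites: Optional[Sequence[PrimerMatchSite]] = None,
    p5_tol: int = 5,
    merge_radius: int = 0,
) -> TisReport:
    """Build TIS candidates from 5'-end support counts.

    Positions with support below ``min_support`` are kept but flagged
    LOW_SUPPORT (presumptive degraded-RNA 5' ends); nearby positions are
    treated as distinct unless ``merge_radius`` > 0, in which case positions
    within the radius merge into the best-supported one.  The +1 base is read
    from the genome, not the reads, so untemplated RNA 5' additions cannot
    shift a call.  Candidates whose +1 lies within ``p5_tol`` of a
    same-strand 5'-primer-match site gain P5_MATCH_SUSPECT.
    """
    merged = _merge_positions(counts, merge_radius)
    candidates: list[TisCandidate] = []
    for (strand, plus1), support in sorted(merged.items()):
        window = extract_window(genome, strand, plus1)
        regions = (
            at_content(window[REGION_I]),
            at_content(window[REGION_II]),
            at_content(window[REGION_III]),
        )
        cand = TisCandidate(
            strand=strand,
            plus1=plus1,
            support=support,
            first_nt=window[REGION_III.start],
            window=window,
            at_content=regions,
            dimer=window[REGION_III.start : REGION_III.start + 2],
        )
        if support < min_support:
            cand.flags.add("LOW_SUPPORT")
        if p5_sites:
            for s in p5_sites:
                if s.kind != "P5_match" or s.strand != strand:
                    continue
                if _dist_to_interval(plus1, s.start, s.end) <= p5_tol:
                    cand.flags.add("P5_MATCH_SUSPECT")
                    break
        candidates.append(cand)
    return _with_summaries(candidates)


def _merge_positions(
    counts: Mapping[tuple[Strand, int], int], radius: int
) -> dict[tuple[Strand, int], int]:
    if radius <= 0:
        return dict(counts)
    merged: dict[tuple[Strand, int], int] = {}
    by_strand: dict[Strand, list[tuple[int, int]]] = {}
    for (strand, pos), n in counts.items():
        by_strand.setdefault(strand, []).append((pos, n))
    for strand, items in by_strand.items():
        items.sort()
        cluster: list[tuple[int, int]] = []
        for pos, n in items:
            if cluster and pos - cluster[-1][0] > radius:
                _flush_cluster(merged, strand, cluster)
                cluster = []
            cluster.append((pos, n))
        if cluster:
            _flush_cluster(merged, strand, cluster)
    return merged


def _flush_cluster(
    merged: dict, strand: Strand, cluster: list[tuple[int, int]]
) -> None:
    total = sum(n for _, n in cluster)
    anchor = max(cluster, key=lambda pn: (pn[1], -pn[0]))[0]
    merged[(strand, anchor)] = total


def _with_summaries(candidates: list[TisCandidate]) -> TisReport:
    passing = [c for c in candidates if c.passing]
    dimers = Counter(c.dimer for c in passing)
    total = sum(c.support for c in passing)
    summary = {"I": 0.0, "II": 0.0, "III": 0.0}
    if total:
        for key, idx in (("I", 0), ("II", 1), ("III", 2)):
            summary[key] = (
                sum(c.support * c.at_content[idx] for c in passing) / total
            )
    return TisReport(candidates, dimers, summary)


def filter_splicing_intermediates(
    report: TisReport,
    annotations: Iterable[GeneAnnotation],
    tol: int = 0,
) -> TisReport:
    """Flag candidates explained by splicing intermediates.

    A candidate whose +1 coincides (within ``tol``) with an annotated intron
    5' boundary on the same strand gains SPLICE_INTERMEDIATE; a GT-start
    candidate with no intron match gains GT_SUSPECT, since GT starts away
    from introns may still be contaminants of unknown type.
    """
    boundaries: dict[Strand, list[int]] = {"+": [], "-": []}
    for ann in annotations:
        boundaries[ann.strand].extend(ann.intron_five_prime_boundaries())
    for cand in report.candidates:
        near = any(
            abs(cand.plus1 - b) <= tol for b in boundaries[cand.strand]
        )
        if near:
            cand.flags.add("SPLICE_INTERMEDIATE")
        elif cand.dimer == "GT":
            cand.flags.add("GT_SUSPECT")
    return _with_summaries(report.candidates)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def report_to_frame(
    report: TisReport, assignment: Optional[StrandAssignment] = None
) -> pd.DataFrame:
    rows = [
        {
            "label": c.label(assignment),
            "strand": c.strand,
            "plus1": c.plus1,
            "support": c.support,
            "first_nt": c.first_nt,
            "dimer": c.dimer,
            "AT_I": round(c.at_content[0], 4),
            "AT_II": round(c.at_content[1], 4),
            "AT_III": round(c.at_content[2], 4),
            "flags": ",".join(sorted(c.flags)) or ".",
        }
        for c in report.candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "label", "strand", "plus1", "support", "first_nt", "dimer",
            "AT_I", "AT_II", "AT_III", "flags",
        ],
    )


def report_to_bed(
    report: TisReport,
    genome: Genome,
    assignment: Optional[StrandAssignment] = None,
) -> list[str]:
    return [
        to_bed6(
            genome.accession, c.plus1, c.plus1, c.label(assignment),
            c.support, c.strand,
        )
        for c in report.candidates
    ]


def windows_to_fasta(
    report: TisReport,
    path,
    assignment: Optional[StrandAssignment] = None,
    passing_only: bool = True,
) -> None:
    cands = report.passing() if passing_only else report.candidates
    with open(path, "w") as fh:
        for c in cands:
            fh.write(f">{c.label(assignment)}\n{c.window}\n")
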