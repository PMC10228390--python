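"""Primer detection, artifact taxonomy and alignment filtering for CCS reads.

A full-length cDNA library read carries the 5' primer at the transcript's 5'
end and the 3' primer — printed in read sense as a polyA stretch followed by
an adapter — at the 3' end.  Internal primer annealing during library
construction instead produces artifact topologies: two 5' primers (double-5),
two 3' primers with polyT (double-3), a 3'-with-polyT / 3'-without-polyT pair
(the fifth type), and 5'-/3'-truncated molecules that look structurally
normal.  This module detects primers by semi-global edit-distance search at
the read ends and applies the resulting decision table, then trims and
orients the surviving transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Optional

import edlib

from .core import Strand, revcomp

# Primers of the full-length transcriptome library this method was built for.
# The 3' primer is printed in read (second-strand) sense: leading polyA, then
# the adapter.
DEFAULT_P5 = "ACACTAGATCGCGTGTGCAATGAAGTCGCAGGGTTGGG"
DEFAULT_P3 = "AAAAAAAAAAAAAAAAAAAAGTACTCTGCGTTTGATACCACTGCTTACACGCGATCTAGTGT"


@dataclass(frozen=True)
class PrimerSet:
    """The 5' and 3' primers of the library.

    ``three_prime`` must begin with a polyA run of at least ``polyT_min``
    (its printed orientation); the run length is what the oligo-dT portion of
    the physical primer guarantees in read sense.
    """

    five_prime: str = DEFAULT_P5
    three_prime: str = DEFAULT_P3
    polyT_min: int = 8

    def __post_init__(self) -> None:
        if not self.five_prime or not self.three_prime:
            raise ValueError("both primers must be non-empty")
        if self.polyT_min < 1:
            raise ValueError("polyT_min must be >= 1")
        if not self.three_prime.startswith("A" * self.polyT_min):
            raise ValueError(
                "three_prime must begin with >= polyT_min A's as printed"
            )

    @property
    def p3_polya_len(self) -> int:
        n = 0
        for c in self.three_prime:
            if c != "A":
                break
            n += 1
        return n

    @property
    def p3_adapter(self) -> str:
        """Non-polyA portion of the 3' primer (the searchable part)."""
        return self.three_prime[self.p3_polya_len :]


@dataclass(frozen=True)
class ClassifyParams:
    max_edit_frac: float = 0.10
    end_search_window: int = 100
    polyT_min: int = 8
    min_transcript_len: int = 1


class ReadClass(str, Enum):
    FULL_LENGTH = "FULL_LENGTH"
    FIVE_ONLY = "FIVE_ONLY"
    THREE_ONLY = "THREE_ONLY"
    DOUBLE_5 = "DOUBLE_5"
    DOUBLE_3 = "DOUBLE_3"
    TYPE_5 = "TYPE_5"
    NO_PRIMER = "NO_PRIMER"
    UNCLASSIFIED = "UNCLASSIFIED"


# classes whose transcript cannot be recovered
_NO_TRANSCRIPT = {
    ReadClass.DOUBLE_5,
    ReadClass.DOUBLE_3,
    ReadClass.TYPE_5,
    ReadClass.NO_PRIMER,
    ReadClass.UNCLASSIFIED,
}


@dataclass
class PrimerHit:
    """A primer located near one read end.

    ``start``/``end`` are 0-based half-open coordinates of the matched
    segment in the read as given; ``offset`` is the distance from the
    corresponding read end.  For P3 hits the coordinates cover the adapter
    portion only and ``tail_run`` spans the adjacent polyA/polyT run.
    """

    primer: Literal["P5", "P3"]
    read_end: Literal["head", "tail"]
    orientation: Literal["forward", "revcomp"]
    offset: int
    edits: int
    start: int
    end: int
    with_polyT: Optional[bool] = None
    tail_run: tuple[int, int] = (0, 0)

    def sort_key(self) -> tuple[int, int, int]:
        return (self.edits, self.offset, 0 if self.read_end == "head" else 1)


def edit_budget(primer: str, max_edit_frac: float) -> int:
    return math.ceil(max_edit_frac * len(primer))


def _search_segment(segment: str, primer: str, k: int) -> Optional[tuple[int, int, int]]:
    """Best infix match of ``primer`` in ``segment`` within ``k`` edits.

    Returns (start, end, edits) with 0-based half-open coordinates, or None.
    edlib's HW mode gives free end-gaps on the segment side, i.e. a
    semi-global alignment of the primer against any read substring.
    """
    if not segment:
        return None
    res = edlib.align(primer, segment, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    # edlib reports the leftmost-start locations first; take the first
    s, e = res["locations"][0]
    return s, e + 1, res["editDistance"]


def locate_primer(
    seq: str,
    primer: str,
    max_edit_frac: float = 0.10,
    end_search_window: int = 100,
) -> Optional[PrimerHit]:
    """Best hit of ``primer`` (either orientation) near either read end.

    Semi-global search with free end-gaps on the read side, edit budget
    ``ceil(max_edit_frac * len(primer))``.  Ties break by fewer edits, then
    smaller offset from the read end, then head before tail.  Returns None
    when nothing fits the budget.
    """
    if not seq:
        raise ValueError("empty read sequence")
    hits = _end_hits(seq, primer, "P5", max_edit_frac, end_search_window)
    return min(hits, key=PrimerHit.sort_key) if hits else None


def _end_hits(
    seq: str,
    primer: str,
    label: Literal["P5", "P3"],
    max_edit_frac: float,
    window: int,
) -> list[PrimerHit]:
    """All end-proximal hits of primer/revcomp(primer) at both read ends."""
    k = edit_budget(primer, max_edit_frac)
    span = min(len(seq), window + len(primer) + k)
    hits: list[PrimerHit] = []
    for orientation, pat in (("forward", primer), ("revcomp", revcomp(primer))):
        m = _search_segment(seq[:span], pat, k)
        if m is not None:
            s, e, ed = m
            if s <= window:
                hits.append(
                    PrimerHit(label, "head", orientation, s, ed, s, e)
                )
        off0 = len(seq) - span
        m = _search_segment(seq[off0:], pat, k)
        if m is not None:
            s, e, ed = m
            # rightmost match in the tail segment: edlib returns leftmost;
            # search the reversed problem to anchor at the read 3' end
            mr = _search_segment(seq[off0:][::-1], pat[::-1], k)
            if mr is not None:
                s = span - mr[1]
                e = span - mr[0]
                ed = mr[2]
            tail_offset = span - e
            if tail_offset <= window:
                hits.append(
                    PrimerHit(
                        label, "tail", orientation, tail_offset, ed,
                        off0 + s, off0 + e,
                    )
                )
    return hits


def _run_len(seq: str, pos: int, base: str, step: int) -> int:
    """Length of the maximal run of ``base`` from ``pos`` going ``step``."""
    n = 0
    i = pos
    while 0 <= i < len(seq) and seq[i] == base:
        n += 1
        i += step
    return n


def _gappy_run(
    seq: str, pos: int, base: str, step: int, max_gap: int = 1
) -> tuple[int, int]:
    """Run of ``base`` from ``pos``, tolerating interior interruptions.

    Interruptions of up to ``max_gap`` non-``base`` characters are skipped
    when more of the run follows (so a sequencing error inside a polyA tail
    does not split it).  Returns (base count, index of the last matching
    base); the count excludes interrupting characters.
    """
    count = 0
    last = pos
    i = pos
    while 0 <= i < len(seq):
        if seq[i] == base:
            count += 1
            last = i
            i += step
        else:
            j, g = i, 0
            while 0 <= j < len(seq) and seq[j] != base and g < max_gap:
                j += step
                g += 1
            if 0 <= j < len(seq) and seq[j] == base:
                i = j
            else:
                break
    return count, last


def _p3_hits(
    seq: str, primers: PrimerSet, params: ClassifyParams
) -> list[PrimerHit]:
    """3'-primer (adapter) hits with the adjacent polyA/polyT run resolved.

    A forward adapter hit is preceded by the polyA run (read sense ... A_n +
    adapter ...); a revcomp hit is followed by the polyT run.  ``with_polyT``
    requires a run of at least ``polyT_min``.
    """
    adapter = primers.p3_adapter
    hits = _end_hits(seq, adapter, "P3", params.max_edit_frac,
                     params.end_search_window)
    for h in hits:
        if h.orientation == "forward":
            run, last = _gappy_run(seq, h.start - 1, "A", -1)
            h.tail_run = (last if run else h.start, h.start)
        else:
            run, last = _gappy_run(seq, h.end, "T", +1)
            h.tail_run = (h.end, last + 1 if run else h.end)
        h.with_polyT = run >= params.polyT_min
    return hits


def detect_tail(seq: str, min_run: int) -> tuple[int, int]:
    """(head polyT length, tail polyA length); runs below min_run report 0."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    head = _run_len(seq, 0, "T", +1)
    tail = _run_len(seq, len(seq) - 1, "A", -1)
    return (head if head >= min_run else 0, tail if tail >= min_run else 0)


@dataclass
class ClassifiedRead:
    read_id: str
    klass: ReadClass
    hits: list[PrimerHit] = field(default_factory=list)
    sense: Optional[bool] = None  # True: read as given is transcript sense
    transcript: str = ""
    polyA_len: int = 0


def _best_per_end(hits: list[PrimerHit]) -> dict[str, PrimerHit]:
    best: dict[str, PrimerHit] = {}
    for h in hits:
        cur = best.get(h.read_end)
        if cur is None or h.sort_key() < cur.sort_key():
            best[h.read_end] = h
    return best


def classify_read(
    seq: str,
    primers: PrimerSet,
    params: ClassifyParams = ClassifyParams(),
    read_id: str = "",
) -> ClassifiedRead:
    """Classify one read by its primer-hit topology and trim the transcript.

    Decision table (best hit per end):

    ==========================  =================
    head / tail combination     class
    ==========================  =================
    P5 + P3-with-polyT          FULL_LENGTH
    P5 + P5 (opposite orient.)  DOUBLE_5
    P3-polyT + P3-polyT         DOUBLE_3
    P3-polyT + P3-no-polyT      TYPE_5
    single P5                   FIVE_ONLY
    single P3                   THREE_ONLY
    nothing                     NO_PRIMER
    anything else               UNCLASSIFIED
    ==========================  =================

    FULL_LENGTH / FIVE_ONLY / THREE_ONLY reads are oriented transcript
    5'→3' and trimmed of primers and tail; others carry no transcript.
    """
    if not seq:
        return ClassifiedRead(read_id, ReadClass.NO_PRIMER)
    seq = seq.upper()
    p5_hits = _end_hits(seq, primers.five_prime, "P5", params.max_edit_frac,
                        params.end_search_window)
    p3_hits = _p3_hits(seq, primers, params)
    per_end = _best_per_end(p5_hits + p3_hits)
    head = per_end.get("head")
    tail = per_end.get("tail")
    all_hits = [h for h in (head, tail) if h is not None]

    if head is None and tail is None:
        return ClassifiedRead(read_id, ReadClass.NO_PRIMER)

    if head is not None and tail is not None:
        kinds = {head.primer, tail.primer}
        if kinds == {"P5"}:
            if head.orientation != tail.orientation:
                return ClassifiedRead(read_id, ReadClass.DOUBLE_5, all_hits)
            return ClassifiedRead(read_id, ReadClass.UNCLASSIFIED, all_hits)
        if kinds == {"P3"}:
            n_polyt = sum(bool(h.with_polyT) for h in (head, tail))
            if n_polyt == 2:
                return ClassifiedRead(read_id, ReadClass.DOUBLE_3, all_hits)
            if n_polyt == 1:
                return ClassifiedRead(read_id, ReadClass.TYPE_5, all_hits)
            return ClassifiedRead(read_id, ReadClass.UNCLASSIFIED, all_hits)
        # one P5, one P3
        p5 = head if head.primer == "P5" else tail
        p3 = tail if p5 is head else head
        sense = p5.read_end == "head"
        consistent = (
            (sense and p5.orientation == "forward"
             and p3.orientation == "forward")
            or (not sense and p5.orientation == "revcomp"
                and p3.orientation == "revcomp")
        )
        if not (p3.with_polyT and consistent):
            return ClassifiedRead(read_id, ReadClass.UNCLASSIFIED, all_hits)
        return _trim_full_length(seq, read_id, p5, p3, all_hits)

    only = head if head is not None else tail
    assert only is not None
    if only.primer == "P5":
        sense = (only.read_end == "head") == (only.orientation == "forward")
        return _trim_five_only(seq, read_id, only, sense, params)
    sense = (only.read_end == "tail") == (only.orientation == "forward")
    return _trim_three_only(seq, read_id, only, sense)


def _trim_full_length(
    seq: str, read_id: str, p5: PrimerHit, p3: PrimerHit, hits: list[PrimerHit]
) -> ClassifiedRead:
    sense = p5.read_end == "head"
    if sense:
        transcript = seq[p5.end : p3.tail_run[0]]
        polya = p3.tail_run[1] - p3.tail_run[0]
    else:
        transcript = revcomp(seq[p3.tail_run[1] : p5.start])
        polya = p3.tail_run[1] - p3.tail_run[0]
    return ClassifiedRead(
        read_id, ReadClass.FULL_LENGTH, hits, sense, transcript, polya
    )


def _trim_five_only(
    seq: str, read_id: str, p5: PrimerHit, sense: bool, params: ClassifyParams
) -> ClassifiedRead:
    body = seq[p5.end :] if p5.read_end == "head" else seq[: p5.start]
    if not sense:
        body = revcomp(body)
    _, polya = detect_tail(body, params.polyT_min) if body else (0, 0)
    if polya:
        body = body[: len(body) - polya]
    return ClassifiedRead(read_id, ReadClass.FIVE_ONLY, [p5], sense, body, polya)


def _trim_three_only(
    seq: str, read_id: str, p3: PrimerHit, sense: bool
) -> ClassifiedRead:
    if p3.orientation == "forward":
        body = seq[: p3.tail_run[0]]
    else:
        body = seq[p3.tail_run[1] :]
    if not sense:
        body = revcomp(body)
    polya = p3.tail_run[1] - p3.tail_run[0]
    return ClassifiedRead(read_id, ReadClass.THREE_ONLY, [p3], sense, body, polya)


# ---------------------------------------------------------------------------
# Alignment filtering
# ---------------------------------------------------------------------------


@dataclass
class AlignedRead:
    """Summary of one read's alignment to the reference."""

    read_id: str
    reference: str
    strand: Strand
    aligned_span: tuple[int, int]  # 1-based inclusive on the reference
    read_length: int
    aligned_length: int
    spliced_blocks: list[tuple[int, int]] = field(default_factory=list)
    aligned_seq: str = ""  # reference-forward aligned portion (no clips)

    def __post_init__(self) -> None:
        if self.aligned_length > self.read_length:
            raise ValueError(
                f"{self.read_id}: aligned_length > read_length"
            )


FilterReason = Literal["pass", "short_aligned", "low_cov"]


def filter_alignment(
    a: AlignedRead, min_aligned: int = 200, min_frac: float = 0.05
) -> tuple[bool, FilterReason]:
    """Keep/drop one alignment by the aligned-length and coverage criteria.

    Drops alignments shorter than ``min_aligned`` bases, or covering less
    than ``min_frac`` of the read (both thresholds pass on equality).
    """
    if a.read_length == 0:
        raise ValueError(f"{a.read_id}: read_length is 0")
    if a.aligned_length < min_aligned:
        return False, "short_aligned"
    if a.aligned_length / a.read_length < min_frac:
        return False, "low_cov"
    return True, "pass"


def aligned_reads_from_sam(
    path: str | Path, min_intron: int = 30
) -> list[AlignedRead]:
    """Primary alignments from a SAM/BAM file as :class:`AlignedRead`.

    Alignment blocks separated by reference gaps of at least ``min_intron``
    are kept as separate spliced blocks; smaller gaps (indels) are merged.
    """
    import pysam

    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            raw = [(s + 1, e) for s, e in rec.get_blocks()]
            blocks: list[list[int]] = []
            for s, e in raw:
                if blocks and s - blocks[-1][1] - 1 < min_intron:
                    blocks[-1][1] = e
                else:
                    blocks.append([s, e])
            aligned_len = sum(e - s + 1 for s, e in blocks)
            read_len = rec.infer_read_length() or len(rec.query_sequence or "")
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    reference=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    aligned_span=(blocks[0][0], blocks[-1][1]),
                    read_length=read_len,
                    aligned_length=aligned_len,
                    spliced_blocks=[(s, e) for s, e in blocks],
                    aligned_seq=rec.query_alignment_sequence or "",
                )
            )
    return out


def class_counts(reads: Iterable[ClassifiedRead]) -> dict[str, int]:
    counts: dict[str, int] = {k.value: 0 for k in ReadClass}
    for r in reads:
        counts[r.klass.value] += 1
    return counts
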