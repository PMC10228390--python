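"""Transcription-termination-site calling at polyA-like sites.

Transcript 3' ends (untemplated tails already trimmed by the classifier;
genome-templated A-runs remain part of the alignment) are assigned to the
nearest same-strand polyA-like site within a tolerance.  A site's support is
the number of transcripts terminating there; its read-through count is the
number of same-strand transcripts whose alignment spans the site without
terminating at it, which estimates the per-site termination probability as
support / (support + readthrough).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core import Genome, Strand, Transcript, to_bed6
from .sites import PolyALikeSite, _dist_to_interval


@dataclass
class TtsCall:
    site: PolyALikeSite
    support: int = 0
    readthrough: int = 0

    @property
    def strand(self) -> Strand:
        return self.site.strand

    @property
    def termination_frequency(self) -> float:
        n = self.support + self.readthrough
        return self.support / n if n else 0.0


@dataclass
class TerminationSummary:
    """Distribution of internal polyA-like sites spanned per transcript."""

    per_transcript: list[int]
    histogram: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not self.histogram:
            self.histogram = Counter(self.per_transcript)


def assign_tts(
    transcripts: Sequence[Transcript],
    sites: Sequence[PolyALikeSite],
    tol: int = 10,
) -> tuple[list[TtsCall], list[Transcript]]:
    """Assign transcript 3' ends to polyA-like sites.

    A 3' end within ``tol`` of a same-strand site (distance measured to the
    site interval, so ends inside the site count as distance 0) increments
    that site's support; the nearest site wins ties, then the smaller start
    coordinate.  Returns the calls plus the transcripts whose 3' ends were
    unassigned.  Each call's ``readthrough`` counts same-strand transcripts
    whose aligned span covers the whole site but which did not terminate
    there.
    """
    calls = [TtsCall(site=s) for s in sites]
    by_strand: dict[Strand, list[TtsCall]] = {"+": [], "-": []}
    for c in calls:
        by_strand[c.strand].append(c)
    unassigned: list[Transcript] = []
    assignment: list[Optional[TtsCall]] = []
    for t in transcripts:
        best: Optional[TtsCall] = None
        best_key: Optional[tuple[int, int]] = None
        for c in by_strand[t.strand]:
            d = _dist_to_interval(t.three_prime, c.site.start, c.site.end)
            if d > tol:
                continue
            key = (d, c.site.start)
            if best_key is None or key < best_key:
                best, best_key = c, key
        if best is None:
            unassigned.append(t)
            assignment.append(None)
        else:
            best.support += 1
            assignment.append(best)
    for t, assigned in zip(transcripts, assignment):
        lo, hi = t.span
        for c in by_strand[t.strand]:
            if c is assigned:
                continue
            if lo <= c.site.start and c.site.end <= hi:
                c.readthrough += 1
    return calls, unassigned


def readthrough_stats(
    transcripts: Sequence[Transcript],
    sites: Sequence[PolyALikeSite],
) -> TerminationSummary:
    """Count same-strand polyA-like sites strictly inside each aligned span.

    "Strictly inside" excludes sites touching either span end, so a
    transcript terminating at a boundary site does not count it as read
    through.
    """
    per: list[int] = []
    for t in transcripts:
        lo, hi = t.span
        n = sum(
            1
            for s in sites
            if s.strand == t.strand and lo < s.start and s.end < hi
        )
        per.append(n)
    return TerminationSummary(per_transcript=per)


def calls_to_frame(calls: Sequence[TtsCall]) -> pd.DataFrame:
    rows = [
        {
            "start": c.site.start,
            "end": c.site.end,
            "strand": c.strand,
            "support": c.support,
            "readthrough": c.readthrough,
            "termination_frequency": round(c.termination_frequency, 4),
            "a_content": round(c.site.a_content, 4),
            "signals": ",".join(sorted(c.site.signals)) or ".",
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "start", "end", "strand", "support", "readthrough",
            "termination_frequency", "a_content", "signals",
        ],
    )


def calls_to_bed(calls: Sequence[TtsCall], genome: Genome) -> list[str]:
    return [
        to_bed6(
            genome.accession, c.site.start, c.site.end,
            f"TTS_{c.site.start}", c.support, c.strand,
        )
        for c in calls
    ]
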