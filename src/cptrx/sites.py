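"""Genome scanning for primer-match sites, homopolymers and polyA-like sites.

Primer-match sites are genomic loci resembling the 3' end of the 5' primer
(seed ``GGGTTGGG``) or a polyT tract; they explain the double-5/double-3 and
truncated library artifacts because primers can anneal there instead of at a
molecule's real ends.  PolyA-like sites are A-rich motifs (often containing
AATAA/AAGAA) at transcript 3' ends that act as transcription terminators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .classify import PrimerSet
from .core import Genome, Strand, other_strand, revcomp

SiteKind = Literal["P5_match", "P3_match"]


@dataclass
class PrimerMatchSite:
    """A locus where a library primer can misprime."""

    start: int  # 1-based inclusive, reference coordinates
    end: int
    strand: Strand
    kind: SiteKind
    motif: str
    score: float  # P5: 1 - edits/seed_len; P3: total T count
    edits: int = 0

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class HomopolymerRun:
    base: str
    start: int  # 1-based; for origin-spanning runs, the start of the tail arc
    length: int


@dataclass
class PolyALikeSite:
    """An A-rich window on one strand, a putative transcription terminator."""

    start: int
    end: int
    strand: Strand
    sequence: str  # 5'→3' on the transcribed strand
    a_content: float
    signals: frozenset[str] = field(default_factory=frozenset)

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


# ---------------------------------------------------------------------------
# Approximate seed matching (P5 sites)
# ---------------------------------------------------------------------------


def _neighborhood(pattern: str, max_edits: int) -> dict[str, int]:
    """All strings within ``max_edits`` of pattern, mapped to edit distance."""
    alphabet = "ACGT"
    current = {pattern: 0}
    for d in range(1, max_edits + 1):
        nxt: dict[str, int] = {}
        for s, dist in current.items():
            if dist != d - 1:
                continue
            for i in range(len(s)):
                for b in alphabet:  # substitution
                    v = s[:i] + b + s[i + 1 :]
                    if v not in current and v not in nxt:
                        nxt[v] = d
                v = s[:i] + s[i + 1 :]  # deletion
                if v and v not in current and v not in nxt:
                    nxt[v] = d
            for i in range(len(s) + 1):  # insertion
                for b in alphabet:
                    v = s[:i] + b + s[i:]
                    if v not in current and v not in nxt:
                        nxt[v] = d
        current.update(nxt)
    return current


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def _scan_strand_seed(
    seq: str, circular: bool, seed: str, max_edits: int
) -> list[tuple[int, int, int, str]]:
    """(start0, length, edits, motif) hits of the seed neighborhood in seq.

    Overlapping hits are clustered; each cluster reports its minimum-edit
    representative.  Coordinates are 0-based on ``seq``; circular scans use
    a doubled prefix and fold positions back.
    """
    n = len(seq)
    hay = seq + seq[: len(seed) + max_edits - 1] if circular else seq
    raw: list[tuple[int, int, int, str]] = []
    for variant, ed in _neighborhood(seed, max_edits).items():
        for p in _find_all(hay, variant):
            if p < n:
                raw.append((p, len(variant), ed, variant))
    raw.sort()
    clusters: list[list[tuple[int, int, int, str]]] = []
    for hit in raw:
        if clusters and hit[0] <= clusters[-1][-1][0] + clusters[-1][-1][1] - 1:
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    out = []
    for cl in clusters:
        best = min(cl, key=lambda h: (h[2], h[0], -h[1]))
        out.append(best)
    return out


def _ref_interval(
    start0: int, length: int, strand: Strand, genome_len: int
) -> tuple[int, int]:
    """Map a 0-based hit on a strand-sense string to reference coordinates."""
    if strand == "+":
        return start0 + 1, start0 + length
    end_ref = genome_len - start0
    return end_ref - length + 1, end_ref


# ---------------------------------------------------------------------------
# T-run detection (P3 sites) and homopolymer census
# ---------------------------------------------------------------------------


def _maximal_runs(seq: str, base: str, circular: bool) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` as (start0, length); circular-aware.

    A run spanning the origin is reported once, starting at its tail-arc
    start.  An all-``base`` sequence is one run of the full length.
    """
    runs: list[tuple[int, int]] = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    if circular and len(runs) >= 2:
        first, last = runs[0], runs[-1]
        if first[0] == 0 and last[0] + last[1] == n and first != last:
            runs = runs[1:-1] + [(last[0], last[1] + first[1])]
    if circular and len(runs) == 1 and runs[0][1] == n:
        pass  # whole-sequence run: already a single run
    return runs


def census_homopolymers(
    genome: Genome, base: str, min_len: int
) -> tuple[int, list[HomopolymerRun]]:
    """Count maximal runs of ``base`` with length >= min_len (circular-aware).

    A run of 13 with min_len 12 counts once (maximal runs, not sliding
    windows); a run wrapping the origin counts once.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    base = base.upper()
    runs = [
        HomopolymerRun(base=base, start=s + 1, length=ln)
        for s, ln in _maximal_runs(genome.sequence, base, genome.circular)
        if ln >= min_len
    ]
    runs.sort(key=lambda r: r.start)
    return len(runs), runs


def _t_run_sites(
    seq: str, strand: Strand, genome_len: int, circular: bool,
    min_t_run: int, max_gap: int = 3,
) -> list[PrimerMatchSite]:
    """PolyT primer-match sites on one strand-sense string.

    Single maximal T-runs of >= min_t_run count, as do pairs of runs
    separated by one interruption of <= max_gap non-T bases whose combined
    T count reaches min_t_run (captures motifs like T2CT9).
    """
    runs = _maximal_runs(seq, "T", circular)
    runs.sort()
    candidates: list[tuple[int, int, int]] = []  # (start0, end0excl, t_count)
    for s, ln in runs:
        if ln >= min_t_run:
            candidates.append((s, s + ln, ln))
    for (s1, l1), (s2, l2) in zip(runs, runs[1:]):
        gap = s2 - (s1 + l1)
        if 0 < gap <= max_gap and l1 + l2 >= min_t_run:
            candidates.append((s1, s2 + l2, l1 + l2))
    # merge overlapping candidates, preferring higher T count then longer
    candidates.sort()
    merged: list[list[int]] = []
    for s, e, t in candidates:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], t)
        else:
            merged.append([s, e, t])
    sites = []
    for s, e, t in merged:
        motif = (seq + seq)[s:e] if e > len(seq) else seq[s:e]
        start, end = _ref_interval(s, e - s, strand, genome_len)
        sites.append(
            PrimerMatchSite(start, end, strand, "P3_match", motif, float(t))
        )
    return sites


def scan_primer_match_sites(
    genome: Genome,
    primers: PrimerSet | None = None,
    seed_len: int = 8,
    max_edits: int = 1,
    min_t_run: int = 8,
) -> list[PrimerMatchSite]:
    """All 5' and 3' primer-match sites on both strands, sorted by position.

    P5_match: loci within ``max_edits`` of the 3'-terminal ``seed_len`` bases
    of the 5' primer (default seed GGGTTGGG).  P3_match: maximal T-runs of
    combined length >= ``min_t_run`` allowing one interruption of <= 3
    non-T bases.
    """
    primers = primers or PrimerSet()
    if seed_len > len(primers.five_prime):
        raise ValueError("seed_len exceeds 5' primer length")
    seed = primers.five_prime[-seed_len:]
    sites: list[PrimerMatchSite] = []
    for strand in ("+", "-"):
        sseq = genome.sequence if strand == "+" else revcomp(genome.sequence)
        for s0, ln, ed, motif in _scan_strand_seed(
            sseq, genome.circular, seed, max_edits
        ):
            start, end = _ref_interval(s0, ln, strand, genome.length)
            if "N" in motif:
                continue  # N never matches a primer position
            sites.append(
                PrimerMatchSite(
                    start, end, strand, "P5_match", motif,
                    1.0 - ed / seed_len, ed,
                )
            )
        sites.extend(
            _t_run_sites(sseq, strand, genome.length, genome.circular, min_t_run)
        )
    sites.sort(key=lambda s: (s.start, s.end, s.strand, s.kind))
    return sites


# ---------------------------------------------------------------------------
# PolyA-like sites
# ---------------------------------------------------------------------------

TERMINATION_SIGNALS = ("AATAA", "AAGAA")


def _chain_runs(
    runs: list[tuple[int, int]],
    seed_idx: int,
    seq_len: int,
    window: int,
    min_a_frac: float,
    frac_of,
    max_gap: int = 3,
) -> tuple[int, int]:
    """Grow a site from a seed A-run by annexing nearby A-runs.

    Neighbouring runs are added (closest gap first, ties rightward) while
    the interruption is <= ``max_gap`` bases, the chained span stays within
    ``window`` and its A-fraction stays >= ``min_a_frac``.  The resulting
    interval starts and ends on an A by construction, which keeps printed
    terminator motifs like A12GA4TA2 intact without diluting them with
    flanking non-A sequence.
    """
    lo_i = hi_i = seed_idx
    s = runs[seed_idx][0]
    e = runs[seed_idx][0] + runs[seed_idx][1]
    while True:
        cand = []
        if lo_i > 0:
            ls, ln = runs[lo_i - 1]
            gap = s - (ls + ln)
            cand.append((gap, 1, ls, e, lo_i - 1, "L"))
        if hi_i + 1 < len(runs):
            rs, rn = runs[hi_i + 1]
            gap = rs - e
            cand.append((gap, 0, s, rs + rn, hi_i + 1, "R"))
        cand = [
            c for c in cand
            if c[0] <= max_gap and c[3] - c[2] <= window
            and frac_of(c[2], c[3]) >= min_a_frac
        ]
        if not cand:
            return s, e
        cand.sort(key=lambda c: (c[0], c[1]))
        _gap, _side, ns, ne, idx, which = cand[0]
        s, e = ns, ne
        if which == "L":
            lo_i = idx
        else:
            hi_i = idx


def scan_polyA_like(
    genome: Genome,
    window: int = 25,
    min_a_frac: float = 0.7,
    min_a_run: int = 5,
) -> list[PolyALikeSite]:
    """A-rich candidate terminator sites on both strands.

    Each maximal A-run of >= ``min_a_run`` on a strand seeds a window of at
    most ``window`` nt expanded while the A-fraction stays >= ``min_a_frac``;
    overlapping windows merge.  Sites carry the AATAA/AAGAA polyadenylation
    signals they contain.
    """
    if window < min_a_run:
        raise ValueError("window must be >= min_a_run")
    out: list[PolyALikeSite] = []
    for strand in ("+", "-"):
        sseq = genome.sequence if strand == "+" else revcomp(genome.sequence)
        runs = sorted(_maximal_runs(sseq, "A", circular=False))

        def frac_of(a: int, b: int, _s=sseq) -> float:
            return _s[a:b].count("A") / (b - a)

        intervals = []
        for idx, (s, ln) in enumerate(runs):
            if ln < min_a_run:
                continue
            intervals.append(
                _chain_runs(runs, idx, len(sseq), window, min_a_frac, frac_of)
            )
        intervals.sort()
        merged: list[list[int]] = []
        for s, e in intervals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            sub = sseq[s:e]
            start, end = _ref_interval(s, e - s, strand, genome.length)
            out.append(
                PolyALikeSite(
                    start, end, strand, sub,
                    a_content=sub.count("A") / len(sub),
                    signals=frozenset(
                        m for m in TERMINATION_SIGNALS if m in sub
                    ),
                )
            )
    out.sort(key=lambda s: (s.start, s.end, s.strand))
    return out


# ---------------------------------------------------------------------------
# Truncation suspects
# ---------------------------------------------------------------------------


def _dist_to_interval(pos: int, start: int, end: int) -> int:
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


TruncFlag = Literal["FIVE_TRUNC_SUSPECT", "THREE_TRUNC_SUSPECT"]


def flag_truncated(
    transcripts: Sequence,
    sites: Sequence[PrimerMatchSite],
    tol: int = 10,
) -> list[frozenset[str]]:
    """Advisory truncation-suspect flags, one set per transcript.

    A transcript 5' end within ``tol`` of a same-strand P5_match marks a
    5'-truncation suspect (the 5' primer can anneal there); a 3' end within
    ``tol`` of an opposite-strand P3_match (an A-run on the transcript's own
    strand) marks a 3'-truncation suspect.  Suspects are advisory: truncated
    molecules are structurally indistinguishable from genuine transcripts.

    ``transcripts`` items need ``strand``, ``five_prime`` and ``three_prime``
    attributes (genomic end coordinates).
    """
    p5 = [s for s in sites if s.kind == "P5_match"]
    p3 = [s for s in sites if s.kind == "P3_match"]
    out = []
    for t in transcripts:
        flags: set[str] = set()
        for s in p5:
            if s.strand == t.strand and _dist_to_interval(
                t.five_prime, s.start, s.end
            ) <= tol:
                flags.add("FIVE_TRUNC_SUSPECT")
                break
        for s in p3:
            if s.strand == other_strand(t.strand) and _dist_to_interval(
                t.three_prime, s.start, s.end
            ) <= tol:
                flags.add("THREE_TRUNC_SUSPECT")
                break
        out.append(frozenset(flags))
    return out
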