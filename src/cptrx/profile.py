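"""Strand-resolved depth profiles, transcriptional units, splice junctions
and C→U RNA-editing detection.

Organelle transcription produces long, overlapping polycistronic transcripts;
on a depth profile these collapse into a small number of contiguous
high-coverage regions per strand — transcriptional units spanning clustered
co-transcribed genes.  Units are called as depth-thresholded runs with gap
bridging, and their ends are annotated with the nearest polyA-like site.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Genome, Strand, Transcript, to_bed6
from .sites import PolyALikeSite, _dist_to_interval

log = logging.getLogger("cptrx")


# ---------------------------------------------------------------------------
# Depth and units
# ---------------------------------------------------------------------------


def depth_profile(
    transcripts: Iterable[Transcript], strand: Strand, genome: Genome
) -> np.ndarray:
    """Per-base depth on one strand; index i is genome position i+1.

    Only exonic alignment blocks contribute; spliced gaps are not covered.
    Blocks may wrap the origin of a circular genome.
    """
    delta = np.zeros(genome.length + 1, dtype=np.int64)
    for t in transcripts:
        if t.strand != strand:
            continue
        for s, e in t.blocks:
            if s < 1 or e > genome.length:
                if not genome.circular:
                    raise ValueError(f"block ({s},{e}) outside linear genome")
                s, e = genome.wrap(s), genome.wrap(e)
            if s <= e:
                delta[s - 1] += 1
                delta[e] -= 1
            else:  # wraps the origin
                delta[s - 1] += 1
                delta[genome.length] -= 1
                delta[0] += 1
                delta[e] -= 1
    return np.cumsum(delta[:-1])


@dataclass
class TranscriptionalUnit:
    strand: Strand
    start: int
    end: int
    mean_depth: float
    boundary_sites: tuple[Optional[PolyALikeSite], Optional[PolyALikeSite]] = (
        None,
        None,
    )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_units(
    depth: np.ndarray,
    strand: Strand,
    min_depth: Optional[float] = None,
    min_len: int = 300,
    max_gap: int = 50,
    sites: Sequence[PolyALikeSite] = (),
    site_tol: int = 30,
) -> list[TranscriptionalUnit]:
    """Maximal runs with depth >= min_depth, bridging gaps <= max_gap.

    ``min_depth`` defaults to half the strand's mean depth.  Runs shorter
    than ``min_len`` after bridging are discarded.  When polyA-like
    ``sites`` are supplied, each unit end is annotated with the nearest
    same-strand site within ``site_tol`` (5' boundary first).
    """
    if min_depth is None:
        min_depth = 0.5 * float(depth.mean())
    if min_depth <= 0:
        min_depth = 1.0
    above = depth >= min_depth
    if not above.any():
        return []
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [0] if above[0] else []
    starts += [int(i) + 1 for i in edges if not above[i]]
    ends = [int(i) for i in edges if above[i]]
    if above[-1]:
        ends.append(len(depth) - 1)
    runs = list(zip(starts, ends))  # 0-based inclusive
    bridged: list[list[int]] = []
    for s, e in runs:
        if bridged and s - bridged[-1][1] - 1 <= max_gap:
            bridged[-1][1] = e
        else:
            bridged.append([s, e])
    units = []
    strand_sites = [s for s in sites if s.strand == strand]
    for s0, e0 in bridged:
        start, end = s0 + 1, e0 + 1
        if end - start + 1 < min_len:
            continue
        mean_depth = float(depth[s0 : e0 + 1].mean())
        five = start if strand == "+" else end
        three = end if strand == "+" else start
        units.append(
            TranscriptionalUnit(
                strand=strand,
                start=start,
                end=end,
                mean_depth=mean_depth,
                boundary_sites=(
                    _nearest_site(five, strand_sites, site_tol),
                    _nearest_site(three, strand_sites, site_tol),
                ),
            )
        )
    return units


def _nearest_site(
    pos: int, sites: Sequence[PolyALikeSite], tol: int
) -> Optional[PolyALikeSite]:
    best, best_d = None, tol + 1
    for s in sites:
        d = _dist_to_interval(pos, s.start, s.end)
        if d < best_d:
            best, best_d = s, d
    return best


def summarize(
    transcripts: Sequence[Transcript], genome: Genome
) -> dict:
    """Coverage, depth and length summary of a transcript set.

    Returns per-strand covered fraction (bases with depth >= 1 over genome
    length), per-strand mean depth, and the median aligned length across all
    transcripts.
    """
    if not transcripts:
        log.warning("summarize: empty transcript set")
        return {
            "covered_fraction": {"+": 0.0, "-": 0.0},
            "mean_depth": {"+": 0.0, "-": 0.0},
            "median_aligned_length": 0.0,
            "n_transcripts": 0,
        }
    covered = {}
    mean_depth = {}
    for strand in ("+", "-"):
        depth = depth_profile(transcripts, strand, genome)
        covered[strand] = float((depth >= 1).mean())
        mean_depth[strand] = float(depth.mean())
    return {
        "covered_fraction": covered,
        "mean_depth": mean_depth,
        "median_aligned_length": float(
            median(t.aligned_length for t in transcripts)
        ),
        "n_transcripts": len(transcripts),
    }


# ---------------------------------------------------------------------------
# Splice junctions
# ---------------------------------------------------------------------------


@dataclass
class Junction:
    strand: Strand
    donor: int
    acceptor: int
    boundary_dimers: tuple[str, str]
    support: int

    @property
    def canonical(self) -> bool:
        """True for the conserved GT-AY donor/acceptor motif (Y = C or T)."""
        d, a = self.boundary_dimers
        return d == "GT" and a in ("AC", "AT")


def extract_junctions(
    transcripts: Iterable[Transcript], genome: Genome
) -> list[Junction]:
    """One junction per distinct (strand, donor, acceptor) with support.

    Donor and acceptor are the intron's first and last genomic bases in
    transcription order; dimers are read from the genome on the transcribed
    strand, so an intron on the "-" strand reports the reverse complement of
    its reference-strand boundaries.
    """
    counts: Counter = Counter()
    for t in transcripts:
        for (s1, e1), (s2, e2) in zip(t.blocks, t.blocks[1:]):
            gs, ge = e1 + 1, s2 - 1
            if gs > ge:
                continue
            if t.strand == "+":
                counts[("+", gs, ge)] += 1
            else:
                counts[("-", ge, gs)] += 1
    out = []
    for (strand, donor, acceptor), support in sorted(counts.items()):
        if strand == "+":
            dimers = (
                genome.fetch(donor, donor + 1, "+"),
                genome.fetch(acceptor - 1, acceptor, "+"),
            )
        else:
            dimers = (
                genome.fetch(donor - 1, donor, "-"),
                genome.fetch(acceptor, acceptor + 1, "-"),
            )
        out.append(Junction(strand, donor, acceptor, dimers, support))
    return out


def junctions_to_frame(junctions: Sequence[Junction]) -> pd.DataFrame:
    rows = [
        {
            "strand": j.strand,
            "donor": j.donor,
            "acceptor": j.acceptor,
            "donor_dimer": j.boundary_dimers[0],
            "acceptor_dimer": j.boundary_dimers[1],
            "support": j.support,
            "canonical": j.canonical,
        }
        for j in junctions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "strand", "donor", "acceptor", "donor_dimer", "acceptor_dimer",
            "support", "canonical",
        ],
    )


# ---------------------------------------------------------------------------
# RNA editing
# ---------------------------------------------------------------------------


@dataclass
class EditingSite:
    strand: Strand
    position: int
    ref_base: str
    alt_fraction: float
    depth: int


Pileup = Mapping[tuple[Strand, int], Mapping[str, int]]


def pileup_from_transcripts(transcripts: Iterable[Transcript]) -> Pileup:
    """Base counts per (strand, position) in transcribed-strand sense.

    Requires transcripts carrying their sequences; the sequence is walked
    along the exonic blocks (leftmost block first on "+", rightmost first on
    "-").
    """
    pile: dict[tuple[Strand, int], Counter] = defaultdict(Counter)
    for t in transcripts:
        if not t.seq:
            continue
        idx = 0
        blocks = t.blocks if t.strand == "+" else t.blocks[::-1]
        for s, e in blocks:
            n = e - s + 1
            chunk = t.seq[idx : idx + n]
            if len(chunk) < n:
                break  # sequence/blocks length mismatch: count what we have
            if t.strand == "+":
                for i, b in enumerate(chunk):
                    pile[("+", s + i)][b] += 1
            else:
                for i, b in enumerate(chunk):
                    pile[("-", e - i)][b] += 1
            idx += n
    return pile


@dataclass
class SnpLikeSite:
    strand: Strand
    position: int
    ref_base: str
    alt_base: str
    alt_fraction: float
    depth: int


def detect_editing(
    pileup: Pileup,
    genome: Genome,
    min_depth: int = 10,
    min_alt_frac: float = 0.2,
) -> tuple[list[EditingSite], list[SnpLikeSite]]:
    """C→U editing sites plus SNP-like mismatches from a strand-aware pileup.

    A position whose transcribed-strand reference base is C and whose read
    T-fraction reaches ``min_alt_frac`` at depth >= ``min_depth`` is an
    editing site; any other mismatch type passing the same thresholds is
    reported separately as SNP-like.
    """
    editing: list[EditingSite] = []
    snp_like: list[SnpLikeSite] = []
    for (strand, pos), counts in sorted(pileup.items()):
        depth = sum(counts.values())
        if depth < min_depth:
            continue
        ref = genome.base(pos, strand)
        if ref == "C":
            frac = counts.get("T", 0) / depth
            if frac >= min_alt_frac:
                editing.append(EditingSite(strand, pos, ref, frac, depth))
                continue
        alts = {b: n for b, n in counts.items() if b != ref}
        if alts:
            alt, n = max(alts.items(), key=lambda kv: kv[1])
            frac = n / depth
            if frac >= min_alt_frac:
                snp_like.append(SnpLikeSite(strand, pos, ref, alt, frac, depth))
    return editing, snp_like


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def depth_to_bedgraph(
    depth: np.ndarray, genome: Genome
) -> list[str]:
    """BedGraph lines (0-based half-open) run-length encoding the profile."""
    lines = []
    vals = depth
    change = np.flatnonzero(np.diff(vals)) + 1
    bounds = [0, *change.tolist(), len(vals)]
    for a, b in zip(bounds, bounds[1:]):
        v = int(vals[a])
        if v:
            lines.append(f"{genome.accession}\t{a}\t{b}\t{v}")
    return lines


def units_to_frame(units: Sequence[TranscriptionalUnit]) -> pd.DataFrame:
    rows = [
        {
            "strand": u.strand,
            "start": u.start,
            "end": u.end,
            "length": u.length,
            "mean_depth": round(u.mean_depth, 2),
            "five_prime_site": _site_str(u.boundary_sites[0]),
            "three_prime_site": _site_str(u.boundary_sites[1]),
        }
        for u in units
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "strand", "start", "end", "length", "mean_depth",
            "five_prime_site", "three_prime_site",
        ],
    )


def _site_str(site: Optional[PolyALikeSite]) -> str:
    return f"{site.start}-{site.end}" if site else "."


def units_to_bed(
    units: Sequence[TranscriptionalUnit], genome: Genome
) -> list[str]:
    return [
        to_bed6(
            genome.accession, u.start, u.end,
            f"TU_{u.start}", int(u.mean_depth), u.strand,
        )
        for u in units
    ]
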