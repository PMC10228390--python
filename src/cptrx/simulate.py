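"""Truth-labelled synthetic library generator.

Builds toy circular organelle genomes with planted promoters (AT-rich
−12..−1 region, +1 base drawn mostly G), polyA-like terminators, introns,
5'-primer-match loci and T-runs; samples transcripts from a multi-promoter /
probabilistic-termination model (degraded 5' ends, splicing intermediates,
C→U editing); and turns transcripts into library molecules including the
internal-mispriming artifact topologies, emitting FASTQ reads, truth-derived
SAM alignments and a per-read truth table.

All randomness flows from a single ``numpy`` Generator seeded once; the draw
order is fixed (genome background, planted bases, then per-read draws in
read order), so fixtures are byte-stable for a given seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import PrimerSet
from .core import GeneAnnotation, Genome, Strand, Transcript, revcomp

log = logging.getLogger("cptrx")

P5_SEED = "GGGTTGGG"  # 3'-terminal seed of the default 5' primer


# ---------------------------------------------------------------------------
# Genome specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PromoterSpec:
    """A planted promoter: transcription starts at ``plus1`` on ``strand``.

    ``weight`` sets the promoter's relative firing rate; ``region2_at`` the
    AT fraction written into the −12..−1 region; ``first_nt_probs`` the
    distribution the +1 base is drawn from (chloroplast initiation strongly
    favours G).
    """

    strand: Strand
    plus1: int
    weight: float = 1.0
    region2_at: float = 0.80
    first_nt_probs: tuple[tuple[str, float], ...] = (
        ("G", 0.80), ("A", 0.10), ("T", 0.05), ("C", 0.05),
    )


@dataclass(frozen=True)
class TerminatorSpec:
    """A planted polyA-like terminator.

    ``position`` is the first base of the planted motif in transcription
    order; the motif is ``AAT`` + A-run on the transcribed strand, so it
    carries an AATAA signal and a maximal A-run of ``a_run``.  Elongating
    polymerase terminates here with probability ``term_prob``.
    """

    strand: Strand
    position: int
    a_run: int = 10
    term_prob: float = 0.8

    @property
    def motif(self) -> str:
        return "AAT" + "A" * self.a_run

    @property
    def ref_interval(self) -> tuple[int, int]:
        n = len(self.motif)
        if self.strand == "+":
            return self.position, self.position + n - 1
        return self.position - n + 1, self.position

    @property
    def end_position(self) -> int:
        """Genomic position of a transcript 3' end terminating here."""
        lo, hi = self.ref_interval
        return hi if self.strand == "+" else lo


@dataclass(frozen=True)
class IntronSpec:
    strand: Strand
    start: int  # reference coordinates, start < end
    end: int
    donor: str = "GT"
    acceptor: str = "AC"

    @property
    def five_prime_boundary(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class EditingSpec:
    strand: Strand
    position: int
    efficiency: float = 0.7


@dataclass
class GenomeSpec:
    """Layout of a synthetic organelle genome.

    Defaults describe the study conditions the package is validated under: a
    30-kb AT-rich circular genome with promoters of mixed strength on both
    strands (more genes, hence heavier traffic, on "-"), chained polyA-like
    terminators with 0.8 termination probability and probability-1 guards so
    transcripts never wrap the origin, one canonical (GT-AC) and one
    non-canonical (TT-GT) intron, and planted internal primer-match loci
    that make mispriming artifacts constructible.
    """

    length: int = 30_000
    gc: float = 0.36
    circular: bool = True
    seed: int = 2024
    promoters: list[PromoterSpec] = field(default_factory=list)
    terminators: list[TerminatorSpec] = field(default_factory=list)
    introns: list[IntronSpec] = field(default_factory=list)
    p5_sites: list[tuple[Strand, int]] = field(default_factory=list)
    t_runs: list[tuple[Strand, int, int]] = field(default_factory=list)
    editing_sites: list[EditingSpec] = field(default_factory=list)
    genes: list[tuple[str, Strand, int, int]] = field(default_factory=list)


def default_spec(seed: int = 2024) -> GenomeSpec:
    """The reference study conditions used by the test and acceptance runs."""
    return GenomeSpec(
        seed=seed,
        promoters=[
            PromoterSpec("+", 2_000, weight=3.0),
            PromoterSpec("+", 12_000, weight=1.0),
            PromoterSpec("-", 28_000, weight=4.0),
            PromoterSpec("-", 22_000, weight=1.5),
            PromoterSpec("-", 17_000, weight=1.0),
        ],
        terminators=[
            TerminatorSpec("+", 5_000, a_run=12, term_prob=0.8),
            TerminatorSpec("+", 9_000, a_run=10, term_prob=0.8),
            TerminatorSpec("+", 15_000, a_run=10, term_prob=0.9),
            TerminatorSpec("+", 20_000, a_run=10, term_prob=1.0),  # guard
            TerminatorSpec("-", 24_000, a_run=12, term_prob=0.8),
            TerminatorSpec("-", 18_500, a_run=10, term_prob=0.8),
            TerminatorSpec("-", 14_000, a_run=10, term_prob=0.9),
            TerminatorSpec("-", 1_000, a_run=10, term_prob=1.0),  # guard
        ],
        introns=[
            IntronSpec("+", 3_000, 3_400, donor="GT", acceptor="AC"),
            IntronSpec("-", 25_400, 25_800, donor="TT", acceptor="GT"),
        ],
        # same-strand seeds feed 5'-truncations; opposite-strand seeds feed
        # double-5 constructs on each strand's transcribed regions
        p5_sites=[
            ("+", 2_600), ("-", 3_700), ("+", 10_500), ("-", 13_300),
            ("+", 21_500), ("-", 26_500), ("+", 26_900),
        ],
        t_runs=[
            ("-", 4_300, 12), ("+", 4_600, 12), ("-", 25_000, 12),
            ("+", 27_000, 17),
        ],
        editing_sites=[
            EditingSpec("+", 2_450, 0.7),
            EditingSpec("-", 27_400, 0.7),
            EditingSpec("+", 13_000, 0.7),
        ],
    )


def promoter_grid_spec(seed: int = 2024, n_promoters: int = 40) -> GenomeSpec:
    """Promoter-composition study conditions: many equal-weight promoters.

    Each promoter draws its −12..−1 region at 80% AT and its +1 base mostly
    G, and is closed by a probability-1 terminator 300 nt downstream, so the
    sampled 5' ends alone determine support.  With 40 promoters (480 region
    II bases) the planted AT fraction is estimated tightly enough to check
    parameter recovery at the few-percent level.
    """
    promoters = []
    terminators = []
    for i in range(n_promoters):
        plus1 = 1_000 + 1_200 * i
        promoters.append(PromoterSpec("+", plus1, weight=1.0))
        terminators.append(TerminatorSpec("+", plus1 + 300, term_prob=1.0))
    return GenomeSpec(
        length=1_000 + 1_200 * n_promoters + 1_000,
        seed=seed,
        promoters=promoters,
        terminators=terminators,
        genes=[("filler", "+", 200, 400)],
    )


@dataclass
class PlantedGenome:
    """A synthetic genome plus the resolved truth of its planted features."""

    genome: Genome
    annotations: list[GeneAnnotation]
    promoters: list[PromoterSpec]  # first_nt resolved: single-entry probs
    terminators: list[TerminatorSpec]
    introns: list[IntronSpec]
    p5_sites: list[tuple[Strand, int, int]]  # strand, start, end
    t_runs: list[tuple[Strand, int, int]]
    editing_sites: list[EditingSpec]

    def promoter_first_nt(self, p: PromoterSpec) -> str:
        return p.first_nt_probs[0][0]


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------


def _planted_intervals(spec: GenomeSpec) -> list[tuple[int, int, str]]:
    """Reference intervals every planted feature writes into."""
    out: list[tuple[int, int, str]] = []
    for p in spec.promoters:
        if p.strand == "+":
            out.append((p.plus1 - 12, p.plus1, f"promoter@{p.plus1}{p.strand}"))
        else:
            out.append((p.plus1, p.plus1 + 12, f"promoter@{p.plus1}{p.strand}"))
    for t in spec.terminators:
        lo, hi = t.ref_interval
        out.append((lo, hi, f"terminator@{t.position}{t.strand}"))
    for i in spec.introns:
        out.append((i.start, i.start + 1, f"intron_donor@{i.start}{i.strand}"))
        out.append((i.end - 1, i.end, f"intron_acceptor@{i.end}{i.strand}"))
    for strand, pos in spec.p5_sites:
        out.append((pos, pos + len(P5_SEED) - 1, f"p5site@{pos}{strand}"))
    for strand, pos, ln in spec.t_runs:
        lo, hi = (pos, pos + ln - 1) if strand == "+" else (pos - ln + 1, pos)
        out.append((lo, hi, f"trun@{pos}{strand}"))
    for e in spec.editing_sites:
        out.append((e.position, e.position, f"editing@{e.position}{e.strand}"))
    return out


def make_genome(spec: GenomeSpec) -> PlantedGenome:
    """Materialize a :class:`GenomeSpec` into sequence plus annotations.

    Deterministic for a fixed ``spec.seed``.  Raises if any two planted
    features overlap (their written intervals would clobber each other).
    """
    intervals = _planted_intervals(spec)
    for lo, hi, name in intervals:
        if lo < 1 or hi > spec.length:
            raise ValueError(f"planted feature outside genome: {name}")
    conflicts = []
    ordered = sorted(intervals)
    for (lo1, hi1, n1), (lo2, hi2, n2) in zip(ordered, ordered[1:]):
        if lo2 <= hi1:
            conflicts.append(f"{n1} overlaps {n2}")
    if conflicts:
        raise ValueError("conflicting planted features: " + "; ".join(conflicts))

    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc / 2
    p_at = (1 - spec.gc) / 2
    seq = rng.choice(
        np.array(list("ACGT")), size=spec.length,
        p=[p_at, p_gc, p_gc, p_at],
    )

    def write(pos: int, s: str) -> None:
        seq[pos - 1 : pos - 1 + len(s)] = list(s)

    resolved_promoters: list[PromoterSpec] = []
    for p in spec.promoters:
        bases, probs = zip(*p.first_nt_probs)
        first = str(rng.choice(np.array(bases), p=np.array(probs)))
        r2 = "".join(
            str(rng.choice(np.array(["A", "T"])))
            if rng.random() < p.region2_at
            else str(rng.choice(np.array(["G", "C"])))
            for _ in range(12)
        )
        if p.strand == "+":
            write(p.plus1 - 12, r2)
            write(p.plus1, first)
        else:
            # minus-sense 5'->3' over reference [plus1, plus1+12] is
            # region II followed by the +1 base
            write(p.plus1, revcomp(r2 + first))
        resolved_promoters.append(
            replace(p, first_nt_probs=((first, 1.0),))
        )
    for t in spec.terminators:
        lo, _hi = t.ref_interval
        write(lo, t.motif if t.strand == "+" else revcomp(t.motif))
    for i in spec.introns:
        if i.strand == "+":
            write(i.start, i.donor)
            write(i.end - 1, i.acceptor)
        else:
            write(i.end - 1, revcomp(i.donor))
            write(i.start, revcomp(i.acceptor))
    p5_resolved = []
    for strand, pos in spec.p5_sites:
        write(pos, P5_SEED if strand == "+" else revcomp(P5_SEED))
        p5_resolved.append((strand, pos, pos + len(P5_SEED) - 1))
    for strand, pos, ln in spec.t_runs:
        lo, hi = (pos, pos + ln - 1) if strand == "+" else (pos - ln + 1, pos)
        write(lo, "T" * ln if strand == "+" else "A" * ln)
    for e in spec.editing_sites:
        write(e.position, "C" if e.strand == "+" else "G")

    genome = Genome(
        accession=f"SIM_{spec.seed}",
        sequence="".join(seq.tolist()),
        circular=spec.circular,
    )
    annotations = _build_annotations(spec)
    return PlantedGenome(
        genome=genome,
        annotations=annotations,
        promoters=resolved_promoters,
        terminators=spec.terminators,
        introns=spec.introns,
        p5_sites=p5_resolved,
        t_runs=list(spec.t_runs),
        editing_sites=list(spec.editing_sites),
    )


def _build_annotations(spec: GenomeSpec) -> list[GeneAnnotation]:
    """Gene models: one host gene per intron plus any extra plain genes.

    When the spec lists no explicit genes, single-exon filler genes are added
    so the "-" strand encodes more genes than "+" (the heavy-strand
    convention of the organism the defaults emulate).
    """
    anns: list[GeneAnnotation] = []
    for n, i in enumerate(spec.introns):
        lo = max(1, i.start - 80)
        hi = min(spec.length, i.end + 80)
        anns.append(
            GeneAnnotation(
                name=f"gene_intron{n + 1}",
                kind="protein_coding",
                strand=i.strand,
                exons=[(lo, i.start - 1), (i.end + 1, hi)],
            )
        )
    genes = spec.genes
    if not genes:
        genes = [
            ("geneA", "+", 2_100, 2_500),
            ("geneB", "+", 12_100, 12_600),
            ("geneC", "-", 27_200, 27_600),
            ("geneD", "-", 23_000, 23_400),
            ("geneE", "-", 21_000, 21_400),
            ("geneF", "-", 16_000, 16_400),
        ]
    for name, strand, lo, hi in genes:
        anns.append(
            GeneAnnotation(
                name=name, kind="protein_coding", strand=strand,
                exons=[(lo, hi)],
            )
        )
    return anns


# ---------------------------------------------------------------------------
# Transcript sampling
# ---------------------------------------------------------------------------


@dataclass
class SimTranscript(Transcript):
    """A sampled transcript carrying its truth labels."""

    true_class: str = "FULL_LENGTH"
    true_tis: Optional[int] = None
    true_tts: Optional[int] = None
    promoter: Optional[PromoterSpec] = None
    terminator: Optional[TerminatorSpec] = None
    n_junctions: int = 0


@dataclass(frozen=True)
class TranscriptRates:
    degraded_frac: float = 0.15
    splice_intermediate_frac: float = 0.03
    mature_splice_prob: float = 0.9
    readthrough_override: Optional[float] = None
    """When set, every terminator's termination probability becomes
    ``1 - readthrough_override`` (used for limit-case checks)."""


def _downstream_terminators(
    planted: PlantedGenome, strand: Strand, start: int
) -> list[TerminatorSpec]:
    terms = [t for t in planted.terminators if t.strand == strand]
    if strand == "+":
        terms = sorted(
            (t for t in terms if t.ref_interval[0] > start),
            key=lambda t: t.position,
        )
    else:
        terms = sorted(
            (t for t in terms if t.ref_interval[1] < start),
            key=lambda t: -t.position,
        )
    return terms


def _transcript_sequence(
    planted: PlantedGenome,
    strand: Strand,
    blocks: list[tuple[int, int]],
    rng: np.random.Generator,
) -> str:
    ordered = blocks if strand == "+" else blocks[::-1]
    chunks = [planted.genome.fetch(s, e, strand) for s, e in ordered]
    seq = list("".join(chunks))
    # C->U editing in transcript sense
    offsets = []
    acc = 0
    for s, e in ordered:
        offsets.append((s, e, acc))
        acc += e - s + 1
    for site in planted.editing_sites:
        if site.strand != strand:
            continue
        for s, e, off in offsets:
            if s <= site.position <= e:
                idx = (
                    off + site.position - s
                    if strand == "+"
                    else off + e - site.position
                )
                if seq[idx] == "C" and rng.random() < site.efficiency:
                    seq[idx] = "T"
    return "".join(seq)


def simulate_transcripts(
    planted: PlantedGenome,
    n_reads: int = 3000,
    rates: TranscriptRates = TranscriptRates(),
    seed: int = 0,
) -> list[SimTranscript]:
    """Sample transcripts from the planted transcription model.

    A transcript starts at a promoter +1 drawn by weight (or, for the
    splicing-intermediate fraction, exactly at an intron 5' boundary), and
    elongates through successive same-strand terminators, stopping at each
    with its termination probability (guard terminators with probability 1
    bound every transcribed region, so no transcript wraps the origin).
    Degraded transcripts get a uniform-random 5' truncation.  Introns fully
    inside a transcript are spliced out with ``mature_splice_prob``.
    """
    rng = np.random.default_rng(seed)
    promoters = planted.promoters
    weights = np.array([p.weight for p in promoters], dtype=float)
    weights /= weights.sum()
    out: list[SimTranscript] = []
    for n in range(n_reads):
        klass = "FULL_LENGTH"
        promoter: Optional[PromoterSpec] = None
        if planted.introns and rng.random() < rates.splice_intermediate_frac:
            intron = planted.introns[rng.integers(len(planted.introns))]
            strand = intron.strand
            five = intron.five_prime_boundary
            klass = "SPLICE_INTERMEDIATE"
            true_tis = None
        else:
            promoter = promoters[
                int(rng.choice(len(promoters), p=weights))
            ]
            strand = promoter.strand
            five = promoter.plus1
            true_tis = promoter.plus1
        terms = _downstream_terminators(planted, strand, five)
        terminator: Optional[TerminatorSpec] = None
        for t in terms:
            p_stop = (
                1 - rates.readthrough_override
                if rates.readthrough_override is not None
                else t.term_prob
            )
            if rng.random() < p_stop:
                terminator = t
                break
        if terminator is None:
            terminator = terms[-1] if terms else None
        if terminator is None:
            # no downstream terminator: clip at the far genome end
            three = planted.genome.length if strand == "+" else 1
        else:
            three = terminator.end_position
        if klass == "FULL_LENGTH" and rng.random() < rates.degraded_frac:
            span = abs(three - five)
            if span > 250:
                shift = int(rng.integers(1, span - 200))
                five = five + shift if strand == "+" else five - shift
                klass = "DEGRADED"
                true_tis = None
        lo, hi = (five, three) if strand == "+" else (three, five)
        blocks = [(lo, hi)]
        n_junctions = 0
        for intron in planted.introns:
            inside = intron.strand == strand and lo < intron.start and (
                intron.end < hi
            )
            if not inside:
                continue
            if klass == "SPLICE_INTERMEDIATE" and intron.five_prime_boundary == five:
                continue  # its own intron is retained up to the boundary
            if rng.random() < rates.mature_splice_prob:
                blocks = _splice_out(blocks, intron)
                n_junctions += 1
        seq = _transcript_sequence(planted, strand, blocks, rng)
        out.append(
            SimTranscript(
                id=f"sim{n:06d}",
                strand=strand,
                blocks=blocks,
                seq=seq,
                true_class=klass,
                true_tis=true_tis,
                true_tts=(
                    terminator.end_position if terminator is not None else None
                ),
                promoter=promoter,
                terminator=terminator,
                n_junctions=n_junctions,
            )
        )
    return out


def _splice_out(
    blocks: list[tuple[int, int]], intron: IntronSpec
) -> list[tuple[int, int]]:
    out = []
    for s, e in blocks:
        if s < intron.start and intron.end < e:
            out.append((s, intron.start - 1))
            out.append((intron.end + 1, e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Library construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactRates:
    """Per-molecule probabilities of the internal-mispriming artifacts.

    The double-5 and double-3 defaults follow the fractions observed among
    aligned reads of the library this method was developed on (20% and
    2.7%); the remaining artifact classes could not be quantified there and
    default to small values.  A draw that lands on an artifact with no
    applicable internal site on the molecule falls back to a normal
    construct (logged).
    """

    double5: float = 0.20
    double3: float = 0.027
    type5: float = 0.005
    trunc5: float = 0.02
    trunc3: float = 0.02
    no_primer: float = 0.005

    def as_items(self) -> list[tuple[str, float]]:
        return [
            ("DOUBLE_5", self.double5),
            ("DOUBLE_3", self.double3),
            ("TYPE_5", self.type5),
            ("FIVE_TRUNC", self.trunc5),
            ("THREE_TRUNC", self.trunc3),
            ("NO_PRIMER", self.no_primer),
        ]


@dataclass
class SimRead:
    read_id: str
    seq: str  # as sequenced (FASTQ orientation)
    ref_forward: str  # reference-forward orientation of the same read
    flag_reverse: bool
    pos: int  # 1-based leftmost aligned reference position
    cigar: str
    strand: Strand  # transcribed strand of the underlying molecule
    truth: dict


@dataclass
class SimLibrary:
    reads: list[SimRead]
    truth: pd.DataFrame
    reference: Genome
    fallbacks: int = 0

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")

    def write_sam(self, path: str | Path) -> None:
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": self.reference.accession,
                    "LN": self.reference.length}],
        }
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for r in self.reads:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = r.read_id
                a.query_sequence = r.ref_forward
                a.flag = 16 if r.flag_reverse else 0
                a.reference_id = 0
                a.reference_start = r.pos - 1
                a.mapping_quality = 60
                a.cigarstring = r.cigar
                fh.write(a)

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _slice_blocks(
    blocks: Sequence[tuple[int, int]], strand: Strand, a: int, b: int
) -> list[tuple[int, int]]:
    """Genomic blocks for transcript-coordinate range [a, b) (sense frame)."""
    ordered = blocks if strand == "+" else list(blocks)[::-1]
    out = []
    off = 0
    for s, e in ordered:
        n = e - s + 1
        lo = max(a, off)
        hi = min(b, off + n)
        if lo < hi:
            if strand == "+":
                out.append((s + (lo - off), s + (hi - off) - 1))
            else:
                out.append((e - (hi - off) + 1, e - (lo - off)))
        off += n
    return sorted(out)


def _cigar(
    head: int, blocks: Sequence[tuple[int, int]], tail: int
) -> str:
    parts = [f"{head}S"] if head else []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1] - 1
            parts.append(f"{gap}N")
        parts.append(f"{e - s + 1}M")
    if tail:
        parts.append(f"{tail}S")
    return "".join(parts)


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _internal_p5_positions(
    t_seq: str, orientation: str, margin: int = 200
) -> list[int]:
    """Internal 5'-primer annealing positions (transcript coordinates).

    ``orientation`` "forward" finds the seed as printed — the configuration
    where the primer anneals to the first-strand cDNA (5'-truncation);
    "revcomp" finds its reverse complement — annealing to the transcript
    itself (double-5).
    """
    pat = P5_SEED if orientation == "forward" else revcomp(P5_SEED)
    pos = _find_all(t_seq, pat)
    return sorted(p for p in pos if margin <= p <= len(t_seq) - 50)


def _internal_runs(
    t_seq: str, base: str, min_run: int, margin: int = 200
) -> list[tuple[int, int]]:
    """Internal maximal runs of ``base`` as transcript-coordinate (start, end)."""
    out = []
    i, n = 0, len(t_seq)
    while i < n:
        if t_seq[i] == base:
            j = i
            while j < n and t_seq[j] == base:
                j += 1
            if j - i >= min_run and margin <= i and j <= n - 50:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


def simulate_library(
    transcripts: Sequence[SimTranscript],
    primers: PrimerSet | None = None,
    reference: Genome | None = None,
    artifact_rates: ArtifactRates = ArtifactRates(),
    tail_len_mean: float = 15.0,
    seq_error: float = 0.005,
    seed: int = 0,
) -> SimLibrary:
    """Turn transcripts into a sequenced library with mispriming artifacts.

    Normal molecules are P5 + transcript + polyA + adapter in transcript
    sense (the oligo-dT portion of the 3' primer guarantees at least 20 As
    in read sense); artifact molecules follow the internal-annealing
    constructions.  Alignments are emitted from the truth coordinates, so no
    external aligner is involved; uniform substitution noise at
    ``seq_error`` exercises the edit-distance budgets.
    """
    primers = primers or PrimerSet()
    if reference is None:
        raise ValueError("reference genome required for alignment emission")
    rng = np.random.default_rng(seed)
    adapter = primers.p3_adapter
    p5 = primers.five_prime
    items = artifact_rates.as_items()
    labels = [k for k, _ in items] + ["NORMAL"]
    probs = [p for _, p in items]
    if sum(probs) > 1:
        raise ValueError("artifact rates sum above 1")
    probs = probs + [1 - sum(probs)]
    reads: list[SimRead] = []
    truth_rows: list[dict] = []
    fallbacks = 0
    for t in transcripts:
        draw = labels[int(rng.choice(len(labels), p=probs))]
        t_seq = t.seq
        a_obs = max(20, int(rng.poisson(tail_len_mean)))
        construct = _construct(
            draw, t, t_seq, p5, adapter, a_obs, primers.polyT_min, rng
        )
        if construct is None:
            fallbacks += 1
            draw = "NORMAL"
            construct = _construct(
                "NORMAL", t, t_seq, p5, adapter, a_obs, primers.polyT_min, rng
            )
        molecule, prefix, t_a, t_b, suffix, true_class = construct
        if true_class == "FULL_LENGTH":
            true_class = t.true_class  # DEGRADED / SPLICE_INTERMEDIATE kept
        blocks = _slice_blocks(t.blocks, t.strand, t_a, t_b)
        if t.strand == "+":
            ref_forward, head, tail = molecule, prefix, suffix
        else:
            ref_forward, head, tail = revcomp(molecule), suffix, prefix
        if seq_error > 0:
            ref_forward = _add_noise(ref_forward, seq_error, rng)
        emit_rc = bool(rng.random() < 0.5)
        seq = revcomp(ref_forward) if emit_rc else ref_forward
        read_id = f"read_{t.id}"
        reads.append(
            SimRead(
                read_id=read_id,
                seq=seq,
                ref_forward=ref_forward,
                flag_reverse=emit_rc,
                pos=blocks[0][0],
                cigar=_cigar(head, blocks, tail),
                strand=t.strand,
                truth={},
            )
        )
        sense5 = t_a == 0
        truth_rows.append(
            {
                "read_id": read_id,
                "true_class": true_class,
                "strand": t.strand,
                "true_tis": t.true_tis if (true_class not in (
                    "DOUBLE_5", "DOUBLE_3", "TYPE_5", "FIVE_TRUNC",
                ) and sense5) else pd.NA,
                "true_tts": t.true_tts if true_class not in (
                    "DOUBLE_5", "THREE_TRUNC",
                ) else pd.NA,
                "n_junctions": sum(
                    1 for (s1, e1), (s2, _) in zip(blocks, blocks[1:])
                ),
                "polyA_len": a_obs if "A" * 5 in molecule[-len(adapter) - a_obs :] else 0,
                "emitted_revcomp": emit_rc,
                "aligned_start": blocks[0][0],
                "aligned_end": blocks[-1][1],
            }
        )
    truth = pd.DataFrame(truth_rows)
    if fallbacks:
        log.info("simulate_library: %d artifact draws fell back to normal",
                 fallbacks)
    return SimLibrary(reads=reads, truth=truth, reference=reference,
                      fallbacks=fallbacks)


def _construct(
    draw: str,
    t: SimTranscript,
    t_seq: str,
    p5: str,
    adapter: str,
    a_obs: int,
    polyt_min: int,
    rng: np.random.Generator,
):
    """Build (molecule, prefix_len, t_start, t_end, suffix_len, class).

    ``t_start``/``t_end`` delimit the transcript portion retained in the
    molecule (transcript sense coordinates); prefix/suffix are the
    non-genomic molecule parts flanking it.  Returns None when the artifact
    has no applicable internal site on this molecule.
    """
    n = len(t_seq)
    if draw == "NORMAL":
        mol = p5 + t_seq + "A" * a_obs + adapter
        return mol, len(p5), 0, n, a_obs + len(adapter), "FULL_LENGTH"
    if draw == "NO_PRIMER":
        return t_seq, 0, 0, n, 0, "NO_PRIMER"
    if draw == "DOUBLE_5":
        # primer anneals to the transcript: revcomp seed occurrence
        sites = _internal_p5_positions(t_seq, "revcomp")
        if not sites:
            return None
        j = int(sites[rng.integers(len(sites))])
        mol = p5 + t_seq[:j] + revcomp(p5)
        return mol, len(p5), 0, j, len(p5), "DOUBLE_5"
    if draw == "FIVE_TRUNC":
        # primer anneals to the first-strand cDNA: forward seed occurrence
        sites = _internal_p5_positions(t_seq, "forward", margin=50)
        sites = [s for s in sites if n - s >= 200]
        if not sites:
            return None
        k = int(sites[rng.integers(len(sites))])
        mol = p5 + t_seq[k:] + "A" * a_obs + adapter
        return mol, len(p5), k, n, a_obs + len(adapter), "FIVE_TRUNC"
    if draw == "DOUBLE_3":
        # polyT anneals to an A-run of the first-strand cDNA, i.e. a T-run
        # of the transcript; the templated T-run stays in the read
        runs = _internal_runs(t_seq, "T", polyt_min)
        if not runs:
            return None
        j, _jend = runs[rng.integers(len(runs))]
        mol = revcomp(adapter) + "T" * 20 + t_seq[j:] + "A" * a_obs + adapter
        return (
            mol, len(adapter) + 20, j, n, a_obs + len(adapter), "DOUBLE_3"
        )
    if draw == "THREE_TRUNC":
        # polyT anneals to an internal A-run of the transcript itself
        runs = _internal_runs(t_seq, "A", polyt_min, margin=200)
        runs = [r for r in runs if r[1] >= 200]
        if not runs:
            return None
        _j, jend = runs[rng.integers(len(runs))]
        mol = p5 + t_seq[:jend] + "A" * 20 + adapter
        return mol, len(p5), 0, jend, 20 + len(adapter), "THREE_TRUNC"
    if draw == "TYPE_5":
        mol = revcomp(adapter) + t_seq + "A" * a_obs + adapter
        return mol, len(adapter), 0, n, a_obs + len(adapter), "TYPE_5"
    raise ValueError(f"unknown draw {draw}")


def _add_noise(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    if not mask.any():
        return seq
    alts = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACGT"}
    idx = np.flatnonzero(mask)
    for i in idx:
        choices = alts[arr[i]]
        arr[i] = choices[int(rng.integers(len(choices)))]
    return "".join(arr.tolist())


# ---------------------------------------------------------------------------
# Fixture writers
# ---------------------------------------------------------------------------


def write_genome_fasta(planted: PlantedGenome, path: str | Path) -> None:
    g = planted.genome
    with open(path, "w") as fh:
        fh.write(f">{g.accession}\n")
        for i in range(0, g.length, 70):
            fh.write(g.sequence[i : i + 70] + "\n")


def write_annotations_gff3(planted: PlantedGenome, path: str | Path) -> None:
    acc = planted.genome.accession
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, ann in enumerate(planted.annotations):
            lo, hi = ann.span
            gid = f"gene{k}"
            fh.write(
                f"{acc}\tcptrx_sim\tgene\t{lo}\t{hi}\t.\t{ann.strand}\t.\t"
                f"ID={gid};Name={ann.name}\n"
            )
            for x, (s, e) in enumerate(ann.exons):
                fh.write(
                    f"{acc}\tcptrx_sim\texon\t{s}\t{e}\t.\t{ann.strand}\t.\t"
                    f"ID={gid}.e{x};Parent={gid}\n"
                )
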