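"""Genome, annotation and coordinate layer shared by all pipeline stages.

Conventions used throughout the package:

* Coordinates are 1-based inclusive (GenBank style).  BED output converts to
  0-based half-open at the serialization boundary only.
* Strands are stored as ``"+"`` (the reference strand) and ``"-"``.  The
  heavy/light nomenclature of organelle genomics — heavy being the strand
  encoding more genes — is a presentation layer resolved by
  :func:`assign_strands`; all stored intervals live on the reference strand
  with a strand flag.
* Promoter offsets follow the no-zero convention: position ``-1`` abuts
  ``+1``, there is no position 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

log = logging.getLogger("cptrx")

Strand = Literal["+", "-"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def other_strand(strand: Strand) -> Strand:
    return "-" if strand == "+" else "+"


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """A single (typically circular) organelle reference sequence.

    Parameters
    ----------
    accession:
        Record identifier, e.g. ``NC_000932``.
    sequence:
        Uppercase nucleotide string over ``{A,C,G,T,N}``.
    circular:
        Whether coordinate arithmetic may wrap through the origin.
    """

    accession: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("genome sequence is empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in genome sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def wrap(self, pos: int) -> int:
        """Map an out-of-range 1-based position onto the circle."""
        return (pos - 1) % self.length + 1

    def fetch(self, start: int, end: int, strand: Strand = "+") -> str:
        """Sequence of the 1-based inclusive interval ``[start, end]``.

        On the ``-`` strand the reverse complement is returned (5'→3' on that
        strand).  ``start`` may exceed the sequence end or be non-positive on
        circular genomes, in which case the interval wraps through the origin.
        """
        if end < start:
            raise ValueError(f"empty interval [{start}, {end}]")
        n = end - start + 1
        if n > self.length:
            raise ValueError("interval longer than genome")
        if start < 1 or end > self.length:
            if not self.circular:
                raise ValueError(
                    f"interval [{start}, {end}] outside linear genome of "
                    f"length {self.length}"
                )
            doubled = self.sequence + self.sequence
            off = (start - 1) % self.length
            out = doubled[off : off + n]
        else:
            out = self.sequence[start - 1 : end]
        return revcomp(out) if strand == "-" else out

    def base(self, pos: int, strand: Strand = "+") -> str:
        return self.fetch(self.wrap(pos) if self.circular else pos,
                          self.wrap(pos) if self.circular else pos, strand)


def load_genome(path: str | Path, circular: bool | None = None) -> Genome:
    """Read a genome from a FASTA or GenBank flatfile with one record.

    The circular flag comes from ``circular`` when given, else from the
    GenBank topology field, else defaults to circular (the organelle-genome
    norm).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fasta" if first == ">" else "genbank"
    records = list(SeqIO.parse(str(path), fmt))
    if len(records) != 1:
        raise ValueError(
            f"{path} contains {len(records)} records; exactly one expected"
        )
    rec = records[0]
    if circular is None:
        topology = rec.annotations.get("topology", "") if fmt == "genbank" else ""
        circular = True if fmt == "fasta" else topology == "circular"
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"{path}: record {rec.id} has an empty sequence")
    return Genome(accession=rec.id, sequence=seq, circular=bool(circular))


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

GeneKind = Literal["protein_coding", "rRNA", "tRNA", "other"]


@dataclass
class GeneAnnotation:
    """A gene with exon structure on reference-strand coordinates."""

    name: str
    kind: GeneKind
    strand: Strand
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.name}: exon list is empty")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"gene {self.name}: exon start {s} > end {e}")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.name}: overlapping exons")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def intron_five_prime_boundaries(self) -> list[int]:
        """Genomic positions of each intron's 5' (donor-side) first base."""
        if self.strand == "+":
            return [s for s, _ in self.introns]
        return [e for _, e in self.introns]


_GENBANK_KINDS = {"CDS": "protein_coding", "rRNA": "rRNA", "tRNA": "tRNA"}
_GFF_KINDS = {
    "CDS": "protein_coding",
    "mRNA": "protein_coding",
    "gene": "other",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
}


def load_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from a GenBank flatfile or a GFF3 file.

    GenBank: one annotation per CDS/rRNA/tRNA feature (exons from the
    feature's location parts).  GFF3: CDS/rRNA/tRNA features grouped by their
    parent gene, exon structure from the feature parts.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(16)
    if first.startswith("LOCUS"):
        return _annotations_from_genbank(path)
    return _annotations_from_gff3(path)


def _annotations_from_genbank(path: Path) -> list[GeneAnnotation]:
    rec = next(SeqIO.parse(str(path), "genbank"))
    out: list[GeneAnnotation] = []
    for feat in rec.features:
        kind = _GENBANK_KINDS.get(feat.type)
        if kind is None:
            continue
        name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        strand: Strand = "-" if feat.location.strand == -1 else "+"
        exons = [
            (int(p.start) + 1, int(p.end)) for p in sorted(
                feat.location.parts, key=lambda p: int(p.start)
            )
        ]
        out.append(GeneAnnotation(name=name, kind=kind, strand=strand, exons=exons))
    return out


def _annotations_from_gff3(path: Path) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: list[GeneAnnotation] = []
    for gene in db.features_of_type(("gene", "tRNA", "rRNA")):
        if gene.featuretype == "gene":
            kinds = {c.featuretype for c in db.children(gene)}
            kind = (
                "tRNA" if "tRNA" in kinds
                else "rRNA" if "rRNA" in kinds
                else "protein_coding" if "CDS" in kinds or "mRNA" in kinds
                else "other"
            )
        elif any(True for _ in db.parents(gene, featuretype="gene")):
            continue  # counted via its parent gene
        else:
            kind = gene.featuretype
        parts = [
            (c.start, c.end)
            for c in db.children(gene, featuretype=("exon", "CDS"))
        ]
        # prefer exon features; fall back to CDS, then the gene span
        exon_parts = [
            (c.start, c.end) for c in db.children(gene, featuretype="exon")
        ]
        if exon_parts:
            parts = exon_parts
        elif not parts:
            parts = [(gene.start, gene.end)]
        parts = _merge_intervals(parts)
        name = gene.attributes.get("Name", gene.attributes.get("ID", ["?"]))[0]
        strand: Strand = "-" if gene.strand == "-" else "+"
        out.append(GeneAnnotation(name=name, kind=kind, strand=strand, exons=parts))
    return out


def _merge_intervals(parts: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    parts = sorted(parts)
    merged: list[list[int]] = []
    for s, e in parts:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# Strand naming
# ---------------------------------------------------------------------------


@dataclass
class StrandAssignment:
    """Maps the heavy/light names onto physical strands.

    The heavy strand is the one encoding strictly more genes; ties go to the
    reference strand so the assignment is deterministic.
    """

    heavy: Strand
    gene_counts: dict[str, int] = field(default_factory=dict)

    @property
    def light(self) -> Strand:
        return other_strand(self.heavy)

    def name_of(self, strand: Strand) -> str:
        return "heavy" if strand == self.heavy else "light"

    def label_suffix(self, strand: Strand) -> str:
        """Trailing "-" marks the heavy strand in TIS/TTS labels."""
        return "-" if strand == self.heavy else ""


def assign_strands(
    genome: Genome, annotations: Iterable[GeneAnnotation]
) -> StrandAssignment:
    """Name the strand encoding more genes the heavy strand."""
    anns = list(annotations)
    if not anns:
        raise ValueError("assign_strands requires at least one annotation")
    counts = {"+": 0, "-": 0}
    for a in anns:
        counts[a.strand] += 1
    heavy: Strand = "-" if counts["-"] > counts["+"] else "+"
    return StrandAssignment(heavy=heavy, gene_counts=counts)


# ---------------------------------------------------------------------------
# Promoter windows
# ---------------------------------------------------------------------------


def extract_window(
    genome: Genome,
    strand: Strand,
    plus1: int,
    up: int = 37,
    down: int = 25,
) -> str:
    """62-nt promoter window around a +1 position, 5'→3' on ``strand``.

    Covers offsets ``-up..-1`` and ``+1..+down`` (no position 0); with the
    defaults that is the −37..+25 segment used for promoter analysis.  On
    circular genomes the window may wrap through the origin; on linear
    genomes an out-of-range window raises ``ValueError``.
    """
    if not (1 <= plus1 <= genome.length):
        raise ValueError(f"plus1={plus1} outside genome of length {genome.length}")
    if strand == "+":
        start, end = plus1 - up, plus1 + down - 1
    else:
        start, end = plus1 - down + 1, plus1 + up
    return genome.fetch(start, end, strand)


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    """An aligned, genome-sense-oriented transcript.

    ``blocks`` are the exonic alignment blocks in genomic order (1-based
    inclusive, reference coordinates); ``seq`` is the transcript sequence
    5'→3' on its own strand (may be empty when unknown).
    """

    id: str
    strand: Strand
    blocks: list[tuple[int, int]]
    seq: str = ""

    def __post_init__(self) -> None:
        self.blocks = sorted((int(s), int(e)) for s, e in self.blocks)
        for s, e in self.blocks:
            if s > e:
                raise ValueError(f"transcript {self.id}: block start > end")

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def five_prime(self) -> int:
        """Genomic position of the transcript's 5' end."""
        return self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1]

    @property
    def three_prime(self) -> int:
        return self.blocks[-1][1] if self.strand == "+" else self.blocks[0][0]

    @property
    def aligned_length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)


# ---------------------------------------------------------------------------
# Interval serialization
# ---------------------------------------------------------------------------


def to_bed6(
    accession: str,
    start: int,
    end: int,
    name: str,
    score: float | int,
    strand: Strand,
) -> str:
    """One BED6 line from a 1-based inclusive interval (bit-exact convert)."""
    return f"{accession}\t{start - 1}\t{end}\t{name}\t{score}\t{strand}"


def write_bed(path: str | Path, lines: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
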