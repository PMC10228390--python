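# Methods

## Coordinates, strands and naming

All genomic intervals are 1-based inclusive; BED/BedGraph output converts
to 0-based half-open at the serialization boundary only, and the
conversion is covered by tests. Strands are stored as `+` (the reference
strand) and `-`; the organelle convention of naming the strand that
encodes more genes the *heavy* strand is a presentation layer:
`assign_strands` counts genes per strand (ties go to the reference strand,
for determinism) and the resulting `StrandAssignment` renders labels such
as `TIS_51887-`, where the trailing minus marks the heavy strand. Promoter
offsets use the no-zero convention: −1 abuts +1.

Circular genomes are handled by modular coordinate arithmetic; sequence
fetches use string doubling, homopolymer runs that span the origin are
merged and counted once, and loading a rotated copy of a circular genome
yields the same site and homopolymer censuses after coordinate rotation
(tested).

## Primer detection and the artifact decision table

Primers are located by semi-global alignment (free end-gaps on the read
side, edlib `HW` mode) of the primer and its reverse complement within a
search window at each read end. Defaults: edit budget
`ceil(0.10 × primer length)` and a 100-nt end window. These were chosen so
that the 38-nt 5' primer and the 42-nt adapter portion of the 3' primer are
separated from random sequence by a wide margin — a random 500-mer matches
the 5' primer within 4 edits with probability well below 1e-4 (exercised by
a 50-trial random-read test) — while tolerating several CCS errors per
primer. Ties between candidate hits break by fewer edits, then smaller
offset from the read end, then head before tail.

The 3' primer is printed in read (second-strand) sense: a 20-A stretch
followed by the adapter. The scanner therefore searches the adapter
portion and then measures the adjacent tail run: an A-run ending where a
forward adapter hit begins, or a T-run starting where a reverse-complement
hit ends. The run measurement tolerates interior interruptions of one base
flanked by run bases, because a single sequencing error inside a polyA
tail must not split it; a hit is "with polyT" when the run carries at
least `polyT_min` (default 8) A/T bases. The threshold is configurable
because chloroplast polyA tails are short; 8 separates the ≥20-base runs
guaranteed by the oligo-dT from templated background.

Classification applies the decision table: 5'+3'-with-polyT in consistent
orientations ⇒ full length; 5' primers at both ends in opposite
orientations ⇒ double-5; two 3'-with-polyT ⇒ double-3; 3'-with-polyT plus
3'-without ⇒ the fifth type; one primer ⇒ five-only / three-only; none ⇒
no-primer; everything else (three-hit topologies, inconsistent
orientations, polyT-less primer pairs) ⇒ unclassified. Full-length,
five-only and three-only reads are oriented transcript-5'→3' and trimmed
of primers and tail; the trimmed transcript never retains a full primer
occurrence under the same edit budget (tested). Classification is
invariant under reverse-complementing the read.

Alignment filters drop reads with aligned regions shorter than 200 nt or
covering less than 5% of the read; both thresholds pass on equality.

## Site scanning

**5' primer-match sites** are all loci on either strand within `max_edits`
(default 1) of the 3'-terminal `seed_len` (default 8) bases of the 5'
primer, i.e. `GGGTTGGG`. The scan enumerates the edit-distance
neighbourhood of the seed and exact-matches it, clustering overlapping
hits to their minimum-edit representative. Sites containing N never match
(conservative calling). **3' primer-match sites** are maximal T-runs with
a combined length of at least `min_t_run` (default 8), allowing one
interruption of up to 3 non-T bases so that motifs like T₂CT₉ count as one
site.

**PolyA-like sites** (candidate terminators) are built per strand by
chaining maximal A-runs: each run of at least `min_a_run` (default 5)
seeds a site that annexes neighbouring A-runs across interruptions of ≤3
bases, closest gap first, while the span stays within `window` (default
25 nt) and its A-fraction at or above `min_a_frac` (default 0.7);
overlapping sites merge. Chaining — rather than growing a window one base
at a time — keeps site boundaries on A's and reproduces the canonical
terminator motifs (A₁₂GA₄TA₂ at a unit 3' end; TAT₈C₂A₂T₅ at a unit 5'
end, which is A-rich on the opposite strand) without diluting them with
flanking sequence. Each site records which of the AATAA/AAGAA
polyadenylation-like signals it contains. On uniform-random sequence the
background density follows the maximal-run statistic
`L·p⁵·(1−p)²` per strand (≈1.1 sites/kb over both strands at p=0.25);
the suite asserts consistency with this closed form rather than an
arbitrary cutoff.

**Truncation suspects.** A transcript whose 5' end lies within `tol`
(default 10 nt) of a *same-strand* 5'-primer-match site is a 5'-truncation
suspect: 5' truncation arises when the primer anneals to the first-strand
cDNA, whose sequence matches the transcript sense. A 3' end within `tol`
of an *opposite-strand* 3'-primer-match site (an A-run on the transcript's
own strand) is a 3'-truncation suspect. Both flags are advisory — the
molecules are structurally indistinguishable from genuine transcripts, so
nothing is removed.

## TIS calling

Full-length transcript 5' ends are counted per exact (strand, position);
no clustering is applied by default because neighbouring genuine TISs one
base apart are real and distinct (a merge radius is exposed as an option,
default 0). Each position becomes a candidate with its 62-nt window
(−37..+25), per-region AT content (regions I/II/III = −37..−13, −12..−1,
+1..+25), first nucleotide and +1..+2 dimer, all read from the *genome*
rather than the reads so that untemplated RNA 5' additions cannot shift a
call. Candidates below `min_support` (default 10) are kept but flagged
`LOW_SUPPORT` and treated as presumptive degraded-RNA ends — the support
threshold is the only degradation model, following the observation that
windows from degraded 5' ends have much lower copy numbers than genuine
promoters. Candidates whose +1 coincides (within `tol`, default 0) with an
annotated intron 5' boundary on the same strand are flagged
`SPLICE_INTERMEDIATE`; GT-start candidates away from introns get
`GT_SUSPECT` (contaminants of unknown type may remain); candidates on 5'
primer-match sites get `P5_MATCH_SUSPECT`. The report carries a dimer
table and support-weighted mean AT content per region over passing
candidates.

## TTS calling

Untemplated tails are removed by the classifier, but genome-templated
A-runs remain part of the alignment, so a transcript terminating at a
polyA-like site may end *inside* it; distances are therefore measured to
the site interval (0 when inside), with `tol` defaulting to 10 nt. The
nearest same-strand site wins ties, then the smaller start coordinate.
Each site's read-through count is the number of same-strand transcripts
whose span covers the whole site without terminating there, so
`support / (support + readthrough)` estimates the per-site termination
probability; on simulated data this recovers the planted probability
within binomial error. `readthrough_stats` reports the distribution of
sites strictly contained in each aligned span. Ends near inverted-repeat
annotations are left as unassigned ends — whether IR stem-loops terminate
transcription or merely stabilize 3' ends is contested, so no IR-TTS
caller is implemented.

## Profiling, junctions, editing

Depth is per-base and per-strand over exonic alignment blocks (spliced
gaps uncovered). Transcriptional units are maximal runs with depth at
least `min_depth` — default half the strand's mean depth — bridging gaps
of ≤50 nt and at least 300 nt long; these defaults reproduce the planted
units of the simulator exactly and are exposed in the config. Unit ends
are annotated with the nearest same-strand polyA-like site. Junctions are
reported per distinct (strand, donor, acceptor) with boundary dimers read
on the transcribed strand and canonicality defined as GT-AY (Y = C or T);
non-canonical organelle junctions such as TT-GT are reported, not
discarded. Trans-spliced genes produce junctions in separate transcript
populations and are not joined. C→U editing sites are pileup positions
whose transcribed-strand reference base is C with a read T-fraction of at
least `min_alt_frac` (default 0.2) at depth ≥10; any other mismatch type
passing the same thresholds is reported separately as SNP-like.

## The simulator

The generator defines the validation conditions. The default synthetic
genome is a 30-kb, 36%-GC circular sequence with:

* five promoters of mixed strength (two on `+`, three on `-`, so the `-`
  strand is heavy), each writing an 80%-AT −12..−1 region and drawing its
  +1 base from {G: 0.8, A: 0.1, T: 0.05, C: 0.05};
* chained polyA-like terminators (`AAT` + A-run motifs, termination
  probability 0.8–0.9) with probability-1 guard terminators bounding each
  transcribed region so transcripts never wrap the origin;
* one canonical (GT-AC) and one non-canonical (TT-GT) intron, each with a
  two-exon host gene, spliced out of mature transcripts with probability
  0.9;
* planted 5'-primer-match seeds and T-runs on both strands, placed inside
  the transcribed regions of each strand so every artifact construction
  has an applicable internal site;
* three C→U editing sites at 70% efficiency.

Transcripts start at a promoter drawn by weight (or, for the 3%
splicing-intermediate fraction, exactly at an intron 5' boundary) and
terminate at each downstream same-strand terminator with its termination
probability (geometric read-through). Fifteen percent are degraded —
uniformly truncated at the 5' end. Library construction wraps each
transcript as P5 + transcript + polyA + adapter, with artifact draws at
the double-5 20%, double-3 2.7%, fifth-type 0.5%, truncation 2% + 2% and
no-primer 0.5% rates observed in or motivated by the library this method
was developed for; a draw without an applicable internal site falls back
to a normal construct, which is why recovered artifact fractions sit
slightly below the configured rates. The observed tail run is at least 20
A's (the oligo-dT contribution) plus a Poisson-distributed templated
excess. Uniform substitution noise (default 0.5%) exercises the
edit-distance budgets. Alignments are emitted directly from the truth
coordinates — no external aligner — with reference-forward SEQ, soft-clips
for non-genomic molecule parts and N-gaps for introns; an emitted-strand
coin flip makes half the FASTQ reads reverse-complemented. All randomness
flows from one numpy generator per stage seed, with a fixed draw order, so
fixtures are byte-stable.

What the simulator does *not* emulate: indel sequencing errors (CCS reads
are substitution-dominated at these accuracies, and the edit-distance
budgets would absorb small indels anyway), inverted repeats and the
two-copy ambiguity they create in alignment, PCR chimeras made of two
transcripts, RNA secondary structure, and base-composition heterogeneity
along the genome. Passing tests therefore demonstrate the correctness of
the decision logic and estimators under the stated noise model, not
aligner robustness on repeat-rich real genomes.

## Problem sizes

The test suite simulates 1,500-read libraries for module-level checks; the
parameter-recovery checks use 4,000 reads, the promoter-composition check
3,000 reads over 40 equal promoters (480 region II bases, giving a
standard error of about 0.013 on the planted 0.80 AT fraction), and the
acceptance script 6,000 reads. These sizes put binomial standard errors
well inside the asserted tolerances while keeping any single run under a
minute.

## Known limitations

* 5'-/3'-truncated artifacts are flagged, never removed; downstream depth
  and unit calls therefore include them, as they must.
* The copy-number threshold suppresses degraded-RNA TISs but also hides
  genuine promoters expressed below 10 supporting reads; previously
  reported TISs at very low expression would need manual rescue.
* Unit boundaries depend on the depth threshold; the half-of-strand-mean
  default is a heuristic tuned on the simulator, and real libraries with
  strong expression skew may need an explicit `unit_min_depth`.
* `pileup_from_transcripts` assumes the transcript sequence walks its
  blocks exactly (true for the emitted alignments; real indel-containing
  alignments contribute only their consistent prefix).
* The GFF3 reader requires exon or CDS children to recover multi-exon
  structure; bare gene features fall back to single-exon spans.
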