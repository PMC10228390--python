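"""Primer-match site scanning, homopolymer census, polyA-like detection."""

import re

import numpy as np
import pytest

from cptrx.core import Genome, Transcript, revcomp
from cptrx.sites import (
    census_homopolymers,
    flag_truncated,
    scan_polyA_like,
    scan_primer_match_sites,
)


def _genome(seq, circular=True):
    return Genome("toy", seq, circular=circular)


def _pad(rng, n):
    # GC-rich padding cannot create A/T runs or seed matches by accident
    return "".join(rng.choice(["G", "C"], size=n))


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(11)


class TestPrimerMatchScan:
    def test_exact_seed_found_once(self, rng):
        seq = _pad(rng, 200) + "GGGTTGGG" + _pad(rng, 200)
        sites = [
            s for s in scan_primer_match_sites(_genome(seq))
            if s.kind == "P5_match" and s.edits == 0
        ]
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].start, plus[0].end) == (201, 208)
        assert plus[0].score == 1.0

    def test_t17_run_found(self, rng):
        seq = _pad(rng, 100) + "T" * 17 + _pad(rng, 100)
        p3 = [
            s for s in scan_primer_match_sites(_genome(seq))
            if s.kind == "P3_match" and s.strand == "+"
        ]
        assert len(p3) == 1
        assert p3[0].motif == "T" * 17
        assert p3[0].score == 17

    def test_interrupted_run_t2ct9(self, rng):
        # T2 C T9: 11 T's with one 1-base interruption counts at min 11
        seq = _pad(rng, 100) + "TTCTTTTTTTTT" + _pad(rng, 100)
        p3 = [
            s for s in scan_primer_match_sites(
                _genome(seq), min_t_run=11
            )
            if s.kind == "P3_match" and s.strand == "+"
        ]
        assert len(p3) == 1
        assert p3[0].score == 11

    def test_all_c_genome_is_empty(self):
        assert scan_primer_match_sites(_genome("C" * 500)) == []

    def test_minus_strand_seed_coordinates(self, rng):
        seq = _pad(rng, 150) + revcomp("GGGTTGGG") + _pad(rng, 150)
        minus = [
            s for s in scan_primer_match_sites(_genome(seq))
            if s.kind == "P5_match" and s.strand == "-" and s.edits == 0
        ]
        assert len(minus) == 1
        assert (minus[0].start, minus[0].end) == (151, 158)

    def test_census_t_runs_are_covered_by_p3_sites(self, planted):
        """Every census T-run above threshold lies inside some P3 site."""
        sites = [
            s for s in scan_primer_match_sites(planted.genome, min_t_run=8)
            if s.kind == "P3_match" and s.strand == "+"
        ]
        _, runs = census_homopolymers(planted.genome, "T", 8)
        assert runs  # the planted T17 at least
        for r in runs:
            lo, hi = r.start, r.start + r.length - 1
            assert any(s.start <= lo and hi <= s.end for s in sites)


class TestHomopolymerCensus:
    def test_exact_a12(self):
        count, runs = census_homopolymers(_genome("A" * 12, circular=False),
                                          "A", 12)
        assert count == 1 and runs[0].length == 12

    def test_a13_is_one_maximal_run(self):
        count, _ = census_homopolymers(_genome("A" * 13, circular=False),
                                       "A", 12)
        assert count == 1

    def test_run_spanning_origin_counts_once(self):
        seq = "A" * 5 + "CGCGC" + "A" * 7
        count, runs = census_homopolymers(_genome(seq), "A", 12)
        assert count == 1
        assert runs[0].length == 12 and runs[0].start == 11

    def test_linear_genome_does_not_wrap(self):
        seq = "A" * 5 + "CGCGC" + "A" * 7
        assert census_homopolymers(_genome(seq, circular=False), "A", 12)[0] == 0

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        """Regex-on-rotated-string oracle over many random genomes."""
        rng = np.random.default_rng(23)
        for _ in range(300):
            n = int(rng.integers(20, 400))
            seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4],
                                     size=n))
            min_len = int(rng.integers(2, 6))
            base = str(rng.choice(list("AT")))
            got, _ = census_homopolymers(_genome(seq), base, min_len)
            assert got == _bruteforce_circular_runs(seq, base, min_len)

    def test_rotation_invariance(self, planted):
        g = planted.genome
        k = 1234
        rotated = Genome(g.accession, g.sequence[k:] + g.sequence[:k])
        for base in "AT":
            assert (
                census_homopolymers(rotated, base, 12)[0]
                == census_homopolymers(g, base, 12)[0]
            )


def _bruteforce_circular_runs(seq, base, min_len):
    """Independent oracle: cut the circle at a non-base position."""
    if set(seq) == {base}:
        return 1 if len(seq) >= min_len else 0
    cut = next(i for i, c in enumerate(seq) if c != base)
    lin = seq[cut:] + seq[:cut]
    return sum(
        1 for m in re.finditer(f"{base}+", lin) if len(m.group()) >= min_len
    )


class TestPolyALike:
    def test_printed_terminator_motif_is_a_site(self, rng):
        motif = "A" * 12 + "G" + "A" * 4 + "T" + "A" * 2
        seq = _pad(rng, 100) + motif + _pad(rng, 100)
        sites = [s for s in scan_polyA_like(_genome(seq)) if s.strand == "+"]
        assert len(sites) == 1
        assert sites[0].a_content > 0.8
        assert 101 >= sites[0].start >= 100 - 5
        assert motif in sites[0].sequence or sites[0].sequence in motif

    def test_t_rich_five_prime_motif_sits_on_other_strand(self, rng):
        # TAT8C2A2T5 in reference sense is A-rich on the opposite strand
        motif = "TA" + "T" * 8 + "CC" + "AA" + "T" * 5
        seq = _pad(rng, 100) + motif + _pad(rng, 100)
        sites = scan_polyA_like(_genome(seq))
        assert any(s.strand == "-" for s in sites)
        assert not any(s.strand == "+" for s in sites)

    def test_gc_only_sequence_has_no_sites(self):
        assert scan_polyA_like(_genome("GC" * 300)) == []

    def test_aataa_signal_annotated(self, rng):
        seq = _pad(rng, 80) + "AATAA" + "A" * 8 + _pad(rng, 80)
        sites = [s for s in scan_polyA_like(_genome(seq)) if s.strand == "+"]
        assert sites and "AATAA" in sites[0].signals

    def test_strand_mirror_symmetry(self, planted):
        """Scanning the reverse-complement genome mirrors strands/coords."""
        g = planted.genome
        mirror = Genome(g.accession, revcomp(g.sequence))
        fwd = scan_polyA_like(g)
        rev = scan_polyA_like(mirror)
        def key(sites, strand):
            return sorted(
                (g.length - s.end + 1, g.length - s.start + 1)
                for s in sites if s.strand == strand
            )
        assert key(fwd, "+") == sorted(
            (s.start, s.end) for s in rev if s.strand == "-"
        )

    def test_random_sequence_density_matches_run_statistics(self):
        """Background site density tracks the maximal-A-run expectation.

        On uniform-random sequence the expected density of seed runs
        (maximal A-runs of >= 5) is L * p^5 * (1-p)^2 per strand; site
        merging can only reduce the count.  The scan must not report more
        sites than seeds, and must find a decent fraction of them.
        """
        rng = np.random.default_rng(99)
        n = 20_000
        seq = "".join(rng.choice(list("ACGT"), size=n))
        sites = scan_polyA_like(_genome(seq))
        expected_seeds = 2 * n * 0.25**5 * 0.75**2  # both strands, ~22
        assert len(sites) <= expected_seeds * 1.5
        assert len(sites) >= expected_seeds * 0.3


class TestFlagTruncated:
    def test_planted_p5_site_flags_five_trunc(self, planted):
        strand, start, end = planted.p5_sites[0][0], *planted.p5_sites[0][1:]
        t = Transcript("t1", strand, [(start, start + 400)])
        sites = scan_primer_match_sites(planted.genome)
        flags = flag_truncated([t], sites)[0]
        assert "FIVE_TRUNC_SUSPECT" in flags

    def test_three_trunc_at_internal_a_run(self, planted):
        # planted T-run on "-" at 4300 is an A-run on "+"; a "+" transcript
        # ending there is a 3'-truncation suspect
        t = Transcript("t2", "+", [(3800, 4300)])
        sites = scan_primer_match_sites(planted.genome)
        assert "THREE_TRUNC_SUSPECT" in flag_truncated([t], sites)[0]

    def test_far_from_all_sites_is_unflagged(self, rng):
        seq = _pad(rng, 2000)
        sites = scan_primer_match_sites(_genome(seq))
        t = Transcript("t3", "+", [(500, 1500)])
        assert flag_truncated([t], sites)[0] == frozenset()
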