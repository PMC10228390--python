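"""TIS aggregation/calling/filtering and TTS assignment/read-through."""

import numpy as np
import pytest

from cptrx.core import GeneAnnotation, Genome, StrandAssignment, Transcript
from cptrx.sites import PolyALikeSite, scan_polyA_like
from cptrx.tis import (
    aggregate_five_prime_ends,
    call_tis,
    filter_splicing_intermediates,
)
from cptrx.tts import assign_tts, readthrough_stats


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(17)
    return Genome("toy", "".join(rng.choice(list("ACGT"), size=2000)))


class TestAggregate:
    def test_exact_position_counting(self):
        ts = [Transcript(f"t{i}", "+", [(500, 900)]) for i in range(3)]
        assert aggregate_five_prime_ends(ts) == {("+", 500): 3}

    def test_empty_input(self):
        assert aggregate_five_prime_ends([]) == {}

    def test_strands_kept_separate(self):
        ts = [
            Transcript("a", "+", [(500, 900)]),
            Transcript("b", "-", [(100, 500)]),
        ]
        assert aggregate_five_prime_ends(ts) == {
            ("+", 500): 1, ("-", 500): 1,
        }


class TestCallTis:
    def test_support_threshold_boundary(self, genome):
        counts = {("+", 500): 10, ("+", 800): 9}
        report = call_tis(counts, genome, min_support=10)
        by_pos = {c.plus1: c for c in report.candidates}
        assert by_pos[500].passing
        assert not by_pos[800].passing
        assert "LOW_SUPPORT" in by_pos[800].flags

    def test_window_and_first_nt_read_from_genome(self, genome):
        report = call_tis({("+", 100): 12}, genome)
        c = report.candidates[0]
        assert len(c.window) == 62
        assert c.first_nt == genome.base(100, "+")
        assert c.dimer == genome.fetch(100, 101, "+")

    def test_region_at_content_on_crafted_window(self):
        # regions: I = 25 C's (AT 0), II = 12 A's (AT 1), III = G + 24 T (0.96)
        seq = "C" * 25 + "A" * 12 + "G" + "T" * 24 + "C" * 40
        g = Genome("w", seq)
        c = call_tis({("+", 38): 10}, g).candidates[0]
        assert c.at_content == (0.0, 1.0, pytest.approx(0.96))
        assert c.first_nt == "G" and c.dimer == "GT"

    def test_dimer_table_totals_match_passing(self, genome):
        counts = {("+", p): 10 + p % 3 for p in range(200, 260, 7)}
        counts[("+", 900)] = 3  # low support: excluded from the table
        report = call_tis(counts, genome)
        assert sum(report.dimer_table.values()) == len(report.passing())

    def test_labels_follow_heavy_strand_convention(self, genome):
        report = call_tis({("-", 700): 15, ("+", 300): 15}, genome)
        sa = StrandAssignment(heavy="-")
        labels = {c.label(sa) for c in report.candidates}
        assert labels == {"TIS_700-", "TIS_300"}

    def test_merge_radius_clusters_neighbours(self, genome):
        counts = {("+", 500): 20, ("+", 501): 5, ("+", 600): 7}
        report = call_tis(counts, genome, min_support=10, merge_radius=2)
        positions = {c.plus1: c.support for c in report.candidates}
        assert positions == {500: 25, 600: 7}


class TestSpliceFilter:
    @staticmethod
    def _gene(strand, exons):
        return GeneAnnotation("g", "protein_coding", strand, exons)

    def test_intron_boundary_gains_splice_flag(self, genome):
        gene = self._gene("+", [(100, 399), (700, 999)])  # intron 400..699
        report = call_tis({("+", 400): 20}, genome)
        report = filter_splicing_intermediates(report, [gene])
        assert "SPLICE_INTERMEDIATE" in report.candidates[0].flags

    def test_minus_strand_boundary_is_intron_end(self, genome):
        gene = self._gene("-", [(100, 399), (700, 999)])
        report = call_tis({("-", 699): 20}, genome)
        report = filter_splicing_intermediates(report, [gene])
        assert "SPLICE_INTERMEDIATE" in report.candidates[0].flags

    def test_gt_away_from_introns_is_suspect(self):
        seq = "C" * 37 + "GT" + "C" * 100
        g = Genome("w", seq)
        report = call_tis({("+", 38): 20}, g)
        report = filter_splicing_intermediates(report, [])
        assert "GT_SUSPECT" in report.candidates[0].flags

    def test_ga_dimer_gets_no_flag(self):
        seq = "C" * 37 + "GA" + "C" * 100
        g = Genome("w", seq)
        report = call_tis({("+", 38): 20}, g)
        report = filter_splicing_intermediates(report, [])
        assert report.candidates[0].flags == set()


def _site(start, end, strand="+"):
    return PolyALikeSite(start, end, strand, "A" * (end - start + 1), 1.0)


class TestAssignTts:
    def test_nearest_site_wins_then_smaller_coordinate(self):
        sites = [_site(100, 110), _site(130, 140), _site(118, 128)]
        t = Transcript("t", "+", [(10, 115)])  # 3' end at 115
        calls, unassigned = assign_tts([t], sites, tol=10)
        supported = [c for c in calls if c.support]
        assert len(supported) == 1
        assert supported[0].site.start == 118  # distance 3 beats distance 5
        assert not unassigned

    def test_end_inside_site_is_distance_zero(self):
        sites = [_site(100, 120)]
        t = Transcript("t", "+", [(10, 110)])
        calls, _ = assign_tts([t], sites, tol=0)
        assert calls[0].support == 1

    def test_far_end_is_unassigned(self):
        sites = [_site(100, 110)]
        t = Transcript("t", "+", [(10, 400)])
        calls, unassigned = assign_tts([t], sites, tol=10)
        assert calls[0].support == 0 and unassigned == [t]

    def test_support_plus_unassigned_conserves_transcripts(self, planted,
                                                           transcripts):
        full = [t for t in transcripts if t.true_class == "FULL_LENGTH"]
        sites = scan_polyA_like(planted.genome)
        calls, unassigned = assign_tts(full, sites)
        assert sum(c.support for c in calls) + len(unassigned) == len(full)

    def test_planted_terminator_support_matches_truth(self, planted,
                                                      transcripts):
        term = planted.terminators[0]  # "+" strand, first in transcription
        truth_n = sum(
            1 for t in transcripts
            if t.terminator is term and t.strand == "+"
        )
        sites = scan_polyA_like(planted.genome)
        calls, _ = assign_tts(
            [t for t in transcripts if t.strand == "+"], sites
        )
        lo, hi = term.ref_interval
        got = sum(
            c.support for c in calls
            if c.strand == "+" and not (c.site.end < lo or hi < c.site.start)
        )
        assert got == truth_n

    def test_termination_probability_recovered(self, planted, transcripts):
        """support/(support+readthrough) estimates the planted 0.8."""
        term = planted.terminators[0]
        sites = scan_polyA_like(planted.genome)
        calls, _ = assign_tts(
            [t for t in transcripts if t.strand == "+"], sites
        )
        lo, hi = term.ref_interval
        call = next(
            c for c in calls
            if c.strand == "+" and not (c.site.end < lo or hi < c.site.start)
        )
        n = call.support + call.readthrough
        p_hat = call.termination_frequency
        se = (0.8 * 0.2 / n) ** 0.5
        assert abs(p_hat - term.term_prob) < 4 * se + 0.02


class TestReadthrough:
    def test_internal_site_counting(self):
        sites = [_site(100, 110), _site(300, 310), _site(500, 510),
                 _site(700, 710)]
        short = Transcript("s", "+", [(120, 290)])     # spans 0 sites
        long = Transcript("l", "+", [(50, 600)])       # strictly spans 3
        summary = readthrough_stats([short, long], sites)
        assert summary.per_transcript == [0, 3]
        assert summary.histogram == {0: 1, 3: 1}

    def test_boundary_site_not_counted_as_internal(self):
        sites = [_site(500, 510)]
        t = Transcript("t", "+", [(100, 510)])  # terminates at the site
        assert readthrough_stats([t], sites).per_transcript == [0]

    def test_short_transcripts_span_at_most_one_site(self, planted,
                                                     transcripts):
        """Transcripts <= 300 nt read through at most one polyA-like site."""
        sites = scan_polyA_like(planted.genome)
        short = [t for t in transcripts if t.aligned_length <= 300]
        if short:
            summary = readthrough_stats(short, sites)
            assert max(summary.per_transcript) <= 1
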