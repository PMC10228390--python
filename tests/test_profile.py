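"""Depth profiles, unit calling, junction extraction, editing detection."""

import numpy as np
import pytest

from cptrx.core import Genome, Transcript
from cptrx.profile import (
    call_units,
    depth_profile,
    detect_editing,
    extract_junctions,
    pileup_from_transcripts,
    summarize,
)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(31)
    return Genome("toy", "".join(rng.choice(list("ACGT"), size=1000)))


class TestDepthProfile:
    def test_single_transcript(self, genome):
        d = depth_profile([Transcript("t", "+", [(1, 10)])], "+", genome)
        assert d[:10].tolist() == [1] * 10
        assert d[10:].sum() == 0

    def test_overlap_adds(self, genome):
        ts = [
            Transcript("a", "+", [(1, 20)]),
            Transcript("b", "+", [(11, 30)]),
        ]
        d = depth_profile(ts, "+", genome)
        assert d[10:20].tolist() == [2] * 10

    def test_spliced_gap_uncovered(self, genome):
        t = Transcript("t", "+", [(1, 10), (21, 30)])
        d = depth_profile([t], "+", genome)
        assert d[10:20].sum() == 0 and d[:10].all() and d[20:30].all()

    def test_other_strand_ignored(self, genome):
        d = depth_profile([Transcript("t", "-", [(1, 10)])], "+", genome)
        assert d.sum() == 0

    def test_matches_interval_stabbing_oracle(self, genome):
        """Brute-force stabbing count over random interval sets."""
        rng = np.random.default_rng(77)
        n = genome.length
        for _ in range(100):
            m = int(rng.integers(1, 30))
            ts = []
            for i in range(m):
                s = int(rng.integers(1, n))
                e = int(rng.integers(s, min(n, s + 200) + 1))
                ts.append(Transcript(f"t{i}", "+", [(s, e)]))
            d = depth_profile(ts, "+", genome)
            probe = rng.integers(1, n + 1, size=25)
            for p in probe:
                brute = sum(
                    1 for t in ts if t.blocks[0][0] <= p <= t.blocks[0][1]
                )
                assert d[p - 1] == brute


class TestCallUnits:
    def test_flat_zero_has_no_units(self):
        assert call_units(np.zeros(5000), "+", min_depth=1) == []

    def test_step_profile_yields_one_unit(self):
        depth = np.zeros(5000)
        depth[1000:2000] = 100
        units = call_units(depth, "+", min_depth=50)
        assert len(units) == 1
        u = units[0]
        assert (u.start, u.end, u.mean_depth) == (1001, 2000, 100.0)

    def test_gap_bridging_and_separation(self):
        depth = np.zeros(10_000)
        depth[1000:2000] = 100
        depth[2030:3000] = 100   # 30-gap: bridged at max_gap 50
        depth[5000:6000] = 100   # 2000-gap: separate unit
        units = call_units(depth, "+", min_depth=50, max_gap=50)
        assert [(u.start, u.end) for u in units] == [
            (1001, 3000), (5001, 6000),
        ]

    def test_short_runs_discarded(self):
        depth = np.zeros(5000)
        depth[100:200] = 100
        assert call_units(depth, "+", min_depth=50, min_len=300) == []

    def test_units_disjoint_and_above_threshold(self):
        rng = np.random.default_rng(13)
        depth = rng.integers(0, 40, size=20_000).astype(float)
        depth[3000:6000] += 100
        units = call_units(depth, "+", min_depth=60)
        for u in units:
            assert u.mean_depth >= 60
        spans = sorted((u.start, u.end) for u in units)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 > e1

    def test_planted_units_recovered(self, planted, transcripts):
        """Transcribed regions on "+" reappear as units at truth bounds."""
        units = call_units(
            depth_profile(transcripts, "+", planted.genome), "+",
            max_gap=50,  # default threshold: half the strand mean depth
        )
        starts = sorted(u.start for u in units)
        # the two "+" promoters anchor the unit 5' boundaries exactly
        assert starts == [2000, 12000]


class TestSummarize:
    def test_half_coverage(self, genome):
        s = summarize([Transcript("t", "+", [(1, 500)])], genome)
        assert s["covered_fraction"]["+"] == 0.5
        assert s["covered_fraction"]["-"] == 0.0

    def test_median_aligned_length(self, genome):
        ts = [
            Transcript("a", "+", [(1, 100)]),
            Transcript("b", "+", [(1, 200)]),
            Transcript("c", "+", [(1, 300)]),
        ]
        assert summarize(ts, genome)["median_aligned_length"] == 200

    def test_empty_input_warns_and_zeroes(self, genome, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="cptrx"):
            s = summarize([], genome)
        assert s["n_transcripts"] == 0
        assert s["median_aligned_length"] == 0.0
        assert caplog.records


class TestJunctions:
    def test_canonical_gt_ac(self):
        seq = "C" * 10 + "GT" + "C" * 86 + "AC" + "C" * 100
        g = Genome("j", seq)
        t = Transcript("t", "+", [(1, 10), (101, 150)])  # intron 11..100
        (j,) = extract_junctions([t], g)
        assert (j.donor, j.acceptor) == (11, 100)
        assert j.boundary_dimers == ("GT", "AC") and j.canonical

    def test_noncanonical_tt_gt(self):
        seq = "C" * 10 + "TT" + "C" * 86 + "GT" + "C" * 100
        g = Genome("j", seq)
        t = Transcript("t", "+", [(1, 10), (101, 150)])
        (j,) = extract_junctions([t], g)
        assert j.boundary_dimers == ("TT", "GT") and not j.canonical

    def test_minus_strand_dimers_are_revcomp(self):
        # "-" intron 11..100: donor dimer at 99..100 read on "-"
        seq = "C" * 10 + "GT" + "C" * 86 + "AC" + "C" * 100
        g = Genome("j", seq)
        t = Transcript("t", "-", [(1, 10), (101, 150)])
        (j,) = extract_junctions([t], g)
        assert (j.donor, j.acceptor) == (100, 11)
        assert j.boundary_dimers == ("GT", "AC")  # revcomp of AC / GT

    def test_support_counts_shared_junctions(self, genome):
        ts = [
            Transcript("a", "+", [(1, 10), (101, 150)]),
            Transcript("b", "+", [(5, 10), (101, 170)]),
            Transcript("c", "+", [(1, 10), (121, 150)]),
        ]
        js = extract_junctions(ts, genome)
        by = {(j.donor, j.acceptor): j.support for j in js}
        assert by[(11, 100)] == 2 and by[(11, 120)] == 1
        assert sum(by.values()) == 3

    def test_planted_introns_recovered_with_dimers(self, planted,
                                                   transcripts):
        js = extract_junctions(transcripts, planted.genome)
        got = {
            (j.strand, j.donor, j.acceptor): (j.boundary_dimers, j.canonical)
            for j in js
        }
        plus, minus = planted.introns
        assert got[("+", plus.start, plus.end)] == (("GT", "AC"), True)
        assert got[("-", minus.end, minus.start)] == (("TT", "GT"), False)


class TestEditing:
    def test_simple_arithmetic_site(self):
        g = Genome("e", "C" * 50)
        pile = {("+", 10): {"T": 8, "C": 2}}
        sites, snp = detect_editing(pile, g, min_depth=5, min_alt_frac=0.5)
        assert len(sites) == 1 and not snp
        assert sites[0].alt_fraction == pytest.approx(0.8)
        assert sites[0].depth == 10

    def test_non_c_reference_is_snp_like(self):
        g = Genome("e", "A" * 50)
        pile = {("+", 10): {"T": 8, "A": 2}}
        sites, snp = detect_editing(pile, g, min_depth=5, min_alt_frac=0.5)
        assert not sites and len(snp) == 1
        assert snp[0].alt_base == "T"

    def test_depth_threshold(self):
        g = Genome("e", "C" * 50)
        pile = {("+", 10): {"T": 4}}
        sites, snp = detect_editing(pile, g, min_depth=5, min_alt_frac=0.2)
        assert not sites and not snp

    def test_planted_sites_recovered_with_no_false_calls(self, planted,
                                                         transcripts):
        pile = pileup_from_transcripts(transcripts)
        sites, _ = detect_editing(pile, planted.genome)
        got = {(s.strand, s.position) for s in sites}
        want = {(e.strand, e.position) for e in planted.editing_sites}
        assert got == want
        for s in sites:
            eff = next(
                e.efficiency for e in planted.editing_sites
                if (e.strand, e.position) == (s.strand, s.position)
            )
            se = (eff * (1 - eff) / s.depth) ** 0.5
            assert abs(s.alt_fraction - eff) < 4 * se + 0.01
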