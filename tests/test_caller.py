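"""LDPR caller: filtering, point scoring, KDE, merging, and properties."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from ldprscan.alignments import LocalAlignment
from ldprscan.caller import (
    CallParams,
    call_ldprs,
    filter_alignments,
    merge_and_trim,
    score_points,
    smooth_and_flag,
    smooth_density,
)


def _aln(a0, a1, b0, b1, chrom="chr1", strand="+"):
    return LocalAlignment(chrom, a0, a1, b0, b1, strand)


def _random_alignments(rng, n, chrom_length=1_000_000, chrom="chr1"):
    out = []
    for _ in range(n):
        a0 = int(rng.integers(0, chrom_length - 20_000))
        alen = int(rng.integers(1_000, 12_000))
        gap = int(rng.integers(0, 400_000))
        b0 = min(a0 + alen + gap, chrom_length - alen - 1)
        blen = int(rng.integers(1_000, 12_000))
        out.append(_aln(a0, a0 + alen, b0, min(b0 + blen, chrom_length)))
    return out


class TestFilter:
    def test_length_exactly_at_cutoff_removed(self):
        # "exceeding 5 Kbp" is strict: a 5,000 bp alignment does not pass
        kept = filter_alignments([_aln(0, 5_000, 10_000, 15_000)])
        assert kept == []
        kept = filter_alignments([_aln(0, 5_001, 10_000, 15_001)])
        assert len(kept) == 1

    def test_distant_mates_removed(self):
        assert filter_alignments([_aln(0, 6_000, 300_000, 306_000)]) == []

    def test_cross_chromosome_rejected(self):
        aln = LocalAlignment("chr1", 0, 6_000, 0, 6_000, "+", b_chrom="chr2")
        assert filter_alignments([aln]) == []

    def test_against_brute_force_predicates(self):
        rng = np.random.default_rng(0)
        alns = _random_alignments(rng, 200)
        kept = filter_alignments(alns)
        expected = [
            a
            for a in alns
            if max(a.a_span, a.b_span) > 5_000
            and max(a.a_end, a.b_end) - min(a.a_start, a.b_start) <= 200_000
        ]
        assert kept == expected

    def test_gap_mode(self):
        # intervals 150 Kbp apart edge-to-edge but spanning > 200 Kbp overall
        a = _aln(0, 60_000, 210_000, 270_000)
        assert filter_alignments([a]) == []
        assert filter_alignments([a], mate_sep_mode="gap") == [a]


class TestScorePoints:
    def test_no_alignments_all_zero(self):
        raw = score_points([], 50_000)
        assert raw.shape == (50,) and not raw.any()

    def test_single_record_arithmetic(self):
        raw = score_points([_aln(10_000, 16_000, 30_000, 36_000)], 50_000)
        for i, v in enumerate(raw):
            pos = i * 1_000
            expected = 6_000.0 if 10_000 <= pos < 16_000 or 30_000 <= pos < 36_000 else 0.0
            assert v == expected

    def test_both_mates_covering_counts_twice(self):
        a = _aln(10_000, 20_000, 15_000, 25_000)
        raw = score_points([a], 30_000)
        assert raw[17] == 20_000.0  # point 17 Kbp covered by both intervals
        raw_once = score_points([a], 30_000, count_once=True)
        assert raw_once[17] == 10_000.0

    def test_against_brute_force_loop(self):
        rng = np.random.default_rng(1)
        alns = _random_alignments(rng, 50, chrom_length=300_000)
        spacing = 1_000
        raw = score_points(alns, 300_000, spacing)
        for i in range(raw.size):
            pos = i * spacing
            expected = 0.0
            for a in alns:
                if a.a_start <= pos < a.a_end:
                    expected += a.a_span
                if a.b_start <= pos < a.b_end:
                    expected += a.b_span
            assert raw[i] == expected


class TestKde:
    def test_integrates_to_one(self):
        # single weighted point well inside the window: Riemann sum ~ 1
        w = np.zeros(2_000)
        w[1_000] = 5_000.0
        pos = np.arange(2_000) * 1_000
        dens = smooth_density(pos, w, 10_000)
        assert math.isclose(dens.sum() * 1_000, 1.0, abs_tol=1e-3)

    def test_matches_quadratic_double_loop(self):
        rng = np.random.default_rng(2)
        n = 500
        pos = np.arange(n) * 1_000
        w = rng.random(n) * 10_000
        w[rng.random(n) < 0.5] = 0.0
        h = 10_000.0
        dens = smooth_density(pos, w, h)
        total = w.sum()
        for i in range(0, n, 7):
            expected = sum(
                w[j] * math.exp(-0.5 * ((pos[i] - pos[j]) / h) ** 2) / math.sqrt(2 * math.pi)
                for j in range(n)
            ) / (h * total)
            assert abs(dens[i] - expected) <= 1e-9 * max(expected, 1e-12)

    def test_zero_weight_window_gives_zeros(self):
        dens = smooth_density(np.arange(100) * 1_000, np.zeros(100), 10_000)
        assert not dens.any()


class TestSmoothAndFlag:
    PARAMS = CallParams(window=200_000, overlap=20_000, threshold_multiplier=5.0)

    def test_all_zero_no_runs(self):
        _, runs = smooth_and_flag(np.zeros(200), 200_000, self.PARAMS)
        assert runs == []

    def test_single_point_single_run(self):
        raw = np.zeros(200)
        raw[100] = 10_000.0
        _, runs = smooth_and_flag(raw, 200_000, self.PARAMS)
        assert len(runs) == 1
        s, e = runs[0]
        assert s <= 100_000 < e

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            smooth_and_flag(np.zeros(10), 10_000, replace(self.PARAMS, threshold_multiplier=0.0))


class TestMergeAndTrim:
    def test_overlapping_runs_union(self):
        cov = [_aln(9_000, 20_000, 40_000, 61_000)]
        out = merge_and_trim([(10_000, 40_000), (35_000, 60_000)], cov)
        assert out == [(10_000, 60_000)]

    def test_trim_to_coverage(self):
        cov = [_aln(12_000, 20_000, 300_000, 308_000)]
        out = merge_and_trim([(0, 50_000)], cov)
        assert out == [(12_000, 20_000)]

    def test_uncovered_run_dropped(self):
        cov = [_aln(500_000, 520_000, 600_000, 620_000)]
        assert merge_and_trim([(0, 50_000)], cov) == []


class TestCallLdprs:
    def test_empty_input_empty_output(self):
        assert call_ldprs([], {"chr1": 500_000}) == []

    def test_single_tandem_pair_single_ldpr(self):
        # one planted 6 Kbp tandem pair -> one LDPR spanning both copies
        aln = _aln(100_000, 106_000, 106_000, 112_000)
        params = CallParams(window=500_000, threshold_multiplier=5.0)
        ldprs = call_ldprs([aln], {"chr1": 500_000}, params)
        assert len(ldprs) == 1
        r = ldprs[0]
        assert r.chrom == "chr1"
        assert r.start == 100_000 and r.end == 112_000

    def test_planted_recovery(self, seed7):
        """Full pipeline on the reference genome: every planted array is
        recovered with Jaccard >= 0.8 and at most one false positive."""
        def jaccard(x, y):
            inter = max(0, min(x[1], y[1]) - max(x[0], y[0]))
            union = (x[1] - x[0]) + (y[1] - y[0]) - inter
            return inter / union

        ldprs = seed7.ldprs
        for chrom, s, e in seed7.sim.truth.planted_ldprs:
            best = max(
                (jaccard((s, e), (r.start, r.end)) for r in ldprs if r.chrom == chrom),
                default=0.0,
            )
            assert best >= 0.8, (chrom, s, e, best)
        false_pos = sum(
            1
            for r in ldprs
            if not any(
                r.chrom == chrom and jaccard((s, e), (r.start, r.end)) >= 0.8
                for chrom, s, e in seed7.sim.truth.planted_ldprs
            )
        )
        assert false_pos <= 1


class TestProperties:
    def test_density_scale_invariance(self):
        rng = np.random.default_rng(3)
        pos = np.arange(300) * 1_000
        w = rng.random(300)
        d1 = smooth_density(pos, w, 10_000)
        d2 = smooth_density(pos, w * 37.5, 10_000)
        np.testing.assert_allclose(d1, d2, rtol=1e-12)

    def test_translation_equivariance(self):
        delta = 40_000  # a multiple of the spacing
        alns = [_aln(50_000, 57_000, 60_000, 67_000)]
        shifted = [_aln(a.a_start + delta, a.a_end + delta, a.b_start + delta, a.b_end + delta)
                   for a in alns]
        params = CallParams(window=400_000, threshold_multiplier=5.0)
        r1 = call_ldprs(alns, {"chr1": 400_000 - delta}, params)
        r2 = call_ldprs(shifted, {"chr1": 400_000}, params)
        # same window for both (single-window chromosomes), so calls shift
        assert [(r.start + delta, r.end + delta) for r in r1] == [(r.start, r.end) for r in r2]

    def test_order_independence(self, seed7):
        params = seed7.params
        rng = np.random.default_rng(4)
        shuffled = list(seed7.alignments)
        rng.shuffle(shuffled)
        assert call_ldprs(shuffled, seed7.chrom_lengths, params) == seed7.ldprs

    def test_threshold_monotonicity(self, seed7):
        """Raising the threshold shrinks the flagged point set."""
        from ldprscan.caller import filter_alignments as _filter

        chrom = "chr1"
        filtered = [a for a in _filter(seed7.alignments) if a.chrom == chrom]
        raw = score_points(filtered, seed7.chrom_lengths[chrom])
        lo = replace(seed7.params, threshold_multiplier=2.0)
        hi = replace(seed7.params, threshold_multiplier=8.0)
        d, runs_lo = smooth_and_flag(raw, seed7.chrom_lengths[chrom], lo)
        _, runs_hi = smooth_and_flag(raw, seed7.chrom_lengths[chrom], hi)

        def points(runs):
            return {p for s, e in runs for p in range(s, e, 1_000)}

        assert points(runs_hi) <= points(runs_lo)
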