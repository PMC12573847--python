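"""Calling long-duplication-prone regions (LDPRs) from local self-alignments.

The method scores *interrogation points* on a fixed 1 Kbp grid: the raw score
of a point is the summed span of every filtered alignment interval covering
it.  A Gaussian kernel density (bandwidth 10 Kbp), weighted by the raw scores
and normalised by the window's total score, turns the raw coverage into a
comparable per-window density; runs of points whose density surpasses a
threshold are flagged, merged across window overlaps, and trimmed so that
every called region begins and ends in repeated sequence.

The alignment filter retains the Kbp-scale, *local* duplication signal: only
alignments longer than 5 Kbp whose two intervals fall fully within 200 Kbp of
one another contribute.  Single dispersed repeats (e.g. the terminal repeats
of one LTR retrotransposon) are too short to pass; tandem arrays of Kbp-scale
units produce the long unit-shifted self-hits the filter is designed around.

The density threshold is a free parameter of the method expressed as a
multiple of the uniform density ``1/window``; :func:`calibrate_threshold`
chooses it by maximising base-pair F1 against a truth interval set on
simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .alignments import LocalAlignment, window_partition

__all__ = [
    "CallParams",
    "LDPR",
    "filter_alignments",
    "score_points",
    "smooth_density",
    "smooth_and_flag",
    "merge_and_trim",
    "call_ldprs",
    "calibrate_threshold",
]


@dataclass(frozen=True)
class CallParams:
    """Tunable parameters of the LDPR caller (lengths in bp)."""

    min_len: int = 5_000
    max_mate_sep: int = 200_000
    spacing: int = 1_000
    bandwidth: int = 10_000
    window: int = 2_000_000
    overlap: int = 200_000
    threshold_multiplier: float = 5.0
    mate_sep_mode: str = "span"   # "span": both intervals inside one 200 Kbp span
    count_once: bool = False      # count an alignment once when both mates cover a point
    drop_reverse: bool = False

    @property
    def threshold(self) -> float:
        """Absolute density threshold: multiplier x uniform density 1/window."""
        return self.threshold_multiplier / self.window


@dataclass(frozen=True)
class LDPR:
    """A called duplication-prone interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    peak_density: float
    n_support_alignments: int

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Stage 1: alignment filtering
# ---------------------------------------------------------------------------

def filter_alignments(
    alignments: Sequence[LocalAlignment],
    min_len: int = 5_000,
    max_mate_sep: int = 200_000,
    mate_sep_mode: str = "span",
    drop_reverse: bool = False,
) -> list[LocalAlignment]:
    """Keep Kbp-scale local alignments.

    Length must strictly exceed ``min_len``.  In the default ``span`` mode
    both intervals must fit inside a single ``max_mate_sep`` span; the
    alternative ``gap`` mode bounds only the gap between them.  Cross-
    chromosome records are dropped (the caller's model is intra-chromosomal).
    """
    if mate_sep_mode not in ("span", "gap"):
        raise ValueError(f"unknown mate_sep_mode {mate_sep_mode!r}")
    out = []
    for aln in alignments:
        if not aln.intra:
            continue
        if drop_reverse and aln.strand == "-":
            continue
        if aln.length <= min_len:
            continue
        if mate_sep_mode == "span":
            sep_ok = max(aln.a_end, aln.b_end) - min(aln.a_start, aln.b_start) <= max_mate_sep
        else:
            sep_ok = aln.b_start - aln.a_end <= max_mate_sep
        if sep_ok:
            out.append(aln)
    return out


# ---------------------------------------------------------------------------
# Stage 2: interrogation-point scoring
# ---------------------------------------------------------------------------

def score_points(
    filtered: Sequence[LocalAlignment],
    chrom_length: int,
    spacing: int = 1_000,
    count_once: bool = False,
) -> np.ndarray:
    """Raw score per interrogation point (grid of multiples of ``spacing``).

    An alignment contributes the span of whichever of its intervals covers
    the point; if both intervals cover it, it contributes twice by default
    (once with the larger span when ``count_once``).
    """
    n_points = (chrom_length + spacing - 1) // spacing
    diff = np.zeros(n_points + 1, dtype=np.float64)

    def add(lo: int, hi: int, value: float) -> None:
        i0 = (lo + spacing - 1) // spacing
        i1 = (hi + spacing - 1) // spacing  # points strictly below hi
        i0, i1 = min(i0, n_points), min(i1, n_points)
        if i0 < i1:
            diff[i0] += value
            diff[i1] -= value

    for aln in filtered:
        if count_once:
            inter_lo = max(aln.a_start, aln.b_start)
            inter_hi = min(aln.a_end, aln.b_end)
            add(aln.a_start, aln.a_end, aln.a_span)
            add(aln.b_start, aln.b_end, aln.b_span)
            if inter_lo < inter_hi:
                add(inter_lo, inter_hi, -min(aln.a_span, aln.b_span))
        else:
            add(aln.a_start, aln.a_end, aln.a_span)
            add(aln.b_start, aln.b_end, aln.b_span)
    return np.cumsum(diff[:-1])


# ---------------------------------------------------------------------------
# Stage 3: weighted KDE and thresholding
# ---------------------------------------------------------------------------

_SQRT2PI = np.sqrt(2.0 * np.pi)


def smooth_density(
    positions: np.ndarray, weights: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Score-weighted Gaussian KDE evaluated at the interrogation points.

    ``density(p) = sum_q w_q K((p - q)/h) / (h * sum_q w_q)`` with the
    standard normal kernel K; the per-window weight normalisation makes
    densities comparable between windows.  Zero total weight yields zeros.
    """
    w = np.asarray(weights, dtype=np.float64)
    total = w.sum()
    if total <= 0:
        return np.zeros_like(w)
    p = np.asarray(positions, dtype=np.float64)
    z = (p[:, None] - p[None, :]) / bandwidth
    kern = np.exp(-0.5 * z * z) / _SQRT2PI
    return (kern @ w) / (bandwidth * total)


def smooth_and_flag(
    raw_scores: np.ndarray,
    chrom_length: int,
    params: CallParams,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Chromosome-wide normalised density and flagged runs.

    The KDE is evaluated window by window (windows from
    :func:`window_partition`, normalised within each window); each point
    takes its density from the single window whose non-overlap core contains
    it, the overlap halves serving as smoothing context.  Runs of consecutive
    points with density strictly above the threshold are returned with extent
    ``[first_pos, last_pos + spacing)``.
    """
    threshold = params.threshold
    if threshold <= 0:
        raise ValueError("density threshold must be positive")
    spacing = params.spacing
    n_points = raw_scores.size
    positions = np.arange(n_points, dtype=np.int64) * spacing
    density = np.zeros(n_points, dtype=np.float64)

    windows = window_partition(chrom_length, params.window, params.overlap)
    # core boundaries: midpoints of consecutive-window overlaps, on the grid
    cores = []
    prev_cut = 0
    for wi, (ws, we) in enumerate(windows):
        if wi + 1 < len(windows):
            ns = windows[wi + 1][0]
            cut = ((ns + we) // 2) // spacing * spacing
        else:
            cut = chrom_length
        cores.append((prev_cut, cut))
        prev_cut = cut

    for (ws, we), (cs, ce) in zip(windows, cores):
        sel = (positions >= ws) & (positions < we)
        if not np.any(sel):
            continue
        dens_w = smooth_density(positions[sel], raw_scores[sel], params.bandwidth)
        core_sel = (positions[sel] >= cs) & (positions[sel] < ce)
        idx = np.flatnonzero(sel)[core_sel]
        density[idx] = dens_w[core_sel]

    flagged = density > threshold
    runs = []
    in_run = False
    start_i = 0
    for i, f in enumerate(flagged):
        if f and not in_run:
            in_run, start_i = True, i
        elif not f and in_run:
            in_run = False
            runs.append((start_i * spacing, (i - 1) * spacing + spacing))
    if in_run:
        runs.append((start_i * spacing, (n_points - 1) * spacing + spacing))
    return density, runs


# ---------------------------------------------------------------------------
# Stage 4: merge and trim
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly overlapping/adjacent intervals."""
    if not intervals:
        return []
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def merge_and_trim(
    runs: list[tuple[int, int]],
    filtered: Sequence[LocalAlignment],
    min_length: int = 0,
) -> list[tuple[int, int]]:
    """Union overlapping runs, then trim each to repeated-sequence coverage.

    The trimmed interval starts at the first base covered by any filtered
    alignment interval and ends after the last, so every region begins and
    ends in repeated sequence; regions containing no covered base are
    dropped, as are regions shorter than ``min_length`` after trimming.
    """
    merged = _merge_intervals(runs)
    coverage = _merge_intervals(
        [(a.a_start, a.a_end) for a in filtered] + [(a.b_start, a.b_end) for a in filtered]
    )
    if not coverage:
        return []
    cov_starts = np.array([c[0] for c in coverage])
    cov_ends = np.array([c[1] for c in coverage])
    out = []
    for s, e in merged:
        # coverage intervals intersecting [s, e)
        i0 = int(np.searchsorted(cov_ends, s, side="right"))
        i1 = int(np.searchsorted(cov_starts, e, side="left"))
        if i0 >= i1:
            continue
        t_start = max(s, int(cov_starts[i0]))
        t_end = min(e, int(cov_ends[i1 - 1]))
        if t_end - t_start >= max(min_length, 1):
            out.append((t_start, t_end))
    return out


# ---------------------------------------------------------------------------
# Composite
# ---------------------------------------------------------------------------

def call_ldprs(
    alignments: Sequence[LocalAlignment],
    chrom_lengths: dict[str, int],
    params: CallParams | None = None,
) -> list[LDPR]:
    """Full pipeline: filter, score, smooth, flag, merge and trim."""
    params = params or CallParams()
    filtered_all = filter_alignments(
        alignments,
        min_len=params.min_len,
        max_mate_sep=params.max_mate_sep,
        mate_sep_mode=params.mate_sep_mode,
        drop_reverse=params.drop_reverse,
    )
    results: list[LDPR] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        filtered = [a for a in filtered_all if a.chrom == chrom]
        raw = score_points(filtered, length, params.spacing, params.count_once)
        density, runs = smooth_and_flag(raw, length, params)
        intervals = merge_and_trim(runs, filtered, min_length=2 * params.spacing)
        for s, e in intervals:
            i0 = (s + params.spacing - 1) // params.spacing
            i1 = (e + params.spacing - 1) // params.spacing
            peak = float(density[i0:i1].max()) if i1 > i0 else 0.0
            support = sum(
                1
                for a in filtered
                if (a.a_start < e and a.a_end > s) or (a.b_start < e and a.b_end > s)
            )
            results.append(LDPR(chrom, s, e, peak, support))
    return results


def _bp_f1(called: list[LDPR], truth: list[tuple[str, int, int]]) -> float:
    """Base-pair-level F1 of called intervals against truth intervals."""
    by_chrom_called: dict[str, list[tuple[int, int]]] = {}
    for r in called:
        by_chrom_called.setdefault(r.chrom, []).append((r.start, r.end))
    by_chrom_truth: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in truth:
        by_chrom_truth.setdefault(c, []).append((s, e))
    tp = fp = fn = 0
    for chrom in set(by_chrom_called) | set(by_chrom_truth):
        cm = _merge_intervals(by_chrom_called.get(chrom, []))
        tm = _merge_intervals(by_chrom_truth.get(chrom, []))
        called_bp = sum(e - s for s, e in cm)
        truth_bp = sum(e - s for s, e in tm)
        inter = 0
        for s, e in cm:
            for ts, te in tm:
                inter += max(0, min(e, te) - max(s, ts))
        tp += inter
        fp += called_bp - inter
        fn += truth_bp - inter
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def calibrate_threshold(
    alignments: Sequence[LocalAlignment],
    chrom_lengths: dict[str, int],
    truth: list[tuple[str, int, int]],
    params: CallParams | None = None,
    multipliers: Sequence[float] = (1, 1.5, 2, 3, 4, 5, 7, 10, 15, 20, 30, 50, 75, 100),
) -> tuple[float, float]:
    """Pick the threshold multiplier maximising base-pair F1 against truth.

    Returns ``(best_multiplier, best_f1)``; ties resolve to the largest
    (most conservative) multiplier.
    """
    params = params or CallParams()
    best = (0.0, -1.0)
    for m in multipliers:
        called = call_ldprs(alignments, chrom_lengths, replace(params, threshold_multiplier=m))
        f1 = _bp_f1(called, truth)
        if f1 >= best[1]:
            best = (float(m), f1)
    return best
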