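"""Local genome self-alignments: container, PAF/lastz I/O, windowing, and a
desk-scale exact-seed self-aligner.

A *local self-alignment* is an off-diagonal hit of a chromosome against
itself: two intervals on the same chromosome whose sequences match locally.
Duplicated segments (tandem arrays, dispersed copies, LTR retrotransposon
termini) show up as such hits; the density caller consumes them.

Coordinates are 0-based half-open throughout.  Records are canonicalised so
that the interval starting first is the ``a`` interval, and mirror duplicates
(a<->b swapped, as produced by symmetric self-alignment) are collapsed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LocalAlignment",
    "read_alignments",
    "write_paf",
    "self_align",
    "window_partition",
]

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.encode()[::-1].translate(_COMPLEMENT).decode()


@dataclass(frozen=True, order=True)
class LocalAlignment:
    """One local alignment between two intervals of the same genome.

    ``b_chrom`` is only set for cross-chromosome records; those are kept for
    plotting but rejected by the LDPR caller, whose model is intra-chromosomal
    duplication density.
    """

    chrom: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str = "+"
    score: float = 0.0
    b_chrom: str | None = None

    def __post_init__(self) -> None:
        if not (self.a_start < self.a_end and self.b_start < self.b_end):
            raise ValueError(f"degenerate alignment interval: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def intra(self) -> bool:
        return self.b_chrom is None or self.b_chrom == self.chrom

    @property
    def a_span(self) -> int:
        return self.a_end - self.a_start

    @property
    def b_span(self) -> int:
        return self.b_end - self.b_start

    @property
    def length(self) -> int:
        """Span used by the length filter: the larger of the two intervals."""
        return max(self.a_span, self.b_span)

    @property
    def trivial(self) -> bool:
        """True for the end-to-end (or any identity) self-hit a == b."""
        return (
            self.intra
            and self.strand == "+"
            and self.a_start == self.b_start
            and self.a_end == self.b_end
        )

    def canonical(self) -> "LocalAlignment":
        """Order intervals so a starts no later than b (intra records only)."""
        if self.intra and (self.b_start, self.b_end) < (self.a_start, self.a_end):
            return dataclasses.replace(
                self,
                a_start=self.b_start,
                a_end=self.b_end,
                b_start=self.a_start,
                b_end=self.a_end,
            )
        return self


def _canonical_key(aln: LocalAlignment):
    return (
        aln.chrom,
        aln.b_chrom or aln.chrom,
        aln.a_start,
        aln.a_end,
        aln.b_start,
        aln.b_end,
        aln.strand,
    )


def canonicalize(alignments: Iterable[LocalAlignment]) -> list[LocalAlignment]:
    """Canonical interval order, trivial-diagonal removal, mirror collapse."""
    seen: dict[tuple, LocalAlignment] = {}
    for aln in alignments:
        aln = aln.canonical()
        if aln.trivial:
            continue
        seen.setdefault(_canonical_key(aln), aln)
    return sorted(seen.values(), key=_canonical_key)


# ---------------------------------------------------------------------------
# PAF / lastz-general I/O
# ---------------------------------------------------------------------------

def read_alignments(path, fmt: str = "paf", column_map: dict | None = None) -> list[LocalAlignment]:
    """Read local alignments from PAF or lastz ``--format=general`` output.

    Mirror records (the symmetric a<->b copy a self-aligner emits for every
    hit) collapse to a single canonical record, and the trivial full-length
    diagonal is dropped.
    """
    if fmt == "paf":
        return canonicalize(_read_paf(path))
    if fmt == "lastz_general":
        return canonicalize(_read_lastz_general(path, column_map))
    raise ValueError(f"unknown alignment format {fmt!r} (expected 'paf' or 'lastz_general')")


def _read_paf(path) -> Iterable[LocalAlignment]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: malformed PAF line ({len(parts)} fields)")
            try:
                qname = parts[0]
                qstart, qend = int(parts[2]), int(parts[3])
                strand = parts[4]
                tname = parts[5]
                tstart, tend = int(parts[7]), int(parts[8])
                nmatch = int(parts[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed PAF line: {exc}") from None
            yield LocalAlignment(
                chrom=qname,
                a_start=qstart,
                a_end=qend,
                b_start=tstart,
                b_end=tend,
                strand=strand,
                score=float(nmatch),
                b_chrom=None if tname == qname else tname,
            )


_LASTZ_DEFAULT_COLUMNS = {
    "name1": 0, "start1": 1, "end1": 2,
    "name2": 3, "strand2": 4, "start2": 5, "end2": 6,
    "score": 7,
}


def _read_lastz_general(path, column_map: dict | None) -> Iterable[LocalAlignment]:
    cols = dict(_LASTZ_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                name1 = parts[cols["name1"]]
                name2 = parts[cols["name2"]]
                # lastz general coordinates are 1-based, end-inclusive
                a_start = int(parts[cols["start1"]]) - 1
                a_end = int(parts[cols["end1"]])
                b_start = int(parts[cols["start2"]]) - 1
                b_end = int(parts[cols["end2"]])
                strand = parts[cols["strand2"]]
                score = float(parts[cols["score"]])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed lastz line: {exc}") from None
            yield LocalAlignment(
                chrom=name1,
                a_start=a_start,
                a_end=a_end,
                b_start=b_start,
                b_end=b_end,
                strand=strand,
                score=score,
                b_chrom=None if name2 == name1 else name2,
            )


def write_paf(alignments: Sequence[LocalAlignment], path, chrom_lengths: dict[str, int]) -> None:
    """Write alignments as minimal PAF (nmatch column carries the score)."""
    with open(path, "w") as fh:
        for aln in alignments:
            b_chrom = aln.b_chrom or aln.chrom
            fields = [
                aln.chrom,
                str(chrom_lengths.get(aln.chrom, 0)),
                str(aln.a_start),
                str(aln.a_end),
                aln.strand,
                b_chrom,
                str(chrom_lengths.get(b_chrom, 0)),
                str(aln.b_start),
                str(aln.b_end),
                str(int(round(aln.score))),
                str(aln.length),
                "255",
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def window_partition(chrom_length: int, window: int = 2_000_000, overlap: int = 200_000) -> list[tuple[int, int]]:
    """Tile ``[0, chrom_length)`` with overlapping windows.

    Consecutive windows share exactly ``overlap`` bp except possibly the last,
    which is right-anchored at the chromosome end.
    """
    if not 0 < overlap < window:
        raise ValueError(f"need 0 < overlap < window, got overlap={overlap}, window={window}")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if chrom_length <= window:
        return [(0, chrom_length)]
    step = window - overlap
    windows = []
    start = 0
    while start + window < chrom_length:
        windows.append((start, start + window))
        start += step
    windows.append((chrom_length - window, chrom_length))
    return windows


# ---------------------------------------------------------------------------
# Built-in self-aligner (exact k-mer seeds + ungapped x-drop extension)
# ---------------------------------------------------------------------------

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i
    _CODE[_c + 32] = _i  # lower case


def _kmer_ids(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, ids) of all unambiguous k-mers, 2-bit packed into int64."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    ids = windows @ powers
    bad = np.convolve((codes >= 4).astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
    pos = np.flatnonzero(~bad)
    return pos, ids[pos]


def _seed_pairs(pos_a, ids_a, pos_b=None, ids_b=None, max_per_kmer: int = 100):
    """Seed position pairs sharing a k-mer.

    Single-sequence mode yields i<j pairs; two-sequence mode yields (a, b)
    pairs.  K-mers occurring more than ``max_per_kmer`` times on one side are
    skipped (low-complexity guard).
    """
    pairs_a, pairs_b = [], []
    if pos_b is None:
        order = np.argsort(ids_a, kind="stable")
        ids_s, pos_s = ids_a[order], pos_a[order]
        boundaries = np.flatnonzero(np.diff(ids_s)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [ids_s.size]))
        for s, e in zip(starts, ends):
            t = e - s
            if t < 2 or t > max_per_kmer:
                continue
            grp = np.sort(pos_s[s:e])
            ii, jj = np.triu_indices(t, k=1)
            pairs_a.append(grp[ii])
            pairs_b.append(grp[jj])
    else:
        order_a = np.argsort(ids_a, kind="stable")
        order_b = np.argsort(ids_b, kind="stable")
        ia, ib = ids_a[order_a], ids_b[order_b]
        pa, pb = pos_a[order_a], pos_b[order_b]
        i = j = 0
        while i < ia.size and j < ib.size:
            if ia[i] < ib[j]:
                i += 1
            elif ia[i] > ib[j]:
                j += 1
            else:
                v = ia[i]
                i2, j2 = i, j
                while i2 < ia.size and ia[i2] == v:
                    i2 += 1
                while j2 < ib.size and ib[j2] == v:
                    j2 += 1
                if (i2 - i) <= max_per_kmer and (j2 - j) <= max_per_kmer:
                    ga, gb = np.sort(pa[i:i2]), np.sort(pb[j:j2])
                    aa = np.repeat(ga, gb.size)
                    bb = np.tile(gb, ga.size)
                    pairs_a.append(aa)
                    pairs_b.append(bb)
                i, j = i2, j2
    if not pairs_a:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(pairs_a), np.concatenate(pairs_b)


def _extend_ungapped(sa: bytes, sb: bytes, i: int, j: int, k: int, xdrop: int):
    """X-drop ungapped extension of an exact seed sa[i:i+k]==sb[j:j+k].

    Returns (a_start, a_end, b_start, b_end, matches) of the best-scoring
    ungapped segment through the seed (+1 match / -1 mismatch / N never
    matches).
    """
    N = ord("N")
    # right extension
    score = best = 0
    p, q = i + k, j + k
    best_p = p
    mis_right_best = mis_right = 0
    la, lb = len(sa), len(sb)
    while p < la and q < lb:
        ca, cb = sa[p], sb[q]
        if ca == cb and ca != N:
            score += 1
        else:
            score -= 1
            mis_right += 1
        p += 1
        q += 1
        if score > best:
            best = score
            best_p = p
            mis_right_best = mis_right
        elif score < best - xdrop:
            break
    right_end = best_p
    # left extension
    score = best = 0
    p, q = i, j
    best_p = p
    mis_left_best = mis_left = 0
    while p > 0 and q > 0:
        p -= 1
        q -= 1
        ca, cb = sa[p], sb[q]
        if ca == cb and ca != N:
            score += 1
        else:
            score -= 1
            mis_left += 1
        if score > best:
            best = score
            best_p = p
            mis_left_best = mis_left
        elif score < best - xdrop:
            break
    left_start = best_p
    length = right_end - left_start
    matches = length - mis_right_best - mis_left_best
    shift = j - i
    return left_start, right_end, left_start + shift, right_end + shift, matches


def _align_diagonals(sa: bytes, sb: bytes, seeds_a, seeds_b, k, xdrop, min_out_len,
                     min_seed_hits, skip_zero_diag):
    """Group seeds by diagonal, extend leftmost-first, skip covered seeds."""
    out = []
    if seeds_a.size == 0:
        return out
    diag = seeds_b - seeds_a
    order = np.lexsort((seeds_a, diag))
    diag, sa_pos = diag[order], seeds_a[order]
    boundaries = np.flatnonzero(np.diff(diag)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [diag.size]))
    for s, e in zip(starts, ends):
        d = int(diag[s])
        if skip_zero_diag and d == 0:
            continue
        if e - s < min_seed_hits:
            continue
        covered_end = -1
        for idx in range(s, e):
            i = int(sa_pos[idx])
            if i < covered_end:
                continue
            a0, a1, b0, b1, matches = _extend_ungapped(sa, sb, i, i + d, k, xdrop)
            covered_end = a1
            if a1 - a0 >= min_out_len:
                out.append((a0, a1, b0, b1, matches))
    return out


def self_align(
    genome: dict[str, str],
    k: int = 15,
    min_seed_hits: int = 1,
    xdrop: int = 50,
    min_out_len: int = 1000,
    include_reverse: bool = True,
) -> list[LocalAlignment]:
    """Find off-diagonal intra-chromosome local self-alignments.

    Exact k-mer seeding with ungapped x-drop extension; a desk-scale
    stand-in for a full genome-to-genome aligner.  Both orientations are
    reported (reverse-strand hits arise from palindromic/inverted repeats).
    Scores are the number of matching bases.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if not genome:
        raise ValueError("empty genome")
    results: list[LocalAlignment] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        sa = seq.encode()
        codes = _CODE[np.frombuffer(sa, dtype=np.uint8)]
        pos, ids = _kmer_ids(codes, k)
        pa, pb = _seed_pairs(pos, ids)
        for a0, a1, b0, b1, matches in _align_diagonals(
            sa, sa, pa, pb, k, xdrop, min_out_len, min_seed_hits, skip_zero_diag=True
        ):
            results.append(
                LocalAlignment(chrom, a0, a1, b0, b1, "+", float(matches))
            )
        if include_reverse:
            rc = revcomp(seq)
            sb = rc.encode()
            codes_rc = _CODE[np.frombuffer(sb, dtype=np.uint8)]
            pos_rc, ids_rc = _kmer_ids(codes_rc, k)
            pa2, pb2 = _seed_pairs(pos, ids, pos_rc, ids_rc)
            L = len(seq)
            for a0, a1, b0, b1, matches in _align_diagonals(
                sa, sb, pa2, pb2, k, xdrop, min_out_len, min_seed_hits, skip_zero_diag=False
            ):
                # map the reverse-complement interval back to forward coords
                f0, f1 = L - b1, L - b0
                if (f0, f1) == (a0, a1):
                    # a perfect palindrome aligned onto itself: not a duplication
                    continue
                results.append(
                    LocalAlignment(chrom, a0, a1, f0, f1, "-", float(matches))
                )
    return canonicalize(results)
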