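"""Region grouping and symmetric alignment dot-plots for cluster follow-up.

Members of a gene cluster are chained into *regions* wherever they fall
within 1 Mbp of each other along a chromosome; a region pair is then drawn
as a dot-plot whose off-diagonal segments are the local alignments between
the two regions, coloured by alignment score (max -> min maps dark blue ->
yellow), with gene tracks along both axes (focal-cluster members in red,
other genes in white).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.collections import LineCollection
from matplotlib.colors import Normalize

from .alignments import LocalAlignment

__all__ = ["Region", "group_regions", "plot_region"]


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    member_gene_ids: tuple[str, ...]


def group_regions(
    members: Sequence[tuple[str, str, int, int]],
    gap: int = 1_000_000,
    flank: int = 50_000,
) -> list[Region]:
    """Single-linkage chaining of cluster members along each chromosome.

    ``members`` rows are ``(gene_id, chrom, start, end)``; genes whose spans
    lie within ``gap`` of each other join one region, whose extent is the
    member span padded by ``flank`` (clamped at zero).
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, chrom, start, end in members:
        by_chrom.setdefault(chrom, []).append((start, end, gid))
    regions = []
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom])
        current: list[tuple[int, int, str]] = [rows[0]]
        for row in rows[1:]:
            if row[0] - max(e for _, e, _ in current) <= gap:
                current.append(row)
            else:
                regions.append(_make_region(chrom, current, flank))
                current = [row]
        regions.append(_make_region(chrom, current, flank))
    return regions


def _make_region(chrom: str, rows: list[tuple[int, int, str]], flank: int) -> Region:
    start = max(0, min(s for s, _, _ in rows) - flank)
    end = max(e for _, e, _ in rows) + flank
    return Region(chrom, start, end, tuple(g for _, _, g in sorted(rows)))


def _segments_for_pair(
    alignments: Sequence[LocalAlignment],
    rx: Region,
    ry: Region,
    min_aln_len: int,
):
    """(x0, y0, x1, y1, score) line segments between the two regions."""
    segs = []
    for aln in alignments:
        if aln.length < min_aln_len:
            continue
        b_chrom = aln.b_chrom or aln.chrom
        candidates = [
            (aln.chrom, aln.a_start, aln.a_end, b_chrom, aln.b_start, aln.b_end),
            (b_chrom, aln.b_start, aln.b_end, aln.chrom, aln.a_start, aln.a_end),
        ]
        for cx, xs, xe, cy, ys, ye in candidates:
            if cx == rx.chrom and cy == ry.chrom and xs < rx.end and xe > rx.start \
                    and ys < ry.end and ye > ry.start:
                if aln.strand == "+":
                    segs.append((xs, ys, xe, ye, aln.score))
                else:
                    segs.append((xs, ye, xe, ys, aln.score))
    return segs


def plot_region(
    region_x: Region,
    region_y: Region,
    alignments: Sequence[LocalAlignment],
    genes,
    focal_gene_ids: set[str],
    out_path,
    min_aln_len: int = 50,
) -> None:
    """Symmetric dot-plot of one region pair with gene tracks.

    ``genes`` is a frame with gene_id/chrom/start/end.  Alignments at least
    ``min_aln_len`` long are drawn as segments coloured by score on a
    max -> min = dark blue -> yellow scale.  A same-region panel also shows
    the identity diagonal and each segment's mirror.  The plot is
    deterministic for a fixed input (segments are sorted before drawing).
    """
    segs = _segments_for_pair(alignments, region_x, region_y, min_aln_len)
    same = region_x == region_y
    if same:
        segs = segs + [(y0, x0, y1, x1, s) for x0, y0, x1, y1, s in segs]
    segs = sorted(set(segs))

    fig, ax = plt.subplots(figsize=(7, 7))
    if segs:
        scores = [s[4] for s in segs]
        norm = Normalize(vmin=min(scores), vmax=max(scores))
        # max score -> dark blue, min -> yellow
        lc = LineCollection(
            [((x0, y0), (x1, y1)) for x0, y0, x1, y1, _ in segs],
            cmap="viridis_r",
            norm=norm,
            linewidths=1.2,
        )
        lc.set_array(np.array(scores))
        ax.add_collection(lc)
        fig.colorbar(lc, ax=ax, label="alignment score", shrink=0.7)
    if same:
        ax.plot(
            [region_x.start, region_x.end],
            [region_y.start, region_y.end],
            color="0.8",
            linewidth=0.8,
            zorder=0,
        )

    track_h = 0.01 * max(region_y.end - region_y.start, 1)
    for row in genes.itertuples():
        color = "red" if row.gene_id in focal_gene_ids else "white"
        if row.chrom == region_x.chrom and row.start < region_x.end and row.end > region_x.start:
            ax.axvspan(row.start, row.end, ymin=0.0, ymax=0.015,
                       color=color, ec="black", lw=0.4)
        if row.chrom == region_y.chrom and row.start < region_y.end and row.end > region_y.start:
            ax.axhspan(row.start, row.end, xmin=0.0, xmax=0.015,
                       color=color, ec="black", lw=0.4)
    del track_h

    ax.set_xlim(region_x.start, region_x.end)
    ax.set_ylim(region_y.start, region_y.end)
    ax.set_xlabel(f"{region_x.chrom}:{region_x.start}-{region_x.end}")
    ax.set_ylabel(f"{region_y.chrom}:{region_y.start}-{region_y.end}")
    ax.set_title("local alignments" + (" (symmetric)" if same else ""))
    kwargs = {}
    if Path(str(out_path)).suffix.lower() == ".png":
        kwargs["metadata"] = {"Software": "ldprscan"}  # keeps the file byte-stable
    fig.savefig(out_path, dpi=120, **kwargs)
    plt.close(fig)
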