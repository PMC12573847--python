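"""Reading and writing of the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; GFF3 is emitted and parsed as
1-based inclusive, BED as 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "read_gff3_genes",
    "read_bed",
    "write_bed",
]


def read_fasta(path) -> dict[str, str]:
    """Genome as an ordered ``{name: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene/mRNA/CDS features from a gene table.

    Expects columns ``gene_id, chrom, start, end`` (0-based half-open CDS
    span); every gene is emitted as a single-CDS transcript ``<gene_id>.1``.
    """
    df = genes.sort_values(["chrom", "start", "gene_id"], kind="stable")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples():
            start1, end1 = row.start + 1, row.end  # to 1-based inclusive
            gid, tid = row.gene_id, f"{row.gene_id}.1"
            fh.write(
                f"{row.chrom}\tldprsim\tgene\t{start1}\t{end1}\t.\t+\t.\tID={gid}\n"
            )
            fh.write(
                f"{row.chrom}\tldprsim\tmRNA\t{start1}\t{end1}\t.\t+\t.\tID={tid};Parent={gid}\n"
            )
            fh.write(
                f"{row.chrom}\tldprsim\tCDS\t{start1}\t{end1}\t.\t+\t0\t"
                f"ID={tid}.cds;Parent={tid}\n"
            )


def read_gff3_genes(path) -> pd.DataFrame:
    """Per-gene longest-transcript CDS spans from a GFF3 file.

    For each gene the transcript with the greatest summed CDS length is
    selected (ties broken by lexicographic transcript ID) and its CDS span
    (min CDS start to max CDS end, 0-based half-open) is reported.  Genes
    without any CDS are excluded with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        best = None  # (-(cds_len), transcript_id, span)
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = list(db.children(mrna, featuretype="CDS"))
            if not cds:
                continue
            total = sum(c.end - c.start + 1 for c in cds)
            span = (min(c.start for c in cds) - 1, max(c.end for c in cds))
            key = (-total, mrna.id)
            if best is None or key < best[0]:
                best = (key, span)
        if best is None:
            logger.warning("gene %s has no CDS features; excluded", gene.id)
            continue
        (neg_total, tid), (s, e) = best
        rows.append((gene.id, gene.seqid, s, e, tid, -neg_total))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "transcript_id", "cds_length"]
    )


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(intervals, path, names=None, scores=None) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            fields = [chrom, str(start), str(end)]
            if names is not None:
                fields.append(names[i])
                if scores is not None:
                    fields.append(str(scores[i]))
            fh.write("\t".join(fields) + "\n")
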