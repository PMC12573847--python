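"""Function-agnostic greedy centroid clustering of protein sequences.

Mirrors the published UCLUST semantics: sequences are processed in
decreasing length order and each is assigned to the *first* existing
centroid whose global-alignment identity reaches the cutoff, else it founds
a new cluster.  Identity is read from a Needleman-Wunsch traceback
(match +1 / mismatch -1 / gap -1, linear gaps) as matching columns divided
by all alignment columns, terminal gaps included; the cutoff of 0.5 keeps
gene families together while splitting unrelated proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GeneCluster", "global_identity", "greedy_cluster", "clusters_to_frame"]

MATCH, MISMATCH, GAP = 1, -1, -1


@dataclass
class GeneCluster:
    cluster_id: str
    centroid_gene_id: str
    member_gene_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


def _nw_matrix(a: str, b: str) -> np.ndarray:
    """Full Needleman-Wunsch score matrix with linear gap penalties.

    Rows are vectorised: the in-row horizontal-gap recurrence
    ``H[j] = max_k<=j (cand[k] - (j - k))`` is a running maximum of
    ``cand[k] + k``.
    """
    n, m = len(a), len(b)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0] = GAP * np.arange(m + 1)
    jidx = np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        s = np.where(bb == ord(a[i - 1]), MATCH, MISMATCH)
        cand = np.empty(m + 1, dtype=np.int32)
        cand[0] = GAP * i
        cand[1:] = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + GAP)
        H[i] = np.maximum.accumulate(cand + jidx) - jidx
    return H


def _identity_from_traceback(a: str, b: str, H: np.ndarray) -> float:
    """Matching columns / all columns along one optimal path.

    Tie-break priority at each cell: diagonal, then up (gap in b), then left
    (gap in a); fixed so the result is deterministic.
    """
    i, j = len(a), len(b)
    matches = columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if H[i, j] == H[i - 1, j - 1] + s:
                matches += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
                columns += 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
        columns += 1
    return matches / columns


def global_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity of two protein sequences, in [0, 1].

    Symmetric by construction (the argument pair is ordered canonically
    before alignment, so tie-breaking cannot depend on argument order).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    a, b = sorted((seq_a, seq_b))
    H = _nw_matrix(a, b)
    return _identity_from_traceback(a, b, H)


def greedy_cluster(proteins: dict[str, str], cutoff: float = 0.5) -> list[GeneCluster]:
    """Greedy first-match centroid clustering at a global-identity cutoff.

    Deterministic: input order is decreasing sequence length with ties broken
    by gene ID; candidates are existing centroids in creation order.  A
    length-ratio bound (identity cannot exceed ``min/max`` of the lengths)
    skips hopeless alignments without changing the result.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    for gid, seq in proteins.items():
        if not seq:
            raise ValueError(f"empty protein sequence for {gid}")
    order = sorted(proteins, key=lambda g: (-len(proteins[g]), g))
    clusters: list[GeneCluster] = []
    for gid in order:
        seq = proteins[gid]
        assigned = False
        for cl in clusters:
            cseq = proteins[cl.centroid_gene_id]
            bound = min(len(seq), len(cseq)) / max(len(seq), len(cseq))
            if bound < cutoff:
                continue
            if global_identity(seq, cseq) >= cutoff:
                cl.member_gene_ids.append(gid)
                assigned = True
                break
        if not assigned:
            clusters.append(
                GeneCluster(f"cl_{len(clusters) + 1:05d}", gid, [gid])
            )
    return clusters


def clusters_to_frame(clusters: list[GeneCluster]):
    """Long-form table: gene_id, cluster_id, is_centroid."""
    import pandas as pd

    rows = [
        (gid, cl.cluster_id, gid == cl.centroid_gene_id)
        for cl in clusters
        for gid in cl.member_gene_ids
    ]
    return pd.DataFrame(rows, columns=["gene_id", "cluster_id", "is_centroid"])
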