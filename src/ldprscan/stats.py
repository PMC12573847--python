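"""Per-cluster tests of gene-cluster / LDPR association.

Each annotated gene is flagged as inside or outside the called LDPRs from
the CDS span of its longest transcript (any overlap counts).  For every gene
cluster a 2x2 table (members/non-members x in/out of LDPRs) is tested for
independence with a two-sided Fisher exact test — an urn model — and
family-wise error is controlled by Bonferroni over the clusters that could
possibly reject, i.e. those with more than one member.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneLdprFlag",
    "ClusterAssociation",
    "assign_flags",
    "fisher_two_sided",
    "bonferroni_cutoff",
    "test_all_clusters",
]

logger = logging.getLogger(__name__)

TIE_REL_TOL = 1e-7  # tables whose pmf is within this relative tolerance count as ties


@dataclass(frozen=True)
class GeneLdprFlag:
    gene_id: str
    in_ldpr: bool


@dataclass
class ClusterAssociation:
    """Fisher result for one cluster.

    ``effect`` is the difference between the cluster's in-LDPR frequency and
    that of all other genes — the volcano-plot abscissa.
    """

    cluster_id: str
    a: int  # members in LDPRs
    b: int  # members outside
    c: int  # non-members in LDPRs
    d: int  # non-members outside
    p_value: float  # NaN when ineligible
    eligible: bool
    significant: bool

    @property
    def size(self) -> int:
        return self.a + self.b

    @property
    def effect(self) -> float:
        in_freq = self.a / (self.a + self.b) if self.a + self.b else 0.0
        out_freq = self.c / (self.c + self.d) if self.c + self.d else 0.0
        return in_freq - out_freq


def assign_flags(genes: pd.DataFrame, ldprs) -> dict[str, bool]:
    """Flag each gene by longest-transcript CDS-span overlap with any LDPR.

    ``genes`` is the table from :func:`ldprscan.io.read_gff3_genes` (or any
    frame with gene_id/chrom/start/end); ``ldprs`` is a list of LDPR objects
    or ``(chrom, start, end)`` tuples.  A single bp of overlap suffices.
    """
    trees: dict[str, IntervalTree] = {}
    for r in ldprs:
        chrom, start, end = (r.chrom, r.start, r.end) if hasattr(r, "chrom") else r
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    flags: dict[str, bool] = {}
    for row in genes.itertuples():
        tree = trees.get(row.chrom)
        flags[row.gene_id] = bool(tree is not None and tree.overlap(row.start, row.end))
    return flags


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

_LOGFACT_CACHE = np.array([])


def _logfact(n: int) -> np.ndarray:
    global _LOGFACT_CACHE
    if _LOGFACT_CACHE.size <= n:
        _LOGFACT_CACHE = np.concatenate(
            ([0.0], np.cumsum(np.log(np.arange(1, n + 1, dtype=np.float64))))
        )
    return _LOGFACT_CACHE


def _hypergeom_pmf_vector(N: int, K: int, n: int) -> tuple[np.ndarray, int]:
    """pmf over the support of a = |members in LDPRs|; returns (pmf, a_min)."""
    lf = _logfact(N)
    a_min = max(0, n - (N - K))
    a_max = min(K, n)
    a = np.arange(a_min, a_max + 1)
    logp = (
        lf[K] - lf[a] - lf[K - a]
        + lf[N - K] - lf[n - a] - lf[N - K - (n - a)]
        - (lf[N] - lf[n] - lf[N - n])
    )
    return np.exp(logp), a_min


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The p-value sums the hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed that of the observed
    table (relative tie tolerance 1e-7).  A zero margin makes the table
    uninformative: p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    N = a + b + c + d
    if N == 0:
        raise ValueError("empty table")
    K, n = a + b, a + c
    if K == 0 or K == N or n == 0 or n == N:
        logger.debug("degenerate margin in table (%d,%d,%d,%d); p = 1", a, b, c, d)
        return 1.0
    pmf, a_min = _hypergeom_pmf_vector(N, K, n)
    p_obs = pmf[a - a_min]
    p = float(pmf[pmf <= p_obs * (1.0 + TIE_REL_TOL)].sum())
    return min(p, 1.0)


def bonferroni_cutoff(alpha: float, cluster_sizes) -> float:
    """alpha divided by the number of clusters with more than one member."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    m = sum(1 for s in cluster_sizes if s >= 2)
    if m == 0:
        raise ValueError("no multi-member clusters to test")
    return alpha / m


def test_all_clusters(
    clusters,
    flags: dict[str, bool],
    alpha: float = 0.05,
    strict_per_ldpr_members: dict[str, int] | None = None,
    min_members_in_ldprs: int = 2,
) -> list[ClusterAssociation]:
    """Fisher-test every cluster against the LDPR flags.

    ``clusters`` is a list of objects with ``cluster_id``/``member_gene_ids``
    (or a mapping id -> members).  Eligibility requires at least
    ``min_members_in_ldprs`` members inside the union of LDPRs; ineligible
    clusters carry p = NaN and cannot be significant.  The Bonferroni cutoff
    divides alpha by the number of multi-member clusters.
    """
    if isinstance(clusters, dict):
        items = [(cid, members) for cid, members in clusters.items()]
    else:
        items = [(cl.cluster_id, cl.member_gene_ids) for cl in clusters]
    total = len(flags)
    total_in = sum(flags.values())
    cutoff = bonferroni_cutoff(alpha, [len(m) for _, m in items])
    out = []
    for cid, members in items:
        a = sum(flags[g] for g in members)
        b = len(members) - a
        c = total_in - a
        d = (total - total_in) - b
        eligible = a >= min_members_in_ldprs
        if strict_per_ldpr_members is not None:
            eligible = eligible and strict_per_ldpr_members.get(cid, 0) >= min_members_in_ldprs
        if eligible:
            p = fisher_two_sided(a, b, c, d)
            significant = p < cutoff
        else:
            p, significant = math.nan, False
        out.append(ClusterAssociation(cid, a, b, c, d, p, eligible, significant))
    return out


def associations_to_frame(associations: list[ClusterAssociation]) -> pd.DataFrame:
    rows = [
        (
            r.cluster_id, r.size, r.a, r.b, r.c, r.d,
            r.p_value, r.effect, r.eligible, r.significant,
        )
        for r in associations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size", "a", "b", "c", "d",
            "p_value", "effect", "eligible", "significant",
        ],
    )
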