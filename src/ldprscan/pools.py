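"""Functional gene pools and the pool-enrichment test.

A *pool* is a set of genes sharing a functional theme, built function-first:
either from GO annotation (all genes whose terms fall under a parent term,
via a supplied term -> ancestor closure table), from descriptor regular
expressions (the arms-race vocabulary: NBS-LRR, receptor-like kinases,
pathogenesis-related proteins, ...), from a homology-coverage filter against
reference sequences (the housekeeping control), or from an explicit list.

Clusters with a strict majority (> 50%) of members in the pool are labelled
pool clusters.  Whether evidence of LDPR association predicts pool
membership is then tested by logistic regression of the cluster label on
x = -log(p) of the cluster's association test, with a likelihood-ratio test
of the slope against the intercept-only null (chi-square, 1 df).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "FunctionPool",
    "PoolTestResult",
    "ARMS_RACE_PATTERNS",
    "build_pool",
    "label_pool_clusters",
    "homology_pool",
    "fit_pool_lrt",
    "read_go_closure",
]

logger = logging.getLogger(__name__)

#: Descriptor patterns for pathogen-interaction / arms-race annotations.
#: A documented approximation of the cereal resistance-domain vocabulary.
ARMS_RACE_PATTERNS = [
    r"(?i)NBS-LRR",
    r"(?i)NB-ARC",
    r"(?i)disease resistance",
    r"(?i)leucine-rich repeat",
    r"(?i)receptor-like kinase",
    r"(?i)pathogenesis-related",
    r"(?i)thionin",
    r"(?i)jacalin",
    r"(?i)jasmonate-induced",
    r"(?i)powdery mildew",
    r"(?i)chitinase",
    r"(?i)defensin",
]


@dataclass
class FunctionPool:
    label: str                     # e.g. "arms_race" or "housekeeping"
    gene_ids: set[str]
    provenance: dict[str, str]     # gene_id -> go_term | descriptor_regex | homology | explicit

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class PoolTestResult:
    """Logistic fit of pool membership on association evidence, with LRT."""

    beta0: float
    beta1: float
    ll_full: float
    ll_null: float
    lrt_stat: float
    df: int
    p_value: float
    n_clusters: int
    n_pool_clusters: int
    converged: bool = True
    separation: bool = False

    def summary(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "ll_full": self.ll_full,
            "ll_null": self.ll_null,
            "lrt_stat": self.lrt_stat,
            "df": self.df,
            "p_value": self.p_value,
            "n_clusters": self.n_clusters,
            "n_pool_clusters": self.n_pool_clusters,
            "converged": self.converged,
            "separation": self.separation,
        }


def read_go_closure(path) -> dict[str, set[str]]:
    """Term -> ancestor-set mapping from a two-column TSV (term, ancestor)."""
    closure: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t")
    for term, anc in zip(df.iloc[:, 0], df.iloc[:, 1]):
        closure.setdefault(str(term), set()).add(str(anc))
    return closure


def build_pool(
    gene_metadata: pd.DataFrame,
    go_root_id: str | None = None,
    descriptor_patterns: list[str] | None = None,
    go_closure: dict[str, set[str]] | None = None,
    label: str = "arms_race",
) -> FunctionPool:
    """Select pool genes by GO parentage and/or descriptor regex.

    A gene joins the pool if any of its GO terms equals ``go_root_id`` or has
    it among its closure ancestors, or if its descriptor matches any pattern.
    Without a closure table, GO terms are matched literally against the root.
    """
    if go_root_id is None and not descriptor_patterns:
        raise ValueError("need a GO root term and/or descriptor patterns")
    compiled = [re.compile(p) for p in (descriptor_patterns or [])]
    closure = go_closure or {}
    genes: set[str] = set()
    provenance: dict[str, str] = {}
    for row in gene_metadata.itertuples():
        gid = row.gene_id
        if go_root_id is not None:
            terms = [t for t in str(row.go_terms).split(";") if t]
            if any(t == go_root_id or go_root_id in closure.get(t, ()) for t in terms):
                genes.add(gid)
                provenance[gid] = "go_term"
                continue
        descriptor = str(row.descriptor)
        if any(p.search(descriptor) for p in compiled):
            genes.add(gid)
            provenance[gid] = "descriptor_regex"
    return FunctionPool(label, genes, provenance)


def label_pool_clusters(clusters, pool: FunctionPool, majority: float = 0.5) -> dict[str, bool]:
    """True for clusters with a strict majority of members in the pool."""
    if isinstance(clusters, dict):
        items = list(clusters.items())
    else:
        items = [(cl.cluster_id, cl.member_gene_ids) for cl in clusters]
    labels = {}
    for cid, members in items:
        n_in = sum(1 for g in members if g in pool.gene_ids)
        labels[cid] = n_in / len(members) > majority
    return labels


def homology_pool(
    homology_table: pd.DataFrame,
    coverage: float = 0.8,
    denominator: str = "mean",
    label: str = "housekeeping",
    variant_separator: str = ".",
) -> FunctionPool:
    """Genes with close homology to reference sequences, by coverage filter.

    The table is a precomputed tabular alignment result with columns
    ``query`` (candidate splice variant), ``subject``, ``aligned_length``,
    ``query_length``, ``subject_length``.  A gene is selected if *any* splice
    variant achieves aligned_length / denominator > ``coverage``, with the
    denominator the mean of the two original lengths (``"max"`` selects the
    longer instead).  Variant IDs are reduced to gene IDs by stripping the
    final separator-delimited suffix.
    """
    required = {"query", "aligned_length", "query_length", "subject_length"}
    missing = required - set(homology_table.columns)
    if missing:
        raise ValueError(f"homology table missing columns: {sorted(missing)}")
    if denominator == "mean":
        denom = (homology_table.query_length + homology_table.subject_length) / 2.0
    elif denominator == "max":
        denom = homology_table[["query_length", "subject_length"]].max(axis=1)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    covered = homology_table.aligned_length / denom > coverage
    genes: set[str] = set()
    provenance: dict[str, str] = {}
    for q in homology_table.loc[covered, "query"]:
        gid = str(q).rsplit(variant_separator, 1)[0]
        genes.add(gid)
        provenance[gid] = "homology"
    return FunctionPool(label, genes, provenance)


# ---------------------------------------------------------------------------
# Logistic regression + likelihood-ratio test
# ---------------------------------------------------------------------------

_MAX_ABS_BETA = 30.0   # |beta| beyond this on standardised data implies separation


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # log-likelihood via the numerically stable log1p(exp) form
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _newton_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                     tol: float = 1e-10, max_iter: int = 100):
    """Newton/IRLS fit; returns (beta, converged)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu) - ridge * beta
        if np.max(np.abs(grad)) <= tol:
            return beta, True
        w = mu * (1.0 - mu)
        H = (X.T * w) @ X + ridge * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        # step halving to guarantee likelihood ascent
        ll0 = _bernoulli_ll(y, eta) - 0.5 * ridge * beta @ beta
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            if _bernoulli_ll(y, X @ cand) - 0.5 * ridge * cand @ cand >= ll0:
                break
            scale *= 0.5
        beta = beta + scale * step
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    grad = X.T @ (y - mu) - ridge * beta
    return beta, bool(np.max(np.abs(grad)) <= tol)


def fit_pool_lrt(
    labels: dict[str, bool] | np.ndarray,
    p_values: dict[str, float] | np.ndarray,
    impute_ineligible: bool = False,
) -> PoolTestResult:
    """Test whether LDPR-association evidence predicts pool membership.

    Fits ``pool ~ -log(p)`` (natural log) by Newton/IRLS to a gradient norm
    of 1e-10 and compares against the intercept-only null with a
    likelihood-ratio test (chi-square, 1 df).  Clusters with NA p-values
    (untested/ineligible) are excluded unless ``impute_ineligible`` imputes
    p = 1 (x = 0, no evidence).  Complete separation triggers a warning and
    a weakly ridge-penalised refit from which the LRT is still computed.
    """
    if isinstance(labels, dict):
        keys = sorted(labels)
        y = np.array([bool(labels[k]) for k in keys], dtype=float)
        p = np.array([p_values[k] for k in keys], dtype=float)
    else:
        y = np.asarray(labels, dtype=float)
        p = np.asarray(p_values, dtype=float)
    if impute_ineligible:
        p = np.where(np.isnan(p), 1.0, p)
    keep = ~np.isnan(p)
    y, p = y[keep], p[keep]
    if y.size == 0:
        raise ValueError("no clusters with usable p-values")
    x = -np.log(np.clip(p, 1e-300, 1.0))
    n = y.size
    n_pool = int(y.sum())

    pbar = y.mean()
    if pbar in (0.0, 1.0):
        ll = 0.0
        return PoolTestResult(
            beta0=np.inf if pbar == 1.0 else -np.inf, beta1=0.0,
            ll_full=ll, ll_null=ll, lrt_stat=0.0, df=1, p_value=1.0,
            n_clusters=n, n_pool_clusters=n_pool,
        )
    ll_null = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))

    if np.ptp(x) == 0.0:
        # constant predictor carries no information: the full model is the null
        return PoolTestResult(
            beta0=float(np.log(pbar / (1 - pbar))), beta1=0.0,
            ll_full=ll_null, ll_null=ll_null, lrt_stat=0.0, df=1, p_value=1.0,
            n_clusters=n, n_pool_clusters=n_pool,
        )

    X = np.column_stack([np.ones(n), x])
    beta, converged = _newton_logistic(X, y)
    separation = (not converged) or np.any(np.abs(beta) > _MAX_ABS_BETA)
    if separation:
        warnings.warn(
            "quasi-complete separation in pool regression; "
            "reporting a weakly penalised fit",
            RuntimeWarning,
            stacklevel=2,
        )
        beta, converged = _newton_logistic(X, y, ridge=1e-4)
    ll_full = _bernoulli_ll(y, X @ beta)
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    p_lrt = float(chi2.sf(lrt, df=1))
    return PoolTestResult(
        beta0=float(beta[0]), beta1=float(beta[1]),
        ll_full=ll_full, ll_null=float(ll_null),
        lrt_stat=lrt, df=1, p_value=min(max(p_lrt, 0.0), 1.0),
        n_clusters=n, n_pool_clusters=n_pool,
        converged=bool(converged), separation=bool(separation),
    )
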