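"""Over-representation analysis (ORA) across annotation sources.

Each term in each (source, category) is scored with an upper-tail
hypergeometric test against the source's declared universe:

    p = P(X >= k),  X ~ Hypergeom(N, K, M)

where N is the universe size, K the term size, M the effective query size
(query genes inside the universe) and k the observed overlap.
Benjamini-Hochberg adjustment is applied within each (source, category).
Top-cluster selection keeps, per group, the ``top_k`` most significant
terms (unadjusted p < alpha, ascending p, term_id as the tie-break) —
the unit whose membership frequencies downstream rank the candidates.
"""

from __future__ import annotations

import logging
from collections.abc import Collection, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model_io import AnnotationSource, normalize_symbol

__all__ = [
    "EnrichmentCluster",
    "EnrichmentTest",
    "bh_adjust",
    "enrich_source",
    "hypergeometric_upper_tail",
    "select_top_clusters",
]

logger = logging.getLogger(__name__)


def hypergeometric_upper_tail(N: int, K: int, M: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe N, term size K, query size M).

    Exact survival-function evaluation (log-space internally); ``k = 0``
    returns 1 by convention.
    """
    for name, v in (("N", N), ("K", K), ("M", M), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name}={v} must be a non-negative integer")
    if K > N or M > N:
        raise ValueError(f"K={K} and M={M} must not exceed N={N}")
    if k > min(K, M):
        raise ValueError(f"k={k} exceeds min(K, M)={min(K, M)}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, M))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class EnrichmentTest:
    """The 2x2 counts and p-values of one hypergeometric ORA test."""

    N: int
    K: int
    M: int
    k: int
    p: float
    p_adj: float


@dataclass(frozen=True)
class EnrichmentCluster:
    """One annotated term's enrichment result from one source/category."""

    term_id: str
    source_name: str
    category: str
    members: frozenset[str]  # the k overlapping genes
    test: EnrichmentTest


def enrich_source(
    query_genes: Collection[str], source: AnnotationSource
) -> list[EnrichmentCluster]:
    """Score every term of ``source`` against the query; keep overlaps k >= 1.

    Query genes outside the source's universe are dropped from the
    effective query size M (logged); results are sorted by (p, term_id).
    BH adjustment is computed over all tested terms of the source,
    including zero-overlap terms (p = 1), so p_adj does not depend on
    which terms happen to overlap.
    """
    query = {normalize_symbol(g) for g in query_genes}
    effective = query & source.universe
    dropped = len(query) - len(effective)
    if dropped:
        logger.info(
            "%s.%s: %d query gene(s) outside universe dropped",
            source.source_name, source.category, dropped,
        )
    if not effective:
        raise ValueError(
            f"{source.source_name}.{source.category}: no query genes in universe"
        )
    N, M = len(source.universe), len(effective)
    term_ids = sorted(source.terms)
    raw: list[tuple[str, frozenset[str], int, float]] = []
    for term_id in term_ids:
        genes = source.terms[term_id]
        overlap = frozenset(genes & effective)
        p = hypergeometric_upper_tail(N, len(genes), M, len(overlap))
        raw.append((term_id, overlap, len(genes), p))
    adjusted = bh_adjust([r[3] for r in raw])
    clusters = [
        EnrichmentCluster(
            term_id,
            source.source_name,
            source.category,
            overlap,
            EnrichmentTest(N, K, M, len(overlap), p, p_adj),
        )
        for (term_id, overlap, K, p), p_adj in zip(raw, adjusted)
        if overlap
    ]
    clusters.sort(key=lambda c: (c.test.p, c.term_id))
    return clusters


def select_top_clusters(
    clusters: Collection[EnrichmentCluster],
    top_k: int = 30,
    alpha: float = 0.05,
) -> list[EnrichmentCluster]:
    """Keep the ``top_k`` most significant clusters within each (source, category).

    Significance and ordering use the unadjusted p (ascending), with
    lexicographic term_id breaking ties deterministically; a group with
    fewer than ``top_k`` significant clusters contributes all of them.
    """
    groups: dict[tuple[str, str], list[EnrichmentCluster]] = {}
    for c in clusters:
        groups.setdefault((c.source_name, c.category), []).append(c)
    selected: list[EnrichmentCluster] = []
    for key in sorted(groups):
        sig = [c for c in groups[key] if c.test.p < alpha]
        sig.sort(key=lambda c: (c.test.p, c.term_id))
        selected.extend(sig[:top_k])
    return selected
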