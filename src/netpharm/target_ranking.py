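"""Cluster-frequency rank aggregation of candidate targets.

Each selected enrichment cluster votes once for every candidate gene it
contains; candidates are ranked by vote count descending. This turns the
heterogeneous per-source top-30 lists into a single frequency ranking,
from which the top-k candidates are taken.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Collection, Sequence
from dataclasses import dataclass, field

from .enrichment import EnrichmentCluster
from .model_io import normalize_symbol

__all__ = ["FrequencyRanking", "cluster_frequency", "top_k_targets"]

logger = logging.getLogger(__name__)


@dataclass
class FrequencyRanking:
    """Per-candidate cluster-membership counts and the derived ordering.

    ``counts[g]`` is the number of distinct selected clusters whose member
    set contains g (a cluster contributes at most one per gene; candidates
    found nowhere get 0). ``ranked`` orders candidates by count
    descending, ties broken by higher summed -log10(p) over containing
    clusters, then lexicographic symbol.
    """

    counts: dict[str, int]
    ranked: list[tuple[str, int]]
    n_clusters_considered: int
    tiebreak_neglogp: dict[str, float] = field(default_factory=dict)


def cluster_frequency(
    selected_clusters: Sequence[EnrichmentCluster],
    candidate_genes: Collection[str],
) -> FrequencyRanking:
    """Count, per candidate, how many selected clusters contain it."""
    if not selected_clusters:
        raise ValueError("no selected clusters to aggregate")
    candidates = {normalize_symbol(g) for g in candidate_genes}
    counts = {g: 0 for g in candidates}
    neglogp = {g: 0.0 for g in candidates}
    for cluster in selected_clusters:
        contribution = -math.log10(max(cluster.test.p, 1e-300))
        for g in candidates & cluster.members:
            counts[g] += 1
            neglogp[g] += contribution
    ranked = sorted(
        counts.items(), key=lambda kv: (-kv[1], -neglogp[kv[0]], kv[0])
    )
    return FrequencyRanking(
        counts=counts,
        ranked=ranked,
        n_clusters_considered=len(selected_clusters),
        tiebreak_neglogp=neglogp,
    )


def top_k_targets(ranking: FrequencyRanking, k: int = 5) -> list[str]:
    """First ``k`` candidates by frequency; zero-count candidates never qualify.

    If fewer than ``k`` candidates have nonzero counts, all of them are
    returned with a warning. A count tie crossing the k-boundary is
    resolved by the ranking's tie-break (summed -log10 p, then symbol)
    and logged.
    """
    if not ranking.ranked:
        raise ValueError("empty ranking")
    nonzero = [(g, c) for g, c in ranking.ranked if c > 0]
    if k > len(nonzero):
        logger.warning(
            "requested top %d but only %d candidates have nonzero counts",
            k, len(nonzero),
        )
        return [g for g, _ in nonzero]
    if len(nonzero) > k and nonzero[k][1] == nonzero[k - 1][1]:
        logger.warning(
            "count tie at the k=%d boundary (count=%d); resolved by summed "
            "-log10(p) then symbol", k, nonzero[k][1],
        )
    return [g for g, _ in nonzero[:k]]
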