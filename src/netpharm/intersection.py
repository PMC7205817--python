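"""Formula-target / disease-target intersection and per-herb contributions.

The candidate space of the screen is the gene set shared by the formula's
compound targets and the disease gene list; nuclear-receptor candidates
are its restriction to the NR catalog. Per-herb contribution counts use
the UpSet convention: every compound is attributed to each herb that
contains it in per-herb totals, while exclusive herb-combination counts
partition the pooled compound set.
"""

from __future__ import annotations

from collections.abc import Collection, Mapping
from dataclasses import dataclass

from .model_io import BipartiteNetwork

__all__ = [
    "HerbContributions",
    "IntersectionResult",
    "corresponding_compounds",
    "intersect_targets",
    "per_herb_contributions",
    "restrict_to_catalog",
    "build_intersection_result",
]


def intersect_targets(formula_targets: Collection[str], disease_targets: Collection[str]) -> set[str]:
    """Exact intersection of formula targets and disease targets (may be empty)."""
    return set(formula_targets) & set(disease_targets)


def restrict_to_catalog(cn_targets: Collection[str], catalog: Collection[str]) -> set[str]:
    """Candidates from the intersection that belong to the receptor catalog."""
    catalog = set(catalog)
    if not catalog:
        raise ValueError("empty catalog: likely a misconfigured catalog file")
    return set(cn_targets) & catalog


def corresponding_compounds(
    gene_set: Collection[str], bipartite: BipartiteNetwork
) -> tuple[set[str], int]:
    """Compounds with at least one edge into ``gene_set`` and the restricted edge count.

    Genes absent from the network's target side contribute nothing (disease
    lists legitimately exceed formula coverage).
    """
    genes = set(gene_set)
    compounds: set[str] = set()
    n_edges = 0
    for g in genes:
        linked = bipartite.compounds_of(g)
        compounds |= linked
        n_edges += len(linked)
    return compounds, n_edges


@dataclass
class HerbContributions:
    """Per-herb and exclusive herb-combination counts over the formula.

    ``exclusive_compounds`` maps a sorted herb-name tuple to the number of
    compounds found in exactly that herb combination; the counts partition
    the pooled compound set.
    """

    per_herb_compounds: dict[str, int]
    per_herb_targets: dict[str, int]
    per_herb_restricted_targets: dict[str, int]
    exclusive_compounds: dict[tuple[str, ...], int]
    pooled_compounds: int


def per_herb_contributions(
    herb_map: Mapping[str, Collection[str]],
    bipartite: BipartiteNetwork,
    gene_set: Collection[str] | None = None,
) -> HerbContributions:
    """Count compound/target contributions of each herb and herb combination.

    A compound shared by several herbs counts once in the pooled total and
    once per member herb in per-herb totals. ``gene_set`` restricts the
    per-herb target counts (e.g. to the disease intersection).
    """
    membership: dict[str, set[str]] = {}
    for herb, cids in herb_map.items():
        for cid in cids:
            membership.setdefault(cid, set()).add(herb)
    unmapped = sorted(bipartite.compounds - set(membership))
    if unmapped:
        raise ValueError(f"compounds missing from herb map: {unmapped[:10]}")

    genes = set(gene_set) if gene_set is not None else None
    per_compounds: dict[str, int] = {}
    per_targets: dict[str, int] = {}
    per_restricted: dict[str, int] = {}
    for herb, cids in herb_map.items():
        targets: set[str] = set()
        for cid in cids:
            targets |= bipartite.targets_of(cid)
        per_compounds[herb] = len(set(cids))
        per_targets[herb] = len(targets)
        per_restricted[herb] = len(targets & genes) if genes is not None else len(targets)

    exclusive: dict[tuple[str, ...], int] = {}
    for herbs in membership.values():
        key = tuple(sorted(herbs))
        exclusive[key] = exclusive.get(key, 0) + 1

    return HerbContributions(
        per_herb_compounds=per_compounds,
        per_herb_targets=per_targets,
        per_herb_restricted_targets=per_restricted,
        exclusive_compounds=exclusive,
        pooled_compounds=len(membership),
    )


@dataclass
class IntersectionResult:
    """Candidate space of the screen: intersection targets and their restrictions."""

    cn_targets: set[str]
    cn_compounds: set[str]
    cn_edge_count: int
    nr_targets: set[str]
    nr_compounds: set[str]
    nr_edge_count: int


def build_intersection_result(
    formula_targets: Collection[str],
    disease_targets: Collection[str],
    catalog: Collection[str],
    bipartite: BipartiteNetwork,
) -> IntersectionResult:
    cn = intersect_targets(formula_targets, disease_targets)
    nr = restrict_to_catalog(cn, catalog) if cn else set()
    cn_compounds, cn_edges = corresponding_compounds(cn, bipartite)
    nr_compounds, nr_edges = corresponding_compounds(nr, bipartite)
    return IntersectionResult(cn, cn_compounds, cn_edges, nr, nr_compounds, nr_edges)
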