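"""Native MCODE molecular-complex detection.

MCODE finds densely interconnected regions of a protein-protein
interaction network in three stages:

1. *Vertex weighting* — each vertex v is weighted by the density of the
   highest k-core of its closed neighborhood multiplied by that core's
   core number k. Vertices below the degree cutoff weigh 0.
2. *Complex prediction* — vertices are seeded in descending weight order;
   from each unseen seed the complex grows outward, recursively including
   unseen neighbors whose weight is within the vertex weight percentage
   (VWP) of the seed weight, i.e. weight >= (1 - VWP) * seed_weight, up
   to ``max_depth`` hops from the seed. Every vertex joins at most one
   complex (before fluff).
3. *Post-processing* — complexes not containing a k_core_filter-core are
   dropped; *fluff* (optional) adds boundary neighbors whose neighborhood
   density exceeds a cutoff; *haircut* (optional) iteratively removes
   singly-connected members.

A complex with n members and e intra-member edges scores
``density * n = (2e / (n(n-1))) * n = 2e/(n-1)`` (loopless density); a
higher score marks a more concentrated cluster. Note that at the default
VWP this expansion is deep: two cliques joined by a single bridge edge
whose vertices all carry equal weight merge into one complex.

All orderings (seed selection, neighbor expansion, reported member
lists) are tie-broken by node label, so results are fully deterministic.

Defaults follow the familiar desktop implementation of the algorithm:
degree cutoff 2, VWP 0.2, 2-core filter, haircut on, fluff off,
max depth 100, loopless densities.
"""

from __future__ import annotations

from collections import deque
from collections.abc import Iterable
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "MCODEComplex",
    "MCODEParams",
    "cluster_score",
    "core_decomposition",
    "find_complexes",
    "vertex_weight",
]


@dataclass(frozen=True)
class MCODEParams:
    include_loops: bool = False
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2  # VWP: vertex weight percentage
    k_core_filter: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.node_score_cutoff < 1.0):
            raise ValueError("node_score_cutoff (VWP) must be in [0, 1)")
        if self.degree_cutoff < 0:
            raise ValueError("degree_cutoff must be >= 0")


@dataclass
class MCODEComplex:
    """A predicted dense subgraph with its density-based score."""

    members: frozenset[str]
    seed: str
    n: int
    e: int
    density: float
    score: float

    @classmethod
    def from_subgraph(cls, graph: nx.Graph, members: Iterable[str], seed: str) -> "MCODEComplex":
        members = frozenset(members)
        sub = graph.subgraph(members)
        n, e = sub.number_of_nodes(), sub.number_of_edges()
        density = _density(n, e)
        return cls(members, seed, n, e, density, cluster_score(n, e))


def _density(n: int, e: int) -> float:
    return 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0


def cluster_score(n: int, e: int) -> float:
    """Loopless density times node count: 2e/(n-1) for n >= 2, else 0."""
    if n < 1 or e < 0:
        raise ValueError("need n >= 1 and e >= 0")
    if e > n * (n - 1) // 2:
        raise ValueError(f"e={e} exceeds maximum {n * (n - 1) // 2} for n={n}")
    return _density(n, e) * n


def core_decomposition(graph: nx.Graph) -> dict[str, int]:
    """Core number of every vertex by iterative minimum-degree peeling.

    core(v) is the largest k such that v belongs to a maximal subgraph of
    minimum degree >= k.
    """
    degrees = dict(graph.degree())
    core: dict[str, int] = {}
    # bucket queue over current degrees; peel the minimum repeatedly
    remaining = set(graph.nodes())
    buckets: dict[int, set[str]] = {}
    for v, d in degrees.items():
        buckets.setdefault(d, set()).add(v)
    current_k = 0
    while remaining:
        d = min(b for b, s in buckets.items() if s)
        current_k = max(current_k, d)
        v = min(buckets[d])  # label tie-break, immaterial to core numbers
        buckets[d].discard(v)
        remaining.discard(v)
        core[v] = current_k
        for u in graph.neighbors(v):
            if u in remaining:
                du = degrees[u]
                buckets[du].discard(u)
                degrees[u] = du - 1
                buckets.setdefault(du - 1, set()).add(u)
    return core


def _highest_k_core(graph: nx.Graph) -> tuple[int, set[str]]:
    """(k_max, members of the highest k-core) of ``graph``."""
    if graph.number_of_nodes() == 0:
        return 0, set()
    core = core_decomposition(graph)
    k_max = max(core.values())
    return k_max, {v for v, k in core.items() if k == k_max}


def vertex_weight(graph: nx.Graph, v: str, params: MCODEParams | None = None) -> float:
    """MCODE weight of v: density of the highest k-core of N[v], times k.

    Isolated vertices and vertices below the degree cutoff weigh 0.
    """
    params = params or MCODEParams()
    if v not in graph:
        raise KeyError(f"vertex {v!r} not in graph")
    neighbors = list(graph.neighbors(v))
    if len(neighbors) < params.degree_cutoff or not neighbors:
        return 0.0
    closed = graph.subgraph([v, *neighbors])
    k_max, core_nodes = _highest_k_core(closed)
    if k_max == 0:
        return 0.0
    core_sub = closed.subgraph(core_nodes)
    n, e = core_sub.number_of_nodes(), core_sub.number_of_edges()
    if params.include_loops:
        possible = n * (n + 1) / 2
        density = e / possible if possible else 0.0
    else:
        density = _density(n, e)
    return k_max * density


def _grow_complex(
    graph: nx.Graph,
    seed: str,
    weights: dict[str, float],
    visited: set[str],
    params: MCODEParams,
) -> set[str]:
    """Breadth-first expansion from ``seed`` under the VWP threshold."""
    threshold = (1.0 - params.node_score_cutoff) * weights[seed]
    members = {seed}
    visited.add(seed)
    queue: deque[tuple[str, int]] = deque([(seed, 0)])
    while queue:
        u, depth = queue.popleft()
        if depth >= params.max_depth:
            continue
        for w in sorted(graph.neighbors(u)):
            if w not in visited and weights[w] >= threshold:
                visited.add(w)
                members.add(w)
                queue.append((w, depth + 1))
    return members


def _haircut(graph: nx.Graph, members: set[str]) -> set[str]:
    members = set(members)
    while True:
        sub = graph.subgraph(members)
        trim = {v for v in members if sub.degree(v) < 2}
        if not trim or trim == members:
            # a lone edge or singleton would vanish entirely; stop
            if trim == members:
                members -= trim
            return members
        members -= trim


def _fluff(graph: nx.Graph, members: set[str], cutoff: float) -> set[str]:
    added: set[str] = set()
    for v in sorted(members):
        for w in sorted(graph.neighbors(v)):
            if w in members or w in added:
                continue
            closed = graph.subgraph([w, *graph.neighbors(w)])
            d = _density(closed.number_of_nodes(), closed.number_of_edges())
            if d > cutoff:
                added.add(w)
    return members | added


def find_complexes(graph: nx.Graph, params: MCODEParams | None = None) -> list[MCODEComplex]:
    """Run full MCODE on an undirected simple graph; complexes sorted by score.

    Sorting is by score descending, then size descending, then smallest
    member label — fully deterministic.
    """
    params = params or MCODEParams()
    if graph.number_of_edges() == 0:
        return []
    weights = {v: vertex_weight(graph, v, params) for v in graph.nodes()}
    order = sorted(graph.nodes(), key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    complexes: list[MCODEComplex] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        members = _grow_complex(graph, seed, weights, visited, params)
        if params.k_core_filter > 0:
            core = core_decomposition(graph.subgraph(members))
            if not core or max(core.values()) < params.k_core_filter:
                continue
        if params.fluff:
            members = _fluff(graph, members, params.fluff_density_cutoff)
        if params.haircut:
            members = _haircut(graph, members)
        if len(members) < 2:
            continue
        complexes.append(MCODEComplex.from_subgraph(graph, members, seed))
    complexes.sort(key=lambda c: (-c.score, -c.n, min(c.members)))
    return complexes
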