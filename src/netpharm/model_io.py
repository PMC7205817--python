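"""Domain types and file I/O for the screening pipeline.

All tabular files are UTF-8, tab-separated, with a mandatory header row;
plain gene lists are one symbol per line with ``#`` comments and no header.
Gene identity is by normalized symbol (uppercased, stripped); see
:func:`normalize_symbol`.
"""

from __future__ import annotations

import csv
from collections.abc import Collection, Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "AnnotationSource",
    "BipartiteNetwork",
    "CompoundRecord",
    "ModelIOError",
    "PPINetwork",
    "export_network",
    "load_compound_table",
    "load_gene_list",
    "load_gmt",
    "load_herb_compounds",
    "load_compound_targets",
    "load_ppi_edges",
    "normalize_symbol",
]


class ModelIOError(ValueError):
    """Raised on malformed input files or violated data invariants."""


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene identifier: strip surrounding whitespace, uppercase.

    Idempotent. Raises :class:`ModelIOError` on empty/blank input.
    """
    out = symbol.strip().upper()
    if not out:
        raise ModelIOError(f"empty gene symbol (from {symbol!r})")
    return out


@dataclass(frozen=True)
class CompoundRecord:
    """A chemical component with ADME properties.

    ``ob`` is oral bioavailability in percent (0-100), ``dl`` the
    drug-likeness index (0-1); either may be ``None`` when the source
    database reports no value. Missing values are retained as missing so
    downstream filters can fail closed.
    """

    compound_id: str
    name: str
    herbs: frozenset[str] = frozenset()
    ob: float | None = None
    dl: float | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ModelIOError("compound_id must be non-empty")
        if self.ob is not None and not (0.0 <= self.ob <= 100.0):
            raise ModelIOError(
                f"{self.compound_id}: ob={self.ob} outside [0, 100]"
            )
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise ModelIOError(f"{self.compound_id}: dl={self.dl} outside [0, 1]")

    def with_herbs(self, herbs: Iterable[str]) -> "CompoundRecord":
        return CompoundRecord(
            self.compound_id, self.name, frozenset(herbs), self.ob, self.dl
        )


class BipartiteNetwork:
    """Deduplicated compound <-> target edge set with adjacency views."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        seen: set[tuple[str, str]] = set()
        compound_index: dict[str, set[str]] = {}
        target_index: dict[str, set[str]] = {}
        for compound_id, gene in edges:
            pair = (compound_id, normalize_symbol(gene))
            if pair in seen:
                continue
            seen.add(pair)
            compound_index.setdefault(pair[0], set()).add(pair[1])
            target_index.setdefault(pair[1], set()).add(pair[0])
        self.edges: frozenset[tuple[str, str]] = frozenset(seen)
        self._compound_index = compound_index
        self._target_index = target_index

    @property
    def compounds(self) -> set[str]:
        return set(self._compound_index)

    @property
    def targets(self) -> set[str]:
        return set(self._target_index)

    def targets_of(self, compound_id: str) -> set[str]:
        return set(self._compound_index.get(compound_id, set()))

    def compounds_of(self, gene: str) -> set[str]:
        return set(self._target_index.get(gene, set()))

    def compound_degree(self, compound_id: str) -> int:
        return len(self._compound_index.get(compound_id, ()))

    def target_degree(self, gene: str) -> int:
        return len(self._target_index.get(gene, ()))

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BipartiteNetwork) and self.edges == other.edges

    def __hash__(self) -> int:
        return hash(self.edges)


@dataclass
class AnnotationSource:
    """One annotation database's term catalog for one category.

    ``terms`` maps term_id -> gene set; every term's genes must lie inside
    the declared ``universe`` (the background for over-representation
    tests).  ``category`` is one of BP, MF, CC or PATHWAY.
    """

    source_name: str
    category: str
    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    CATEGORIES = ("BP", "MF", "CC", "PATHWAY")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ModelIOError(
                f"category {self.category!r} not in {self.CATEGORIES}"
            )
        offenders = {
            term: sorted(genes - self.universe)
            for term, genes in self.terms.items()
            if not genes <= self.universe
        }
        if offenders:
            raise ModelIOError(
                f"{self.source_name}.{self.category}: genes outside declared "
                f"universe: {offenders}"
            )


@dataclass(frozen=True)
class PPINetwork:
    """Undirected protein-protein interaction network (no self-loops)."""

    nodes: frozenset[str]
    edges: frozenset[frozenset[str]]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "PPINetwork":
        nodes: set[str] = {normalize_symbol(n) for n in extra_nodes}
        out: set[frozenset[str]] = set()
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                raise ModelIOError(f"self-loop on {a} rejected")
            out.add(frozenset((a, b)))
            nodes.update((a, b))
        return cls(frozenset(nodes), frozenset(out))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(tuple(sorted(e)) for e in self.edges))
        return g

    def edge_pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.edges)


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ModelIOError(f"{path}: missing required column(s) {missing}")
    return df


def load_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read compounds.tsv (compound_id, name, ob, dl).

    Empty ob/dl cells become missing values; malformed numerics and
    duplicate compound_ids are errors. Herb memberships are supplied
    separately (see :func:`load_herb_compounds`).
    """
    df = _read_tsv(path, ("compound_id", "name", "ob", "dl"))
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cid = row.compound_id.strip()
        if cid in seen:
            raise ModelIOError(f"{path}: duplicate compound_id {cid!r} (row {i})")
        seen.add(cid)
        values: dict[str, float | None] = {}
        for col in ("ob", "dl"):
            cell = getattr(row, col).strip()
            if cell == "":
                values[col] = None
                continue
            try:
                values[col] = float(cell)
            except ValueError as exc:
                raise ModelIOError(
                    f"{path}: row {i}: cannot parse {col}={cell!r}"
                ) from exc
        records.append(
            CompoundRecord(cid, row.name.strip(), frozenset(), values["ob"], values["dl"])
        )
    return records


def load_herb_compounds(path: str | Path) -> dict[str, set[str]]:
    """Read herb_compounds.tsv (herb, compound_id) -> herb -> compound set."""
    df = _read_tsv(path, ("herb", "compound_id"))
    herb_map: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        herb_map.setdefault(row.herb.strip(), set()).add(row.compound_id.strip())
    return herb_map


def attach_herbs(
    records: list[CompoundRecord], herb_map: Mapping[str, Collection[str]]
) -> list[CompoundRecord]:
    """Return records with herb memberships filled in from a herb map."""
    by_compound: dict[str, set[str]] = {}
    for herb, cids in herb_map.items():
        for cid in cids:
            by_compound.setdefault(cid, set()).add(herb)
    return [r.with_herbs(by_compound.get(r.compound_id, set())) for r in records]


def load_compound_targets(path: str | Path) -> BipartiteNetwork:
    """Read compound_targets.tsv (compound_id, gene_symbol)."""
    df = _read_tsv(path, ("compound_id", "gene_symbol"))
    return BipartiteNetwork(
        (row.compound_id.strip(), row.gene_symbol)
        for row in df.itertuples(index=False)
    )


def load_gene_list(path: str | Path, allow_empty: bool = False) -> set[str]:
    """Read a one-symbol-per-line gene list; '#' lines are comments.

    An empty result is an error unless ``allow_empty`` is set, which
    distinguishes a truncated file from a legitimately empty set.
    """
    out: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.add(normalize_symbol(line))
    if not out and not allow_empty:
        raise ModelIOError(f"{path}: gene list is empty")
    return out


def load_gmt(
    path: str | Path,
    source_name: str,
    category: str,
    universe: Collection[str] | None = None,
) -> AnnotationSource:
    """Read a GMT file (term_id <tab> description <tab> gene ...).

    When ``universe`` is omitted it defaults to the union of all term gene
    sets; when given, genes outside it are an error (reported per term).
    """
    terms: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ModelIOError(
                f"{path}: line {lineno}: GMT record needs >=3 tab-separated "
                f"fields, got {len(fields)}"
            )
        term_id = fields[0].strip()
        if term_id in terms:
            raise ModelIOError(f"{path}: line {lineno}: duplicate term {term_id!r}")
        terms[term_id] = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
    if universe is None:
        uni = frozenset().union(*terms.values()) if terms else frozenset()
    else:
        uni = frozenset(normalize_symbol(g) for g in universe)
    return AnnotationSource(source_name, category, terms, uni)


def load_ppi_edges(path: str | Path) -> PPINetwork:
    """Read a PPI edge list TSV (gene_a, gene_b); self-loops rejected."""
    df = _read_tsv(path, ("gene_a", "gene_b"))
    return PPINetwork.from_edges(
        (row.gene_a, row.gene_b) for row in df.itertuples(index=False)
    )


# ---------------------------------------------------------------------------
# writers


def export_network(
    nodes: Iterable[str],
    edges: Iterable[tuple[str, str]],
    path: str | Path,
    fmt: str = "sif",
    relation: str = "pp",
) -> None:
    """Write a network as SIF, GraphML or a 2-column TSV edge list.

    SIF uses the relation token ``ct`` for compound-target edges and
    ``pp`` for protein-protein edges; isolated nodes get node-only SIF
    lines.  GraphML round-trips through :mod:`networkx`.
    """
    nodes = sorted(set(nodes))
    edge_list = sorted({(a, b) for a, b in edges})
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "sif":
        touched = {n for e in edge_list for n in e}
        with path.open("w", encoding="utf-8") as fh:
            for a, b in edge_list:
                fh.write(f"{a}\t{relation}\t{b}\n")
            for n in nodes:
                if n not in touched:
                    fh.write(f"{n}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edge_list, relation=relation)
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        with path.open("w", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["node_a", "node_b"])
            writer.writerows(edge_list)
    else:
        raise ModelIOError(f"unknown export format {fmt!r} (sif/graphml/tsv)")
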