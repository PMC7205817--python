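"""Seeded synthetic datasets with planted ground truth.

The generator emulates the *statistical shape* of the databases a
network-pharmacology screen consumes — a multi-herb formula with
overlapping compound sets, a heavy-tailed bipartite compound-target
network, a disease gene list with a controllable overlap with the
formula's targets, annotation sources with terms planted to be
over-represented among the intersection genes, and a sparse PPI network
with planted dense complexes — so that every downstream stage has a
parameter-recovery test without any database download.

Planted truth is explicit: designated top nuclear receptors appear in
planted enriched terms at strictly ordered rates (so their expected
cluster frequencies are ordered as configured); a designated
"super-compound" is wired to every planted top NR and passes the ADME
screen; planted PPI complexes are near-cliques containing designated NRs.

Every stage draws from its own RNG stream derived from the master seed,
so adding a stage never perturbs earlier stages and a fixed seed fully
determines all outputs.
"""

from __future__ import annotations

import json
from collections.abc import Collection, Sequence
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .model_io import (
    AnnotationSource,
    BipartiteNetwork,
    CompoundRecord,
    PPINetwork,
    attach_herbs,
)
from .nr_catalog import DEFAULT_NR_CATALOG

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_all",
    "simulate_annotations",
    "simulate_formula",
    "simulate_ppi",
    "write_dataset",
]

_HERB_NAMES = (
    "chaihu", "chenpi", "chuanxiong", "xiangfu", "zhiqiao", "baishao", "gancao",
)

# default planted top NRs with strictly ordered cluster-membership rates
_DEFAULT_PLANTED = (
    ("PPARG", 0.70),
    ("NR1H4", 0.50),
    ("PPARA", 0.35),
    ("RARA", 0.22),
    ("PPARD", 0.12),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data generator; the seed fixes everything."""

    seed: int = 0
    # formula
    n_herbs: int = 7
    compounds_per_herb: int = 40
    herb_overlap_fraction: float = 0.2
    n_targets: int = 300
    n_catalog_targets: int = 25  # catalog members placed on the formula target side
    target_degree_exponent: float = 1.0
    mean_targets_per_compound: float = 6.0
    n_disease_genes: int = 800
    disease_overlap_fraction: float = 0.5
    nr_catalog_size: int = 48
    planted_top_nrs: tuple[tuple[str, float], ...] = _DEFAULT_PLANTED
    planted_nr_support: int = 3  # extra single-NR compounds per planted NR
    super_compound: bool = True
    ob_range: tuple[float, float] = (0.0, 100.0)
    dl_range: tuple[float, float] = (0.0, 1.0)
    ob_dl_correlation: float = 0.0
    # annotation sources
    n_sources: int = 6
    categories: tuple[str, ...] = ("BP", "MF", "CC")
    terms_per_category: int = 40
    planted_enriched_terms: int = 8
    term_size_range: tuple[int, int] = (15, 25)
    planted_intersection_rate: float = 0.6
    universe_padding: int = 1000
    # PPI
    ppi_background_n: int = 250
    ppi_background_p: float = 0.02
    planted_complexes: tuple[tuple[int, tuple[str, ...]], ...] = (
        (12, ("PPARG",)),
        (8, ("PPARA",)),
        (6, ("NR1H4",)),
        (4, ("RARA",)),
    )
    complex_edge_dropout: float = 0.1

    def validate(self) -> None:
        for name in ("herb_overlap_fraction", "disease_overlap_fraction",
                     "planted_intersection_rate", "complex_edge_dropout",
                     "ppi_background_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_herbs < 1 or self.compounds_per_herb < 1:
            raise ValueError("need at least one herb with one compound")
        planted = [s for s, _ in self.planted_top_nrs]
        if len(set(planted)) != len(planted):
            raise ValueError("duplicate planted NR symbols")
        for _, rate in self.planted_top_nrs:
            if not (0.0 <= rate <= 1.0):
                raise ValueError("planted NR rates must lie in [0, 1]")
        if self.n_catalog_targets > min(self.nr_catalog_size, self.n_targets):
            raise ValueError(
                "n_catalog_targets exceeds catalog size or formula target pool"
            )
        if len(planted) > self.n_catalog_targets:
            raise ValueError("more planted NRs than catalog targets in the formula")
        if self.term_size_range[0] < 1 or self.term_size_range[0] > self.term_size_range[1]:
            raise ValueError(f"bad term_size_range {self.term_size_range}")
        for size, _members in self.planted_complexes:
            if size < 3:
                raise ValueError(f"planted complex size {size} < 3")
        n_support = len(planted) * self.planted_nr_support
        n_regular = self.n_herbs * self.compounds_per_herb
        if planted and n_support > n_regular:
            raise ValueError("planted_nr_support demands more compounds than exist")

    def nr_catalog(self) -> list[str]:
        catalog = list(DEFAULT_NR_CATALOG[: self.nr_catalog_size])
        for i in range(len(catalog), self.nr_catalog_size):
            catalog.append(f"NRX{i:03d}")
        return catalog


@dataclass
class SyntheticDataset:
    """One complete generated file set plus its planted ground truth."""

    config: SimulationConfig
    compounds: list[CompoundRecord]
    herb_map: dict[str, set[str]]
    bipartite: BipartiteNetwork
    disease_genes: set[str]
    nr_catalog: list[str]
    universe: set[str]
    sources: list[AnnotationSource]
    ppi: PPINetwork
    ground_truth: dict = field(default_factory=dict)

    @property
    def formula_targets(self) -> set[str]:
        return self.bipartite.targets

    @property
    def intersection(self) -> set[str]:
        return self.formula_targets & self.disease_genes


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def _weighted_sample(
    rng: np.random.Generator, items: Sequence[str], weights: np.ndarray, k: int
) -> list[str]:
    """k distinct items, probability proportional to weight (Efraimidis-Spirakis)."""
    k = min(k, len(items))
    keys = rng.random(len(items)) ** (1.0 / np.maximum(weights, 1e-12))
    idx = np.argsort(-keys)[:k]
    return [items[i] for i in idx]


def simulate_formula(config: SimulationConfig) -> SyntheticDataset:
    """Generate herbs, compounds, the compound-target network and gene lists.

    Returns a dataset with empty annotation/PPI slots (filled by
    :func:`simulate_all`).
    """
    config.validate()
    rng = _rng(config, 1)
    catalog = config.nr_catalog()
    planted = [s for s, _ in config.planted_top_nrs]

    # --- herbs and compounds -------------------------------------------------
    herbs = [
        _HERB_NAMES[i] if i < len(_HERB_NAMES) else f"herb{i + 1:02d}"
        for i in range(config.n_herbs)
    ]
    cpp = config.compounds_per_herb
    k_shared = int(round(config.herb_overlap_fraction * cpp))
    shared_pool = [f"C{i + 1:04d}" for i in range(cpp)]
    next_id = cpp + 1
    herb_map: dict[str, set[str]] = {}
    for herb in herbs:
        members: set[str] = set()
        if k_shared:
            members.update(
                rng.choice(shared_pool, size=k_shared, replace=False).tolist()
            )
        for _ in range(cpp - k_shared):
            members.add(f"C{next_id:04d}")
            next_id += 1
        herb_map[herb] = members
    compound_ids = sorted(set().union(*herb_map.values()))

    super_id = None
    if config.super_compound and planted:
        super_id = "C0000"
        for herb in rng.choice(herbs, size=min(2, len(herbs)), replace=False):
            herb_map[herb].add(super_id)
        compound_ids.append(super_id)
    compound_ids.sort()

    # --- ADME properties -----------------------------------------------------
    n = len(compound_ids)
    rho = config.ob_dl_correlation
    if rho:
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        from scipy.stats import norm  # Gaussian copula for the correlation knob

        u_ob, u_dl = norm.cdf(z[:, 0]), norm.cdf(z[:, 1])
    else:
        u_ob, u_dl = rng.random(n), rng.random(n)
    ob = config.ob_range[0] + u_ob * (config.ob_range[1] - config.ob_range[0])
    dl = config.dl_range[0] + u_dl * (config.dl_range[1] - config.dl_range[0])
    records = []
    for i, cid in enumerate(compound_ids):
        if cid == super_id:
            # planted to clear the default ADME thresholds decisively
            ob_i = float(np.clip(75.0, *config.ob_range))
            dl_i = float(np.clip(0.75, *config.dl_range))
        else:
            ob_i, dl_i = float(ob[i]), float(dl[i])
        records.append(CompoundRecord(cid, f"compound-{cid}", frozenset(), ob_i, dl_i))

    # --- target pool and bipartite edges ------------------------------------
    extra_catalog = [s for s in catalog if s not in planted][
        : config.n_catalog_targets - len(planted)
    ]
    n_generic = max(config.n_targets - len(planted) - len(extra_catalog), 0)
    generic = [f"T{i + 1:04d}" for i in range(n_generic)]
    pa_pool = sorted(extra_catalog + generic)  # planted NRs wired explicitly
    pa_index = {t: i for i, t in enumerate(pa_pool)}
    pa_deg = np.zeros(len(pa_pool))
    edges: set[tuple[str, str]] = set()
    regular = [c for c in compound_ids if c != super_id]
    for cid in regular:
        d = 1 + rng.poisson(max(config.mean_targets_per_compound - 1.0, 0.0))
        d = min(int(d), len(pa_pool))
        w = (pa_deg + 1.0) ** config.target_degree_exponent
        chosen = _weighted_sample(rng, pa_pool, w, d)
        for t in chosen:
            edges.add((cid, t))
            pa_deg[pa_index[t]] += 1

    # curated planted-NR wiring: the super-compound hits every planted NR,
    # and each planted NR gets `planted_nr_support` distinct single-NR compounds
    if planted:
        n_support = config.planted_nr_support * len(planted)
        support = (
            rng.choice(regular, size=n_support, replace=False).tolist()
            if n_support
            else []
        )
        for j, nr in enumerate(planted):
            if super_id:
                edges.add((super_id, nr))
            for cid in support[
                j * config.planted_nr_support : (j + 1) * config.planted_nr_support
            ]:
                edges.add((cid, nr))

    bipartite = BipartiteNetwork(edges)
    formula_targets = bipartite.targets

    # --- disease gene list ---------------------------------------------------
    n_overlap = int(round(config.disease_overlap_fraction * len(formula_targets)))
    if n_overlap > config.n_disease_genes:
        raise ValueError(
            f"disease overlap ({n_overlap}) exceeds n_disease_genes "
            f"({config.n_disease_genes}); infeasible config"
        )
    disease: set[str] = set()
    if n_overlap:
        forced = [nr for nr in planted if nr in formula_targets]
        forced = forced[:n_overlap]
        rest = sorted(formula_targets - set(forced))
        extra = rng.choice(rest, size=n_overlap - len(forced), replace=False).tolist()
        disease.update(forced)
        disease.update(extra)
    disease.update(f"D{i + 1:04d}" for i in range(config.n_disease_genes - n_overlap))

    ground_truth = {
        "planted_top_nrs": [list(t) for t in config.planted_top_nrs],
        "super_compound": super_id,
        "herbs": herbs,
        "shared_pool_size": len(shared_pool),
        "shared_draws_per_herb": k_shared,
    }
    records = attach_herbs(records, herb_map)
    return SyntheticDataset(
        config=config,
        compounds=records,
        herb_map=herb_map,
        bipartite=bipartite,
        disease_genes=disease,
        nr_catalog=catalog,
        universe=set(),
        sources=[],
        ppi=PPINetwork(frozenset(), frozenset()),
        ground_truth=ground_truth,
    )


def simulate_annotations(
    config: SimulationConfig,
    intersection_genes: Collection[str],
    universe: Collection[str],
) -> tuple[list[AnnotationSource], dict[str, list[str]]]:
    """Generate annotation sources with planted over-represented terms.

    Planted terms draw ``planted_intersection_rate`` of their members from
    the intersection genes (driving their hypergeometric p far below any
    sensible alpha) and include each planted top NR independently at its
    configured rate; background terms are uniform draws from the universe.
    Returns the sources and a map "source.category" -> planted term ids.
    """
    config.validate()
    rng = _rng(config, 2)
    universe = sorted({g for g in universe})
    inter = sorted(set(intersection_genes) & set(universe))
    uni_set = set(universe)
    if config.term_size_range[1] > len(universe):
        raise ValueError(
            f"term size up to {config.term_size_range[1]} exceeds universe "
            f"({len(universe)} genes)"
        )
    rates = [(nr, rate) for nr, rate in config.planted_top_nrs if nr in uni_set]
    sources: list[AnnotationSource] = []
    planted_ids: dict[str, list[str]] = {}
    lo, hi = config.term_size_range
    for s in range(config.n_sources):
        src = f"db{s + 1}"
        for cat in config.categories:
            terms: dict[str, frozenset[str]] = {}
            planted_here: list[str] = []
            n_planted = min(config.planted_enriched_terms, config.terms_per_category)
            for i in range(config.terms_per_category):
                term_id = f"{src}.{cat}.t{i + 1:04d}"
                size = int(rng.integers(lo, hi + 1))
                if i < n_planted and inter:
                    members: set[str] = set()
                    for nr, rate in rates:
                        if nr in inter and rng.random() < rate:
                            members.add(nr)
                    n_int = min(int(round(config.planted_intersection_rate * size)),
                                len(inter))
                    members.update(
                        rng.choice(inter, size=n_int, replace=False).tolist()
                    )
                    fill = sorted(uni_set - members)
                    n_fill = min(max(size - len(members), 0), len(fill))
                    members.update(
                        rng.choice(fill, size=n_fill, replace=False).tolist()
                    )
                    planted_here.append(term_id)
                else:
                    members = set(
                        rng.choice(universe, size=size, replace=False).tolist()
                    )
                terms[term_id] = frozenset(members)
            sources.append(AnnotationSource(src, cat, terms, frozenset(universe)))
            planted_ids[f"{src}.{cat}"] = planted_here
    return sources, planted_ids


def simulate_ppi(
    config: SimulationConfig,
    gene_pool: Collection[str],
) -> tuple[PPINetwork, list[list[str]]]:
    """Background G(n, p) over genes from ``gene_pool`` plus planted near-cliques.

    Each planted complex is a clique on its members (designated NRs plus
    random fill from the pool) minus a ``complex_edge_dropout`` fraction
    of its edges. Returns the network and the planted member lists.
    """
    config.validate()
    rng = _rng(config, 3)
    pool = sorted(set(gene_pool))
    if not pool:
        raise ValueError("empty gene pool for PPI simulation")

    used: set[str] = set()
    complexes: list[list[str]] = []
    for size, fixed in config.planted_complexes:
        if size > len(pool):
            raise ValueError(f"planted complex size {size} exceeds pool ({len(pool)})")
        members = [m for m in fixed]
        missing = sorted(set(members) - set(pool))
        if missing:
            raise ValueError(f"planted complex members not in gene pool: {missing}")
        avail = sorted(set(pool) - used - set(members))
        fill = rng.choice(avail, size=size - len(members), replace=False).tolist()
        members = sorted(set(members) | set(fill))
        used.update(members)
        complexes.append(members)

    n_bg = min(config.ppi_background_n, len(pool))
    nodes = set(used)
    remaining = sorted(set(pool) - nodes)
    if len(nodes) < n_bg:
        nodes.update(
            rng.choice(remaining, size=n_bg - len(nodes), replace=False).tolist()
        )
    node_list = sorted(nodes)

    edges: set[frozenset[str]] = set()
    m = len(node_list)
    if m >= 2 and config.ppi_background_p > 0:
        iu, ju = np.triu_indices(m, k=1)
        mask = rng.random(len(iu)) < config.ppi_background_p
        for a, b in zip(iu[mask], ju[mask]):
            edges.add(frozenset((node_list[a], node_list[b])))

    for members in complexes:
        pairs = [
            frozenset((members[i], members[j]))
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
        n_drop = int(np.floor(config.complex_edge_dropout * len(pairs)))
        drop_idx = set(
            rng.choice(len(pairs), size=n_drop, replace=False).tolist()
        ) if n_drop else set()
        for idx, pair in enumerate(pairs):
            if idx in drop_idx:
                edges.discard(pair)
            else:
                edges.add(pair)

    ppi = PPINetwork(frozenset(node_list), frozenset(edges))
    return ppi, complexes


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Run all generator stages and assemble a complete dataset."""
    ds = simulate_formula(config)
    inter = ds.intersection
    padding = {f"U{i + 1:04d}" for i in range(config.universe_padding)}
    ds.universe = ds.formula_targets | ds.disease_genes | padding
    ds.sources, planted_ids = simulate_annotations(config, inter, ds.universe)
    ds.ground_truth["planted_terms"] = planted_ids

    fixed = {m for _, members in config.planted_complexes for m in members}
    pool = inter if fixed <= inter and inter else (inter | ds.formula_targets)
    ds.ppi, planted_complexes = simulate_ppi(config, pool)
    ds.ground_truth["planted_complexes"] = planted_complexes
    return ds


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the full model_io file set plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with (out / "compounds.tsv").open("w", encoding="utf-8") as fh:
        fh.write("compound_id\tname\tob\tdl\n")
        for r in ds.compounds:
            ob = "" if r.ob is None else f"{r.ob:.6g}"
            dl = "" if r.dl is None else f"{r.dl:.6g}"
            fh.write(f"{r.compound_id}\t{r.name}\t{ob}\t{dl}\n")

    with (out / "herb_compounds.tsv").open("w", encoding="utf-8") as fh:
        fh.write("herb\tcompound_id\n")
        for herb in sorted(ds.herb_map):
            for cid in sorted(ds.herb_map[herb]):
                fh.write(f"{herb}\t{cid}\n")

    with (out / "compound_targets.tsv").open("w", encoding="utf-8") as fh:
        fh.write("compound_id\tgene_symbol\n")
        for cid, gene in sorted(ds.bipartite.edges):
            fh.write(f"{cid}\t{gene}\n")

    for name, genes in (
        ("disease_genes.txt", ds.disease_genes),
        ("nr_catalog.txt", ds.nr_catalog),
        ("universe.txt", ds.universe),
    ):
        (out / name).write_text(
            "\n".join(sorted(genes)) + "\n", encoding="utf-8"
        )

    gmt_dir = out / "gmt"
    gmt_dir.mkdir(exist_ok=True)
    for source in ds.sources:
        path = gmt_dir / f"{source.source_name}.{source.category}.gmt"
        with path.open("w", encoding="utf-8") as fh:
            for term_id in sorted(source.terms):
                genes = "\t".join(sorted(source.terms[term_id]))
                fh.write(f"{term_id}\tsynthetic term\t{genes}\n")

    with (out / "ppi_edges.tsv").open("w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in ds.ppi.edge_pairs():
            fh.write(f"{a}\t{b}\n")

    truth = dict(ds.ground_truth)
    truth["config"] = asdict(ds.config)
    (out / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, default=list) + "\n", encoding="utf-8"
    )
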