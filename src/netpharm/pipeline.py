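"""End-to-end screen orchestration.

``run_screen`` composes the stages in order: target intersection ->
per-source enrichment -> top-cluster selection -> cluster-frequency
ranking -> top-k targets -> (in parallel, as supporting evidence) MCODE
on the PPI restricted to intersection genes -> ADME filter -> compound
frequency -> herb attribution. MCODE complex membership is reported as
corroborating evidence and never alters the frequency ranking.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import model_io
from .enrichment import EnrichmentCluster, enrich_source, select_top_clusters
from .intersection import (
    HerbContributions,
    IntersectionResult,
    build_intersection_result,
    per_herb_contributions,
)
from .mcode import MCODEComplex, MCODEParams, find_complexes
from .model_io import BipartiteNetwork, CompoundRecord, PPINetwork
from .nr_catalog import DEFAULT_NR_CATALOG
from .screening import (
    ScreeningResult,
    adme_filter,
    compound_frequency,
    herb_attribution,
)
from .synthetic import SimulationConfig, SyntheticDataset, simulate_all
from .target_ranking import FrequencyRanking, cluster_frequency, top_k_targets

__all__ = [
    "InputData",
    "NoCandidatesError",
    "PipelineConfig",
    "RunResult",
    "ValidationError",
    "load_input_dir",
    "run_screen",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Configuration or input validation failure (CLI exit code 2)."""


class NoCandidatesError(RuntimeError):
    """Empty intersection: nothing to screen (CLI exit code 3)."""


@dataclass
class InputData:
    """Everything one screen consumes, already parsed."""

    compounds: list[CompoundRecord]
    herb_map: dict[str, set[str]]
    bipartite: BipartiteNetwork
    disease_genes: set[str]
    nr_catalog: list[str]
    sources: list[model_io.AnnotationSource]
    ppi: PPINetwork
    digests: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_synthetic(cls, ds: SyntheticDataset) -> "InputData":
        return cls(
            compounds=ds.compounds,
            herb_map=ds.herb_map,
            bipartite=ds.bipartite,
            disease_genes=ds.disease_genes,
            nr_catalog=ds.nr_catalog,
            sources=ds.sources,
            ppi=ds.ppi,
            digests={"synthetic_seed": str(ds.config.seed)},
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_input_dir(path: str | Path) -> InputData:
    """Load the standard file set (as written by ``write_dataset``) from a directory."""
    root = Path(path)
    required = ["compounds.tsv", "herb_compounds.tsv", "compound_targets.tsv",
                "disease_genes.txt", "nr_catalog.txt"]
    missing = [f for f in required if not (root / f).exists()]
    if missing:
        raise ValidationError(f"{root}: missing input file(s) {missing}")
    records = model_io.load_compound_table(root / "compounds.tsv")
    herb_map = model_io.load_herb_compounds(root / "herb_compounds.tsv")
    records = model_io.attach_herbs(records, herb_map)
    bipartite = model_io.load_compound_targets(root / "compound_targets.tsv")
    disease = model_io.load_gene_list(root / "disease_genes.txt")
    catalog = sorted(model_io.load_gene_list(root / "nr_catalog.txt"))
    universe = None
    if (root / "universe.txt").exists():
        universe = model_io.load_gene_list(root / "universe.txt")
    gmt_dir = root / "gmt" if (root / "gmt").is_dir() else root
    sources = []
    for gmt in sorted(gmt_dir.glob("*.gmt")):
        parts = gmt.stem.rsplit(".", 1)
        if len(parts) != 2:
            raise ValidationError(
                f"{gmt}: GMT files must be named <source>.<category>.gmt"
            )
        sources.append(model_io.load_gmt(gmt, parts[0], parts[1], universe))
    ppi = (
        model_io.load_ppi_edges(root / "ppi_edges.tsv")
        if (root / "ppi_edges.tsv").exists()
        else PPINetwork(frozenset(), frozenset())
    )
    digests = {f: _digest(root / f) for f in required}
    return InputData(records, herb_map, bipartite, disease, catalog, sources,
                     ppi, digests)


@dataclass
class PipelineConfig:
    """All pipeline-level constants of one screen."""

    input_dir: str | None = None
    out_dir: str | None = None
    seed: int = 0
    simulate: bool = False
    sim: SimulationConfig | None = None
    top_k_clusters: int = 30
    alpha: float = 0.05
    top_k_targets: int = 5
    top_k_compounds: int = 5
    ob_min: float = 30.0
    dl_min: float = 0.18
    rank_all_candidates: bool = False
    run_mcode: bool = True
    mcode: MCODEParams = field(default_factory=MCODEParams)

    def validate(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError(f"alpha={self.alpha} outside (0, 1]")
        for name in ("top_k_clusters", "top_k_targets", "top_k_compounds"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0.0 <= self.ob_min <= 100.0):
            raise ValidationError(f"ob_min={self.ob_min} outside [0, 100]")
        if not (0.0 <= self.dl_min <= 1.0):
            raise ValidationError(f"dl_min={self.dl_min} outside [0, 1]")
        if not self.simulate:
            if self.input_dir is None:
                raise ValidationError("either input_dir or simulate is required")
            if not Path(self.input_dir).is_dir():
                raise ValidationError(f"input_dir {self.input_dir} does not exist")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        """Build from a flat key-value mapping; ``sim_*`` keys feed the
        simulator, ``mcode_*`` keys the MCODE parameters."""
        raw = dict(raw)
        sim_kwargs = {
            k[4:]: v for k, v in raw.items() if k.startswith("sim_")
        }
        mcode_kwargs = {
            k[6:]: v for k, v in raw.items() if k.startswith("mcode_")
        }
        top = {
            k: v
            for k, v in raw.items()
            if not k.startswith(("sim_", "mcode_"))
        }
        known = {f.name for f in dataclasses.fields(cls)} - {"sim", "mcode"}
        unknown = set(top) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**top)
        if sim_kwargs or cfg.simulate:
            sim_kwargs.setdefault("seed", cfg.seed)
            try:
                cfg.sim = SimulationConfig(**sim_kwargs)
            except TypeError as exc:
                raise ValidationError(str(exc)) from exc
        if mcode_kwargs:
            try:
                cfg.mcode = MCODEParams(**mcode_kwargs)
            except TypeError as exc:
                raise ValidationError(str(exc)) from exc
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a flat mapping")
        return cls.from_dict(raw)


@dataclass
class RunResult:
    """Full output of one screen, serializable to JSON."""

    intersection: IntersectionResult
    contributions: HerbContributions
    n_clusters_tested: int
    selected_clusters: list[EnrichmentCluster]
    ranking: FrequencyRanking
    complexes: list[MCODEComplex]
    complex_membership: dict[str, list[int]]
    screening: ScreeningResult
    sizes: dict[str, int]

    def to_dict(self) -> dict[str, Any]:
        return {
            "sizes": self.sizes,
            "cn_targets": sorted(self.intersection.cn_targets),
            "nr_targets": sorted(self.intersection.nr_targets),
            "cn_edge_count": self.intersection.cn_edge_count,
            "nr_edge_count": self.intersection.nr_edge_count,
            "per_herb_compounds": self.contributions.per_herb_compounds,
            "per_herb_targets": self.contributions.per_herb_targets,
            "per_herb_cn_targets": self.contributions.per_herb_restricted_targets,
            "upset_counts": {
                "+".join(k): v
                for k, v in sorted(self.contributions.exclusive_compounds.items())
            },
            "n_clusters_tested": self.n_clusters_tested,
            "n_clusters_selected": len(self.selected_clusters),
            "frequency_ranking": [list(t) for t in self.ranking.ranked],
            "complexes": [
                {
                    "rank": i + 1,
                    "seed": c.seed,
                    "n": c.n,
                    "e": c.e,
                    "density": round(c.density, 6),
                    "score": round(c.score, 3),
                    "members": sorted(c.members),
                }
                for i, c in enumerate(self.complexes)
            ],
            "complex_membership": self.complex_membership,
            "screening": self.screening.to_dict(),
        }


def run_screen(
    config: PipelineConfig,
    data: InputData | None = None,
    write: bool = True,
) -> RunResult:
    """Execute the full screen; raises :class:`NoCandidatesError` on an
    empty intersection and stage-labelled errors otherwise."""
    config.validate()
    if data is None:
        if config.simulate:
            sim = config.sim or SimulationConfig(seed=config.seed)
            data = InputData.from_synthetic(simulate_all(sim))
        else:
            data = load_input_dir(config.input_dir)

    def stage(name: str):
        logger.info("stage: %s", name)

    stage("intersect")
    inter = build_intersection_result(
        data.bipartite.targets, data.disease_genes, data.nr_catalog, data.bipartite
    )
    if not inter.cn_targets:
        raise NoCandidatesError(
            "formula targets and disease genes do not intersect; no candidates"
        )
    contributions = per_herb_contributions(
        data.herb_map, data.bipartite, inter.cn_targets
    )

    stage("enrich")
    if not data.sources:
        raise ValidationError("enrich: no annotation sources supplied")
    clusters: list[EnrichmentCluster] = []
    for source in data.sources:
        clusters.extend(enrich_source(inter.cn_targets, source))
    selected = select_top_clusters(clusters, config.top_k_clusters, config.alpha)
    if not selected:
        raise NoCandidatesError("no significant clusters selected")

    stage("rank-targets")
    candidates = (
        inter.cn_targets if config.rank_all_candidates else inter.nr_targets
    )
    if not candidates:
        raise NoCandidatesError("no catalog candidates in the intersection")
    ranking = cluster_frequency(selected, candidates)
    tops = top_k_targets(ranking, config.top_k_targets)

    stage("mcode")
    complexes: list[MCODEComplex] = []
    membership: dict[str, list[int]] = {t: [] for t in tops}
    if config.run_mcode and data.ppi.edges:
        graph = data.ppi.to_networkx().subgraph(
            data.ppi.nodes & inter.cn_targets
        ).copy()
        complexes = find_complexes(graph, config.mcode)
        for i, c in enumerate(complexes):
            for t in tops:
                if t in c.members:
                    membership[t].append(i + 1)

    stage("screen-compounds")
    adme_pass = adme_filter(data.compounds, config.ob_min, config.dl_min)
    if not adme_pass:
        raise ValidationError(
            "screen-compounds: no compounds pass ADME; review ob_min/dl_min"
        )
    crank = compound_frequency(tops, data.bipartite, adme_pass, inter.cn_targets)
    top_compounds = [c for c, _ in crank.ranked[: config.top_k_compounds]]
    attribution = herb_attribution(top_compounds, data.herb_map)

    screening = ScreeningResult(
        cn_targets=sorted(inter.cn_targets),
        nr_targets=sorted(inter.nr_targets),
        top_targets=[(t, ranking.counts[t]) for t in tops],
        adme_pass=sorted(adme_pass),
        compound_counts=crank.counts,
        top_compounds=top_compounds,
        uncovered_targets=crank.uncovered_targets,
        herb_attribution={c: h for c, h in attribution.items()},
        provenance={
            "parameters": {
                "top_k_clusters": config.top_k_clusters,
                "alpha": config.alpha,
                "top_k_targets": config.top_k_targets,
                "top_k_compounds": config.top_k_compounds,
                "ob_min": config.ob_min,
                "dl_min": config.dl_min,
                "mcode": dataclasses.asdict(config.mcode),
                "seed": config.seed,
            },
            "input_digests": data.digests,
        },
    )
    result = RunResult(
        intersection=inter,
        contributions=contributions,
        n_clusters_tested=len(clusters),
        selected_clusters=selected,
        ranking=ranking,
        complexes=complexes,
        complex_membership=membership,
        screening=screening,
        sizes={
            "formula_compounds": len(data.bipartite.compounds),
            "formula_targets": len(data.bipartite.targets),
            "disease_genes": len(data.disease_genes),
            "cn_targets": len(inter.cn_targets),
            "nr_targets": len(inter.nr_targets),
            "nr_catalog": len(data.nr_catalog),
        },
    )
    if write and config.out_dir:
        write_outputs(result, config.out_dir)
    return result


def write_outputs(result: RunResult, out_dir: str | Path) -> None:
    """Serialize every intermediate table, the JSON result and the report."""
    from .report import make_report

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def gene_list(name: str, genes) -> None:
        (out / name).write_text("\n".join(sorted(genes)) + "\n", encoding="utf-8")

    gene_list("cn_targets.tsv", result.intersection.cn_targets)
    gene_list("nr_targets.tsv", result.intersection.nr_targets)
    gene_list("cn_compounds.tsv", result.intersection.cn_compounds)

    with (out / "per_herb_counts.tsv").open("w", encoding="utf-8") as fh:
        fh.write("herb\tcompounds\ttargets\tcn_targets\n")
        for herb in sorted(result.contributions.per_herb_compounds):
            fh.write(
                f"{herb}\t{result.contributions.per_herb_compounds[herb]}"
                f"\t{result.contributions.per_herb_targets[herb]}"
                f"\t{result.contributions.per_herb_restricted_targets[herb]}\n"
            )
    with (out / "upset_counts.tsv").open("w", encoding="utf-8") as fh:
        fh.write("herb_combination\texclusive_compounds\n")
        for combo, n in sorted(result.contributions.exclusive_compounds.items()):
            fh.write(f"{'+'.join(combo)}\t{n}\n")

    with (out / "clusters.tsv").open("w", encoding="utf-8") as fh:
        fh.write("source\tcategory\tterm_id\tN\tK\tM\tk\tp\tp_adj\tmembers\n")
        for c in result.selected_clusters:
            t = c.test
            fh.write(
                f"{c.source_name}\t{c.category}\t{c.term_id}\t{t.N}\t{t.K}\t{t.M}"
                f"\t{t.k}\t{t.p:.6g}\t{t.p_adj:.6g}\t{';'.join(sorted(c.members))}\n"
            )

    with (out / "ranking.tsv").open("w", encoding="utf-8") as fh:
        fh.write("gene\tcount\trank\n")
        for i, (g, n) in enumerate(result.ranking.ranked, start=1):
            fh.write(f"{g}\t{n}\t{i}\n")

    with (out / "complexes.tsv").open("w", encoding="utf-8") as fh:
        fh.write("complex_id\tseed\tn\te\tdensity\tscore\tmembers\n")
        for i, c in enumerate(result.complexes, start=1):
            fh.write(
                f"{i}\t{c.seed}\t{c.n}\t{c.e}\t{c.density:.6g}\t{c.score:.3f}"
                f"\t{';'.join(sorted(c.members))}\n"
            )

    gene_list("adme_pass.tsv", result.screening.adme_pass)
    with (out / "compound_ranking.tsv").open("w", encoding="utf-8") as fh:
        fh.write("compound_id\ttop_target_count\n")
        for c, n in sorted(
            result.screening.compound_counts.items(), key=lambda kv: (-kv[1], kv[0])
        ):
            fh.write(f"{c}\t{n}\n")

    (out / "run_result.json").write_text(
        json.dumps(result.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    (out / "screening_result.json").write_text(
        json.dumps(result.screening.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    (out / "report.md").write_text(make_report(result), encoding="utf-8")
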