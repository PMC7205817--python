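"""ADME compound filtering and top-target frequency ranking of compounds.

Compounds pass the ADME screen when oral bioavailability strictly exceeds
``ob_min`` (percent) and drug-likeness strictly exceeds ``dl_min``;
records with either property missing fail closed. Passing compounds are
then ranked by how many of the top-ranked targets they hit, and the final
top-k compounds are attributed back to their source herbs.
"""

from __future__ import annotations

import logging
from collections.abc import Collection, Mapping, Sequence
from dataclasses import dataclass, field
from typing import Any

from .model_io import BipartiteNetwork, CompoundRecord

__all__ = [
    "ScreeningResult",
    "adme_filter",
    "compound_frequency",
    "herb_attribution",
]

logger = logging.getLogger(__name__)


def adme_filter(
    compounds: Collection[CompoundRecord],
    ob_min: float = 30.0,
    dl_min: float = 0.18,
) -> set[str]:
    """Compound ids with ob > ob_min and dl > dl_min (missing values fail)."""
    return {
        c.compound_id
        for c in compounds
        if c.ob is not None and c.dl is not None and c.ob > ob_min and c.dl > dl_min
    }


@dataclass
class CompoundRanking:
    counts: dict[str, int]
    ranked: list[tuple[str, int]]
    uncovered_targets: list[str]


def compound_frequency(
    top_targets: Sequence[str],
    bipartite: BipartiteNetwork,
    adme_pass: Collection[str],
    cn_targets: Collection[str] | None = None,
) -> CompoundRanking:
    """Rank ADME-passing compounds by the number of distinct top targets they hit.

    Ties are broken by higher total degree into ``cn_targets`` (the
    disease-intersection target set; full target degree when omitted),
    then lexicographic compound id. Top targets reached by no passing
    compound are reported as uncovered rather than erased — an ADME
    screen can legitimately strip all compounds from a target.
    """
    if not top_targets:
        raise ValueError("top_targets is empty")
    if not adme_pass:
        raise ValueError(
            "no compounds pass the ADME screen; review ob_min/dl_min thresholds"
        )
    tops = list(dict.fromkeys(top_targets))
    passing = set(adme_pass)
    counts: dict[str, int] = {c: 0 for c in passing}
    for t in tops:
        for c in bipartite.compounds_of(t):
            if c in passing:
                counts[c] += 1
    cn = set(cn_targets) if cn_targets is not None else None

    def cn_degree(c: str) -> int:
        targets = bipartite.targets_of(c)
        return len(targets & cn) if cn is not None else len(targets)

    ranked = sorted(
        ((c, n) for c, n in counts.items() if n > 0),
        key=lambda kv: (-kv[1], -cn_degree(kv[0]), kv[0]),
    )
    uncovered = sorted(
        t for t in tops if not (bipartite.compounds_of(t) & passing)
    )
    if uncovered:
        logger.info("top targets with no ADME-passing compound: %s", uncovered)
    return CompoundRanking(counts=counts, ranked=ranked, uncovered_targets=uncovered)


def herb_attribution(
    top_compounds: Sequence[str], herb_map: Mapping[str, Collection[str]]
) -> dict[str, set[str]]:
    """Map each top compound to every herb containing it; uncovered -> error."""
    by_compound: dict[str, set[str]] = {}
    for herb, cids in herb_map.items():
        for cid in cids:
            by_compound.setdefault(cid, set()).add(herb)
    missing = [c for c in top_compounds if c not in by_compound]
    if missing:
        raise ValueError(f"compounds absent from herb map: {missing}")
    return {c: set(by_compound[c]) for c in top_compounds}


@dataclass
class ScreeningResult:
    """End-to-end provenance of one screen."""

    cn_targets: list[str]
    nr_targets: list[str]
    top_targets: list[tuple[str, int]]
    adme_pass: list[str]
    compound_counts: dict[str, int]
    top_compounds: list[str]
    uncovered_targets: list[str]
    herb_attribution: dict[str, list[str]]
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "cn_targets": sorted(self.cn_targets),
            "nr_targets": sorted(self.nr_targets),
            "top_targets": [list(t) for t in self.top_targets],
            "adme_pass": sorted(self.adme_pass),
            "compound_counts": dict(sorted(self.compound_counts.items())),
            "top_compounds": list(self.top_compounds),
            "uncovered_targets": list(self.uncovered_targets),
            "herb_attribution": {
                c: sorted(h) for c, h in sorted(self.herb_attribution.items())
            },
            "provenance": self.provenance,
        }
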