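"""Human-readable markdown report of one screen.

Every number printed here is recomputed from the serialized result
object; the report performs no arithmetic of its own beyond formatting
count ratios as percentages.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import RunResult

__all__ = ["make_report", "percent"]


def percent(numerator: int | float, denominator: int | float, decimals: int = 2) -> float:
    """``100 * numerator / denominator`` rounded to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def _pct_cell(n: int, d: int) -> str:
    return f"{percent(n, d, 2):.2f}% ({percent(n, d, 1):.1f}%)"


def make_report(result: "RunResult") -> str:
    """Render the screen as markdown; percentages shown to 2 d.p. with the
    coarser 1 d.p. rendering in parentheses."""
    s = result.sizes
    lines: list[str] = []
    add = lines.append
    add("# Screening report\n")

    add("## Candidate space\n")
    add("| quantity | count | of formula targets | of disease genes | of catalog |")
    add("|---|---|---|---|---|")
    add(
        f"| intersection targets | {s['cn_targets']} "
        f"| {_pct_cell(s['cn_targets'], s['formula_targets'])} "
        f"| {_pct_cell(s['cn_targets'], s['disease_genes'])} | — |"
    )
    add(
        f"| catalog (NR) targets | {s['nr_targets']} "
        f"| {_pct_cell(s['nr_targets'], s['formula_targets'])} "
        f"| {_pct_cell(s['nr_targets'], s['disease_genes'])} "
        f"| {_pct_cell(s['nr_targets'], s['nr_catalog'])} |"
    )
    add(
        f"\nFormula: {s['formula_compounds']} compounds, "
        f"{s['formula_targets']} targets; disease list: {s['disease_genes']} genes; "
        f"restricted edge counts: {result.intersection.cn_edge_count} (intersection), "
        f"{result.intersection.nr_edge_count} (catalog).\n"
    )

    add("## Per-herb contributions\n")
    add("| herb | compounds | targets | intersection targets |")
    add("|---|---|---|---|")
    for herb in sorted(result.contributions.per_herb_compounds):
        add(
            f"| {herb} | {result.contributions.per_herb_compounds[herb]} "
            f"| {result.contributions.per_herb_targets[herb]} "
            f"| {result.contributions.per_herb_restricted_targets[herb]} |"
        )
    add(f"\nPooled compounds: {result.contributions.pooled_compounds}\n")

    add("## Cluster-frequency ranking\n")
    add(
        f"{result.n_clusters_tested} clusters tested, "
        f"{len(result.selected_clusters)} selected "
        f"(frequencies counted over the selected clusters).\n"
    )
    add("| rank | gene | clusters containing it |")
    add("|---|---|---|")
    for i, (g, n) in enumerate(result.ranking.ranked[:10], start=1):
        add(f"| {i} | {g} | {n} |")
    add("")

    add("## MCODE complexes\n")
    if result.complexes:
        add("| complex | n | e | score |")
        add("|---|---|---|---|")
        for i, c in enumerate(result.complexes, start=1):
            add(f"| {i} | {c.n} | {c.e} | {c.score:.3f} |")
        add("")
        for target, ids in sorted(result.complex_membership.items()):
            where = ", ".join(str(i) for i in ids) if ids else "none"
            add(f"- {target}: complex {where}")
        add("")
    else:
        add("none found\n")

    add("## ADME screen and top compounds\n")
    add(f"{len(result.screening.adme_pass)} compounds pass the ADME thresholds.")
    if result.screening.uncovered_targets:
        add(
            "Top targets with no passing compound: "
            + ", ".join(result.screening.uncovered_targets)
        )
    add("")
    add("| compound | top targets hit | herbs |")
    add("|---|---|---|")
    for c in result.screening.top_compounds:
        herbs = ", ".join(sorted(result.screening.herb_attribution[c]))
        add(f"| {c} | {result.screening.compound_counts[c]} | {herbs} |")
    add("")
    return "\n".join(lines)
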