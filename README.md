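# netpharm

Network-pharmacology screening of nuclear-receptor (NR) targets and herbal
compounds, as used to nominate candidate targets and active components of
multi-herb formulas against complex diseases such as non-alcoholic fatty
liver disease. The package turns the usual chain of web-database lookups
into a tested, file-based, fully reproducible pipeline, and ships a seeded
synthetic-data generator with planted ground truth so every stage has a
parameter-recovery test without any database access.

## What it computes

Given a compound table with ADME properties, a herb→compound map, a
compound→target edge list, a disease gene list, an NR catalog (48 human
nuclear receptors by default), GMT annotation sources and a PPI edge list:

1. **Intersection** — candidate targets C&N = formula targets ∩ disease
   genes; NR candidates = C&N ∩ catalog; per-herb and UpSet-style
   exclusive herb-combination compound counts.
2. **Enrichment** — per (source, category) over-representation analysis
   with the upper-tail hypergeometric test
   `p = Σ_{i≥k} C(K,i)·C(N−K,M−i)/C(N,M)`
   (N universe, K term size, M query size, k overlap), BH-adjusted within
   each group; the top 30 clusters per group (unadjusted p < 0.05) are kept.
3. **Target ranking** — each selected cluster votes once for every NR
   candidate it contains; candidates are ranked by vote count and the top
   5 taken.
4. **MCODE** — a native implementation of molecular-complex detection on
   the PPI restricted to C&N: vertices weighted by (density of the highest
   k-core of their closed neighborhood) × k, complexes grown from
   high-weight seeds within the vertex-weight-percentage tolerance
   (default 0.2), post-processed with a 2-core filter and haircut. A
   complex with n nodes and e edges scores `2e/(n−1)`. Complex membership
   corroborates the ranking but never alters it.
5. **Compound screening** — ADME filter (oral bioavailability > 30 %,
   drug-likeness > 0.18, strict, missing values fail), then compounds
   ranked by how many top targets they hit; top 5 compounds attributed
   back to their herbs.

## Worked example

Run the full screen on the default synthetic dataset (7 herbs × 40
compounds, 300-gene target pool, 800 disease genes at 50 % overlap, 6
annotation sources × BP/MF/CC with planted enriched terms, PPI with four
planted complexes):

```sh
netpharm run --simulate --seed 1 --out demo/
```

prints

```
top targets: PPARG, NR1H4, PPARA, RARA, PPARD | top compounds: C0000, C0221, C0143, C0112, C0180
```

i.e. the screen recovers the five planted NRs in their planted order, and
the planted "super-compound" C0000 (wired to all five NRs and passing
ADME) ranks first. `demo/report.md` contains the full accounting, e.g.
the MCODE complex table

```
| complex | n  | e  | score  |
|---------|----|----|--------|
| 1       | 11 | 52 | 10.400 |
| 2       | 8  | 26 | 7.429  |
| 3       | 6  | 14 | 5.600  |
| 4       | 4  | 6  | 4.000  |
```

with PPARG/PPARA/NR1H4/RARA each falling in one complex and PPARD in none
— the complexes corroborate four of the five top targets. All
intermediate tables (`cn_targets.tsv`, `clusters.tsv`, `ranking.tsv`,
`complexes.tsv`, `adme_pass.tsv`, …) are written next to the report.

Each stage is also available on its own: `netpharm simulate | intersect |
enrich | rank-targets | mcode | screen-compounds | report` (exit codes:
0 success, 2 validation failure, 3 empty candidate set), and everything
is importable as a library (`from netpharm import run_screen, ...`).

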