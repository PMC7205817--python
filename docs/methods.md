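# Methods

## The screening model

The pipeline operationalizes a common network-pharmacology strategy for
multi-herb formulas: a formula is modeled as a bipartite compound–target
network, the disease as a gene list, and candidate targets as their
intersection (C&N). Because a single enrichment service's ranking is
sensitive to its database snapshot and statistics, the screen aggregates
*several* annotation sources: each (source, category) group is scored
independently, only its 30 most significant terms survive, and a
candidate's final rank is the number of surviving clusters that contain
it. This cluster-frequency statistic deliberately ignores p-value
magnitudes beyond the selection step — a candidate recurring across many
moderately significant clusters outranks one sitting in a single extreme
cluster — which is what makes the aggregation robust across
heterogeneous sources. p-value magnitude re-enters only as a tie-break
(summed −log10 p over containing clusters, then symbol).

Candidates are restricted to the 48-gene human nuclear-receptor catalog
by default (`rank_all_candidates` lifts the restriction). The compound
side mirrors the target side: ADME-passing compounds are ranked by how
many of the top-k targets they hit.

### Enrichment statistic

Every term is tested with the upper-tail hypergeometric probability
against the source's *declared* universe, never against the query's
parent set, so p-values are reproducible from the files alone. BH
adjustment runs within each (source, category) over all tested terms
(including zero-overlap terms at p = 1), so adjusted values do not
depend on which terms happen to intersect the query. Selection orders by
unadjusted p (with lexicographic term-id tie-break at the cutoff);
adjusted values are reported alongside. The six heterogeneous services
of the original workflow are modeled as six `AnnotationSource` inputs
scored with this single uniform statistic; reproducing each service's
proprietary variant is a non-goal, since the aggregation step consumes
only per-source rankings.

Hypergeometric p-values are discrete: for realistic term sizes the
achieved size P(p < α) sits *below* α (conservative), by more than
sampling noise. The null-calibration test therefore checks validity
one-sidedly (empirical size ≤ α + 3 SE and clearly nonzero) rather than
two-sided agreement with α.

### MCODE

`mcode` is a native implementation of molecular-complex detection:

* weight(v) = k<sub>max</sub> × density of the highest k-core of the
  closed neighborhood N[v]; vertices under the degree cutoff weigh 0;
* seeds in descending weight order; breadth-first inclusion of unseen
  neighbors with weight ≥ (1 − VWP) × seed weight, to `max_depth` hops;
  every node joins at most one complex;
* post-processing: 2-core filter, optional fluff (boundary neighbors
  with neighborhood density above a cutoff), haircut (iterative removal
  of singly connected members);
* score = loopless density × size = 2e/(n − 1).

Defaults match the familiar desktop tool: degree cutoff 2, VWP 0.2,
2-core filter, haircut on, fluff off, max depth 100, loopless density.
All orderings are tie-broken by node label, so output is deterministic
under arbitrary input orderings and relabelings. One behavioral
consequence of the deep expansion is worth knowing: when two dense
regions of equal vertex weight are joined by a single bridge edge (two
K4s, say), the expansion crosses the bridge and reports one merged
complex rather than two — separating them requires a VWP small enough
to exclude the bridge endpoints' weights, not the default. The complex
report is evidence *about* the ranked targets (which complexes contain
them), never a filter on the ranking: a top target absent from every
complex keeps its rank.

k-core decomposition is implemented natively by minimum-degree peeling
(it is integral to the algorithm); the test suite cross-checks it
against an independent library implementation on random graphs.

### ADME screen

Strict inequalities exactly as conventionally printed: OB > 30 (%),
DL > 0.18 (unitless). Records missing either value fail closed — a
compound without curated ADME data is never promoted. Both thresholds
are parameters; lowering either can only grow the passing set
(monotonicity is property-tested).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *shape* of the real inputs at desk scale,
with planted ground truth; defaults (chosen once, stated here as the
package's study conditions):

| parameter | default | rationale |
|---|---|---|
| herbs | 7 × 40 compounds, 20 % drawn from a shared pool | seven-herb formula with overlapping compound sets |
| target pool | 300 genes incl. 25 catalog NRs | scaled-down formula target space |
| compound degree | 1 + Poisson(5), preferential attachment on targets (exponent 1.0) | heavy-tailed hub targets must exist for the frequency and MCODE stages to be exercised realistically |
| disease list | 800 genes, 50 % overlap with formula targets | intersection of roughly half the formula targets |
| OB, DL | i.i.d. Uniform(0, 100) / Uniform(0, 1); correlation knob off | no joint distribution is assumed; ~35 % of compounds pass the default screen by chance |
| annotation | 6 sources × {BP, MF, CC} × 40 terms of 15–25 genes; 8 planted per group; planted terms draw 60 % of members from the intersection | planted terms reach p ≪ 10⁻⁶ while background terms stay null |
| planted NR rates | PPARG 0.70, NR1H4 0.50, PPARA 0.35, RARA 0.22, PPARD 0.12 | strictly ordered with gaps wide enough that the ordering is identifiable from ~150–170 selected clusters |
| PPI | up to 250 intersection genes, background G(n, p = 0.02); planted near-cliques of 12/8/6/4 around PPARG/PPARA/NR1H4/RARA (10 % edge dropout) | four complexes contain four of the top five NRs; the fifth (PPARD) belongs to none |
| super-compound | C0000: edges to all five planted NRs, OB 75 / DL 0.75, member of two herbs | well-defined compound-level truth |

Planted top NRs receive *curated* edges — the super-compound plus three
distinct single-NR support compounds each — rather than preferential-
attachment edges, so no background compound can tie the super-compound's
top-target count. Each generator stage draws from its own stream spawned
from the master seed, so adding a stage never perturbs earlier ones, and
a fixed seed makes the whole file set byte-identical across runs.

What the generator does **not** emulate, hence what passing tests do not
show about real data: no chemical structures (OB/DL are synthetic
numbers, not computed properties); annotation terms are flat sets with
no ontology DAG, no term redundancy and no gene-length bias; the PPI
background is Erdős–Rényi, not degree-heterogeneous like curated
interactomes; and real databases' identifier noise (aliases, obsolete
symbols) is reduced to case/whitespace normalization plus an optional
mapping table.

## Numerical and design choices

* Hypergeometric tails via the exact survival function (log-space
  internally); verified against an exact rational enumeration oracle to
  1e−12 on all instances with N ≤ 12.
* BH step-up via the standard multiple-testing routine; verified against
  hand-computed vectors; order-equivariance property-tested.
* Cluster frequency counts cluster *membership*, not multiplicity (a
  member set cannot contain a gene twice), and counts per cluster, not
  per source: the same term id recurring in two sources contributes two
  votes, as each source's cluster is a distinct piece of evidence.
* Degenerate inputs fail loudly and early: empty gene lists, empty
  catalogs, empty ADME-passing sets and empty intersections are errors
  (the CLI maps the empty intersection to exit code 3), never silently
  empty results.
* MCODE scores are reported to 3 decimals in outputs; full precision is
  kept internally.
* Percentages are reported to 2 decimals with the coarser 1-decimal
  rendering alongside; JSON stores the counts, so every percentage is
  recomputable.
* Problem sizes in the test suite (e.g. 100-seed end-to-end recovery at
  the default generator scale, 200×40-term null calibration) were chosen
  to make the recovery probabilities sharply testable at desk scale.

## Known limitations

* The screen is correlational: cluster frequency measures annotation
  consensus, not causal involvement; docking, expression and in-vivo
  validation are out of scope.
* Published headline counts from live-database workflows (hundreds of
  compounds, thousands of disease genes) are snapshot-dependent and not
  reproducible from files; the package reproduces the *method* and its
  worked-example arithmetic, and validates recovery on planted truth.
* The MCODE bridge-merging behavior described above means complex counts
  depend on VWP in graphs with equal-weight bottlenecks.
* With very small universes the discrete hypergeometric test loses
  resolution (few achievable p-values); universes of ≥ a few hundred
  genes are recommended.
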