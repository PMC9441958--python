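# Methods

## Scope and data model

The package operates on four external inputs: an undirected PPI edge table,
a table of disease-gene relevance scores (GeneCards-style, dimensionless,
≥ 0), a component–target incidence table, and a physicochemical property
table per component; gene-set collections are supplied as GMT. All readers
normalise gene symbols (strip whitespace, upper-case) so that identifiers
match across sources; duplicate score rows collapse to the maximum, which is
the conservative choice for the strictly-above-mean pathogenicity filter.
Self-loops in the PPI are dropped on input: a random walk cannot cross
module boundaries through them, so they carry no information for motif
detection.

## Filters

*Pathogenic genes* are those with relevance score strictly greater than the
mean over all scored genes. The strict inequality means a constant score
table yields an empty set (with a warning) rather than an arbitrary half.

*Active components* must satisfy all of MW ≤ 500 g/mol, logP ≤ 5, HBD ≤ 5,
HBA ≤ 10 and Caco-2 ≥ −0.4 (log10 cm/s permeability surrogate, the common
TCMSP convention). Components missing any required descriptor are rejected
and logged — an unknown value cannot be shown to pass. Every cut-off is
configurable.

## Networks and topology

The disease network is exactly the PPI subgraph induced on the pathogenic
genes; pathogenic genes absent from the PPI are counted and dropped.
Whether edges to non-pathogenic neighbours should be kept is a genuinely
open design point; the induced-subgraph reading is the stricter one and is
what the rest of the pipeline assumes. Genes that are both targets and
disease genes become single dual-role nodes in the merged C-T-P-D network —
this sharing is what connects components to the disease module.

Topology statistics follow the NetworkAnalyzer conventions: heterogeneity
is the coefficient of variation of the degree sequence using the population
standard deviation; centralization is Freeman's degree centralization
Σᵢ(k_max − kᵢ)/((n−1)(n−2)), undefined (reported missing) below three
nodes; betweenness is normalised shortest-path betweenness on unweighted
paths (edge weights as distances are deliberately not the default, since
interaction confidence weights are not metric lengths).

## Random walk and map equation

The walk uses row-normalised symmetric edge weights and uniform
teleportation at rate τ ∈ [0, 1), default 0.15 — the standard restart value
for walks of this kind; the results are insensitive to moderate changes
because teleportation only regularises the stationary distribution.
Degree-zero nodes get uniform transition rows. The stationary visit rates
solve p = τ/n + (1−τ)·pω, found by damped (lazy-walk) power iteration to an
L1 residual of 1e−10 within 10,000 iterations; laziness leaves the fixed
point unchanged but guarantees convergence on bipartite graphs at τ = 0,
where the undamped iteration oscillates with period two.

The module exit probability is computed exactly as

    qᵢ = τ·(n−nᵢ)/n·Σ_{α∈i} p_α + (1−τ)·Σ_{α∈i} Σ_{β∉i} p_α ω_αβ

and the partition quality is the two-level map-equation codelength
L = q↷H(Q) + Σᵢ pᵢ↻H(Pᵢ) in bits, with 0·log 0 ≡ 0. For the all-in-one
partition q = 0 and L reduces to the entropy of the visit rates, a closed
form the tests assert to 1e−12.

The optimizer is deliberately simple and fully deterministic given a seed:
starting from singletons, sweeps of single-node moves accept the move that
most decreases L (ties to the smallest destination module id), followed by
greedy pairwise module merges, repeating until no move improves L by more
than 1e−12. Per-module flow statistics are maintained incrementally so a
move costs O(degree). The seed only shuffles the node visiting order.
Accepted moves form a strictly decreasing L sequence (asserted per move),
and the incremental codelength is cross-checked against a from-scratch
evaluation at the end of the run. On planted-module bipartite benchmarks
this optimizer reaches the same partitions as an independent Infomap
implementation; hierarchical (multi-level) coding and directed walks are
out of scope.

CIM extraction keeps modules with at least one component node and at least
`min_pathogenic` pathogenic genes (default 1), ranked by the summed
relevance of their pathogenic genes and optionally truncated to `top_k`.
Both knobs are exposed because no principled universal cut exists; the
default keeps every qualifying module.

## Effective proteins and FCG selection

The importance of a CIM target combines connectivity and influence:
min-max-scaled degree within the CIM-induced subgraph plus min-max-scaled
relevance (non-pathogenic targets contribute 0), so scores live in [0, 2].
This scoring is intentionally isolated behind one function
(`score_effective_proteins`) so an alternative importance measure can be
substituted without touching the selectors. When all raw values are equal
the scaled value is 0 (no information, no rank).

Per component, H_t counts the effective proteins it targets and L_t is its
contribution toward pathogenic genes: by default the summed relevance of
the pathogenic effective proteins targeted (`score_sum`), with a `count`
mode counting them instead. Both readings are provided because
"contribution index" does not pin down a formula; `score_sum` uses the
available relevance information and is the default.

The TCA knapsack maximises CCI = Σ L_t y_t under Σ H_t y_t ≤ S with the
exact dynamic program m(t, S_sub) = max{m(t+1, S_sub), m(t+1, S_sub−H_t)
+ L_t}; equal-value branches prefer exclusion, making the reconstruction
deterministic. S below the smallest H_t yields the valid empty selection.
The knapsack objective is additive and ignores target-set overlap between
components, whereas the quantity one actually wants bounded is the *union*
coverage of effective proteins; the greedy union-coverage accumulation
(largest marginal gain, ties by larger L_t then id) is therefore the
default FCG extractor, cutting the curve at 90% coverage. On instances
with disjoint target sets the two selectors coincide, which the tests
check. The budget default S = ⌈0.8·ΣH_t⌉ is a convenience anchor; the
greedy path does not use it.

## Enrichment

Over-representation is one-sided hypergeometric: p = P(X ≥ k) for
X ~ Hypergeom(N, K, n), computed with scipy's survival function and checked
against exact factorial tail sums in the tests. The multiple-testing gate
defaults to Benjamini–Hochberg FDR at 0.05 (statsmodels implementation); a
raw p < 0.05 mode exists because published analyses often gate on raw p.
The default universe is all genes of the supplied GMT collection,
configurable to the network's gene set. GO and pathway collections are
treated identically as flat gene sets; term ancestry is out of scope.

## Synthetic benchmark

The generator emulates the real inputs at desk scale with a single seed
threaded through every draw (same seed ⇒ byte-identical file tree):

- **PPI**: Barabási–Albert preferential attachment, 300 genes, mean degree
  ≈ 4 — connected and scale-free-like, matching the heavy-tailed degree
  distributions of curated interactomes.
- **Relevance scores**: lognormal(0, 1) background; a planted pathogenic
  subset (20% of genes) is shifted up by +2 (two log-standard-deviation
  units added on the score scale). The additive shift gives the clean
  above-the-mean split the filter assumes: planted scores start above the
  background mean by construction, so the filter recovers the planted set
  at ≈ 95–100% while admitting the heavy right tail of the background
  (~24% false positives), much like real relevance-score exports.
- **C-T table**: 40 components × 160 targets in 4 planted blocks with
  within-block wiring probability 0.6 and cross-block 0.06 (ratio 10).
  These densities reproduce realistic C-T mean degrees (≈ 31 per component,
  ≈ 8 per target, close to published component–target networks) and give a
  planted structure the motif detector recovers at NMI ≥ 0.9. Pathogenic
  target genes fill the first blocks, concentrating the disease signal in
  a few modules as the motif model assumes. Isolated nodes are rewired to
  one in-block partner.
- **Core components**: five components receive a disjoint partition of a
  20-target universe (removed from all other components), making them the
  unique minimum cover — the greedy selector must find exactly this set.
- **Properties**: drug-like draws within the filter box; 15% of non-core
  components get a violating MW or Caco-2 value.
- **Gene sets**: one per planted block (cycled), plus 3 noise genes each.

What the benchmark does *not* emulate: real PPI clustering coefficients and
confidence weights, correlated physicochemical descriptors, curated pathway
structure, or literature-derived component chemistry. Passing tests show
the algorithms are correct on data with the assumed generative structure,
not that a particular biological conclusion is reproduced.

## Pipeline, determinism, problem sizes

The pipeline runs nine stages (filters; disease + C-T networks; C-T-P-D
merge with topology; motif detection; CIM validation; effective proteins;
component metrics; knapsack + greedy FCG; FCG enrichment), each writing a
deterministic JSON/TSV report; the manifest records the seed and SHA-256
hashes of all inputs and outputs, so reruns with unchanged inputs are
byte-identical. Default problem sizes (300 genes, 40 components) keep a
full simulate-plus-run cycle under a second and the whole test suite in
seconds while remaining large enough for meaningful module recovery.

## Known limitations

- The CIM-vs-network pathway-coincidence validation is only informative
  when the CIM is a selective subset of the network. On the default
  benchmark the above-mean filter's background false positives place
  pathogenic genes in every module, so all block modules qualify as CIM and
  the coincidence comparison degenerates (both queries approach the full
  target set). Raising `min_pathogenic` or setting `top_k_motifs` makes the
  CIM selective; the default stays permissive rather than hiding modules.
- The importance score for effective proteins is one reasonable choice of
  "influence + connectivity", not a canonical statistic; it is replaceable
  behind its function boundary.
- The knapsack treats L_t as additive across components; overlap-aware
  selection is exactly what the greedy union-coverage path provides, and
  no branch-and-bound or approximation schemes are implemented because the
  instances are small (tens of components).
- Directed walks, hierarchical map equations, GO term ancestry, and any
  database retrieval are out of scope; the pipeline consumes pre-merged
  tables.
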