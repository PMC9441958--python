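# netpharm

Network pharmacology for multi-component interventions: given a
protein–protein interaction (PPI) network, disease-gene relevance scores, a
component–target (C-T) interaction table, and physicochemical descriptors of
the components, `netpharm` identifies the *core intervention motifs* (CIM)
of the merged component–target–pathogenic-gene–disease (C-T-P-D) network and
selects the minimal *functional components group* (FCG) that covers the
disease-relevant targets. It is written for computational
systems-pharmacology work on herbal formulas and other multi-component
therapies, where the question is not "which single compound acts on which
single target" but "which small subset of components jointly covers the
disease module".

## Method

1. **Filters.** Disease genes with relevance score strictly above the mean
   are kept as *pathogenic genes*; components must pass a combined
   Lipinski / Caco-2 drug-likeness filter (MW ≤ 500 g/mol, logP ≤ 5,
   HBD ≤ 5, HBA ≤ 10, Caco-2 ≥ −0.4; all configurable).
2. **Networks.** The disease network is the PPI subgraph induced on the
   pathogenic genes (nodes weighted by relevance); the bipartite C-T network
   joins it through genes that are both targets and disease genes, giving
   the C-T-P-D network. Topology is summarised by degree, betweenness,
   network heterogeneity sd(k)/mean(k) and Freeman degree centralization
   Σᵢ(k_max − kᵢ)/((n−1)(n−2)).
3. **Motif detection.** A random walker with teleportation rate τ (default
   0.15) explores the network; the probability of exiting module *i* is

        qᵢ = τ·(n−nᵢ)/n·Σ_{α∈i} p_α + (1−τ)·Σ_{α∈i} Σ_{β∉i} p_α ω_αβ

   with stationary visit rates p and row-normalised weights ω. Modules are
   found by minimising the two-level map-equation codelength
   L = q↷H(Q) + Σᵢ pᵢ↻H(Pᵢ) with a seeded deterministic local-move +
   merge optimizer. Modules containing components and pathogenic genes,
   ranked by summed pathogenic relevance, form the CIM.
4. **FCG selection.** CIM targets are *effective proteins*, ranked by
   min-max-scaled within-CIM degree plus relevance. Each component t gets a
   coverage weight H_t (effective proteins targeted) and contribution index
   L_t (relevance mass of pathogenic effective proteins targeted). The
   target-coverage-accumulation (TCA) selector solves the exact 0/1
   knapsack max Σ L_t y_t s.t. Σ H_t y_t ≤ S, and a greedy union-coverage
   ranking cuts the accumulation curve at a coverage threshold (default
   90%) to yield the FCG.
5. **Validation.** Hypergeometric over-representation of gene sets (GMT)
   with Benjamini–Hochberg control, Venn overlap reports, and centrality
   baselines (closeness, average shortest path, neighborhood connectivity)
   for comparison.

A seeded synthetic benchmark (scale-free PPI, heavy-tailed relevance scores
with a planted pathogenic subset, planted-module bipartite C-T table) makes
every stage testable without database access.

## Worked example

```bash
netpharm simulate bench --seed 1          # write synthetic inputs + ground truth
cat > config.yaml <<EOF
ppi: bench/ppi.tsv
scores: bench/scores.tsv
component_targets: bench/component_targets.tsv
properties: bench/properties.tsv
gene_sets: bench/gene_sets.gmt
seed: 1
EOF
netpharm run config.yaml --outdir run
```

prints the nine completed stages and leaves reports in `run/`. On this
bundle (300 genes, 40 components, 4 planted modules, seed 1) the run gives:

- 115 of 300 genes pass the above-mean pathogenicity filter, recovering
  95% of the 60 planted pathogenic genes;
- the C-T-P-D network has 229 nodes and 1,064 edges, heterogeneity 0.948
  and centralization 0.118;
- 4 core intervention motifs are retained out of 19 modules, holding 153
  effective proteins; 85.9% of the CIM's pathogenic genes coincide with the
  C-T network's pathogenic targets;
- the greedy coverage curve (`run/coverage_curve.tsv`) reaches the 90%
  threshold after 8 of 34 candidate components (top-5 coverage 77.8%), so
  the FCG has 8 components; the knapsack optimum at the default budget has
  CCI ≈ 1686.4.

The same numbers are reproduced by the acceptance script below; the motif
detector recovers the planted module labels with NMI 1.0 on this seed.

## Layout

- `src/netpharm/io.py` — TSV/GMT/SIF/GraphML readers and writers
- `src/netpharm/networks.py` — filters, network assembly, topology statistics
- `src/netpharm/motifs.py` — random walk, map equation, optimizer, CIM
- `src/netpharm/fcg.py` — effective proteins, knapsack, greedy coverage
- `src/netpharm/enrich.py` — hypergeometric enrichment, BH, baselines
- `src/netpharm/synth.py` — seeded synthetic benchmarks with ground truth
- `src/netpharm/pipeline.py`, `cli.py` — orchestration and `netpharm` CLI

See `docs/methods.md` for model assumptions, parameter defaults, and known
limitations.
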