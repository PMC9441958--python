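"""Seeded synthetic benchmarks with known ground truth.

Real inputs to the pipeline come from curated databases (PPI repositories,
disease-gene relevance scores, predicted component-target interactions).
This module emulates all of them at desk scale so that every stage can be
tested without downloads:

* a connected scale-free-like PPI via preferential attachment;
* heavy-tailed relevance scores (lognormal) with a planted high-score
  pathogenic subset, additively shifted so that the above-mean filter
  recovers it;
* a planted-module bipartite component-target table (stochastic block
  structure with within-block probability ``p_in`` and cross-block
  ``p_out``), yielding ground-truth module labels for motif recovery;
* physicochemical property rows, most drug-like and a configurable fraction
  violating the Lipinski/Caco-2 filter;
* gene sets built as planted blocks plus noise genes;
* a planted core component set constructed as the unique minimum cover of a
  designated target universe (each core component holds a private target),
  for evaluating the greedy coverage selector.

Everything is driven by one seed; regenerating with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ValidationError
from .io import (ComponentTargetTable, EdgeTable, GeneScoreTable,
                 GeneSetCollection, PropertyRecord, PropertyTable)

__all__ = [
    "BenchmarkConfig",
    "BenchmarkBundle",
    "simulate_ppi",
    "simulate_ct",
    "make_benchmark",
]


def simulate_ppi(n_genes: int = 300, mean_degree: float = 4, seed: int = 0) -> EdgeTable:
    """Connected scale-free-like PPI via Barabasi-Albert preferential
    attachment; node ids G0001..; edge weights 1.0."""
    if n_genes < 10:
        raise ValidationError(f"n_genes must be >= 10, got {n_genes}")
    m = max(1, int(round(mean_degree / 2)))
    if m >= n_genes:
        raise ValidationError("mean_degree too large for n_genes")
    g = nx.barabasi_albert_graph(n_genes, m, seed=int(seed))
    name = {i: f"G{i + 1:04d}" for i in g.nodes}
    edges = [(name[u], name[v], 1.0) for u, v in sorted(g.edges())]
    return EdgeTable(edges=edges)


def simulate_ct(n_components: int = 40, n_targets: int = 160, n_modules: int = 4,
                p_in: float = 0.6, p_out: float = 0.06, seed: int = 0,
                target_names: list[str] | None = None,
                component_names: list[str] | None = None):
    """Planted-module bipartite component-target table.

    Components and targets are split into ``n_modules`` contiguous blocks;
    a component-target pair is wired with probability ``p_in`` inside a
    block and ``p_out`` across blocks. Nodes left isolated are rewired to
    one random in-block partner. Returns ``(table, labels)`` with labels
    mapping every node id to its planted block.
    """
    if not p_in > p_out:
        raise ValidationError(f"p_in must exceed p_out (got {p_in} <= {p_out})")
    if n_components < n_modules or n_targets < n_modules:
        raise ValidationError("need at least one component and target per module")
    comps = component_names or [f"C{i + 1:03d}" for i in range(n_components)]
    targs = target_names or [f"T{i + 1:04d}" for i in range(n_targets)]
    if len(comps) != n_components or len(targs) != n_targets:
        raise ValidationError("name list lengths must match counts")
    rng = np.random.default_rng(seed)
    comp_block = {c: i * n_modules // n_components for i, c in enumerate(comps)}
    targ_block = {t: i * n_modules // n_targets for i, t in enumerate(targs)}
    table: dict[str, set[str]] = {c: set() for c in comps}
    hit_targets: set[str] = set()
    for c in comps:
        draws = rng.random(n_targets)
        for t, u in zip(targs, draws):
            prob = p_in if comp_block[c] == targ_block[t] else p_out
            if u < prob:
                table[c].add(t)
                hit_targets.add(t)
    # rewire isolated nodes to one in-block partner
    for c in comps:
        if not table[c]:
            block = [t for t in targs if targ_block[t] == comp_block[c]]
            pick = block[int(rng.integers(len(block)))]
            table[c].add(pick)
            hit_targets.add(pick)
    for t in targs:
        if t not in hit_targets:
            block = [c for c in comps if comp_block[c] == targ_block[t]]
            pick = block[int(rng.integers(len(block)))]
            table[pick].add(t)
    labels = {**comp_block, **targ_block}
    return ComponentTargetTable(targets=table), labels


@dataclass
class BenchmarkConfig:
    """Default scale: 300 genes, 40 components, 4 planted modules — large
    enough for motif recovery, small enough for seconds-scale tests."""

    n_genes: int = 300
    ppi_mean_degree: float = 4.0
    n_components: int = 40
    n_targets: int = 160
    n_modules: int = 4
    p_in: float = 0.6
    p_out: float = 0.06
    pathogenic_fraction: float = 0.2
    score_sigma: float = 1.0  # lognormal log-sd of relevance scores
    score_shift: float = 2.0  # additive shift of planted pathogenic scores
    n_gene_sets: int = 12
    noise_genes_per_set: int = 3
    n_core_components: int = 5
    core_universe_size: int = 20  # targets partitioned among core components
    property_fail_fraction: float = 0.15

    def validate(self) -> None:
        problems = []
        if self.n_genes < self.n_targets:
            problems.append("n_genes must be >= n_targets")
        if not (0 < self.pathogenic_fraction < 1):
            problems.append("pathogenic_fraction must be in (0, 1)")
        if not self.p_in > self.p_out:
            problems.append("p_in must exceed p_out")
        if self.n_core_components > self.n_components:
            problems.append("n_core_components must be <= n_components")
        if self.core_universe_size < self.n_core_components:
            problems.append("core_universe_size must be >= n_core_components")
        if not (0 <= self.property_fail_fraction < 1):
            problems.append("property_fail_fraction must be in [0, 1)")
        if problems:
            raise ValidationError("invalid benchmark config: " + "; ".join(problems))


@dataclass
class BenchmarkBundle:
    config: BenchmarkConfig
    seed: int
    ppi: EdgeTable
    scores: GeneScoreTable
    ct: ComponentTargetTable
    properties: PropertyTable
    gene_sets: GeneSetCollection
    planted_labels: dict[str, int]
    planted_pathogenic: set[str] = field(default_factory=set)
    core_components: set[str] = field(default_factory=set)
    core_universe: set[str] = field(default_factory=set)

    def write(self, outdir) -> dict[str, str]:
        """Write the TSV/GMT inputs plus a ground-truth JSON; deterministic
        byte-for-byte for a fixed config and seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _emit(name, lines):
            path = outdir / name
            path.write_text("".join(lines), encoding="utf-8")
            paths[name] = str(path)

        _emit("ppi.tsv", [f"{u}\t{v}\t{w:g}\n" for u, v, w in self.ppi.edges])
        _emit("scores.tsv", [f"{g}\t{s:.6f}\n" for g, s in sorted(self.scores.scores.items())])
        _emit("component_targets.tsv",
              [f"{c}\t{t}\n" for c in self.ct.components() for t in sorted(self.ct.targets[c])])
        prop_lines = []
        for comp in sorted(self.properties.records):
            r = self.properties.records[comp]
            vals = [("NA" if x is None else f"{x:.4f}")
                    for x in (r.mw, r.logp, r.hbd, r.hba, r.caco2)]
            prop_lines.append(comp + "\t" + "\t".join(vals) + "\n")
        _emit("properties.tsv", prop_lines)
        gmt_lines = []
        for term in self.gene_sets.terms():
            desc, genes = self.gene_sets.sets[term]
            gmt_lines.append("\t".join([term, desc, *sorted(genes)]) + "\n")
        _emit("gene_sets.gmt", gmt_lines)
        truth = {
            "seed": self.seed,
            "config": asdict(self.config),
            "planted_labels": {k: int(v) for k, v in sorted(self.planted_labels.items())},
            "planted_pathogenic": sorted(self.planted_pathogenic),
            "core_components": sorted(self.core_components),
            "core_universe": sorted(self.core_universe),
        }
        (outdir / "ground_truth.json").write_text(
            json.dumps(truth, sort_keys=True, indent=2) + "\n", encoding="utf-8")
        paths["ground_truth.json"] = str(outdir / "ground_truth.json")
        return paths


def make_benchmark(config: BenchmarkConfig | None = None, seed: int = 0) -> BenchmarkBundle:
    """Generate a full input bundle with planted ground truth."""
    cfg = config or BenchmarkConfig()
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    s_ppi, s_scores, s_ct, s_prop, s_sets, s_core = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)]

    ppi = simulate_ppi(cfg.n_genes, cfg.ppi_mean_degree, seed=s_ppi)
    genes = sorted(ppi.node_set())

    # relevance scores: lognormal background, planted pathogenic genes get
    # an additive +shift so the above-mean rule splits them cleanly
    rng = np.random.default_rng(s_scores)
    n_patho = int(round(cfg.pathogenic_fraction * len(genes)))
    pathogenic = {str(g) for g in rng.choice(genes, size=n_patho, replace=False)}
    base = rng.lognormal(mean=0.0, sigma=cfg.score_sigma, size=len(genes))
    scores = {}
    for g, x in zip(genes, base):
        scores[g] = float(x + (cfg.score_shift if g in pathogenic else 0.0))
    score_table = GeneScoreTable(scores=scores)

    # planted-module C-T table over a gene subset enriched in pathogenic genes
    rng_ct = np.random.default_rng(s_ct)
    patho_sorted = sorted(pathogenic)
    other = [g for g in genes if g not in pathogenic]
    n_patho_targets = min(len(patho_sorted), cfg.n_targets // 2)
    patho_targets = sorted(str(g) for g in rng_ct.choice(
        patho_sorted, size=n_patho_targets, replace=False))
    other_targets = sorted(str(g) for g in rng_ct.choice(
        other, size=cfg.n_targets - n_patho_targets, replace=False))
    # pathogenic targets fill the first blocks: the disease signal is
    # concentrated in a few modules, as the motif model assumes
    target_genes = patho_targets + other_targets
    ct, labels = simulate_ct(cfg.n_components, cfg.n_targets, cfg.n_modules,
                             cfg.p_in, cfg.p_out, seed=s_ct,
                             target_names=target_genes)

    # planted core components: unique minimum cover of a target universe
    rng_core = np.random.default_rng(s_core)
    comps = ct.components()
    core = sorted(str(c) for c in rng_core.choice(comps, size=cfg.n_core_components,
                                                  replace=False))
    universe = sorted(str(t) for t in rng_core.choice(target_genes,
                                                      size=cfg.core_universe_size,
                                                      replace=False))
    shares = np.array_split(np.array(universe), cfg.n_core_components)
    for c in comps:  # core universe targets belong to core components only
        ct.targets[c] -= set(universe)
    for c, share in zip(core, shares):
        ct.targets[c] |= set(share.tolist())

    # physicochemical properties: drug-like by default, a fraction failing
    rng_p = np.random.default_rng(s_prop)
    records = {}
    n_fail = int(round(cfg.property_fail_fraction * len(comps)))
    failing = {str(c) for c in rng_p.choice([c for c in comps if c not in set(core)],
                                            size=min(n_fail, len(comps) - len(core)),
                                            replace=False)}
    for comp in comps:
        rec = PropertyRecord(
            component=comp,
            mw=float(rng_p.uniform(150, 480)),
            logp=float(rng_p.uniform(-2.0, 4.5)),
            hbd=float(rng_p.integers(0, 6)),
            hba=float(rng_p.integers(0, 11)),
            caco2=float(rng_p.uniform(-0.3, 1.5)),
        )
        if comp in failing:
            if rng_p.random() < 0.5:
                rec.mw = float(rng_p.uniform(520, 900))
            else:
                rec.caco2 = float(rng_p.uniform(-3.0, -0.5))
        records[comp] = rec
    properties = PropertyTable(records=records)

    # gene sets: planted target blocks plus noise genes
    rng_s = np.random.default_rng(s_sets)
    blocks: dict[int, set[str]] = {}
    for t in target_genes:
        blocks.setdefault(labels[t], set()).add(t)
    sets: dict[str, tuple[str, set[str]]] = {}
    non_target = [g for g in genes if g not in set(target_genes)]
    for i in range(cfg.n_gene_sets):
        block = blocks[i % cfg.n_modules]
        members = set(block)
        if cfg.noise_genes_per_set and non_target:
            noise = rng_s.choice(non_target, size=min(cfg.noise_genes_per_set,
                                                      len(non_target)), replace=False)
            members |= set(noise.tolist())
        sets[f"SET{i + 1:03d}"] = (f"planted block {i % cfg.n_modules}", members)
    gene_sets = GeneSetCollection(sets=sets)

    return BenchmarkBundle(
        config=cfg, seed=seed, ppi=ppi, scores=score_table, ct=ct,
        properties=properties, gene_sets=gene_sets, planted_labels=labels,
        planted_pathogenic=pathogenic, core_components=set(core),
        core_universe=set(universe),
    )
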