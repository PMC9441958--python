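"""End-to-end orchestration of the component-selection strategy.

The pipeline runs nine stages over a single config: drug-likeness and
pathogenicity filters, disease / C-T network construction, the merged
C-T-P-D network with topology statistics, map-equation motif detection with
CIM extraction, CIM validation (pathogenic-gene overlap and pathway
coincidence), effective-protein scoring, per-component H_t/L_t metrics,
knapsack + greedy FCG selection, and enrichment of the FCG targets. Every
stage writes its report into the artifact directory and is recorded in a
manifest together with the seed and SHA-256 hashes of all inputs, so a
rerun with unchanged inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrich import hypergeom_enrich, set_overlap
from .errors import PipelineError, ValidationError
from .fcg import component_metrics, greedy_coverage, knapsack_select, score_effective_proteins
from .io import (read_component_targets, read_edge_table, read_gene_scores,
                 read_gmt, read_property_table, write_network, write_report)
from .motifs import extract_cim, optimize_partition
from .networks import (LipinskiThresholds, build_ct_network, build_disease_network,
                       filter_active_components, filter_pathogenic_genes, merge_ctpd,
                       topology_stats)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = (
    "filters",
    "networks",
    "merge_ctpd",
    "motif_detection",
    "cim_validation",
    "effective_proteins",
    "component_metrics",
    "fcg_selection",
    "enrichment",
)


@dataclass
class PipelineConfig:
    """All file paths and thresholds driving a pipeline run."""

    ppi: str = ""
    scores: str = ""
    component_targets: str = ""
    properties: str = ""
    gene_sets: str = ""

    seed: int = 0
    tau: float = 0.15
    lipinski: LipinskiThresholds = field(default_factory=LipinskiThresholds)
    min_pathogenic: int = 1  # per-module pathogenic genes required for a CIM
    top_k_motifs: int | None = None
    keep_fraction: float = 1.0  # effective proteins retained
    lt_mode: str = "score_sum"  # L_t definition: score_sum | count
    budget: int | None = None  # knapsack S; None derives it from budget_fraction
    budget_fraction: float = 0.8  # S = ceil(fraction * sum H_t)
    coverage_threshold: float = 0.90
    alpha: float = 0.05  # enrichment significance level
    significance: str = "q"  # gate on BH q ("q") or raw p ("p")
    selection_mode: str = "greedy"  # FCG extraction: greedy | knapsack

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config must be a YAML mapping")
        lip = raw.pop("lipinski", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if lip:
            cfg.lipinski = LipinskiThresholds(**lip)
        cfg.validate_values()
        return cfg

    def validate_values(self) -> None:
        problems = []
        if not (0 <= self.tau < 1):
            problems.append(f"tau must be in [0, 1): {self.tau}")
        if not (0 < self.coverage_threshold <= 1):
            problems.append(f"coverage_threshold must be in (0, 1]: {self.coverage_threshold}")
        if not (0 < self.keep_fraction <= 1):
            problems.append(f"keep_fraction must be in (0, 1]: {self.keep_fraction}")
        if not (0 < self.alpha < 1):
            problems.append(f"alpha must be in (0, 1): {self.alpha}")
        if self.lt_mode not in ("score_sum", "count"):
            problems.append(f"lt_mode must be score_sum or count: {self.lt_mode}")
        if self.selection_mode not in ("greedy", "knapsack"):
            problems.append(f"selection_mode must be greedy or knapsack: {self.selection_mode}")
        if self.significance not in ("q", "p"):
            problems.append(f"significance must be 'q' or 'p': {self.significance}")
        if problems:
            raise ValidationError("; ".join(problems))

    def input_paths(self) -> dict[str, str]:
        return {
            "ppi": self.ppi,
            "scores": self.scores,
            "component_targets": self.component_targets,
            "properties": self.properties,
            "gene_sets": self.gene_sets,
        }


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _significant_terms(results, alpha: float, gate: str) -> set[str]:
    if gate == "p":
        return {r.term for r in results if r.p < alpha}
    return {r.term for r in results if r.q < alpha}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages and return the manifest (also written to
    ``manifest.json``). A stage failure aborts with the failing stage named;
    reports of completed stages are retained."""
    config.validate_values()
    missing = [name for name, p in config.input_paths().items()
               if not p or not Path(p).exists()]
    if missing:
        raise ValidationError(f"missing input file(s) for: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package": "netpharm",
        "version": __version__,
        "seed": config.seed,
        "tau": config.tau,
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in config.input_paths().items()},
        "stages": [],
    }
    state: dict = {}

    def _record(stage: str, outputs: dict[str, Path]) -> None:
        manifest["stages"].append({
            "name": stage,
            "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
        })

    def _run(stage, fn):
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineError(stage, exc) from exc
        log.info("stage %-18s done in %.2fs", stage, time.perf_counter() - t0)
        _record(stage, outputs or {})

    # ----- stage: filters ------------------------------------------------
    def stage_filters():
        state["scores"] = read_gene_scores(config.scores)
        state["ppi"] = read_edge_table(config.ppi)
        state["ct"] = read_component_targets(config.component_targets)
        state["props"] = read_property_table(config.properties)
        state["gmt"] = read_gmt(config.gene_sets)
        state["pathogenic"] = filter_pathogenic_genes(state["scores"])
        state["active"] = filter_active_components(state["props"], config.lipinski)
        state["active"] &= set(state["ct"].targets)
        out = outdir / "filters.json"
        write_report({
            "n_pathogenic": len(state["pathogenic"]),
            "pathogenic_genes": sorted(state["pathogenic"]),
            "n_active_components": len(state["active"]),
            "active_components": sorted(state["active"]),
        }, out)
        return {"filters.json": out}

    # ----- stage: disease and C-T networks ------------------------------
    def stage_networks():
        state["disease_net"] = build_disease_network(
            state["ppi"], state["pathogenic"], state["scores"])
        dn = outdir / "disease_network.tsv"
        write_network(state["disease_net"], dn, format="tsv")
        state["ct_net"] = build_ct_network(state["ct"], state["active"])
        cn = outdir / "ct_network.sif"
        write_network(state["ct_net"], cn, format="sif")
        return {"disease_network.tsv": dn, "ct_network.sif": cn}

    # ----- stage: merged C-T-P-D network --------------------------------
    def stage_merge():
        net = merge_ctpd(state["ct_net"], state["disease_net"])
        state["ctpd"] = net
        topo = topology_stats(net)
        state["topology"] = topo
        sif = outdir / "ctpd_network.sif"
        write_network(net, sif, format="sif")
        rep = outdir / "topology.json"
        write_report({
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "heterogeneity": topo.heterogeneity,
            "centralization": topo.centralization,
            "mean_degree_by_role": topo.mean_degree_by_role,
        }, rep)
        return {"ctpd_network.sif": sif, "topology.json": rep}

    # ----- stage: motif detection ---------------------------------------
    def stage_motifs():
        partition = optimize_partition(state["ctpd"], tau=config.tau, seed=config.seed)
        state["partition"] = partition
        cim = extract_cim(partition, state["ctpd"], state["pathogenic"],
                          min_pathogenic=config.min_pathogenic,
                          top_k=config.top_k_motifs)
        state["cim"] = cim
        pj = outdir / "partition.json"
        write_report(partition, pj)
        mem = outdir / "module_membership.tsv"
        with open(mem, "w", encoding="utf-8") as fh:
            for node in sorted(partition.assignment):
                fh.write(f"{node}\t{partition.assignment[node]}\n")
        cj = outdir / "cim.json"
        write_report(cim, cj)
        return {"partition.json": pj, "module_membership.tsv": mem, "cim.json": cj}

    # ----- stage: CIM validation ----------------------------------------
    def stage_validation():
        cim = state["cim"]
        pathogenic = state["pathogenic"]
        ct_targets = state["ct_net"].targets
        cim_patho = {g for m in cim.modules for g in m.pathogenic_genes}
        overlap = set_overlap(cim_patho, ct_targets & pathogenic)
        universe = state["gmt"].all_genes()
        enr_cim = hypergeom_enrich(cim.all_targets(), state["gmt"], universe)
        enr_patho = hypergeom_enrich(pathogenic, state["gmt"], universe)
        terms_cim = _significant_terms(enr_cim, config.alpha, config.significance)
        terms_patho = _significant_terms(enr_patho, config.alpha, config.significance)
        pathway = set_overlap(terms_cim, terms_patho)
        state["validation"] = {
            "pathogenic_overlap": overlap,
            "pathway_coincidence": pathway,
        }
        out = outdir / "cim_validation.json"
        write_report({
            "n_motifs": len(cim),
            "pathogenic_genes_in_cim": overlap.size_a,
            "pathogenic_genes_in_ct": overlap.size_b,
            "pathogenic_overlap": overlap.intersection,
            "pathogenic_coincidence": overlap.coincidence,
            "n_terms_cim": len(terms_cim),
            "n_terms_pathogenic": len(terms_patho),
            "pathway_coincidence": pathway.coincidence,
        }, out)
        return {"cim_validation.json": out}

    # ----- stage: effective proteins ------------------------------------
    def stage_effective():
        eff = score_effective_proteins(state["cim"], state["ctpd"], state["scores"],
                                       keep_fraction=config.keep_fraction)
        state["effective"] = eff
        out = outdir / "effective_proteins.json"
        write_report(eff, out)
        return {"effective_proteins.json": out}

    # ----- stage: component metrics -------------------------------------
    def stage_metrics():
        ct_cim = state["ct"].restrict(state["cim"].all_components() & set(state["ct"].targets))
        state["ct_cim"] = ct_cim
        items = component_metrics(ct_cim, state["effective"], state["scores"],
                                  mode=config.lt_mode, pathogenic=state["pathogenic"])
        state["items"] = items
        out = outdir / "component_metrics.json"
        write_report(items, out)
        return {"component_metrics.json": out}

    # ----- stage: FCG selection -----------------------------------------
    def stage_fcg():
        items = state["items"]
        budget = config.budget
        if budget is None:
            budget = max(1, math.ceil(config.budget_fraction
                                      * sum(it.coverage for it in items)))
        knap = knapsack_select(items, budget)
        values = {it.component: it.value for it in items}
        greedy = greedy_coverage(state["ct_cim"], state["effective"],
                                 threshold=config.coverage_threshold, values=values)
        state["knapsack"] = knap
        state["greedy"] = greedy
        state["fcg"] = (set(greedy.fcg) if config.selection_mode == "greedy"
                        else set(knap.selected))
        kj = outdir / "knapsack.json"
        write_report(knap, kj)
        fj = outdir / "fcg.json"
        write_report({
            "mode": config.selection_mode,
            "components": sorted(state["fcg"]),
            "coverage_curve": greedy.coverage_curve,
            "order": greedy.order,
            "threshold": greedy.threshold,
            "threshold_reached": greedy.threshold_reached,
            "cci": knap.cci,
        }, fj)
        curve = outdir / "coverage_curve.tsv"
        with open(curve, "w", encoding="utf-8") as fh:
            for rank, cov in enumerate(greedy.coverage_curve, start=1):
                fh.write(f"{rank}\t{cov:.6f}\n")
        return {"knapsack.json": kj, "fcg.json": fj, "coverage_curve.tsv": curve}

    # ----- stage: enrichment of FCG targets -----------------------------
    def stage_enrich():
        universe = state["gmt"].all_genes()
        fcg_targets = set()
        for comp in state["fcg"]:
            fcg_targets |= state["ct"].targets.get(comp, set())
        results = hypergeom_enrich(fcg_targets & universe, state["gmt"], universe)
        state["fcg_enrichment"] = results
        out = outdir / "fcg_enrichment.json"
        write_report(results, out)
        return {"fcg_enrichment.json": out,
                "fcg_enrichment.tsv": out.with_suffix(".tsv")}

    _run("filters", stage_filters)
    _run("networks", stage_networks)
    _run("merge_ctpd", stage_merge)
    _run("motif_detection", stage_motifs)
    _run("cim_validation", stage_validation)
    _run("effective_proteins", stage_effective)
    _run("component_metrics", stage_metrics)
    _run("fcg_selection", stage_fcg)
    _run("enrichment", stage_enrich)

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n", encoding="utf-8")
    manifest["state"] = state  # in-memory results for programmatic callers
    return manifest
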