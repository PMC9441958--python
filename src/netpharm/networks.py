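"""Filters and network assembly.

The pipeline works with three graphs:

* the weighted disease gene regulatory network — the PPI subgraph induced on
  the high-pathogenicity genes (relevance score strictly above the mean),
  each node carrying its relevance score;
* the bipartite component-target (C-T) network of the drug-likeness-filtered
  components;
* their union, the component-target-pathogenic-gene-disease (C-T-P-D)
  network, joined through genes that are both targets and disease genes.

Topology statistics follow the NetworkAnalyzer conventions: heterogeneity is
the coefficient of variation of the degree distribution (population standard
deviation over the mean) and centralization is Freeman degree
centralization, sum(k_max - k_i) / ((n - 1)(n - 2)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ValidationError
from .io import ComponentTargetTable, EdgeTable, GeneScoreTable, PropertyTable

log = logging.getLogger(__name__)

__all__ = [
    "ROLE_COMPONENT",
    "ROLE_TARGET",
    "ROLE_DISEASE",
    "WeightedNetwork",
    "TopologyReport",
    "LipinskiThresholds",
    "filter_pathogenic_genes",
    "filter_active_components",
    "build_disease_network",
    "build_ct_network",
    "merge_ctpd",
    "topology_stats",
]

ROLE_COMPONENT = "component"
ROLE_TARGET = "target"
ROLE_DISEASE = "disease_gene"


def as_graph(net) -> nx.Graph:
    """Accept either a WeightedNetwork or a bare networkx graph."""
    return net if isinstance(net, nx.Graph) else net.graph


class WeightedNetwork:
    """Typed-node weighted undirected graph.

    Thin wrapper around :class:`networkx.Graph`. Node attribute ``roles`` is
    a set drawn from {component, target, disease_gene} (a gene may be both
    target and disease gene); optional ``score`` holds a relevance score.
    Edge attributes: ``weight`` (> 0, finite) and ``etype`` in {ct, ppi}.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------
    def add_node(self, node: str, role: str, score: float | None = None) -> None:
        if node in self.graph:
            self.graph.nodes[node]["roles"].add(role)
            if score is not None:
                self.graph.nodes[node]["score"] = float(score)
        else:
            self.graph.add_node(node, roles={role},
                                score=None if score is None else float(score))

    def add_edge(self, u: str, v: str, weight: float = 1.0, etype: str = "ppi") -> None:
        if u == v:
            raise ValidationError(f"self-loop {u!r} not allowed")
        if not math.isfinite(weight) or weight <= 0:
            raise ValidationError(f"edge weight must be finite > 0, got {weight}")
        self.graph.add_edge(u, v, weight=float(weight), etype=etype)

    # -- queries ----------------------------------------------------------
    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if role in d["roles"]}

    @property
    def components(self) -> set[str]:
        return self.nodes_with_role(ROLE_COMPONENT)

    @property
    def targets(self) -> set[str]:
        return self.nodes_with_role(ROLE_TARGET)

    @property
    def disease_genes(self) -> set[str]:
        return self.nodes_with_role(ROLE_DISEASE)

    def score(self, node: str) -> float | None:
        return self.graph.nodes[node].get("score")

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class TopologyReport:
    degree: dict[str, int]
    betweenness: dict[str, float]
    heterogeneity: float
    centralization: float | None  # None when n < 3
    mean_degree_by_role: dict[str, float] = field(default_factory=dict)


@dataclass
class LipinskiThresholds:
    """Drug-likeness cut-offs: Lipinski's rule of five plus a Caco-2
    permeability floor (log10 cm/s, TCMSP convention). All configurable."""

    mw_max: float = 500.0
    logp_max: float = 5.0
    hbd_max: float = 5.0
    hba_max: float = 10.0
    caco2_min: float = -0.4


def filter_pathogenic_genes(scores: GeneScoreTable) -> set[str]:
    """Keep genes whose relevance score is strictly above the mean score."""
    if len(scores) == 0:
        raise ValidationError("empty gene score table")
    mean = scores.mean()
    kept = {g for g, s in scores.scores.items() if s > mean}
    if not kept:
        log.warning("filter_pathogenic_genes: no gene exceeds the mean score %.4g", mean)
    return kept


def filter_active_components(props: PropertyTable,
                             thresholds: LipinskiThresholds | None = None) -> set[str]:
    """Keep components passing the combined Lipinski + Caco-2 filter.

    A component missing any required field is rejected (and logged): an
    unknown property cannot be shown to pass.
    """
    th = thresholds or LipinskiThresholds()
    kept: set[str] = set()
    for comp, rec in props.records.items():
        missing = [name for name in ("mw", "logp", "hbd", "hba", "caco2")
                   if getattr(rec, name) is None]
        if missing:
            log.info("filter_active_components: %s rejected, missing %s", comp, missing)
            continue
        ok = (rec.mw <= th.mw_max and rec.logp <= th.logp_max
              and rec.hbd <= th.hbd_max and rec.hba <= th.hba_max
              and rec.caco2 >= th.caco2_min)
        if ok:
            kept.add(comp)
    return kept


def build_disease_network(ppi: EdgeTable, pathogenic: set[str],
                          scores: GeneScoreTable) -> WeightedNetwork:
    """Induce the PPI subgraph on the pathogenic genes.

    Nodes carry their relevance score; pathogenic genes absent from the PPI
    are dropped (the count is logged).
    """
    ppi_nodes = ppi.node_set()
    mapped = pathogenic & ppi_nodes
    if not mapped:
        raise ValidationError("no pathogenic gene maps to the PPI network")
    unmapped = len(pathogenic) - len(mapped)
    if unmapped:
        log.info("build_disease_network: %d pathogenic gene(s) absent from the PPI", unmapped)
    net = WeightedNetwork()
    for g in mapped:
        net.add_node(g, ROLE_DISEASE, score=scores.get(g, 0.0))
    for u, v, w in ppi.edges:
        if u in mapped and v in mapped:
            net.add_edge(u, v, weight=w if w > 0 else 1.0, etype="ppi")
    return net


def build_ct_network(ct: ComponentTargetTable, active: set[str]) -> WeightedNetwork:
    """Bipartite component-target network restricted to active components."""
    unknown = active - set(ct.targets)
    if unknown:
        raise ValidationError(f"active components not in the C-T table: {sorted(unknown)[:5]}")
    net = WeightedNetwork()
    for comp in sorted(active):
        genes = ct.targets[comp]
        if not genes:
            continue
        net.add_node(comp, ROLE_COMPONENT)
        for g in sorted(genes):
            net.add_node(g, ROLE_TARGET)
            net.add_edge(comp, g, weight=1.0, etype="ct")
    if net.number_of_nodes() == 0:
        raise ValidationError("C-T network is empty after restricting to active components")
    return net


def merge_ctpd(ct_net: WeightedNetwork, disease_net: WeightedNetwork) -> WeightedNetwork:
    """Union of the C-T and disease networks.

    Genes appearing in both keep a single node with both the target and
    disease_gene roles — these shared genes are what connect components to
    the disease module.
    """
    for name, net in (("C-T", ct_net), ("disease", disease_net)):
        if net.number_of_nodes() == 0:
            raise ValidationError(f"{name} network is empty")
    merged = WeightedNetwork()
    for src in (ct_net, disease_net):
        for n, d in src.graph.nodes(data=True):
            for role in sorted(d["roles"]):
                merged.add_node(n, role, score=d.get("score"))
        for u, v, d in src.graph.edges(data=True):
            merged.add_edge(u, v, weight=d["weight"], etype=d["etype"])
    return merged


def topology_stats(net: WeightedNetwork) -> TopologyReport:
    """Degree/betweenness per node plus whole-network heterogeneity and
    Freeman degree centralization. Betweenness is the standard normalised
    shortest-path betweenness (computed per connected component by the
    Brandes algorithm; unweighted paths)."""
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValidationError("empty network")
    degree = {v: d for v, d in g.degree()}
    ks = np.array(list(degree.values()), dtype=float)
    mean_k = ks.mean()
    heterogeneity = float(ks.std(ddof=0) / mean_k) if mean_k > 0 else 0.0
    if n < 3:
        centralization = None
        log.warning("topology_stats: centralization undefined for n < 3")
    else:
        centralization = float((ks.max() - ks).sum() / ((n - 1) * (n - 2)))
    betweenness = nx.betweenness_centrality(g, normalized=True)
    roles: dict[str, list[int]] = {}
    for v, d in g.nodes(data=True):
        for role in d.get("roles", ()):  # plain graphs may lack roles
            roles.setdefault(role, []).append(degree[v])
    mean_by_role = {r: float(np.mean(v)) for r, v in roles.items()}
    return TopologyReport(degree=degree, betweenness=betweenness,
                          heterogeneity=heterogeneity, centralization=centralization,
                          mean_degree_by_role=mean_by_role)
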