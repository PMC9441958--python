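"""Gene-set enrichment and motif-validation statistics.

Over-representation is tested one-sided with the hypergeometric upper tail:
for a universe of N genes, a term of K genes and a query of n genes with k
genes overlapping, p = P(X >= k), X ~ Hypergeom(N, K, n). Multiple testing
is controlled with Benjamini-Hochberg step-up FDR. The module also holds
the motif-validation helpers: set-overlap (Venn) reports, the centrality
baselines used to benchmark effective-protein selection, and the
term-coverage comparison between node selections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import UsageError, ValidationError
from .io import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "OverlapReport",
    "hypergeom_enrich",
    "adjust_bh",
    "set_overlap",
    "baseline_select",
    "compare_selections",
]


@dataclass
class EnrichmentResult:
    term: str
    description: str
    set_size: int  # K, after intersecting with the universe
    query_size: int  # n
    overlap: int  # k
    universe_size: int  # N
    p: float
    q: float  # BH-adjusted


@dataclass
class OverlapReport:
    size_a: int
    size_b: int
    intersection: int
    jaccard: float
    coincidence: float | None  # |A & B| / |A|; None when A is empty


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(query: set[str], collection: GeneSetCollection,
                     universe: set[str]) -> list[EnrichmentResult]:
    """One-sided over-representation of ``query`` in every term of the
    collection, against ``universe``; results sorted by q then term id."""
    if not universe:
        raise ValidationError("empty universe")
    query = set(query) & universe
    N = len(universe)
    n = len(query)
    rows = []
    for term in collection.terms():
        desc, members = collection.sets[term]
        K = len(members & universe)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append((term, desc, K, k, min(max(p, 0.0), 1.0)))
    qvals = adjust_bh([r[4] for r in rows])
    results = [
        EnrichmentResult(term=term, description=desc, set_size=K, query_size=n,
                         overlap=k, universe_size=N, p=p, q=float(q))
        for (term, desc, K, k, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.term))
    return results


def set_overlap(a: set, b: set) -> OverlapReport:
    """Venn arithmetic between a candidate set A and a reference set B;
    coincidence is the fraction of A also found in B."""
    inter = len(a & b)
    union = len(a | b)
    return OverlapReport(
        size_a=len(a), size_b=len(b), intersection=inter,
        jaccard=inter / union if union else 0.0,
        coincidence=inter / len(a) if a else None,
    )


_BASELINES = ("closeness", "avg_shortest_path", "neighborhood_connectivity")


def baseline_select(net, method: str, k: int) -> set[str]:
    """Top-k nodes by a classical centrality baseline.

    ``closeness`` and ``neighborhood_connectivity`` rank descending,
    ``avg_shortest_path`` ascending (shorter is more central). Disconnected
    graphs are handled per component (unreachable pairs excluded, flagged
    with a log message). Ties break by node id.
    """
    graph = net if isinstance(net, nx.Graph) else net.graph
    if method not in _BASELINES:
        raise UsageError(f"unknown method {method!r}; choose from {_BASELINES}")
    if k > graph.number_of_nodes():
        raise ValidationError(f"k={k} exceeds node count {graph.number_of_nodes()}")
    if not nx.is_connected(graph):
        log.warning("baseline_select: graph is disconnected; "
                    "path metrics computed within components only")
    if method == "closeness":
        metric = nx.closeness_centrality(graph)
        reverse = True
    elif method == "neighborhood_connectivity":
        metric = nx.average_neighbor_degree(graph)
        reverse = True
    else:  # mean shortest-path length to reachable nodes
        metric = {}
        for comp in nx.connected_components(graph):
            sub = graph.subgraph(comp)
            for v in comp:
                if len(comp) == 1:
                    metric[v] = float("inf")
                else:
                    lengths = nx.single_source_shortest_path_length(sub, v)
                    metric[v] = sum(lengths.values()) / (len(comp) - 1)
        reverse = False
    sign = -1.0 if reverse else 1.0
    ranked = sorted(graph.nodes, key=lambda v: (sign * metric[v], v))
    return set(ranked[:k])


def compare_selections(reference_terms: dict[str, set[str]],
                       intervention_terms: set[str]) -> list[tuple[str, float]]:
    """Fraction of the intervention term set recovered by each selection's
    enriched terms; sorted by descending coverage (ties by name)."""
    if not intervention_terms:
        raise ValidationError("empty intervention term set")
    table = [
        (name, len(terms & intervention_terms) / len(intervention_terms))
        for name, terms in reference_terms.items()
    ]
    table.sort(key=lambda r: (-r[1], r[0]))
    return table
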