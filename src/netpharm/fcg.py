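"""Functional components group (FCG) selection.

Inside the core intervention motifs (CIM) every target node is an
"effective protein". Each candidate component t is summarised by

* H_t — its target coverage: how many effective proteins it targets;
* L_t — its contribution index toward the pathogenic genes: by default the
  sum of the relevance scores of the pathogenic effective proteins it
  targets (``score_sum`` mode); ``count`` mode counts them instead.

Two selectors are provided.  The target-coverage-accumulation (TCA)
knapsack maximises the cumulative contribution index

    CCI = max sum_t L_t y_t   subject to  sum_t H_t y_t <= S,  y_t in {0,1}

by the exact dynamic program m(t, S_sub) = max{m(t+1, S_sub),
m(t+1, S_sub - H_t) + L_t}.  The greedy union-coverage selector orders
components by marginal gain of effective-protein coverage and cuts the
ranking at the first prefix reaching a coverage threshold (default 90%);
this is the default FCG extraction because the knapsack objective is
additive and ignores target-set overlap between components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import UsageError, ValidationError
from .io import ComponentTargetTable, GeneScoreTable
from .motifs import MotifSet
from .networks import WeightedNetwork, filter_pathogenic_genes

log = logging.getLogger(__name__)

__all__ = [
    "EffectiveProtein",
    "EffectiveProteinSet",
    "KnapsackItem",
    "KnapsackInstance",
    "FCGSelection",
    "score_effective_proteins",
    "component_metrics",
    "knapsack_select",
    "greedy_coverage",
]


@dataclass
class EffectiveProtein:
    protein: str
    importance: float
    module_id: int


@dataclass
class EffectiveProteinSet:
    """CIM target proteins ranked by importance (descending, ties by id)."""

    proteins: list[EffectiveProtein] = field(default_factory=list)

    def names(self) -> set[str]:
        return {p.protein for p in self.proteins}

    def ordered_names(self) -> list[str]:
        return [p.protein for p in self.proteins]

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class KnapsackItem:
    component: str
    coverage: int  # H_t
    value: float  # L_t


@dataclass
class KnapsackInstance:
    items: list[KnapsackItem]
    budget: int  # S
    selected: list[str] = field(default_factory=list)  # components with y_t = 1
    cci: float = 0.0

    def total_coverage(self) -> int:
        chosen = set(self.selected)
        return sum(it.coverage for it in self.items if it.component in chosen)


@dataclass
class FCGSelection:
    """Greedy coverage-accumulation ranking and the selected FCG prefix."""

    order: list[str]  # all candidate components, greedy order
    coverage_curve: list[float]  # cumulative fraction of effective proteins
    threshold: float
    fcg: list[str]  # shortest prefix reaching the threshold
    threshold_reached: bool = True

    def final_coverage(self) -> float:
        return self.coverage_curve[-1] if self.coverage_curve else 0.0


def _minmax(values: dict[str, float]) -> dict[str, float]:
    lo, hi = min(values.values()), max(values.values())
    if hi <= lo:
        return {k: 0.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def score_effective_proteins(cim: MotifSet, net: WeightedNetwork,
                             scores: GeneScoreTable,
                             keep_fraction: float = 1.0) -> EffectiveProteinSet:
    """Rank CIM targets by importance = scaled connectivity + scaled influence.

    Connectivity is the node degree within the CIM-induced subgraph;
    influence is the disease relevance score (0 for non-pathogenic targets).
    Both are min-max scaled to [0, 1] over the CIM targets, so the best
    possible importance is 2.0. Returns the top ``keep_fraction`` of
    targets (default all), sorted descending with ties broken by node id.
    """
    if not (0 < keep_fraction <= 1):
        raise UsageError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if len(cim) == 0:
        raise ValidationError("empty motif set")
    cim_nodes = cim.all_nodes()
    sub = net.graph.subgraph(cim_nodes)
    module_of = {t: m.module_id for m in cim.modules for t in m.targets}
    targets = sorted(module_of)
    if not targets:
        raise ValidationError("CIM contains no target nodes")
    degree = {t: sub.degree(t) for t in targets}
    relevance = {t: float(scores.get(t, 0.0)) for t in targets}
    zd, zr = _minmax(degree), _minmax(relevance)
    ranked = sorted(targets, key=lambda t: (-(zd[t] + zr[t]), t))
    n_keep = max(1, math.ceil(keep_fraction * len(ranked)))
    proteins = [EffectiveProtein(protein=t, importance=zd[t] + zr[t],
                                 module_id=module_of[t])
                for t in ranked[:n_keep]]
    return EffectiveProteinSet(proteins=proteins)


def component_metrics(ct: ComponentTargetTable, effective: EffectiveProteinSet,
                      scores: GeneScoreTable, mode: str = "score_sum",
                      pathogenic: set[str] | None = None) -> list[KnapsackItem]:
    """Per-component H_t (effective proteins targeted) and L_t (contribution
    toward pathogenic genes).

    ``mode='score_sum'`` (default): L_t is the summed relevance score of the
    pathogenic effective proteins the component targets. ``mode='count'``:
    L_t counts them. ``pathogenic`` defaults to the above-mean-score rule
    applied to ``scores``. Components with H_t = 0 are excluded (logged).
    """
    if mode not in ("score_sum", "count"):
        raise UsageError(f"unknown L_t mode {mode!r}")
    if len(effective) == 0:
        raise ValidationError("empty effective protein set")
    if pathogenic is None:
        pathogenic = filter_pathogenic_genes(scores)
    eff = effective.names()
    items: list[KnapsackItem] = []
    n_excluded = 0
    for comp in ct.components():
        hits = ct.targets[comp] & eff
        if not hits:
            n_excluded += 1
            continue
        patho_hits = hits & pathogenic
        if mode == "count":
            value = float(len(patho_hits))
        else:
            value = float(sum(scores.get(g, 0.0) for g in patho_hits))
        items.append(KnapsackItem(component=comp, coverage=len(hits), value=value))
    if n_excluded:
        log.info("component_metrics: excluded %d component(s) with H_t = 0", n_excluded)
    if not items:
        raise ValidationError("every component has zero effective-target coverage")
    return items


def knapsack_select(items: list[KnapsackItem], budget: int) -> KnapsackInstance:
    """Exact 0/1 knapsack by the m(t, S_sub) dynamic program.

    Maximises CCI = sum L_t y_t under sum H_t y_t <= budget. Ties prefer
    excluding the item (the first branch of the recursion), making the
    solution deterministic. ``budget`` below the smallest H_t yields the
    valid empty selection with CCI = 0.
    """
    if budget <= 0:
        raise ValidationError(f"budget S must be > 0, got {budget}")
    for it in items:
        if it.coverage <= 0:
            raise ValidationError(f"H_t must be > 0 (component {it.component})")
        if int(it.coverage) != it.coverage:
            raise ValidationError(f"H_t must be an integer count (component {it.component})")
    S = int(budget)
    n = len(items)
    if min((it.coverage for it in items), default=0) > S:
        log.info("knapsack_select: budget %d below smallest H_t; empty selection", S)
        return KnapsackInstance(items=list(items), budget=S, selected=[], cci=0.0)
    # m[t][s]: optimum over items t..n-1 with remaining capacity s
    m = [[0.0] * (S + 1) for _ in range(n + 1)]
    for t in range(n - 1, -1, -1):
        H, L = items[t].coverage, items[t].value
        row, nxt = m[t], m[t + 1]
        for s in range(S + 1):
            best = nxt[s]
            if s >= H:
                take = nxt[s - H] + L
                if take > best:  # strict: equal value prefers exclusion
                    best = take
            row[s] = best
    selected: list[str] = []
    s = S
    for t in range(n):
        H, L = items[t].coverage, items[t].value
        if s >= H and m[t + 1][s - H] + L > m[t + 1][s]:
            selected.append(items[t].component)
            s -= H
    return KnapsackInstance(items=list(items), budget=S, selected=selected,
                            cci=float(m[0][S]))


def greedy_coverage(ct: ComponentTargetTable, effective: EffectiveProteinSet,
                    threshold: float = 0.90,
                    values: dict[str, float] | None = None) -> FCGSelection:
    """Greedy union-coverage accumulation of effective proteins.

    At every step adds the component with the largest marginal gain of
    uncovered effective proteins (ties: larger contribution value L_t if
    ``values`` is given, then lexicographic id), recording the cumulative
    coverage fraction. The FCG is the shortest prefix whose coverage
    reaches ``threshold``; if the candidates cannot reach it, the full
    ranking is returned flagged (and a warning logged).
    """
    if not (0 < threshold <= 1):
        raise UsageError(f"threshold must be in (0, 1], got {threshold}")
    if len(effective) == 0:
        raise ValidationError("empty effective protein set")
    eff = effective.names()
    candidates = {c: ct.targets[c] & eff for c in ct.components()}
    candidates = {c: hits for c, hits in candidates.items() if hits}
    if not candidates:
        raise ValidationError("no component targets any effective protein")
    vals = values or {}
    covered: set[str] = set()
    order: list[str] = []
    curve: list[float] = []
    remaining = dict(candidates)
    total = len(eff)
    while remaining:
        best = min(
            remaining,
            key=lambda c: (-len(remaining[c] - covered), -vals.get(c, 0.0), c),
        )
        covered |= remaining.pop(best)
        order.append(best)
        curve.append(len(covered) / total)
    fcg: list[str] = []
    reached = False
    for i, cov in enumerate(curve):
        if cov >= threshold - 1e-12:
            fcg = order[: i + 1]
            reached = True
            break
    if not reached:
        log.warning("greedy_coverage: achievable coverage %.4f below threshold %.4f",
                    curve[-1], threshold)
        fcg = list(order)
    return FCGSelection(order=order, coverage_curve=curve, threshold=threshold,
                        fcg=fcg, threshold_reached=reached)
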