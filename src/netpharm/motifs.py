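"""Map-equation motif detection on weighted networks.

A random walker moves over the undirected network with row-normalised edge
weights omega_ab and restarts uniformly at rate tau (teleportation). The
stationary visit rates p_a solve

    p = tau/n + (1 - tau) * p @ omega.

Given a partition into modules, the probability that a step of the walk
exits module i is

    q_i = tau * (n - n_i)/n * sum_{a in i} p_a
          + (1 - tau) * sum_{a in i} sum_{b not in i} p_a * omega_ab,

and the quality of the partition is the two-level map-equation codelength

    L = q_total * H(Q) + sum_i p_i_circ * H(P_i)   [bits],

where q_total = sum_i q_i, Q = {q_i / q_total}, p_i_circ = q_i + module
visit mass, and P_i mixes q_i with the member visit rates. Lower L means the
partition compresses the walk better, i.e. captures genuine modules.

The optimizer is a deterministic seeded local-move scheme: starting from
singleton modules, it sweeps single-node moves (accepting the move that most
decreases L, ties broken by smallest destination module id), then greedy
module merges, repeating both phases until no move improves L by more than
1e-12. Dangling (degree-zero) nodes are given uniform transition rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .errors import ConvergenceError, ValidationError
from .networks import WeightedNetwork, as_graph

log = logging.getLogger(__name__)

__all__ = [
    "RandomWalkModel",
    "Partition",
    "ModuleStats",
    "CimModule",
    "MotifSet",
    "build_random_walk",
    "module_exit_probability",
    "map_codelength",
    "optimize_partition",
    "extract_cim",
]

_EPS_MOVE = 1e-12


def _plogp(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


@dataclass
class RandomWalkModel:
    """Row-stochastic walk with uniform teleportation and its stationary
    visit rates."""

    nodes: list[str]
    tau: float
    transition: sp.csr_matrix  # rows of dangling nodes are all-zero here
    dangling: np.ndarray  # bool mask; conceptually a uniform row 1/n
    p: np.ndarray  # stationary visit rates, sums to 1

    def __post_init__(self):
        self.index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class ModuleStats:
    n_members: int
    visit_mass: float
    exit_probability: float


@dataclass
class Partition:
    """Node -> module assignment plus per-module flow statistics and the
    total codelength in bits."""

    assignment: dict[str, int]
    modules: dict[int, ModuleStats]
    codelength: float
    n: int
    tau: float

    def members(self, module_id: int) -> list[str]:
        return sorted(v for v, m in self.assignment.items() if m == module_id)

    def n_modules(self) -> int:
        return len(self.modules)


def build_random_walk(net, tau: float = 0.15, tol: float = 1e-10,
                      max_iter: int = 10000) -> RandomWalkModel:
    """Build the teleporting random walk and solve for its visit rates.

    The stationary distribution is found by power iteration to an L1
    residual below ``tol``.
    """
    graph = as_graph(net)
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValidationError("cannot build a random walk on an empty network")
    if not (0 <= tau < 1):
        raise ValidationError(f"teleportation rate must be in [0, 1), got {tau}")
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        i, j = index[u], index[v]
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((w, w))
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    row_sum = np.asarray(W.sum(axis=1)).ravel()
    dangling = row_sum == 0
    inv = np.zeros(n)
    inv[~dangling] = 1.0 / row_sum[~dangling]
    P = sp.diags(inv) @ W  # dangling rows stay zero; treated as uniform below

    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        step = tau / n + (1 - tau) * (p @ P + p[dangling].sum() / n)
        # lazy-walk damping: same fixed point, aperiodic even at tau = 0
        p_new = 0.5 * p + 0.5 * np.asarray(step).ravel()
        resid = np.abs(p_new - p).sum()
        p = p_new
        if resid < 0.5 * tol:
            break
    else:
        raise ConvergenceError(
            f"power iteration did not reach tol={tol} in {max_iter} iterations",
            residual=resid)
    p = p / p.sum()
    return RandomWalkModel(nodes=nodes, tau=tau, transition=P.tocsr(),
                           dangling=dangling, p=p)


def _labels_array(partition: Mapping[str, int], model: RandomWalkModel) -> np.ndarray:
    missing = [v for v in model.nodes if v not in partition]
    if missing:
        raise ValidationError(f"partition does not cover nodes {missing[:5]}")
    return np.array([partition[v] for v in model.nodes])


def _exit_vector(labels: np.ndarray, model: RandomWalkModel):
    """Per-module (n_i, mass_i, q_i) under the printed exit-probability
    formula, vectorised over the sparse flow matrix."""
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    n = model.n
    n_i = np.bincount(inv, minlength=k).astype(float)
    mass = np.bincount(inv, weights=model.p, minlength=k)
    # sparse flow out of each module: sum_a p_a - within-module flow
    F = sp.diags(model.p) @ model.transition  # f_ab = p_a * omega_ab
    coo = F.tocoo()
    same = inv[coo.row] == inv[coo.col]
    within = np.bincount(inv[coo.row][same], weights=coo.data[same], minlength=k)
    sparse_mass = np.bincount(inv, weights=np.where(model.dangling, 0.0, model.p),
                              minlength=k)
    exit_sparse = sparse_mass - within
    dmass = np.bincount(inv, weights=np.where(model.dangling, model.p, 0.0),
                        minlength=k)
    frac_out = (n - n_i) / n
    q = model.tau * frac_out * mass + (1 - model.tau) * (exit_sparse + dmass * frac_out)
    q = np.maximum(q, 0.0)
    return uniq, n_i, mass, q


def module_exit_probability(partition: Mapping[str, int],
                            model: RandomWalkModel) -> dict[int, float]:
    """Exit probability q_i of every module under the current partition."""
    labels = _labels_array(partition, model)
    uniq, _, _, q = _exit_vector(labels, model)
    return {int(m): float(qi) for m, qi in zip(uniq, q)}


def _codelength_from(q: np.ndarray, mass: np.ndarray, p: np.ndarray) -> float:
    qT = q.sum()
    L = (_plogp(np.array([qT]))[0]
         - 2.0 * _plogp(q).sum()
         + _plogp(q + mass).sum()
         - _plogp(p).sum())
    return float(max(L, 0.0))


def map_codelength(partition: Mapping[str, int], model: RandomWalkModel) -> float:
    """Two-level map-equation codelength in bits (0*log 0 treated as 0)."""
    labels = _labels_array(partition, model)
    _, _, mass, q = _exit_vector(labels, model)
    return _codelength_from(q, mass, model.p)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class _Optimizer:
    """Incremental local-move/merge optimisation of the codelength.

    Per-module state (member count, visit mass, sparse exit flow, dangling
    mass) is updated in O(deg) per accepted move, so the codelength never
    has to be recomputed from scratch inside the sweeps.
    """

    def __init__(self, model: RandomWalkModel):
        self.model = model
        n = model.n
        self.n = n
        p = model.p
        # adjacency with both flow directions per node
        P = model.transition
        self.nbrs: list[np.ndarray] = []
        self.f_out: list[np.ndarray] = []  # p_v * omega_vu
        self.f_in: list[np.ndarray] = []  # p_u * omega_uv
        F = (sp.diags(p) @ P).tocsr()
        FT = F.T.tocsr()
        for v in range(n):
            s, e = F.indptr[v], F.indptr[v + 1]
            self.nbrs.append(F.indices[s:e].copy())
            self.f_out.append(F.data[s:e].copy())
            st, et = FT.indptr[v], FT.indptr[v + 1]
            # CSR of F and F^T have identical sparsity per row for symmetric
            # structure; align incoming flows with the same neighbor order.
            fin = {int(j): float(x) for j, x in zip(FT.indices[st:et], FT.data[st:et])}
            self.f_in.append(np.array([fin.get(int(j), 0.0) for j in self.nbrs[v]]))
        self.labels = np.arange(n)
        self.n_i = {v: 1 for v in range(n)}
        self.mass = {v: float(p[v]) for v in range(n)}
        self.exitsp = {v: 0.0 if model.dangling[v] else float(p[v]) for v in range(n)}
        self.dmass = {v: float(p[v]) if model.dangling[v] else 0.0 for v in range(n)}
        self.q = {v: self._q_of(v) for v in range(n)}
        self.qT = sum(self.q.values())
        self.const = -_plogp(p).sum()
        self.L = self._full_L()

    # -- codelength pieces -------------------------------------------------
    def _q_from(self, n_i, mass, exitsp, dmass) -> float:
        frac = (self.n - n_i) / self.n
        tau = self.model.tau
        return max(tau * frac * mass + (1 - tau) * (exitsp + dmass * frac), 0.0)

    def _q_of(self, m) -> float:
        return self._q_from(self.n_i[m], self.mass[m], self.exitsp[m], self.dmass[m])

    @staticmethod
    def _term(q, mass) -> float:
        t = 0.0
        if q > 0:
            t -= 2.0 * q * np.log2(q)
        pc = q + mass
        if pc > 0:
            t += pc * np.log2(pc)
        return t

    def _full_L(self) -> float:
        qT = self.qT
        L = (qT * np.log2(qT) if qT > 0 else 0.0) + self.const
        for m in self.q:
            L += self._term(self.q[m], self.mass[m])
        return float(L)

    # -- node moves --------------------------------------------------------
    def _move_delta(self, v: int, a: int, b: int, fva, fav, fvb, fbv):
        """Codelength change if node v moves from module a to module b.

        f?? are the sparse flows between v and the current members of a and
        b (v->a, a->v, v->b, b->v)."""
        p_v = float(self.model.p[v])
        dang = bool(self.model.dangling[v])
        na, ma, ea, da = self.n_i[a], self.mass[a], self.exitsp[a], self.dmass[a]
        nb, mb, eb, db = self.n_i[b], self.mass[b], self.exitsp[b], self.dmass[b]
        if dang:
            na2, ma2, ea2, da2 = na - 1, ma - p_v, ea, da - p_v
            nb2, mb2, eb2, db2 = nb + 1, mb + p_v, eb, db + p_v
        else:
            na2, ma2 = na - 1, ma - p_v
            ea2 = ea - (p_v - fva) + fav
            da2 = da
            nb2, mb2 = nb + 1, mb + p_v
            eb2 = eb + (p_v - fvb) - fbv
            db2 = db
        qa, qb = self.q[a], self.q[b]
        qa2 = self._q_from(na2, ma2, ea2, da2) if na2 > 0 else 0.0
        qb2 = self._q_from(nb2, mb2, eb2, db2)
        qT2 = self.qT - qa - qb + qa2 + qb2
        delta = ((qT2 * np.log2(qT2) if qT2 > 0 else 0.0)
                 - (self.qT * np.log2(self.qT) if self.qT > 0 else 0.0))
        delta -= self._term(qa, ma) + self._term(qb, mb)
        if na2 > 0:
            delta += self._term(qa2, ma2)
        delta += self._term(qb2, mb2)
        new_a = (na2, ma2, ea2, da2, qa2)
        new_b = (nb2, mb2, eb2, db2, qb2)
        return float(delta), new_a, new_b

    def sweep(self, order: np.ndarray) -> int:
        moved = 0
        for v in order:
            v = int(v)
            a = int(self.labels[v])
            nbrs = self.nbrs[v]
            if len(nbrs) == 0:
                continue
            # group flows by candidate module
            fout: dict[int, float] = {}
            fin: dict[int, float] = {}
            for j, fo, fi in zip(nbrs, self.f_out[v], self.f_in[v]):
                m = int(self.labels[j])
                fout[m] = fout.get(m, 0.0) + float(fo)
                fin[m] = fin.get(m, 0.0) + float(fi)
            fva, fav = fout.get(a, 0.0), fin.get(a, 0.0)
            best = None
            for b in sorted(set(fout) - {a}):
                delta, new_a, new_b = self._move_delta(
                    v, a, b, fva, fav, fout.get(b, 0.0), fin.get(b, 0.0))
                if delta < -_EPS_MOVE and (best is None or delta < best[0] - _EPS_MOVE):
                    best = (delta, b, new_a, new_b)
            if best is None:
                continue
            delta, b, new_a, new_b = best
            self._apply_move(v, a, b, new_a, new_b, delta)
            moved += 1
        return moved

    def _apply_move(self, v, a, b, new_a, new_b, delta):
        na2, ma2, ea2, da2, qa2 = new_a
        nb2, mb2, eb2, db2, qb2 = new_b
        self.qT += qa2 + qb2 - self.q[a] - self.q[b]
        if na2 == 0:
            for d in (self.n_i, self.mass, self.exitsp, self.dmass, self.q):
                del d[a]
        else:
            self.n_i[a], self.mass[a], self.exitsp[a], self.dmass[a], self.q[a] = \
                na2, ma2, ea2, da2, qa2
        self.n_i[b], self.mass[b], self.exitsp[b], self.dmass[b], self.q[b] = \
            nb2, mb2, eb2, db2, qb2
        self.labels[v] = b
        assert delta < -_EPS_MOVE  # accepted moves strictly decrease L
        self.L += delta

    # -- merges ------------------------------------------------------------
    def _inter_flows(self) -> dict[tuple[int, int], float]:
        flows: dict[tuple[int, int], float] = {}
        for v in range(self.n):
            a = int(self.labels[v])
            for j, fo in zip(self.nbrs[v], self.f_out[v]):
                b = int(self.labels[j])
                if a != b:
                    flows[(a, b)] = flows.get((a, b), 0.0) + float(fo)
        return flows

    def merge_pass(self) -> int:
        merges = 0
        while True:
            flows = self._inter_flows()
            pairs = sorted({(min(a, b), max(a, b)) for a, b in flows})
            best = None
            for a, b in pairs:
                n2 = self.n_i[a] + self.n_i[b]
                m2 = self.mass[a] + self.mass[b]
                e2 = (self.exitsp[a] + self.exitsp[b]
                      - flows.get((a, b), 0.0) - flows.get((b, a), 0.0))
                d2 = self.dmass[a] + self.dmass[b]
                q2 = self._q_from(n2, m2, e2, d2)
                qT2 = self.qT - self.q[a] - self.q[b] + q2
                delta = ((qT2 * np.log2(qT2) if qT2 > 0 else 0.0)
                         - (self.qT * np.log2(self.qT) if self.qT > 0 else 0.0))
                delta -= self._term(self.q[a], self.mass[a])
                delta -= self._term(self.q[b], self.mass[b])
                delta += self._term(q2, m2)
                if delta < -_EPS_MOVE and (best is None or delta < best[0] - _EPS_MOVE):
                    best = (float(delta), a, b, (n2, m2, e2, d2, q2))
            if best is None:
                return merges
            delta, a, b, (n2, m2, e2, d2, q2) = best
            self.qT += q2 - self.q[a] - self.q[b]
            self.labels[self.labels == b] = a
            self.n_i[a], self.mass[a], self.exitsp[a], self.dmass[a], self.q[a] = \
                n2, m2, e2, d2, q2
            for d in (self.n_i, self.mass, self.exitsp, self.dmass, self.q):
                del d[b]
            assert delta < -_EPS_MOVE
            self.L += delta
            merges += 1


def optimize_partition(net, tau: float = 0.15, seed: int = 0) -> Partition:
    """Seeded local-move + merge minimisation of the map-equation codelength.

    Deterministic given ``seed`` (which only shuffles the node visiting
    order). Starts from singleton modules; stops when no single-node move or
    module merge decreases the codelength by more than 1e-12.
    """
    model = build_random_walk(net, tau=tau)
    opt = _Optimizer(model)
    rng = np.random.default_rng(seed)
    for _round in range(200):
        changed = 0
        for _sweep in range(200):
            order = rng.permutation(model.n)
            moved = opt.sweep(order)
            changed += moved
            if moved == 0:
                break
        merged = opt.merge_pass()
        changed += merged
        if changed == 0:
            break

    # relabel modules contiguously, ordered by their smallest member node
    members: dict[int, list[str]] = {}
    for idx, m in enumerate(opt.labels):
        members.setdefault(int(m), []).append(model.nodes[idx])
    order = sorted(members, key=lambda m: min(members[m]))
    relabel = {old: new for new, old in enumerate(order)}
    assignment = {v: relabel[int(m)] for v, m in zip(model.nodes, opt.labels)}

    q = module_exit_probability(assignment, model)
    L = map_codelength(assignment, model)
    if not np.isclose(L, opt.L, rtol=0, atol=1e-8):  # guard against drift
        log.warning("optimize_partition: incremental L %.12g vs exact %.12g", opt.L, L)
    modules = {}
    for m in sorted(set(assignment.values())):
        mem = [v for v in model.nodes if assignment[v] == m]
        mass = float(sum(model.p[model.index[v]] for v in mem))
        modules[m] = ModuleStats(n_members=len(mem), visit_mass=mass,
                                 exit_probability=q[m])
    return Partition(assignment=assignment, modules=modules, codelength=L,
                     n=model.n, tau=tau)


# ---------------------------------------------------------------------------
# CIM extraction
# ---------------------------------------------------------------------------


@dataclass
class CimModule:
    module_id: int
    components: list[str]
    targets: list[str]
    pathogenic_genes: list[str]
    pathogenic_score_sum: float


@dataclass
class MotifSet:
    """Core intervention motifs: retained modules ordered by descending
    pathogenic relevance score sum."""

    modules: list[CimModule] = field(default_factory=list)

    def all_components(self) -> set[str]:
        return {c for m in self.modules for c in m.components}

    def all_targets(self) -> set[str]:
        return {t for m in self.modules for t in m.targets}

    def all_nodes(self) -> set[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= set(m.components) | set(m.targets)
            out |= set(m.pathogenic_genes)
        return out

    def __len__(self) -> int:
        return len(self.modules)


def extract_cim(partition: Partition, net: WeightedNetwork, pathogenic: set[str],
                min_pathogenic: int = 1, top_k: int | None = None) -> MotifSet:
    """Retain modules with at least one component node and at least
    ``min_pathogenic`` pathogenic genes; rank by descending sum of the
    contained pathogenic genes' relevance scores, truncate to ``top_k``."""
    comp_nodes = net.components
    target_nodes = net.targets
    by_module: dict[int, list[str]] = {}
    for v, m in partition.assignment.items():
        by_module.setdefault(m, []).append(v)
    modules: list[CimModule] = []
    for m, nodes in by_module.items():
        comps = sorted(n for n in nodes if n in comp_nodes)
        if not comps:
            continue
        path_genes = sorted(n for n in nodes if n in pathogenic)
        if len(path_genes) < min_pathogenic:
            continue
        score_sum = 0.0
        for g in path_genes:
            s = net.score(g)
            score_sum += float(s) if s is not None else 0.0
        targets = sorted(n for n in nodes if n in target_nodes)
        modules.append(CimModule(module_id=m, components=comps, targets=targets,
                                 pathogenic_genes=path_genes,
                                 pathogenic_score_sum=score_sum))
    if not modules:
        raise ValidationError(
            "no module qualifies as a core intervention motif "
            f"(min_pathogenic={min_pathogenic})")
    modules.sort(key=lambda m: (-m.pathogenic_score_sum, m.module_id))
    if top_k is not None:
        modules = modules[:top_k]
    return MotifSet(modules=modules)
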