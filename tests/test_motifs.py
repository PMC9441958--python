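import itertools
import math

import networkx as nx
import numpy as np
import pytest

import netpharm as nph
from netpharm.errors import ValidationError
from netpharm.motifs import (build_random_walk, extract_cim, map_codelength,
                             module_exit_probability, optimize_partition)


def _dense_omega(model):
    """Dense row-stochastic transition matrix, dangling rows uniform."""
    omega = model.transition.toarray()
    n = model.n
    omega[model.dangling] = 1.0 / n
    return omega


def _brute_exit(partition, model):
    """Literal double-sum evaluation of the exit-probability formula."""
    omega = _dense_omega(model)
    n = model.n
    idx = model.index
    modules = sorted(set(partition.values()))
    out = {}
    for m in modules:
        members = [v for v in model.nodes if partition[v] == m]
        others = [v for v in model.nodes if partition[v] != m]
        n_i = len(members)
        mass = sum(model.p[idx[a]] for a in members)
        flow = sum(model.p[idx[a]] * omega[idx[a], idx[b]]
                   for a in members for b in others)
        out[m] = model.tau * (n - n_i) / n * mass + (1 - model.tau) * flow
    return out


def _entropy_bits(probs):
    return -sum(p * math.log2(p) for p in probs if p > 0)


def _brute_codelength(partition, model):
    """Direct evaluation of the two-level map equation from its definition."""
    q = _brute_exit(partition, model)
    q_total = sum(q.values())
    L = 0.0
    if q_total > 0:
        L += q_total * _entropy_bits([qi / q_total for qi in q.values()])
    for m in q:
        members = [v for v in model.nodes if partition[v] == m]
        mass = sum(model.p[model.index[v]] for v in members)
        p_circ = q[m] + mass
        inner = [q[m] / p_circ] + [model.p[model.index[v]] / p_circ for v in members]
        L += p_circ * _entropy_bits(inner)
    return L


def _random_weighted_graph(n, p_edge, seed):
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p_edge, seed=int(seed))
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    for u, v in g.edges():
        g[u][v]["weight"] = float(rng.uniform(0.1, 3.0))
    # keep isolated nodes: they exercise the dangling rule
    return g


class TestRandomWalk:
    def test_symmetric_cycle_uniform_rates(self):
        g = nx.cycle_graph(3)
        model = build_random_walk(g, tau=0.25)
        assert model.p == pytest.approx([1 / 3] * 3, abs=1e-9)

    def test_two_nodes_symmetric(self):
        g = nx.Graph([("A", "B")])
        model = build_random_walk(g, tau=0.15)
        assert model.p == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_dangling_node_keeps_mass_normalised(self):
        g = nx.Graph([("A", "B")])
        g.add_node("C")  # isolated: uniform transition row
        model = build_random_walk(g, tau=0.15)
        assert model.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert model.dangling[model.index["C"]]

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValidationError):
            build_random_walk(nx.path_graph(3), tau=1.0)

    @pytest.mark.parametrize("tau", [0.0, 0.15, 0.5])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_visit_rates_sum_to_one(self, tau, seed):
        g = _random_weighted_graph(25, 0.15, seed)
        model = build_random_walk(g, tau=tau)
        assert model.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert (model.p >= 0).all()


class TestExitProbability:
    def test_single_module_exits_nowhere(self):
        g = nx.path_graph(4)
        model = build_random_walk(g, tau=0.15)
        q = module_exit_probability({v: 0 for v in g.nodes}, model)
        assert q[0] == pytest.approx(0.0, abs=1e-15)

    def test_two_node_singletons_tau_zero(self):
        model = build_random_walk(nx.Graph([("A", "B")]), tau=0.0)
        q = module_exit_probability({"A": 0, "B": 1}, model)
        assert q[0] == pytest.approx(0.5, abs=1e-12)

    def test_two_node_singletons_with_teleportation(self):
        # tau*(1/2)*0.5 + (1-tau)*0.5 with tau = 0.15
        model = build_random_walk(nx.Graph([("A", "B")]), tau=0.15)
        q = module_exit_probability({"A": 0, "B": 1}, model)
        assert q[0] == pytest.approx(0.4625, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.0, 0.15, 0.3])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_double_sum_oracle(self, tau, seed):
        g = _random_weighted_graph(24, 0.15, seed)
        model = build_random_walk(g, tau=tau)
        rng = np.random.default_rng(seed)
        partition = {v: int(rng.integers(4)) for v in model.nodes}
        fast = module_exit_probability(partition, model)
        brute = _brute_exit(partition, model)
        for m in brute:
            assert fast[m] == pytest.approx(brute[m], abs=1e-12)


class TestCodelength:
    def test_single_node_single_module_is_zero(self):
        g = nx.Graph()
        g.add_node("A")
        model = build_random_walk(g, tau=0.15)
        assert map_codelength({"A": 0}, model) == pytest.approx(0.0, abs=1e-12)

    def test_two_node_one_module_is_one_bit(self):
        model = build_random_walk(nx.Graph([("A", "B")]), tau=0.15)
        assert map_codelength({"A": 0, "B": 0}, model) == pytest.approx(1.0, abs=1e-12)

    def test_one_module_codelength_equals_visit_entropy(self):
        g = _random_weighted_graph(20, 0.2, 3)
        model = build_random_walk(g, tau=0.15)
        L = map_codelength({v: 0 for v in model.nodes}, model)
        assert L == pytest.approx(_entropy_bits(model.p), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_definition_oracle(self, seed):
        g = _random_weighted_graph(18, 0.2, seed)
        model = build_random_walk(g, tau=0.15)
        rng = np.random.default_rng(seed)
        partition = {v: int(rng.integers(3)) for v in model.nodes}
        assert map_codelength(partition, model) == pytest.approx(
            _brute_codelength(partition, model), abs=1e-12)


def _set_partitions(items):
    """All set partitions (Bell number enumeration) of a small list."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
        yield [[head]] + part


class TestOptimizer:
    def test_two_cliques_split_into_two_modules(self, two_clique_graph):
        part = optimize_partition(two_clique_graph, tau=0.15, seed=0)
        labels = {frozenset(v for v, m in part.assignment.items() if m == mid)
                  for mid in set(part.assignment.values())}
        assert labels == {frozenset({"a0", "a1", "a2", "a3"}),
                          frozenset({"b0", "b1", "b2", "b3"})}
        model = build_random_walk(two_clique_graph, tau=0.15)
        one_module = map_codelength({v: 0 for v in two_clique_graph.nodes}, model)
        assert part.codelength < one_module

    def test_k4_single_module_is_global_optimum(self):
        """Exhaustive check over all 15 partitions of K4."""
        g = nx.complete_graph(4)
        model = build_random_walk(g, tau=0.15)
        nodes = list(g.nodes)
        best = min(
            (map_codelength({v: i for i, block in enumerate(p) for v in block}, model)
             for p in _set_partitions(nodes)),
        )
        part = optimize_partition(g, tau=0.15, seed=0)
        assert part.n_modules() == 1
        assert part.codelength == pytest.approx(best, abs=1e-12)

    def test_same_seed_same_partition(self, two_clique_graph):
        p1 = optimize_partition(two_clique_graph, tau=0.15, seed=11)
        p2 = optimize_partition(two_clique_graph, tau=0.15, seed=11)
        assert p1.assignment == p2.assignment
        assert p1.codelength == p2.codelength

    def test_partition_stats_consistent(self, two_clique_graph):
        part = optimize_partition(two_clique_graph, tau=0.15, seed=0)
        assert part.n == 8
        assert sum(s.n_members for s in part.modules.values()) == 8
        assert sum(s.visit_mass for s in part.modules.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(s.exit_probability >= 0 for s in part.modules.values())

    def test_planted_blocks_recovered(self):
        from sklearn.metrics import normalized_mutual_info_score

        ct, labels = nph.simulate_ct(n_components=20, n_targets=80, seed=3)
        g = nx.Graph()
        for c, ts in ct.targets.items():
            for t in ts:
                g.add_edge(c, t, weight=1.0)
        part = optimize_partition(g, tau=0.15, seed=3)
        nodes = sorted(g.nodes)
        nmi = normalized_mutual_info_score(
            [labels[v] for v in nodes], [part.assignment[v] for v in nodes])
        assert nmi >= 0.8


class TestExtractCim:
    def _toy(self):
        net = nph.WeightedNetwork()
        net.add_node("c1", "component")
        net.add_node("c2", "component")
        for g, s in (("A", 5.0), ("B", 3.0)):
            net.add_node(g, "target")
            net.add_node(g, "disease_gene", score=s)
        net.add_node("C", "target")
        net.add_edge("c1", "A", etype="ct")
        net.add_edge("c2", "B", etype="ct")
        net.add_edge("c1", "C", etype="ct")
        return net

    def test_component_free_modules_dropped(self):
        net = self._toy()
        part = nph.Partition(
            assignment={"c1": 0, "A": 0, "C": 0, "c2": 1, "B": 1},
            modules={}, codelength=0.0, n=5, tau=0.15)
        cim = extract_cim(part, net, pathogenic={"A", "B"})
        assert len(cim) == 2
        # ranked by pathogenic score sum: module with A (5.0) first
        assert cim.modules[0].pathogenic_genes == ["A"]

    def test_top_k_truncates(self):
        net = self._toy()
        part = nph.Partition(
            assignment={"c1": 0, "A": 0, "C": 0, "c2": 1, "B": 1},
            modules={}, codelength=0.0, n=5, tau=0.15)
        cim = extract_cim(part, net, pathogenic={"A", "B"}, top_k=1)
        assert len(cim) == 1
        assert cim.modules[0].pathogenic_score_sum == pytest.approx(5.0)

    def test_min_pathogenic_drops_sparse_modules(self):
        net = self._toy()
        part = nph.Partition(
            assignment={"c1": 0, "A": 0, "C": 0, "c2": 1, "B": 1},
            modules={}, codelength=0.0, n=5, tau=0.15)
        # each module holds a single pathogenic gene: min_pathogenic=2 empties the CIM
        with pytest.raises(ValidationError):
            extract_cim(part, net, pathogenic={"A", "B"}, min_pathogenic=2)
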