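import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import netpharm as nph
from netpharm.errors import UsageError, ValidationError
from netpharm.fcg import (EffectiveProtein, EffectiveProteinSet, KnapsackItem,
                          component_metrics, greedy_coverage, knapsack_select,
                          score_effective_proteins)
from netpharm.motifs import CimModule, MotifSet


def _eff(*genes):
    return EffectiveProteinSet([EffectiveProtein(g, 0.0, 0) for g in genes])


class TestEffectiveProteins:
    def _cim_net(self):
        net = nph.WeightedNetwork()
        net.add_node("c1", "component")
        for g in ("A", "B", "C", "D"):
            net.add_node(g, "target")
        for g in ("A", "B", "C"):
            net.add_edge("c1", g, etype="ct")
        net.add_edge("A", "B", etype="ppi")
        cim = MotifSet([CimModule(0, ["c1"], ["A", "B", "C", "D"], ["A"], 9.0)])
        return net, cim

    def test_max_degree_max_relevance_scores_two(self):
        net, cim = self._cim_net()
        scores = nph.GeneScoreTable({"A": 9.0, "B": 1.0})
        eff = score_effective_proteins(cim, net, scores)
        top = eff.proteins[0]
        assert top.protein == "A"
        assert top.importance == pytest.approx(2.0)

    def test_isolated_non_pathogenic_target_scores_zero(self):
        net, cim = self._cim_net()
        scores = nph.GeneScoreTable({"A": 9.0})
        eff = score_effective_proteins(cim, net, scores)
        by_name = {p.protein: p.importance for p in eff.proteins}
        assert by_name["D"] == pytest.approx(0.0)

    def test_keep_fraction_halves_output(self):
        net, cim = self._cim_net()
        scores = nph.GeneScoreTable({"A": 9.0})
        eff = score_effective_proteins(cim, net, scores, keep_fraction=0.5)
        assert len(eff) == 2

    def test_bad_keep_fraction_rejected(self):
        net, cim = self._cim_net()
        with pytest.raises(UsageError):
            score_effective_proteins(cim, net, nph.GeneScoreTable({}), keep_fraction=0.0)


class TestComponentMetrics:
    def test_rule_application(self):
        ct = nph.ComponentTargetTable({"t": {"A", "B"}})
        scores = nph.GeneScoreTable({"A": 2.0, "B": 0.5})
        eff = _eff("A", "B", "C")
        items = component_metrics(ct, eff, scores, mode="score_sum",
                                  pathogenic={"A"})
        assert items[0].coverage == 2  # H_t: effective targets hit
        assert items[0].value == pytest.approx(2.0)  # L_t: pathogenic score sum
        items_count = component_metrics(ct, eff, scores, mode="count",
                                        pathogenic={"A"})
        assert items_count[0].value == 1.0  # pathogenic effective targets

    def test_zero_coverage_component_excluded(self):
        ct = nph.ComponentTargetTable({"t": {"X"}, "u": {"A"}})
        items = component_metrics(ct, _eff("A"), nph.GeneScoreTable({"A": 1.0}),
                                  pathogenic={"A"})
        assert [it.component for it in items] == ["u"]

    def test_identical_target_sets_identical_metrics(self):
        ct = nph.ComponentTargetTable({"t": {"A", "B"}, "u": {"A", "B"}})
        items = component_metrics(ct, _eff("A", "B"), nph.GeneScoreTable({"A": 3.0}),
                                  pathogenic={"A"})
        assert (items[0].coverage, items[0].value) == (items[1].coverage, items[1].value)

    def test_all_excluded_is_error(self):
        ct = nph.ComponentTargetTable({"t": {"X"}})
        with pytest.raises(ValidationError):
            component_metrics(ct, _eff("A"), nph.GeneScoreTable({"A": 1.0}),
                              pathogenic=set())


def _brute_knapsack(items, budget):
    best = 0.0
    for mask in itertools.product((0, 1), repeat=len(items)):
        weight = sum(it.coverage for it, y in zip(items, mask) if y)
        if weight <= budget:
            value = sum(it.value for it, y in zip(items, mask) if y)
            best = max(best, value)
    return best


class TestKnapsack:
    def test_worked_example(self):
        items = [KnapsackItem("a", 2, 3.0), KnapsackItem("b", 3, 4.0),
                 KnapsackItem("c", 4, 5.0)]
        sol = knapsack_select(items, 5)
        assert sol.selected == ["a", "b"]
        assert sol.cci == pytest.approx(7.0)

    def test_unconstrained_budget_selects_all(self):
        items = [KnapsackItem("a", 2, 3.0), KnapsackItem("b", 3, 4.0)]
        sol = knapsack_select(items, 100)
        assert set(sol.selected) == {"a", "b"}
        assert sol.cci == pytest.approx(7.0)

    def test_zero_budget_rejected(self):
        with pytest.raises(ValidationError):
            knapsack_select([KnapsackItem("a", 1, 1.0)], 0)

    def test_budget_below_min_weight_gives_empty_solution(self):
        sol = knapsack_select([KnapsackItem("a", 5, 1.0)], 2)
        assert sol.selected == []
        assert sol.cci == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        items = [KnapsackItem(f"c{i}", int(rng.integers(1, 11)),
                              float(rng.uniform(0.1, 10.0))) for i in range(n)]
        budget = int(rng.integers(1, sum(it.coverage for it in items) + 1))
        sol = knapsack_select(items, budget)
        assert sol.cci == pytest.approx(_brute_knapsack(items, budget), abs=1e-9)
        chosen = {it.component: it for it in items}
        assert sum(chosen[c].coverage for c in sol.selected) <= budget

    @given(st.lists(st.tuples(st.integers(1, 8), st.floats(0.1, 10)),
                    min_size=1, max_size=8),
           st.integers(1, 40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_optimum_monotone_in_budget(self, raw, budget):
        items = [KnapsackItem(f"c{i}", h, v) for i, (h, v) in enumerate(raw)]
        lo = knapsack_select(items, budget).cci
        hi = knapsack_select(items, budget + 1).cci
        assert hi >= lo - 1e-12


class TestGreedyCoverage:
    def test_worked_example_order_and_fcg(self):
        ct = nph.ComponentTargetTable({"A": {"a", "b", "c"}, "B": {"c", "d"},
                                       "C": {"e"}})
        sel = greedy_coverage(ct, _eff("a", "b", "c", "d", "e"), threshold=0.8)
        assert sel.order[:2] == ["A", "B"]
        assert sel.coverage_curve[0] == pytest.approx(0.6)
        assert sel.coverage_curve[1] == pytest.approx(0.8)
        assert sel.fcg == ["A", "B"]

    def test_threshold_one_needs_all(self):
        ct = nph.ComponentTargetTable({"A": {"a", "b", "c"}, "B": {"c", "d"},
                                       "C": {"e"}})
        sel = greedy_coverage(ct, _eff("a", "b", "c", "d", "e"), threshold=1.0)
        assert set(sel.fcg) == {"A", "B", "C"}

    def test_single_component_covering_everything(self):
        ct = nph.ComponentTargetTable({"A": {"a", "b"}})
        sel = greedy_coverage(ct, _eff("a", "b"), threshold=0.9)
        assert sel.fcg == ["A"]
        assert sel.coverage_curve == [1.0]

    def test_unreachable_threshold_flagged(self):
        ct = nph.ComponentTargetTable({"A": {"a"}})
        sel = greedy_coverage(ct, _eff("a", "b", "c"), threshold=0.9)
        assert not sel.threshold_reached
        assert sel.fcg == ["A"]

    @pytest.mark.parametrize("seed", range(8))
    def test_curve_monotone_and_terminal_value_exact(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        ct = nph.ComponentTargetTable({
            f"c{i}": {g for g in genes if rng.random() < 0.2} | {genes[i]}
            for i in range(12)})
        eff = _eff(*genes[:20])
        sel = greedy_coverage(ct, eff, threshold=0.9)
        assert all(b >= a - 1e-12 for a, b in
                   zip(sel.coverage_curve, sel.coverage_curve[1:]))
        union = set()
        for c in sel.order:
            union |= ct.targets[c] & eff.names()
        assert sel.coverage_curve[-1] == pytest.approx(len(union) / 20)

    def test_modular_instance_agrees_with_knapsack(self):
        """Disjoint target sets: greedy and full-budget knapsack coincide."""
        ct = nph.ComponentTargetTable({"A": {"a", "b"}, "B": {"c"}, "C": {"d", "e"}})
        eff = _eff("a", "b", "c", "d", "e")
        scores = nph.GeneScoreTable({g: 1.0 for g in "abcde"})
        items = component_metrics(ct, eff, scores, pathogenic={"a", "b", "c", "d", "e"})
        knap = knapsack_select(items, sum(it.coverage for it in items))
        sel = greedy_coverage(ct, eff, threshold=1.0)
        assert set(knap.selected) == set(sel.fcg)

    def test_planted_minimum_cover_recovered(self, bundle):
        """On the benchmark's core-component instance, greedy finds a cover
        no larger than the optimum + 1 (here: exactly the planted cores)."""
        eff = _eff(*bundle.core_universe)
        sel = greedy_coverage(bundle.ct, eff, threshold=1.0)
        assert set(sel.fcg) == bundle.core_components
        assert len(sel.fcg) <= len(bundle.core_components) + 1
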