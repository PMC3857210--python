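"""Indicator-matrix construction and K/L-constrained subnetwork mining."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netcondense import (
    ExpressionMatrix,
    GroupLabels,
    IndicatorMatrix,
    build_indicator_matrix,
    min_L_for_size,
    network_from_edges,
    node_activity,
    solve_ines_exact,
    solve_ines_greedy,
    standardize_samples,
    validate_solution,
)


def indicator(rows, cases=None):
    """IndicatorMatrix from {gene: 0/1 list}."""
    genes = sorted(rows)
    n = len(rows[genes[0]])
    cases = cases or [f"c{j}" for j in range(n)]
    return IndicatorMatrix(
        pd.DataFrame([rows[g] for g in genes], index=genes, columns=cases,
                     dtype=np.int8),
        alpha=0.05,
    )


def brute_force_best(net, ind, K, L):
    """Independent oracle: enumerate every non-empty node subset, keep the
    connected feasible ones (<= K inactive members, >= 1 active member),
    return (best size, set of best node sets, all inclusion-maximal sets)."""
    act = node_activity(ind, L)
    active = set(act.index[act["active"]])
    nodes = sorted(net.graph.nodes)
    g = net.graph
    feasible = []
    for r in range(1, len(nodes) + 1):
        for sub in combinations(nodes, r):
            s = set(sub)
            inactive = s - active
            if len(inactive) > K or len(s) == len(inactive):
                continue
            # BFS connectivity
            seen = {sub[0]}
            stack = [sub[0]]
            while stack:
                x = stack.pop()
                for y in g.neighbors(x):
                    if y in s and y not in seen:
                        seen.add(y)
                        stack.append(y)
            if seen == s:
                feasible.append(frozenset(s))
    if not feasible:
        return 0, set(), set()
    best = max(len(s) for s in feasible)
    optima = {s for s in feasible if len(s) == best}
    fs = set(feasible)
    maximal = {s for s in fs if not any(s < t for t in fs)}
    return best, optima, maximal


class TestBuildIndicatorMatrix:
    @staticmethod
    def standardized(values, genes, samples):
        return ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=samples),
            scale="standardized",
        )

    def test_case_at_control_mean_is_inactive(self):
        genes = ["g1", "g2"]
        a = [f"a{j}" for j in range(10)]
        vals = np.vstack([np.linspace(-1, 1, 11), np.linspace(1, -1, 11)])
        m = self.standardized(vals, genes, a + ["case"])
        # place the case exactly at the control mean
        m.values.loc["g1", "case"] = m.values.loc["g1", a].mean()
        m.values.loc["g2", "case"] = m.values.loc["g2", a].mean()
        g = GroupLabels({**{s: "A" for s in a}, "case": "B"})
        ind = build_indicator_matrix(m, g, alpha=0.05)
        assert ind.values["case"].tolist() == [0, 0]

    def test_z_of_three_is_active_at_five_percent(self):
        a = [f"a{j}" for j in range(9)]
        control = np.array([-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0])
        sd = control.std(ddof=1)
        m = self.standardized(
            np.vstack([np.append(control, 3.0 * sd),
                       np.append(control, 1.0 * sd)]),
            ["hit", "null"], a + ["case"],
        )
        g = GroupLabels({**{s: "A" for s in a}, "case": "B"})
        ind = build_indicator_matrix(m, g, alpha=0.05)
        assert ind.values.loc["hit", "case"] == 1  # |z|=3 > 1.959964
        assert ind.values.loc["null", "case"] == 0  # |z|=1 < 1.959964

    def test_null_activation_rate_calibrated(self, rng):
        """Cases drawn from the control distribution activate at ~alpha."""
        n_genes, n_a, n_b = 100, 182, 30
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"a{j}" for j in range(n_a)] + [f"b{j}" for j in range(n_b)]
        m = ExpressionMatrix(
            pd.DataFrame(np.exp2(rng.normal(8, 1.5, (n_genes, n_a + n_b))),
                         index=genes, columns=samples)
        )
        g = GroupLabels(
            {**{f"a{j}": "A" for j in range(n_a)},
             **{f"b{j}": "B" for j in range(n_b)}}
        )
        ind = build_indicator_matrix(standardize_samples(m, log2=True), g, alpha=0.05)
        rate = ind.values.to_numpy().mean()
        n_entries = n_genes * n_b
        se = np.sqrt(0.05 * 0.95 / n_entries)
        assert abs(rate - 0.05) < 3 * se

    def test_zero_variance_gene_warns_and_zeroes(self):
        a = [f"a{j}" for j in range(5)]
        vals = np.vstack([[1.0] * 6, [-1.0, 0.0, 1.0, 2.0, -2.0, 5.0]])
        m = self.standardized(vals, ["flat", "ok"], a + ["case"])
        g = GroupLabels({**{s: "A" for s in a}, "case": "B"})
        with pytest.warns(UserWarning, match="zero control variance"):
            ind = build_indicator_matrix(m, g)
        assert ind.values.loc["flat"].sum() == 0

    def test_requires_standardized_matrix(self, small_matrix, small_labels):
        with pytest.raises(ValueError, match="standardize"):
            build_indicator_matrix(small_matrix, small_labels)


class TestNodeActivity:
    def test_fully_active_gene(self):
        ind = indicator({"g": [1] * 48})
        act = node_activity(ind, 0)
        assert bool(act.loc["g", "active"])

    def test_partial_activity_threshold(self):
        ind = indicator({"g": [1] * 30 + [0] * 18})
        assert not node_activity(ind, 17).loc["g", "active"]
        assert node_activity(ind, 18).loc["g", "active"]

    def test_vacuous_budget_activates_everything(self):
        ind = indicator({"g1": [0] * 5, "g2": [1, 0, 0, 0, 0]})
        act = node_activity(ind, 5)
        assert act["active"].all()

    def test_budget_out_of_range_rejected(self):
        ind = indicator({"g": [1, 0]})
        with pytest.raises(ValueError):
            node_activity(ind, 3)


class TestExactSolver:
    def test_all_active_path(self):
        net = network_from_edges([("a", "b"), ("b", "c")])
        ind = indicator({"a": [1, 1], "b": [1, 1], "c": [1, 1]})
        sols = solve_ines_exact(net, ind, K=8, L=0)
        assert sols[0].nodes == {"a", "b", "c"}
        assert sols[0].exception_nodes == frozenset()

    def test_exception_node_bridges_actives(self):
        net = network_from_edges([("a", "x"), ("x", "b")])
        ind = indicator({"a": [1], "b": [1], "x": [0]})
        at_k0 = solve_ines_exact(net, ind, K=0, L=0)
        assert {s.nodes for s in at_k0} == {frozenset({"a"}), frozenset({"b"})}
        at_k1 = solve_ines_exact(net, ind, K=1, L=0)
        assert at_k1[0].nodes == {"a", "b", "x"}
        assert at_k1[0].exception_nodes == {"x"}

    def test_no_active_nodes_means_empty_network(self):
        net = network_from_edges([("a", "b")])
        ind = indicator({"a": [0], "b": [0]})
        assert solve_ines_exact(net, ind, K=0, L=0) == []
        # exception budget alone must not manufacture a solution
        assert solve_ines_exact(net, ind, K=8, L=0) == []

    def test_node_limit_directs_to_greedy(self):
        net = network_from_edges([(f"n{i}", f"n{i + 1}") for i in range(30)])
        ind = indicator({f"n{i}": [1] for i in range(31)})
        with pytest.raises(ValueError, match="greedy"):
            solve_ines_exact(net, ind, K=0, L=0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 11))
            nodes = [f"n{i}" for i in range(n)]
            pairs = [
                (a, b) for a, b in combinations(nodes, 2) if rng.random() < 0.35
            ]
            if not pairs:
                continue
            net = network_from_edges(pairs)
            present = sorted(net.graph.nodes)
            ind = indicator(
                {x: rng.integers(0, 2, size=4).tolist() for x in present}
            )
            K = int(rng.integers(0, 3))
            L = int(rng.integers(0, 4))
            best, optima, maximal = brute_force_best(net, ind, K, L)
            sols = solve_ines_exact(net, ind, K, L, top_n=10_000)
            if best == 0:
                assert sols == []
                continue
            assert sols[0].size == best
            assert {s.nodes for s in sols if s.size == best} == optima
            assert maximal <= {s.nodes for s in sols}
            for s in sols:
                assert validate_solution(net, ind, K, L, s)


class TestGreedySolver:
    def test_completes_fully_active_clique(self):
        nodes = [f"n{i}" for i in range(6)]
        net = network_from_edges(list(combinations(nodes, 2)))
        ind = indicator({x: [1, 1] for x in nodes})
        sols = solve_ines_greedy(net, ind, K=0, L=0, seed=5)
        assert sols[0].size == 6

    def test_deterministic_under_seed(self, rng):
        nodes = [f"n{i}" for i in range(15)]
        pairs = [(a, b) for a, b in combinations(nodes, 2) if rng.random() < 0.3]
        net = network_from_edges(pairs)
        present = sorted(net.graph.nodes)
        ind = indicator({x: rng.integers(0, 2, size=5).tolist() for x in present})
        a = solve_ines_greedy(net, ind, K=2, L=2, seed=11)
        b = solve_ines_greedy(net, ind, K=2, L=2, seed=11)
        assert [(s.nodes, s.exception_nodes) for s in a] == [
            (s.nodes, s.exception_nodes) for s in b
        ]

    def test_bounded_by_exact_and_valid(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            nodes = [f"n{i}" for i in range(n)]
            pairs = [
                (a, b) for a, b in combinations(nodes, 2) if rng.random() < 0.4
            ]
            if not pairs:
                continue
            net = network_from_edges(pairs)
            present = sorted(net.graph.nodes)
            ind = indicator(
                {x: rng.integers(0, 2, size=4).tolist() for x in present}
            )
            K, L = int(rng.integers(0, 3)), int(rng.integers(0, 4))
            exact = solve_ines_exact(net, ind, K, L, top_n=1)
            greedy = solve_ines_greedy(net, ind, K, L, seed=3)
            if not exact:
                assert greedy == []
                continue
            for s in greedy:
                assert validate_solution(net, ind, K, L, s)
                assert s.size <= exact[0].size


class TestSolutionSizeMonotonicity:
    def test_monotone_in_K_and_L(self, rng):
        nodes = [f"n{i}" for i in range(10)]
        pairs = [(a, b) for a, b in combinations(nodes, 2) if rng.random() < 0.35]
        net = network_from_edges(pairs)
        present = sorted(net.graph.nodes)
        ind = indicator({x: rng.integers(0, 2, size=5).tolist() for x in present})

        def best(K, L):
            sols = solve_ines_exact(net, ind, K, L, top_n=1)
            return sols[0].size if sols else 0

        for L in range(0, 6):
            sizes = [best(K, L) for K in range(0, 4)]
            assert sizes == sorted(sizes)
        for K in range(0, 4):
            sizes = [best(K, L) for L in range(0, 6)]
            assert sizes == sorted(sizes)


class TestMinLForSize:
    def test_all_active_returns_zero(self):
        net = network_from_edges([("a", "b"), ("b", "c")])
        ind = indicator({"a": [1, 1], "b": [1, 1], "c": [1, 1]})
        assert min_L_for_size(net, ind, K=0, target_size=3) == 0

    def test_single_gene_missing_cases(self):
        n_cases = 48
        row = [1] * 30 + [0] * 18
        net = network_from_edges([("g", "h")])
        ind = indicator({"g": row, "h": [0] * n_cases})
        assert min_L_for_size(net, ind, K=0, target_size=1) == 18

    def test_monotone_in_target_size(self, rng):
        nodes = [f"n{i}" for i in range(8)]
        net = network_from_edges([(nodes[i], nodes[i + 1]) for i in range(7)])
        ind = indicator({x: rng.integers(0, 2, size=6).tolist() for x in nodes})
        answers = [
            min_L_for_size(net, ind, K=1, target_size=t) for t in range(1, 5)
        ]
        filtered = [a for a in answers if a is not None]
        assert filtered == sorted(filtered)

    def test_unattainable_reported(self):
        net = network_from_edges([("a", "b")])
        ind = indicator({"a": [0, 1], "b": [1, 0]})
        assert min_L_for_size(net, ind, K=0, target_size=5) is None
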