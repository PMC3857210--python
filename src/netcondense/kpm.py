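"""Per-case indicator matrix and K/L-constrained active-subnetwork
extraction (individual-node-exception semantics).

The indicator matrix marks, for every gene and every case sample
(responder), whether the case's expression is significantly different from
the control group (non-responders): the case value is z-tested two-tailed
against the gene-wise control mean and sample standard deviation at level
alpha. A gene is *active* at case-exception budget L when it fails the test
in at most L cases.

A solution is a connected subgraph containing at most K inactive
("exception") nodes, every other node being active; solutions without a
single active node are not reported (a budget of exception nodes on its own
carries no signal — this is what makes an "empty network" possible even at
K > 0). The extraction maximizes the number of genes. Two solvers are
provided: an exact one for small instances and a deterministic seeded
greedy for large ones; the exact solver enumerates exception subsets
E (|E| <= K) and takes connected components of the graph induced on
active-union-E, which yields every inclusion-maximal feasible node set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import GROUP_A, GROUP_B, STANDARDIZED, ExpressionMatrix, GroupLabels
from .network import InteractionNetwork

EXACT_NODE_LIMIT = 25


@dataclass
class IndicatorMatrix:
    """Genes x cases binary activity matrix (cases = group-B samples)."""

    values: pd.DataFrame  # int8 entries in {0, 1}
    alpha: float

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("indicator entries must be 0 or 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def case_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cases(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def read_indicator_matrix(path: str | Path, alpha: float = 0.05) -> IndicatorMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return IndicatorMatrix(df.astype(np.int8), alpha=alpha)


def build_indicator_matrix(
    m: ExpressionMatrix, g: GroupLabels, alpha: float = 0.05
) -> IndicatorMatrix:
    """z-test every case sample against the control-group distribution.

    Expects a per-sample standardized matrix. For gene i and case c,
    z = (x_ic - mean_A_i) / sd_A_i with the control mean and sample standard
    deviation (ddof=1) taken over group-A samples; the entry is 1 iff
    |z| >= the two-tailed normal critical value at ``alpha`` (1.959964...
    at alpha=0.05). Genes with zero control variance get all-zero rows with
    a warning.
    """
    if m.scale != STANDARDIZED:
        raise ValueError("build_indicator_matrix expects a standardized matrix "
                         "(apply standardize_samples first)")
    g.check_covers(m)
    a_cols = [s for s in g.samples(GROUP_A) if s in m.values.columns]
    b_cols = [s for s in g.samples(GROUP_B) if s in m.values.columns]
    if len(a_cols) < 2:
        raise ValueError("need at least 2 control (group A) samples")
    X = m.values
    mu = X[a_cols].mean(axis=1)
    sd = X[a_cols].std(axis=1, ddof=1)
    crit = stats.norm.ppf(1 - alpha / 2)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} gene(s) with zero control variance; "
            "their indicator rows are all zero"
        )
    safe_sd = sd.where(~flat, 1.0)
    z = X[b_cols].sub(mu, axis=0).div(safe_sd, axis=0)
    ind = (z.abs() >= crit).astype(np.int8)
    ind.loc[flat] = 0
    return IndicatorMatrix(ind, alpha=alpha)


def node_activity(ind: IndicatorMatrix, L: int) -> pd.DataFrame:
    """Per-gene exception count (cases with entry 0) and active flag
    (exception count <= L)."""
    if not 0 <= L <= ind.n_cases:
        raise ValueError(f"L must be in [0, {ind.n_cases}]")
    exc = (ind.values == 0).sum(axis=1)
    return pd.DataFrame({"exception_count": exc, "active": exc <= L})


@dataclass(frozen=True)
class KPMSolution:
    """A connected active subnetwork under the K/L exception model."""

    nodes: frozenset[str]
    exception_nodes: frozenset[str]
    total_active_entries: int

    @property
    def size(self) -> int:
        return len(self.nodes)

    def sort_key(self) -> tuple:
        return (-self.size, -self.total_active_entries, tuple(sorted(self.nodes)))


def validate_solution(
    net: InteractionNetwork, ind: IndicatorMatrix, K: int, L: int, sol: KPMSolution
) -> bool:
    """Independent constraint check: induced connectivity, <= K exception
    nodes, every non-exception node active at level L, >= 1 active node."""
    if not sol.nodes:
        return False
    sub = net.graph.subgraph(sol.nodes)
    if sub.number_of_nodes() != len(sol.nodes) or not nx.is_connected(sub):
        return False
    act = node_activity(ind, L)
    active = set(act.index[act["active"]])
    exceptions = set(sol.nodes) - active
    if exceptions != set(sol.exception_nodes):
        return False
    if len(exceptions) > K:
        return False
    return len(sol.nodes - exceptions) >= 1


def _make_solution(nodes: Iterable[str], active: set[str], ind: IndicatorMatrix) -> KPMSolution:
    nodeset = frozenset(nodes)
    total = int(ind.values.loc[sorted(nodeset)].to_numpy().sum())
    return KPMSolution(
        nodes=nodeset,
        exception_nodes=frozenset(nodeset - active),
        total_active_entries=total,
    )


def _check_inputs(net: InteractionNetwork, ind: IndicatorMatrix) -> None:
    missing = sorted(set(net.graph.nodes) - set(ind.gene_ids))
    if missing:
        raise ValueError(
            f"network genes absent from the indicator matrix: {missing[:5]}"
        )


def solve_ines_exact(
    net: InteractionNetwork,
    ind: IndicatorMatrix,
    K: int,
    L: int,
    top_n: int = 5,
    node_limit: int = EXACT_NODE_LIMIT,
) -> list[KPMSolution]:
    """Exact K/L extraction on small instances.

    Enumerates all exception subsets E of inactive nodes with |E| <= K and
    collects the connected components of the subgraph induced on
    active-union-E that contain at least one active node. Every
    inclusion-maximal feasible node set arises this way: a maximal feasible
    S with exception set E_S is by maximality exactly the component of
    G[active ∪ E_S] that contains it. Solutions are deduplicated and ranked
    by size desc, then total active indicator entries desc, then
    lexicographically; the top_n distinct node sets are returned.
    """
    _check_inputs(net, ind)
    if net.n_nodes > node_limit:
        raise ValueError(
            f"{net.n_nodes} nodes exceeds the exact-solver limit {node_limit}; "
            "use solve_ines_greedy"
        )
    act = node_activity(ind, L)
    active = set(act.index[act["active"]]) & set(net.graph.nodes)
    inactive = sorted(set(net.graph.nodes) - active)
    solutions: dict[frozenset[str], KPMSolution] = {}
    for k in range(0, min(K, len(inactive)) + 1):
        for E in combinations(inactive, k):
            allowed = active | set(E)
            if not allowed:
                continue
            sub = net.graph.subgraph(allowed)
            for comp in nx.connected_components(sub):
                if not comp & active:
                    continue
                key = frozenset(comp)
                if key not in solutions:
                    solutions[key] = _make_solution(key, active, ind)
    return sorted(solutions.values(), key=KPMSolution.sort_key)[:top_n]


def solve_ines_greedy(
    net: InteractionNetwork,
    ind: IndicatorMatrix,
    K: int,
    L: int,
    top_n: int = 5,
    restarts: int | None = None,
    seed: int = 0,
) -> list[KPMSolution]:
    """Seeded greedy K/L extraction for instances of any size.

    Grows a solution from each active seed node (seed order randomized by
    ``seed``, at most ``restarts`` seeds): active neighbours are always
    admitted; when none remain and exception budget is left, the inactive
    neighbour opening access to the most active nodes outside the current
    set is admitted (ties broken lexicographically). Deterministic for a
    fixed seed. Returns the top_n distinct solutions.
    """
    _check_inputs(net, ind)
    act = node_activity(ind, L)
    active = set(act.index[act["active"]]) & set(net.graph.nodes)
    if not active:
        return []
    rng = np.random.default_rng(seed)
    seeds = sorted(active)
    rng.shuffle(seeds)
    if restarts is not None:
        seeds = seeds[: max(restarts, 1)]
    g = net.graph
    solutions: dict[frozenset[str], KPMSolution] = {}
    for s0 in seeds:
        S = {s0}
        exceptions = 0
        frontier = set(g.neighbors(s0))
        while True:
            cand_active = sorted((frontier - S) & active)
            if cand_active:
                pick = cand_active[0]
            else:
                if exceptions >= K:
                    break
                cand_inact = sorted(frontier - S - active)
                if not cand_inact:
                    break
                # favour the exception node that unlocks the most new
                # active genes
                pick = max(
                    cand_inact,
                    key=lambda n: (
                        len(set(g.neighbors(n)) & active - S),
                        n,
                    ),
                )
                exceptions += 1
            S.add(pick)
            frontier |= set(g.neighbors(pick))
        key = frozenset(S)
        if key not in solutions:
            solutions[key] = _make_solution(key, active, ind)
    return sorted(solutions.values(), key=KPMSolution.sort_key)[:top_n]


def solve_ines(
    net: InteractionNetwork,
    ind: IndicatorMatrix,
    K: int,
    L: int,
    top_n: int = 5,
    solver: str = "auto",
    seed: int = 0,
) -> list[KPMSolution]:
    """Dispatch to the exact solver when the instance is small enough,
    otherwise to the greedy one."""
    if solver == "auto":
        solver = "exact" if net.n_nodes <= EXACT_NODE_LIMIT else "greedy"
    if solver == "exact":
        return solve_ines_exact(net, ind, K, L, top_n=top_n)
    if solver == "greedy":
        return solve_ines_greedy(net, ind, K, L, top_n=top_n, seed=seed)
    raise ValueError(f"unknown solver {solver!r}")


def min_L_for_size(
    net: InteractionNetwork,
    ind: IndicatorMatrix,
    K: int,
    target_size: int,
    solver: str = "auto",
    seed: int = 0,
) -> int | None:
    """Smallest case-exception budget L yielding a solution of at least
    ``target_size`` genes (binary search; solution size is monotone
    non-decreasing in L). Returns None when unattainable even at
    L = number of cases."""
    if target_size < 1:
        raise ValueError("target_size must be >= 1")

    def best_size(L: int) -> int:
        sols = solve_ines(net, ind, K, L, top_n=1, solver=solver, seed=seed)
        return sols[0].size if sols else 0

    lo, hi = 0, ind.n_cases
    if best_size(hi) < target_size:
        return None
    while lo < hi:
        mid = (lo + hi) // 2
        if best_size(mid) >= target_size:
            hi = mid
        else:
            lo = mid + 1
    return lo
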