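"""Link scores, condensation to the top differentially regulated
interactions, and interaction/gene-level significance testing.

The link score of an interaction (i, j) between two groups A and B is the
log2 fold change of the product of the endpoint group means,

    LS(i,j) = [log2 mB_i + log2 mB_j] - [log2 mA_i + log2 mA_j],

i.e. the sum of the endpoint log2 fold changes. Positive scores mark
interactions up-regulated in group B (responders), negative scores
down-regulated ones. The score is scale invariant and antisymmetric under
swapping the groups. A non-logarithmic difference-of-products variant
(mB_i*mB_j - mA_i*mA_j) is available behind a flag.

The condensed subnetwork keeps the k_up highest-scoring and k_down
lowest-scoring interactions; its genes typically aggregate into a few
connected components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import GROUP_A, GROUP_B, ExpressionMatrix, GroupLabels
from .network import AnnotatedNetwork, canonical_edge

UP = "up"
DOWN = "down"


def compute_link_scores(an: AnnotatedNetwork, variant: str = "log_ratio") -> pd.DataFrame:
    """Per-edge link score table.

    Returns a DataFrame with columns gene_a, gene_b (canonical order) and
    link_score, one row per edge of the annotated network, sorted by edge.
    ``variant='diff_product'`` computes mB_i*mB_j - mA_i*mA_j instead of the
    default log2 form.
    """
    if variant not in ("log_ratio", "diff_product"):
        raise ValueError(f"unknown link-score variant {variant!r}")
    rows = []
    for u, v in an.edges:
        ma_u, mb_u = an.means(u)
        ma_v, mb_v = an.means(v)
        for gene, m in ((u, ma_u), (u, mb_u), (v, ma_v), (v, mb_v)):
            if m <= 0:
                raise ValueError(f"nonpositive mean for gene {gene!r}")
        if variant == "log_ratio":
            ls = (np.log2(mb_u) + np.log2(mb_v)) - (np.log2(ma_u) + np.log2(ma_v))
        else:
            ls = mb_u * mb_v - ma_u * ma_v
        rows.append((u, v, float(ls)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "link_score"])


@dataclass
class CondensedSubnetwork:
    """The k most up- and k most down-regulated interactions.

    edges : DataFrame with gene_a, gene_b, link_score, direction (up/down).
    node_means : optional per-gene (mean_A, mean_B) annotation frame.
    """

    edges: pd.DataFrame
    node_means: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.gene_a, row.gene_b,
                link_score=row.link_score, direction=row.direction,
            )
        return g

    def edge_set(self) -> set[tuple[str, str, str]]:
        """Direction-aware canonical edge triples (a, b, direction)."""
        return {
            (r.gene_a, r.gene_b, r.direction)
            for r in self.edges.itertuples(index=False)
        }


def select_top_links(
    link_scores: pd.DataFrame, k_up: int, k_down: int,
    node_means: pd.DataFrame | None = None,
) -> CondensedSubnetwork:
    """Select the k_up edges with largest positive scores and the k_down with
    most negative scores.

    Ties break deterministically on the canonical edge identifier: up edges
    are ordered by (-link_score, gene_a, gene_b), down edges by
    (link_score, gene_a, gene_b). Zero-score edges belong to neither
    direction. If k_up + k_down exceeds the edge count the selection is
    clamped with a warning.
    """
    if k_up < 0 or k_down < 0:
        raise ValueError("k_up and k_down must be non-negative")
    ls = link_scores.copy()
    if k_up + k_down > len(ls):
        warnings.warn(
            f"k_up+k_down={k_up + k_down} exceeds {len(ls)} edges; clamping"
        )
    pos = ls[ls["link_score"] > 0].sort_values(
        by=["link_score", "gene_a", "gene_b"],
        ascending=[False, True, True], kind="mergesort",
    ).head(k_up)
    neg = ls[ls["link_score"] < 0].sort_values(
        by=["link_score", "gene_a", "gene_b"],
        ascending=[True, True, True], kind="mergesort",
    ).head(k_down)
    pos = pos.assign(direction=UP)
    neg = neg.assign(direction=DOWN)
    sel = pd.concat([pos, neg], ignore_index=True)
    return CondensedSubnetwork(edges=sel, node_means=node_means)


def components(cs: CondensedSubnetwork) -> list[list[str]]:
    """Connected components of the selected-edge graph, sorted by size
    descending then lexicographically by smallest member."""
    comps = [sorted(c) for c in nx.connected_components(cs.graph())]
    return sorted(comps, key=lambda c: (-len(c), c))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def _log2_values(m: ExpressionMatrix) -> pd.DataFrame:
    if m.scale != "linear":
        raise ValueError("significance tests expect linear-scale intensities")
    return np.log2(m.values)


def _group_columns(m: ExpressionMatrix, g: GroupLabels) -> tuple[list[str], list[str]]:
    g.check_covers(m)
    cols = set(m.sample_ids)
    a = [s for s in g.samples(GROUP_A) if s in cols]
    b = [s for s in g.samples(GROUP_B) if s in cols]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    return a, b


def test_interaction_shifts(
    m: ExpressionMatrix, g: GroupLabels,
    edges: pd.DataFrame | list[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-tailed t-test of per-sample interaction activity.

    The activity of edge (i, j) in sample s is log2 x_is + log2 x_js (the
    per-sample analogue of the link score). P-values are BH-adjusted across
    the supplied edge set. Returns a frame indexed by canonical edge string
    ``a--b`` with t_statistic, raw_p, bh_q, significant.
    """
    if isinstance(edges, pd.DataFrame):
        pairs = [canonical_edge(r.gene_a, r.gene_b) for r in edges.itertuples(index=False)]
    else:
        pairs = [canonical_edge(a, b) for a, b in edges]
    logx = _log2_values(m)
    missing = sorted({x for p in pairs for x in p} - set(m.gene_ids))
    if missing:
        raise ValueError(f"edge genes absent from the matrix: {missing[:5]}")
    a_cols, b_cols = _group_columns(m, g)
    rows = []
    for u, v in pairs:
        act = logx.loc[u] + logx.loc[v]
        t, p = stats.ttest_ind(act[b_cols], act[a_cols], equal_var=False)
        rows.append((f"{u}--{v}", float(t), float(p)))
    out = pd.DataFrame(rows, columns=["edge", "t_statistic", "raw_p"]).set_index("edge")
    out["bh_q"] = bh_adjust(out["raw_p"].to_numpy())
    out["significant"] = out["bh_q"] < alpha
    return out


def test_gene_de(
    m: ExpressionMatrix, g: GroupLabels,
    genes: list[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Welch two-tailed t-test per gene on log2 intensities, BH-adjusted
    across the supplied gene set. Returns (result frame, fraction of genes
    with bh_q < alpha)."""
    missing = sorted(set(genes) - set(m.gene_ids))
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing[:5]}")
    logx = _log2_values(m)
    a_cols, b_cols = _group_columns(m, g)
    rows = []
    for gene in genes:
        x = logx.loc[gene]
        t, p = stats.ttest_ind(x[b_cols], x[a_cols], equal_var=False)
        rows.append((gene, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "t_statistic", "raw_p"]).set_index("gene")
    out["bh_q"] = bh_adjust(out["raw_p"].to_numpy())
    out["significant"] = out["bh_q"] < alpha
    frac = float(out["significant"].mean()) if len(out) else float("nan")
    return out, frac
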