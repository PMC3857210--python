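"""Confidence-filtered interaction networks and their intersection with
expression data.

The input is a STRING-style links table with per-evidence-channel confidence
scores (experimental, database, textmining). An edge is retained when any
selected channel reaches the threshold (default 0.85); a combined-score mode
is available behind a flag. Networks are undirected simple graphs held in a
:class:`networkx.Graph` with channel scores as edge attributes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

CHANNELS = ("experimental", "database", "textmining")


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Unordered pair in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionNetwork:
    """Undirected gene/protein graph with per-channel confidence scores."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops[:3]}")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(canonical_edge(u, v) for u, v in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class AnnotatedNetwork:
    """Interaction network restricted to expressed genes, with per-node
    linear-scale group means (``mean_A`` non-responders, ``mean_B``
    responders) stored as node attributes."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(canonical_edge(u, v) for u, v in self.graph.edges)

    def means(self, gene: str) -> tuple[float, float]:
        d = self.graph.nodes[gene]
        return d["mean_A"], d["mean_B"]


def _detect_scale(col: pd.Series) -> float:
    """STRING ships scores either on 0-1 or integer 0-1000; detect divisor."""
    vals = col.dropna()
    if len(vals) and (vals % 1 == 0).all() and vals.max() > 1:
        return 1000.0
    return 1.0


def read_string_edges(
    path: str | Path,
    threshold: float = 0.85,
    channels: Sequence[str] = CHANNELS,
    combined: bool = False,
) -> InteractionNetwork:
    """Parse a STRING-style links table into a confidence-filtered network.

    Keeps an edge iff the maximum over the selected channels is >= threshold
    (``combined=True`` instead uses 1 - prod(1 - s_c), the usual evidence
    integration). Rows are canonicalized and deduplicated keeping the
    per-channel maximum; self-loops are dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("protein1", "protein2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    missing = [c for c in channels if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing channel column(s) {missing}")
    channels = list(channels)
    scores = df[channels].astype(float).copy()
    for c in channels:
        scores[c] = scores[c] / _detect_scale(df[c])

    g = nx.Graph()
    for (a, b), ch in zip(
        zip(df["protein1"].astype(str), df["protein2"].astype(str)),
        scores.itertuples(index=False),
    ):
        if a == b:
            continue
        u, v = canonical_edge(a, b)
        row = dict(zip(channels, ch))
        if g.has_edge(u, v):
            for c in channels:
                g[u][v][c] = max(g[u][v][c], row[c])
        else:
            g.add_edge(u, v, **row)

    drop = []
    for u, v, d in g.edges(data=True):
        vals = [d[c] for c in channels]
        if combined:
            comb = 1.0
            for s in vals:
                comb *= 1.0 - s
            score = 1.0 - comb
        else:
            score = max(vals)
        if score < threshold:
            drop.append((u, v))
    g.remove_edges_from(drop)
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        warnings.warn(f"no edge passes threshold {threshold}; empty network")
    return InteractionNetwork(g)


def load_actions(net: InteractionNetwork, path: str | Path) -> InteractionNetwork:
    """Attach optional effect annotations (stimulation/inhibition) from a
    STRING-actions-style TSV with columns item_a, item_b, mode. Effects are
    annotations only; they never influence scoring."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("item_a", "item_b", "mode"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for a, b, mode in zip(df["item_a"], df["item_b"], df["mode"]):
        u, v = canonical_edge(str(a), str(b))
        if net.graph.has_edge(u, v):
            net.graph[u][v]["effect"] = str(mode)
    return net


def map_expression_to_network(
    net: InteractionNetwork, gm: pd.DataFrame
) -> AnnotatedNetwork:
    """Restrict the network to genes with expression and annotate node means.

    ``gm`` is the group-mean table (index gene_id, columns mean_A, mean_B).
    Identifier matching is exact and case-sensitive.
    """
    expressed = set(gm.index)
    keep = [n for n in net.graph.nodes if n in expressed]
    if not keep:
        raise ValueError("expression and network identifier sets are disjoint")
    sub = net.graph.subgraph(keep).copy()
    dropped_edges = net.n_edges - sub.number_of_edges()
    logger.info(
        "mapped %d of %d network genes to expression; dropped %d edges",
        len(keep), net.n_nodes, dropped_edges,
    )
    for n in sub.nodes:
        ma, mb = float(gm.loc[n, "mean_A"]), float(gm.loc[n, "mean_B"])
        if ma <= 0 or mb <= 0:
            raise ValueError(f"nonpositive group mean for gene {n!r}")
        sub.nodes[n]["mean_A"] = ma
        sub.nodes[n]["mean_B"] = mb
    return AnnotatedNetwork(sub)


def write_network(
    net: InteractionNetwork | AnnotatedNetwork,
    path: str | Path,
    fmt: str = "sif",
) -> None:
    """Serialize to SIF (relation ``pp`` unless an effect is annotated) or
    GraphML (all node/edge attributes carried along)."""
    g = net.graph
    if fmt.lower() == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(g.edges(data=True)):
                rel = d.get("effect", "pp")
                fh.write(f"{u}\t{rel}\t{v}\n")
    elif fmt.lower() == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'sif' or 'graphml')")


def read_graphml(path: str | Path) -> InteractionNetwork:
    return InteractionNetwork(nx.read_graphml(path))


def network_from_edges(
    edges: Iterable[tuple[str, str]],
    channel_scores: dict | None = None,
) -> InteractionNetwork:
    """Build a network directly from canonicalized edge pairs (testing and
    synthetic-data convenience)."""
    g = nx.Graph()
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop {a!r}")
        u, v = canonical_edge(a, b)
        attrs = (channel_scores or {}).get((u, v), {})
        g.add_edge(u, v, **attrs)
    return InteractionNetwork(g)
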