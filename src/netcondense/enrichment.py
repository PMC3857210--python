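"""Hypergeometric over-representation analysis of gene sets.

One-sided upper-tail test: with a background universe of size N, a term set
of size n (after intersection with the background), and a query of size q,
the p-value for an overlap of k genes is P[X >= k] for
X ~ Hypergeometric(N, n, q). P-values are BH-adjusted across the terms of a
collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .linkscore import bh_adjust


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT-style)."""

    name: str
    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        empties = [n for n, s in self.sets.items() if not s]
        if empties:
            raise ValueError(f"empty gene set(s): {empties[:5]}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then tab-separated
    member genes (duplicates within a set are collapsed)."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line "
                                 "(need name, description, >=1 member)")
            set_name, description, *members = parts
            if set_name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {set_name!r} has no members")
            sets[set_name] = frozenset(members)
            desc[set_name] = description
    return GeneSetCollection(name=name or Path(path).stem, sets=sets, descriptions=desc)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_name in sorted(coll.sets):
            description = (coll.descriptions or {}).get(set_name, "")
            members = "\t".join(sorted(coll.sets[set_name]))
            fh.write(f"{set_name}\t{description}\t{members}\n")


def hypergeom_upper_tail(overlap: int, background: int, set_size: int, query: int) -> float:
    """P[X >= overlap] for X ~ Hypergeometric(background, set_size, query)."""
    if overlap <= 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, background, set_size, query))


def enrich(
    query: Iterable[str],
    background: Iterable[str],
    coll: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of ``coll`` against
    ``background``.

    The query must be a subset of the background; term sets are intersected
    with the background before testing. Returns a frame sorted by raw_p
    ascending (ties by term name) with overlap counts, p-values, BH q-values
    and the overlapping genes.
    """
    query = frozenset(query)
    background = frozenset(background)
    if not query:
        raise ValueError("empty query gene set")
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside the background: {sorted(stray)[:5]}")
    rows = []
    for term in sorted(coll.sets):
        members = coll.sets[term] & background
        hit = sorted(query & members)
        p = hypergeom_upper_tail(len(hit), len(background), len(members), len(query))
        rows.append(
            {
                "term": term,
                "overlap": len(hit),
                "set_size": len(members),
                "query_size": len(query),
                "background_size": len(background),
                "raw_p": p,
                "genes": ",".join(hit),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out["bh_q"] = bh_adjust(out["raw_p"].to_numpy())
    out["significant"] = out["bh_q"] < alpha
    return out.sort_values(by=["raw_p", "term"], kind="mergesort")
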