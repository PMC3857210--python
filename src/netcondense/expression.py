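"""Expression-matrix handling: reading, quantile normalization, probe
collapsing, group summaries and per-sample standardization.

The conventions follow two-group microarray response studies: a table of
strictly positive linear-scale intensities (genes x samples), samples
labelled into a control-like group ``A`` (non-responders) and a case group
``B`` (responders). Group means are taken on the linear scale; log2 enters
only downstream (link scores, t-tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAR = "linear"
STANDARDIZED = "standardized"

GROUP_A = "A"  # non-responders (reference group)
GROUP_B = "B"  # responders (case group)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table.

    values : DataFrame indexed by gene_id with sample_id columns.
    scale  : ``"linear"`` (strictly positive intensities) or
             ``"standardized"`` (each sample column mean 0, variance 1).
    """

    values: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, STANDARDIZED):
            raise ValueError(f"unknown scale flag {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dups[:5])}")
        if self.values.isna().any().any():
            raise ValueError("missing values are not allowed (no imputation rule)")
        if self.scale == LINEAR and (self.values.to_numpy() <= 0).any():
            raise ValueError(
                "linear-scale intensities must be strictly positive; "
                "apply a floor explicitly with floor_intensities() if intended"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GroupLabels:
    """sample_id -> group mapping; group A = non-responders, B = responders."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in (GROUP_A, GROUP_B)}
        if bad:
            raise ValueError(f"groups must be 'A' or 'B', got {sorted(bad)}")
        if not self.samples(GROUP_A) or not self.samples(GROUP_B):
            raise ValueError("both groups must be non-empty")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def check_covers(self, m: ExpressionMatrix) -> None:
        missing = [s for s in m.sample_ids if s not in self.mapping]
        if missing:
            raise ValueError(f"unlabelled samples: {missing[:5]}")

    def to_tsv(self, path: str | Path) -> None:
        pd.Series(dict(self.mapping), name="group").rename_axis("sample_id").to_csv(
            path, sep="\t"
        )


def read_groups(path: str | Path) -> GroupLabels:
    """Two-column TSV (sample_id, group) with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, group)")
    return GroupLabels(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(
    path: str | Path,
    orientation: str = "rows=genes",
    scale: str = LINEAR,
) -> ExpressionMatrix:
    """Read a delimited expression table with one header line.

    ``orientation`` declares what the file's rows are; the result is always
    genes x samples. Non-numeric body cells raise a parse error naming the
    offending row and column.
    """
    if orientation not in ("rows=genes", "rows=samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    body = raw.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & raw.notna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at "
            f"row {raw.index[i]!r}, column {raw.columns[j]!r}"
        )
    body.index = body.index.astype(str)
    body.columns = body.columns.astype(str)
    if orientation == "rows=samples":
        body = body.T
    body.index.name = "gene_id"
    body.columns.name = None
    return ExpressionMatrix(body.astype(float), scale=scale)


def floor_intensities(m: ExpressionMatrix, eps: float = 1e-6) -> ExpressionMatrix:
    """Clip linear intensities from below at ``eps`` (opt-in; never automatic)."""
    if m.scale != LINEAR:
        raise ValueError("flooring applies to linear-scale matrices only")
    return ExpressionMatrix(m.values.clip(lower=eps), scale=LINEAR)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the same value distribution.

    Each column's values are replaced by the across-sample means of the
    rank-ordered values; within-column order is preserved. Tied values
    receive the mean of the rank-means their rank span covers, which makes
    the operation deterministic and independent of input row order.
    """
    if m.scale != LINEAR:
        raise ValueError("quantile normalization expects a linear-scale matrix")
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = m.values.to_numpy(dtype=float)
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    csum = np.concatenate(([0.0], np.cumsum(mean_sorted)))
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        uniq, inv, counts = np.unique(X[:, j], return_inverse=True, return_counts=True)
        ends = np.cumsum(counts)
        starts = ends - counts
        block_means = (csum[ends] - csum[starts]) / counts
        out[:, j] = block_means[inv]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        scale=LINEAR,
    )


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (probe_id, gene_id); ambiguous probes must be absent."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    probes = df.iloc[:, 0]
    if probes.duplicated().any():
        raise ValueError("probe map contains duplicated probe identifiers")
    return dict(zip(probes, df.iloc[:, 1]))


def drop_ambiguous_probes(pairs: Iterable[tuple[str, str]]) -> dict[str, str]:
    """From (probe, gene) pairs keep only probes mapping to exactly one gene."""
    seen: dict[str, set[str]] = {}
    for p, g in pairs:
        seen.setdefault(p, set()).add(g)
    return {p: next(iter(gs)) for p, gs in seen.items() if len(gs) == 1}


def collapse_probes(m: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    A gene's value in each sample is the arithmetic mean over its probes'
    values in that sample. Probes absent from the map are dropped (count
    logged).
    """
    keep = [p for p in m.gene_ids if p in probe_map]
    dropped = m.n_genes - len(keep)
    if not keep:
        raise ValueError("no probe of the matrix appears in the probe map")
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    sub = m.values.loc[keep]
    genes = pd.Index([probe_map[p] for p in keep], name="gene_id")
    collapsed = sub.groupby(genes, sort=True).mean()
    return ExpressionMatrix(collapsed, scale=m.scale)


def group_means(m: ExpressionMatrix, g: GroupLabels) -> pd.DataFrame:
    """Per-gene arithmetic mean within each group, on the linear scale.

    Returns a DataFrame indexed by gene_id with columns ``mean_A`` and
    ``mean_B``.
    """
    if m.scale != LINEAR:
        raise ValueError("group means are taken on the linear scale")
    g.check_covers(m)
    out = {}
    for grp, col in ((GROUP_A, "mean_A"), (GROUP_B, "mean_B")):
        samples = [s for s in g.samples(grp) if s in m.values.columns]
        if not samples:
            raise ValueError(f"group {grp} has no samples in the matrix")
        out[col] = m.values[samples].mean(axis=1)
    return pd.DataFrame(out)


def standardize_samples(m: ExpressionMatrix, log2: bool = False) -> ExpressionMatrix:
    """Scale each sample column to mean 0 and unit sample variance (ddof=1).

    With ``log2=True`` intensities are log2-transformed first (linear input
    required); this is the variant used ahead of per-case activity testing,
    where the roughly log-normal intensity distribution would otherwise
    skew the case z-scores.
    """
    if m.n_genes < 2:
        raise ValueError("standardization needs at least 2 genes per sample")
    if log2 and m.scale != LINEAR:
        raise ValueError("log2 transform applies to linear-scale matrices only")
    X = m.values.to_numpy(dtype=float)
    if log2:
        X = np.log2(X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"constant expression in sample(s) {list(m.values.columns[flat[:5]])}"
        )
    Z = (X - mu) / sd
    return ExpressionMatrix(
        pd.DataFrame(Z, index=m.values.index, columns=m.values.columns),
        scale=STANDARDIZED,
    )
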