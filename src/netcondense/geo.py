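"""Minimal reader for GEO Series-Matrix text files.

A series-matrix file interleaves ``!``-prefixed metadata lines with one
tab-separated value table delimited by ``!series_matrix_table_begin`` /
``!series_matrix_table_end``. This reader extracts the value table as an
:class:`ExpressionMatrix` and collects the per-sample
``!Sample_characteristics_ch1`` lines, from which two-group labels can be
derived with a caller-supplied predicate (e.g. matching a pCR /
residual-disease response field).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Callable

import pandas as pd

from .expression import GROUP_A, GROUP_B, ExpressionMatrix, GroupLabels


def read_series_matrix(path: str | Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Return (expression matrix, sample characteristics frame).

    The characteristics frame has one row per sample (indexed by GEO sample
    accession) and one column per ``!Sample_characteristics_ch1`` line, in
    file order.
    """
    char_lines: list[list[str]] = []
    sample_ids: list[str] | None = None
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_geo_accession"):
                sample_ids = [f.strip('"') for f in line.split("\t")[1:]]
            elif line.startswith("!Sample_characteristics_ch1"):
                char_lines.append([f.strip('"') for f in line.split("\t")[1:]])
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix table found")
    body = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    body.columns = [str(c).strip('"') for c in body.columns]
    body.index = [str(i).strip('"') for i in body.index]
    matrix = ExpressionMatrix(body.astype(float), scale="linear")
    if sample_ids is None:
        sample_ids = list(body.columns)
    chars = pd.DataFrame(
        {f"characteristics_{i}": vals for i, vals in enumerate(char_lines)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return matrix, chars


def labels_from_characteristics(
    chars: pd.DataFrame, is_case: Callable[[pd.Series], bool]
) -> GroupLabels:
    """Build two-group labels from a characteristics frame: samples for
    which ``is_case`` returns True become group B (cases/responders), the
    rest group A."""
    mapping = {
        str(s): (GROUP_B if is_case(row) else GROUP_A)
        for s, row in chars.iterrows()
    }
    return GroupLabels(mapping)
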