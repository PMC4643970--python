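"""Probe-to-gene reduction and gene-panel filtering.

Mirrors the standard microarray preprocessing chain for pooled MAS5-normalized
data: replicate spots within an array are averaged, multiple probes (or probe
sets) per gene symbol are reduced to the single probe with the highest average
intensity across all arrays, and analyses are restricted to a declared gene
panel (here, a T-cell compartment signature supplied as a GMT set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import validate_expression


def average_replicates(matrix: pd.DataFrame, replicate_groups: dict[str, str]) -> pd.DataFrame:
    """Average replicate rows (per sample, arithmetic mean); ungrouped rows pass through.

    ``replicate_groups`` maps row id -> group id; each group collapses to one
    row named by the group id.
    """
    grouped = {rid: gid for rid, gid in replicate_groups.items() if rid in matrix.index}
    by_group: dict[str, list[str]] = {}
    for rid, gid in grouped.items():
        by_group.setdefault(gid, []).append(rid)
    for gid, rows in by_group.items():
        if not rows:
            raise ValueError(f"empty replicate group {gid!r}")
    passthrough = matrix.loc[[r for r in matrix.index if r not in grouped]]
    collapsed = pd.DataFrame(
        {gid: matrix.loc[rows].mean(axis=0) for gid, rows in by_group.items()}
    ).T
    collapsed.index.name = matrix.index.name
    out = pd.concat([passthrough, collapsed]) if len(collapsed) else passthrough
    return out


@dataclass
class CollapseResult:
    matrix: pd.DataFrame  # gene-level, rows = gene symbols
    chosen_probe: pd.Series  # gene -> probe id that supplied the row


def collapse_probes(matrix: pd.DataFrame, probe_map: pd.Series) -> CollapseResult:
    """One row per gene symbol: the probe with the highest mean signal across arrays.

    The mean is the unweighted arithmetic mean over all samples on the linear
    scale; ties break to the lexicographically smallest probe id. Output rows
    are copies of input rows (no new values are invented).
    """
    unmapped = matrix.index.difference(probe_map.index)
    if len(unmapped):
        raise ValueError(f"unmapped probes: {unmapped.tolist()[:5]}")
    means = matrix.mean(axis=1)
    # Sort by probe id first so idxmax's first-wins rule realizes the tie-break.
    order = means.loc[sorted(matrix.index)]
    genes = probe_map.loc[order.index]
    chosen = order.groupby(genes).idxmax()
    chosen = chosen.sort_index()
    collapsed = matrix.loc[chosen.values]
    collapsed.index = pd.Index(chosen.index, name="gene_symbol")
    return CollapseResult(matrix=collapsed, chosen_probe=chosen.rename("probe_id"))


def filter_to_panel(matrix: pd.DataFrame, panel: list[str]) -> pd.DataFrame:
    """Restrict a gene-level matrix to a gene panel, preserving matrix row order.

    Panel genes absent from the matrix are reported via ``UserWarning``; an
    empty intersection is an error.
    """
    panel_set = set(panel)
    if len(panel_set) != len(panel):
        raise ValueError("panel contains duplicate gene symbols")
    keep = [g for g in matrix.index if g in panel_set]
    if not keep:
        raise ValueError("panel does not intersect the matrix genes")
    missing = sorted(panel_set - set(matrix.index))
    if missing:
        warnings.warn(
            f"{len(missing)} panel genes absent from the matrix: {missing[:10]}",
            UserWarning,
            stacklevel=2,
        )
    return matrix.loc[keep]


def load_and_validate(matrix: pd.DataFrame) -> pd.DataFrame:
    """Alias kept for pipeline symmetry: reject non-finite / non-positive rows."""
    return validate_expression(matrix)
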