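"""Readers and writers for the plain-text formats used throughout the package.

Expression matrices are tab-separated with probe/gene identifiers in the first
column and one column per sample; values are positive, linear-scale normalized
signal (MAS5-like units). Gene sets travel as GMT (name, description, then one
gene symbol per tab-delimited field). Sample annotations and probe maps are
two/three-column TSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

CLASS_HEALTHY = "healthy"
CLASS_MALIGNANT = "malignant"


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate an expression matrix: unique ids, finite strictly-positive values.

    Raises ``ValueError`` naming the offending rows; silent imputation would
    corrupt downstream fold-changes, so nothing is repaired here.
    """
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids: {dups[:5]}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    values = matrix.to_numpy(dtype=float)
    bad = ~np.isfinite(values) | (values <= 0)
    if bad.any():
        rows = matrix.index[bad.any(axis=1)].tolist()
        raise ValueError(
            f"non-finite or non-positive signal in rows {rows[:5]} "
            "(linear-scale normalized signal must be > 0)"
        )
    return matrix


def read_expression(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    return validate_expression(matrix)


def write_expression(matrix: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_probe_map(path: str | Path) -> pd.Series:
    """Probe→gene map as a Series indexed by probe id."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError("probe map needs two columns: probe_id, gene_symbol")
    return table.set_index(table.columns[0])[table.columns[1]]


def write_probe_map(probe_map: pd.Series, path: str | Path) -> None:
    probe_map.rename_axis("probe_id").rename("gene_symbol").to_csv(path, sep="\t")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Sample annotations: sample_id, class (healthy/malignant), subtype."""
    table = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    unknown = set(table["class"]) - {CLASS_HEALTHY, CLASS_MALIGNANT}
    if unknown:
        raise ValueError(f"unknown sample classes: {sorted(unknown)}")
    return table


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, _desc, *genes = fields
        members = [g for g in genes if g]
        if not members:
            raise ValueError(f"empty gene set {name!r}")
        sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    lines = []
    for name, genes in sets.items():
        desc = descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
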