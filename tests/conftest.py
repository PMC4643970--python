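"""Shared fixtures: small toy matrices and the default synthetic cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pantcl
from pantcl.class_comparison import DECriteria, permutation_test
from pantcl.preprocess import collapse_probes, filter_to_panel


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-condition cohort (seed 0), collapsed to gene level."""
    dataset = pantcl.simulate_dataset(pantcl.SimulationConfig(seed=0))
    collapsed = collapse_probes(dataset.expression, dataset.probe_map)
    panel = filter_to_panel(collapsed.matrix, dataset.gene_sets["TCELL_COMPARTMENT"])
    return {"dataset": dataset, "gene_matrix": collapsed.matrix, "panel_matrix": panel}


def run_subtype_de(dataset, panel_matrix, seed_base=1000, criteria=None):
    """Per-subtype healthy-vs-malignant DE over the panel matrix."""
    annotations = dataset.annotations
    healthy = annotations.index[annotations["class"] == "healthy"]
    results = {}
    subtypes = sorted(set(annotations["subtype"]) - {"CD4", "CD8"})
    for i, subtype in enumerate(subtypes):
        cols = list(healthy) + list(annotations.index[annotations["subtype"] == subtype])
        results[subtype] = permutation_test(
            panel_matrix[cols],
            annotations.loc[cols, "class"],
            criteria or DECriteria(),
            seed=seed_base + i,
            reference="healthy",
        )
    return results


def two_group_matrix(values_by_gene: dict[str, list[float]], n_group1: int) -> tuple[pd.DataFrame, pd.Series]:
    """Tiny expression matrix + labels helper for toy class comparisons."""
    n = len(next(iter(values_by_gene.values())))
    cols = [f"s{i}" for i in range(n)]
    matrix = pd.DataFrame(values_by_gene, index=cols).T
    labels = pd.Series(["g1"] * n_group1 + ["g2"] * (n - n_group1), index=cols)
    return matrix, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
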