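"""CAV1-correlated gene pre-filtering and High-vs-Low tumor-microenvironment DE.

The whole-biopsy (tumor microenvironment) contrast between CAV1-High and
CAV1-Low malignant samples is restricted, before testing, to genes whose log2
signal correlates with the anchor gene across the malignant samples (Pearson
p < 0.01 and |r| >= 0.22, both enforced). The filtered submatrix then goes
through the class-comparison engine in Korn mode (false-discovery proportion
<= 1% at 99% confidence), which is exactly equivalent to running the engine
directly on that submatrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .class_comparison import MODE_KORN, DECriteria, DEResult, permutation_test
from .stratify import StratificationResult


@dataclass
class CorrelationFilterResult:
    table: pd.DataFrame  # per gene: r, p, passed
    anchor: str
    samples: list[str]
    p_cutoff: float
    r_cutoff: float
    metadata: dict = field(default_factory=dict)

    @property
    def passing_genes(self) -> list[str]:
        return self.table.index[self.table["passed"]].tolist()


def correlation_filter(
    matrix: pd.DataFrame,
    anchor_gene: str,
    samples: list[str] | None = None,
    p_cutoff: float = 0.01,
    r_cutoff: float = 0.22,
) -> CorrelationFilterResult:
    """Pearson correlation of each gene's log2 signal with the anchor's.

    Two-sided p from t = r sqrt(n-2) / sqrt(1-r^2) on n-2 df. A gene passes iff
    p < ``p_cutoff`` and |r| >= ``r_cutoff`` (sign-symmetric by construction).
    Constant genes fail with r recorded as NaN; a constant anchor is an error.
    """
    if anchor_gene not in matrix.index:
        raise ValueError(f"anchor gene {anchor_gene!r} not in matrix")
    sub = matrix if samples is None else matrix[samples]
    n = sub.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation filter")
    x = np.log2(sub.to_numpy(dtype=float))
    anchor = np.log2(sub.loc[anchor_gene].to_numpy(dtype=float))
    a = anchor - anchor.mean()
    sa = np.sqrt((a**2).sum())
    if sa == 0.0:
        raise ValueError("anchor gene is constant over the chosen samples")
    xc = x - x.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ a) / (sx * sa)
    r = np.where(sx == 0.0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isnan(r), 1.0, np.where(np.abs(r) >= 1.0, 0.0, p))
    passed = (~np.isnan(r)) & (p < p_cutoff) & (np.abs(r) >= r_cutoff)
    table = pd.DataFrame({"r": r, "p": p, "passed": passed}, index=matrix.index)
    return CorrelationFilterResult(
        table=table,
        anchor=anchor_gene,
        samples=list(sub.columns),
        p_cutoff=p_cutoff,
        r_cutoff=r_cutoff,
        metadata={"n_samples": n, "scale": "log2"},
    )


@dataclass
class TMEResult:
    de: DEResult
    n_tested: int
    n_de: int
    n_up: int
    n_down: int

    @property
    def fraction_up(self) -> float:
        return self.n_up / self.n_de if self.n_de else float("nan")


def tme_de(
    matrix: pd.DataFrame,
    stratification: StratificationResult,
    filtered: CorrelationFilterResult,
    criteria: DECriteria | None = None,
    seed: int | None = 0,
) -> TMEResult:
    """CAV1-High vs CAV1-Low class comparison over the correlation-filtered genes.

    Fold-changes are High-vs-Low (Low as reference), so a positive sign means
    overexpressed in the High tumor microenvironment.
    """
    criteria = criteria or DECriteria(mode=MODE_KORN)
    genes = filtered.passing_genes
    if not genes:
        raise ValueError("correlation filter passed no genes")
    labels = stratification.labels
    sub = matrix.loc[genes, labels.index]
    de = permutation_test(sub, labels, criteria=criteria, seed=seed, reference="Low")
    sig = de.table["significant"]
    n_up = int((sig & (de.table["fold_change"] > 1.0)).sum())
    n_down = int((sig & (de.table["fold_change"] < -1.0)).sum())
    return TMEResult(de=de, n_tested=len(genes), n_de=int(sig.sum()), n_up=n_up, n_down=n_down)
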