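"""Top-scoring-pairs (TSP) rank classifier.

TSP selects, from a candidate gene list, the single unordered gene pair (i, j)
whose within-sample ordering best separates two classes: with
p_hat_ij(c) = frequency of {signal_i < signal_j} in class c, the pair score is
Delta_ij = |p_hat_ij(class1) - p_hat_ij(class2)|. Classification of a new
sample uses only which of the two genes is larger — a rank rule invariant to
any within-sample monotone transformation of the signal. Delta ties break to
the larger secondary rank score Gamma (the between-class gap in the mean
within-sample rank difference of the two genes), then to the lexicographically
smallest pair. Within-sample ties of the two signals count as not(i < j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class TSPModel:
    gene_i: str
    gene_j: str
    p_hat: dict[str, float]  # class -> frequency of signal_i < signal_j
    delta: float
    gamma: float
    classes: tuple[str, str]

    def decision(self, i_less_than_j: bool) -> str:
        """Class predicted for a given ordering of (gene_i, gene_j)."""
        c1, c2 = self.classes
        favored = c1 if self.p_hat[c1] >= self.p_hat[c2] else c2
        other = c2 if favored == c1 else c1
        return favored if i_less_than_j else other


@dataclass
class ClassifierEval:
    tp: int
    fn: int
    tn: int
    fp: int
    scheme: str
    pairs: list[tuple[str, str]]  # selected pair per fold (one entry for resubstitution)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def _pair_scores(x: np.ndarray, mask1: np.ndarray, mask2: np.ndarray):
    """Delta and Gamma for all unordered pairs of the rows of ``x``.

    Returns (delta, gamma, p1, p2) as (G, G) arrays for i < j entries.
    """
    less = x[:, None, :] < x[None, :, :]  # i < j per sample
    p1 = less[:, :, mask1].mean(axis=2)
    p2 = less[:, :, mask2].mean(axis=2)
    delta = np.abs(p1 - p2)
    ranks = np.apply_along_axis(rankdata, 0, x)  # within-sample ranks of candidates
    diff = ranks[:, None, :] - ranks[None, :, :]
    gamma = np.abs(diff[:, :, mask1].mean(axis=2) - diff[:, :, mask2].mean(axis=2))
    return delta, gamma, p1, p2


def fit_tsp(matrix: pd.DataFrame, labels: pd.Series, candidates: list[str]) -> TSPModel:
    """Score every unordered candidate pair and return the top-scoring one."""
    labels = labels.loc[matrix.columns]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    genes = [g for g in candidates if g in matrix.index]
    if len(genes) < 2:
        raise ValueError("fewer than two candidate genes present in the matrix")
    genes = sorted(genes)
    x = matrix.loc[genes].to_numpy(dtype=float)
    mask1 = (labels == classes[0]).to_numpy()
    mask2 = ~mask1
    if not mask1.any() or not mask2.any():
        raise ValueError("both classes must be non-empty")

    delta, gamma, p1, p2 = _pair_scores(x, mask1, mask2)
    best = None
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            key = (delta[i, j], gamma[i, j])
            if best is None or key > best[0]:
                best = (key, i, j)
    _, i, j = best
    return TSPModel(
        gene_i=genes[i],
        gene_j=genes[j],
        p_hat={classes[0]: float(p1[i, j]), classes[1]: float(p2[i, j])},
        delta=float(delta[i, j]),
        gamma=float(gamma[i, j]),
        classes=(classes[0], classes[1]),
    )


def predict(model: TSPModel, sample: pd.Series) -> str:
    """Classify one sample from the ordering of the model's two genes.

    Equal signals count as not(i < j), matching the fitting convention.
    """
    for gene in (model.gene_i, model.gene_j):
        if gene not in sample.index:
            raise ValueError(f"sample is missing model gene {gene!r}")
    return model.decision(bool(sample[model.gene_i] < sample[model.gene_j]))


def evaluate(
    matrix: pd.DataFrame,
    labels: pd.Series,
    candidates: list[str],
    scheme: str = "LOOCV",
    positive_class: str | None = None,
) -> ClassifierEval:
    """Evaluate TSP with malignant-style positive class for sensitivity/specificity.

    LOOCV refits the pair within each fold; resubstitution fits once and
    predicts the training samples.
    """
    scheme = scheme.upper()
    if scheme not in ("LOOCV", "RESUBSTITUTION"):
        raise ValueError(f"unknown scheme {scheme!r}")
    labels = labels.loc[matrix.columns]
    classes = sorted(labels.unique())
    if positive_class is None:
        positive_class = "malignant" if "malignant" in classes else classes[1]
    negative_class = classes[0] if classes[1] == positive_class else classes[1]

    predictions: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    if scheme == "RESUBSTITUTION":
        model = fit_tsp(matrix, labels, candidates)
        pairs.append((model.gene_i, model.gene_j))
        for sid in matrix.columns:
            predictions[sid] = predict(model, matrix[sid])
    else:
        for sid in matrix.columns:
            rest = matrix.drop(columns=[sid])
            fold_labels = labels.drop(index=sid)
            if fold_labels.nunique() < 2:
                raise ValueError(f"fold leaving out {sid!r} loses an entire class")
            model = fit_tsp(rest, fold_labels, candidates)
            pairs.append((model.gene_i, model.gene_j))
            predictions[sid] = predict(model, matrix[sid])

    pred = pd.Series(predictions).loc[matrix.columns]
    is_pos = labels == positive_class
    tp = int(((pred == positive_class) & is_pos).sum())
    fn = int(((pred == negative_class) & is_pos).sum())
    tn = int(((pred == negative_class) & ~is_pos).sum())
    fp = int(((pred == positive_class) & ~is_pos).sum())
    return ClassifierEval(tp=tp, fn=fn, tn=tn, fp=fp, scheme=scheme, pairs=pairs)
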