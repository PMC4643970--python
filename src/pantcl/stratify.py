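"""Expression-threshold stratification of malignant samples (CAV1-High/Low).

The threshold is computed from healthy controls only, on the linear normalized
signal of the designated gene/probe: T = mean + 2 * sample SD (ddof = 1). A
malignant sample is High when its signal exceeds T strictly, Low otherwise.
Quartiles for the healthy boxplot-outlier rule use linear interpolation, and
the convention is recorded in the result so outlier sets are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HIGH = "High"
LOW = "Low"
QUARTILE_CONVENTION = "linear_interpolation"


def round_half_up_pct(fraction: float) -> int:
    """Whole-percent rounding with .5 rounding up (88% for 7/8, 63% for 5/8)."""
    return int(np.floor(100.0 * fraction + 0.5))


@dataclass
class StratificationResult:
    gene: str
    healthy_mean: float
    healthy_sd: float
    threshold: float
    labels: pd.Series  # per malignant sample: High/Low
    per_subtype: pd.DataFrame  # n_high, n, fraction, pct per subtype
    pooled_fraction: float
    pooled_n_high: int
    pooled_n: int
    healthy_below_threshold_fraction: float
    healthy_outliers: list[str]
    metadata: dict = field(default_factory=lambda: {"quartiles": QUARTILE_CONVENTION})

    @property
    def pooled_pct(self) -> int:
        return round_half_up_pct(self.pooled_fraction)

    @property
    def high_samples(self) -> list[str]:
        return self.labels.index[self.labels == HIGH].tolist()

    @property
    def low_samples(self) -> list[str]:
        return self.labels.index[self.labels == LOW].tolist()


def compute_threshold(healthy_values) -> tuple[float, float, float]:
    """(mean, sample SD, threshold = mean + 2 SD) on the input linear scale."""
    values = np.asarray(healthy_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 healthy samples for a threshold")
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    return mu, sd, mu + 2.0 * sd


def classify_samples(
    malignant_values: pd.Series, threshold: float, subtypes: pd.Series | None = None
) -> tuple[pd.Series, pd.DataFrame, float]:
    """High/Low labels (value > T strictly is High) plus per-subtype fractions."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    labels = pd.Series(
        np.where(malignant_values.to_numpy(dtype=float) > threshold, HIGH, LOW),
        index=malignant_values.index,
        name="cav1_label",
    )
    if subtypes is None:
        subtypes = pd.Series("all", index=malignant_values.index)
    subtypes = subtypes.loc[malignant_values.index]
    rows = []
    for subtype, group in labels.groupby(subtypes, sort=True):
        n_high = int((group == HIGH).sum())
        rows.append((subtype, n_high, len(group), n_high / len(group)))
    per_subtype = pd.DataFrame(rows, columns=["subtype", "n_high", "n", "fraction"]).set_index(
        "subtype"
    )
    per_subtype["pct"] = [round_half_up_pct(f) for f in per_subtype["fraction"]]
    pooled = float((labels == HIGH).mean())
    return labels, per_subtype, pooled


def healthy_outliers(healthy_values: pd.Series, threshold: float | None = None):
    """Boxplot-rule outliers among healthy samples (above Q3 + 1.5 IQR).

    Also reports the fraction of healthy values at or below the stratification
    threshold when one is supplied.
    """
    values = healthy_values.to_numpy(dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 healthy values for the boxplot rule")
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation convention
    fence = q3 + 1.5 * (q3 - q1)
    outliers = healthy_values.index[values > fence].tolist()
    below = float((values <= threshold).mean()) if threshold is not None else float("nan")
    return outliers, fence, below


def stratify_cohort(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    gene: str = "CAV1",
) -> StratificationResult:
    """Threshold on healthy samples of ``gene`` and classify malignant samples.

    The threshold depends only on healthy samples, so adding or removing
    malignant samples never moves it; and because both the threshold and the
    signals scale together, labels are invariant to a common positive
    rescaling of the matrix.
    """
    if gene not in matrix.index:
        raise ValueError(f"gene {gene!r} not in matrix")
    annotations = annotations.loc[matrix.columns]
    healthy_ids = annotations.index[annotations["class"] == "healthy"]
    malignant_ids = annotations.index[annotations["class"] == "malignant"]
    signal = matrix.loc[gene]
    mu, sd, threshold = compute_threshold(signal.loc[healthy_ids])
    labels, per_subtype, pooled = classify_samples(
        signal.loc[malignant_ids], threshold, annotations.loc[malignant_ids, "subtype"]
    )
    outliers, _fence, below = healthy_outliers(signal.loc[healthy_ids], threshold)
    return StratificationResult(
        gene=gene,
        healthy_mean=mu,
        healthy_sd=sd,
        threshold=threshold,
        labels=labels,
        per_subtype=per_subtype,
        pooled_fraction=pooled,
        pooled_n_high=int((labels == HIGH).sum()),
        pooled_n=len(labels),
        healthy_below_threshold_fraction=below,
        healthy_outliers=outliers,
    )


def summarize_counts(per_subtype_counts: dict[str, tuple[int, int]]) -> dict:
    """Pool per-subtype High/total counts into the overall classification rate.

    Given e.g. {"AITL": (33, 43), ...} returns per-subtype and pooled
    fractions with whole-percent (half-up) renderings — the arithmetic behind
    a pooled "67% (125/187)" style statement.
    """
    per_subtype = {}
    n_high = 0
    n_total = 0
    for subtype, (high, total) in per_subtype_counts.items():
        if not 0 <= high <= total:
            raise ValueError(f"bad counts for {subtype}: {high}/{total}")
        per_subtype[subtype] = {
            "n_high": high,
            "n": total,
            "fraction": high / total,
            "pct": round_half_up_pct(high / total),
        }
        n_high += high
        n_total += total
    pooled_fraction = n_high / n_total
    return {
        "per_subtype": per_subtype,
        "pooled_n_high": n_high,
        "pooled_n": n_total,
        "pooled_fraction": pooled_fraction,
        "pooled_pct": round_half_up_pct(pooled_fraction),
    }
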