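"""Tissue-microarray immunohistochemistry scoring summaries.

Per-core staining calls (lymphoid compartment: positive / light / negative;
stromal compartment: positive / negative / none-recorded) are tabulated to
patient-level positivity per subtype and marker, then pooled per marker across
subtypes. A patient is lymphoid-positive for a marker if any of their cores is
scored positive or light (the any-core rule; "light" merges into positive —
the only rule under which core-level narratives reconcile with patient-count
denominators). Percentages are whole-percent, half rounding up.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .stratify import round_half_up_pct

LYMPHOID_CALLS = {"positive", "light", "negative"}
STROMAL_CALLS = {"positive", "negative", "none-recorded"}
POSITIVE_CALLS = {"positive", "light"}


@dataclass
class StainingSummary:
    per_subtype: pd.DataFrame  # (subtype, marker): n_positive, n_patients, pct
    pooled: pd.DataFrame  # marker: n_positive, n_patients, pct
    stromal: pd.DataFrame  # (subtype, marker): n_positive, n_patients, pct

    def pct(self, subtype: str, marker: str) -> int:
        return int(self.per_subtype.loc[(subtype, marker), "pct"])


def _validate(records: pd.DataFrame) -> None:
    required = {"core_id", "patient_id", "subtype", "marker", "lymphoid_call", "stromal_call"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"staining table lacks columns: {sorted(missing)}")
    bad = records.loc[~records["lymphoid_call"].isin(LYMPHOID_CALLS)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"unknown lymphoid call {row['lymphoid_call']!r} in core {row['core_id']!r}"
        )
    bad = records.loc[~records["stromal_call"].isin(STROMAL_CALLS)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"unknown stromal call {row['stromal_call']!r} in core {row['core_id']!r}"
        )


def summarize_staining(records: pd.DataFrame, rule: str = "any") -> StainingSummary:
    """Patient-level positivity per (subtype, marker), pooled per marker.

    ``rule`` is "any" (any core positive/light makes the patient positive; the
    default) or "all" (every core must be positive/light). Order of records
    and duplicate-core shuffling do not affect the summary.
    """
    if rule not in ("any", "all"):
        raise ValueError(f"unknown core aggregation rule {rule!r}")
    _validate(records)
    pos = records.assign(
        lymph_pos=records["lymphoid_call"].isin(POSITIVE_CALLS),
        strom_pos=records["stromal_call"] == "positive",
    )
    agg = "any" if rule == "any" else "all"
    patient = pos.groupby(["subtype", "marker", "patient_id"], sort=True).agg(
        lymph_pos=("lymph_pos", agg), strom_pos=("strom_pos", agg)
    )

    def _tab(col: str) -> pd.DataFrame:
        grouped = patient.groupby(level=["subtype", "marker"], sort=True)[col]
        out = grouped.agg(n_positive="sum", n_patients="size")
        out["pct"] = [
            round_half_up_pct(p / n) for p, n in zip(out["n_positive"], out["n_patients"])
        ]
        return out

    per_subtype = _tab("lymph_pos")
    stromal = _tab("strom_pos")

    pooled_grp = patient.groupby(level="marker", sort=True)["lymph_pos"]
    pooled = pooled_grp.agg(n_positive="sum", n_patients="size")
    pooled["pct"] = [
        round_half_up_pct(p / n) for p, n in zip(pooled["n_positive"], pooled["n_patients"])
    ]
    return StainingSummary(per_subtype=per_subtype, pooled=pooled, stromal=stromal)


def pooled_positivity(per_subtype_counts: dict[str, tuple[int, int]]) -> dict:
    """Pool per-subtype (positive, total) patient counts for one marker."""
    n_pos = sum(p for p, _ in per_subtype_counts.values())
    n_tot = sum(t for _, t in per_subtype_counts.values())
    if any(not 0 <= p <= t for p, t in per_subtype_counts.values()):
        raise ValueError("counts must satisfy 0 <= positive <= total")
    return {
        "n_positive": n_pos,
        "n_patients": n_tot,
        "fraction": n_pos / n_tot,
        "pct": round_half_up_pct(n_pos / n_tot),
    }


def majority_vote(calls: list[str]) -> str:
    """Optional helper to collapse multiple raters' calls into one consensus.

    Positive-leaning tie-break: positive > light > negative on equal counts.
    """
    order = {"positive": 0, "light": 1, "negative": 2}
    unknown = [c for c in calls if c not in order]
    if unknown:
        raise ValueError(f"unknown call token {unknown[0]!r}")
    counts = pd.Series(calls).value_counts()
    best = max(counts.index, key=lambda c: (counts[c], -order[c]))
    return best
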