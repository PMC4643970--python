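"""Pan-subtype and relaxed shared gene signatures from per-subtype DE results.

A gene enters the pan list only if it is significant with the same direction
in every subtype (up with FC > 1 everywhere, or down with FC < -1 everywhere);
the relaxed list asks for a consistent direction in at least ``min_support``
subtypes. Genes significant with conflicting directions are excluded from both
and reported separately — the deterministic replacement for a manual
compilation step.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .class_comparison import DEResult


@dataclass
class SignatureResult:
    pan_up: list[str]
    pan_down: list[str]
    relaxed: pd.DataFrame  # gene, support, direction (+1/-1); includes pan genes
    conflicted: list[str]
    fold_changes: pd.DataFrame  # gene x subtype
    min_support: int

    @property
    def relaxed_genes(self) -> list[str]:
        return self.relaxed.index.tolist()


def intersect_signatures(
    per_subtype: dict[str, DEResult], min_support: int = 3
) -> SignatureResult:
    """Combine per-subtype DE results over a common gene universe.

    Raises on mismatched gene universes. Monotone in the criteria: relaxing
    the per-subtype significance never shrinks the pan lists; and
    ``min_support = n`` makes the relaxed list reproduce the pan lists.
    """
    if len(per_subtype) < 2:
        raise ValueError("need at least two subtypes to intersect")
    subtypes = list(per_subtype)
    universe = per_subtype[subtypes[0]].table.index
    for s in subtypes[1:]:
        if not universe.equals(per_subtype[s].table.index):
            raise ValueError(f"gene universe of {s!r} differs from {subtypes[0]!r}")
    if not 1 <= min_support <= len(subtypes):
        raise ValueError("min_support outside [1, number of subtypes]")

    fc = pd.DataFrame({s: per_subtype[s].table["fold_change"] for s in subtypes})
    sig = pd.DataFrame({s: per_subtype[s].table["significant"] for s in subtypes})
    up = sig & (fc > 1.0)
    down = sig & (fc < -1.0)
    n_up = up.sum(axis=1)
    n_down = down.sum(axis=1)

    conflicted = universe[(n_up > 0) & (n_down > 0)]
    clean = ~universe.isin(conflicted)

    pan = len(subtypes)
    pan_up = universe[(n_up == pan) & clean].tolist()
    pan_down = universe[(n_down == pan) & clean].tolist()

    relaxed_mask = clean & ((n_up >= min_support) | (n_down >= min_support))
    relaxed = pd.DataFrame(
        {
            "support": n_up.where(n_up >= n_down, n_down)[relaxed_mask],
            "direction": (n_up >= min_support).map({True: 1, False: -1})[relaxed_mask],
        }
    )
    relaxed.index.name = "gene"

    return SignatureResult(
        pan_up=pan_up,
        pan_down=pan_down,
        relaxed=relaxed,
        conflicted=conflicted.tolist(),
        fold_changes=fc,
        min_support=min_support,
    )
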