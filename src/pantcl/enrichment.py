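"""Gene-category over/under-representation and fold-change rank enrichment.

Self-contained statistics for GMT-supplied categories, in the style of the
classical gene-list analysis tools:

* ``overrepresentation`` — an exact binomial test of the number of list
  members falling in a category against the category's frequency in the
  reference universe, two-sided by doubling the smaller tail (a hypergeometric
  variant is available);
* ``rank_enrichment`` — a two-sided Mann-Whitney U test comparing the signed
  fold-changes of category members against non-members, with exhaustive
  enumeration when both groups have at most 8 members and a tie-corrected
  normal approximation otherwise.

Both apply Bonferroni correction across the categories actually tested.
Database-versioned term counts from any particular ontology release are not
reproducible here; the categories are whatever the caller supplies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

EXACT_MW_MAX = 8


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per category: n_observed/expected (or medians), direction, p, p_bonferroni
    test: str
    n_categories: int
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p_bonferroni"] < self.alpha]


def binomial_two_sided(k: int, n: int, q: float) -> float:
    """Two-sided exact binomial p by doubling the smaller tail, capped at 1."""
    lower = stats.binom.cdf(k, n, q)
    upper = stats.binom.sf(k - 1, n, q)
    return float(min(1.0, 2.0 * min(lower, upper)))


def hypergeom_two_sided(k: int, n_list: int, m_category: int, n_universe: int) -> float:
    lower = stats.hypergeom.cdf(k, n_universe, m_category, n_list)
    upper = stats.hypergeom.sf(k - 1, n_universe, m_category, n_list)
    return float(min(1.0, 2.0 * min(lower, upper)))


def overrepresentation(
    gene_list: list[str],
    universe: list[str],
    categories: dict[str, list[str]],
    test: str = "binomial",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Category over/under-representation of ``gene_list`` within ``universe``.

    Categories are intersected with the universe first; empty intersections
    are skipped with a warning. Direction is "+" iff observed > expected.
    """
    if test not in ("binomial", "hypergeometric"):
        raise ValueError(f"unknown test {test!r}")
    universe_set = set(universe)
    list_set = set(gene_list)
    if not list_set <= universe_set:
        raise ValueError("gene list is not a subset of the universe")
    n = len(list_set)
    rows = []
    for name, members in categories.items():
        cat = set(members) & universe_set
        if not cat:
            warnings.warn(f"category {name!r} does not intersect the universe; skipped",
                          UserWarning, stacklevel=2)
            continue
        k = len(list_set & cat)
        q = len(cat) / len(universe_set)
        expected = n * q
        if test == "binomial":
            p = binomial_two_sided(k, n, q)
        else:
            p = hypergeom_two_sided(k, n, len(cat), len(universe_set))
        rows.append((name, k, expected, "+" if k > expected else "-", p))
    table = pd.DataFrame(
        rows, columns=["category", "n_observed", "expected", "direction", "p"]
    ).set_index("category")
    table["p_bonferroni"] = np.minimum(1.0, table["p"] * len(table))
    return EnrichmentResult(table=table, test=f"{test}_overrep", n_categories=len(table), alpha=alpha)


def _mann_whitney_u(in_values: np.ndarray, out_values: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([in_values, out_values]))
    n_in = len(in_values)
    return float(ranks[:n_in].sum() - n_in * (n_in + 1) / 2.0)


def mannwhitney_exact_p(in_values, out_values) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Handles ties through midranks; two-sided as twice the smaller tail of the
    enumerated U distribution, capped at 1.
    """
    in_values = np.asarray(in_values, dtype=float)
    out_values = np.asarray(out_values, dtype=float)
    pooled = np.concatenate([in_values, out_values])
    ranks = rankdata(pooled)
    n_in = len(in_values)
    n_tot = len(pooled)
    offset = n_in * (n_in + 1) / 2.0
    u_obs = float(ranks[:n_in].sum() - offset)
    us = np.array(
        [sum(ranks[list(c)]) - offset for c in combinations(range(n_tot), n_in)]
    )
    lower = np.mean(us <= u_obs + 1e-12)
    upper = np.mean(us >= u_obs - 1e-12)
    return float(min(1.0, 2.0 * min(lower, upper)))


def mannwhitney_asymptotic_p(in_values, out_values) -> float:
    """Tie-corrected normal approximation (no continuity correction)."""
    in_values = np.asarray(in_values, dtype=float)
    out_values = np.asarray(out_values, dtype=float)
    n1, n2 = len(in_values), len(out_values)
    u = _mann_whitney_u(in_values, out_values)
    n = n1 + n2
    pooled = np.concatenate([in_values, out_values])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (u - n1 * n2 / 2.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def rank_enrichment(
    fold_changes: pd.Series,
    categories: dict[str, list[str]],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Mann-Whitney comparison of category members' fold-changes vs non-members.

    Exact enumeration when both groups have <= 8 members, tie-corrected normal
    approximation otherwise. Direction is "+" iff the category median exceeds
    the complement median. Categories with fewer than 2 usable members on
    either side are skipped with a warning.
    """
    genes = fold_changes.index
    rows = []
    for name, members in categories.items():
        mask = genes.isin(set(members))
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        if n_in < 2 or n_out < 2:
            warnings.warn(f"category {name!r} has <2 members in or out of the list; skipped",
                          UserWarning, stacklevel=2)
            continue
        inside = fold_changes[mask].to_numpy(dtype=float)
        outside = fold_changes[~mask].to_numpy(dtype=float)
        if n_in <= EXACT_MW_MAX and n_out <= EXACT_MW_MAX:
            p = mannwhitney_exact_p(inside, outside)
            method = "exact"
        else:
            p = mannwhitney_asymptotic_p(inside, outside)
            method = "asymptotic"
        direction = "+" if np.median(inside) > np.median(outside) else "-"
        rows.append((name, n_in, float(np.median(inside)), float(np.median(outside)), direction, p, method))
    table = pd.DataFrame(
        rows,
        columns=["category", "n_members", "median_in", "median_out", "direction", "p", "method"],
    ).set_index("category")
    table["p_bonferroni"] = np.minimum(1.0, table["p"] * len(table))
    return EnrichmentResult(
        table=table, test="mannwhitney_enrich", n_categories=len(table), alpha=alpha
    )
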