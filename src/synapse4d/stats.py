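"""Group comparisons: two-tailed Mann-Whitney U with Bonferroni correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "mannwhitney_bonferroni", "significance_stars"]


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """Pairwise Mann-Whitney results with Bonferroni-adjusted p-values."""

    table: pd.DataFrame          # group_a, group_b, U, p_raw, p_adj, stars
    n_comparisons: int


def _mwu(x: np.ndarray, y: np.ndarray):
    if np.ptp(np.concatenate([x, y])) == 0:
        # identical constant groups: no evidence either way
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 20 and len(y) <= 20
                         and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mannwhitney_bonferroni(samples: dict[str, np.ndarray],
                           comparisons: list[tuple[str, str]] | None = None,
                           ) -> GroupComparison:
    """Two-tailed Mann-Whitney U for each comparison, Bonferroni-corrected.

    The exact null distribution is used for small tie-free samples
    (n <= 20 per group), otherwise the normal approximation with tie
    correction.  The Bonferroni family is the set of comparisons actually
    performed (all pairs by default); adjusted p-values are capped at 1.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for name, vals in groups.items():
        if vals.size < 1:
            raise ValueError(f"group {name!r} is empty")
    if comparisons is None:
        names = list(groups)
        comparisons = [(a, b) for i, a in enumerate(names)
                       for b in names[i + 1:]]
    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        u, p = _mwu(groups[a], groups[b])
        p_adj = min(p * m, 1.0)
        rows.append({"group_a": a, "group_b": b, "U": u, "p_raw": p,
                     "p_adj": p_adj, "stars": significance_stars(p_adj)})
    return GroupComparison(table=pd.DataFrame(rows), n_comparisons=m)
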