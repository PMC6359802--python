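"""Exploratory screen of immune-function categories against disease control.

For each of the 41 immune-function categories the cohort is scored (mean
member-gene rank), discretized into fixed tertiles, and the disease-control
rate is compared between each pair of tertiles with a continuity-corrected
chi-square proportion test. Within each category the three pairwise
p-values are Holm-adjusted. Categories with an empty tertile lack dynamic
range in the study population and are excluded rather than tested.

Note on significance calls: the screen reports the full ranked table;
the alpha threshold is a reporting aid, not a hard filter (borderline
categories are of interest in an exploratory screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .config import DEFAULT_THRESHOLDS, Thresholds
from .ranking import (TERTILES, rank_transform, signature_score_cohort,
                      tertile_of_cohort)

#: tertile pairs tested, in reporting order
TERTILE_PAIRS = (("low", "medium"), ("medium", "high"), ("low", "high"))


def pairwise_prop_test(dc1: int, n1: int, dc2: int, n2: int) -> Tuple[float, float]:
    """Two-sample proportion test with Yates continuity correction.

    Compares dc1/n1 vs dc2/n2 via the 2x2 chi-square with df=1. The
    continuity correction is capped at |observed - expected| so the
    statistic is never negative (chi2 = 0 when |O-E| <= 0.5).

    Returns (statistic, p-value).
    """
    for dc, n in ((dc1, n1), (dc2, n2)):
        if n < 1:
            raise ValueError("each group needs n >= 1")
        if not (0 <= dc <= n):
            raise ValueError(f"count {dc} outside [0, {n}]")
    table = np.array([[dc1, n1 - dc1], [dc2, n2 - dc2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        # a zero column total means both groups are at the same extreme
        # proportion (all DC or all NDC): no evidence of a difference
        return 0.0, 1.0
    res = chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


#: Prevalence comparisons between strata use the identical mechanics.
prevalence_prop_test = pairwise_prop_test


def holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjusted p-values, returned in the input order.

    Sort ascending; the i-th smallest raw p (1-based) becomes
    ``max_{j<=i} min(1, (m-j+1) p_(j))``. Implemented directly: it is a
    ten-line computation and this function sits in the screen's inner
    loop, where a heavier multiple-testing front end is unwarranted.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return list(adjusted)


@dataclass
class ScreenResult:
    """Per-category outcome of the function screen."""

    category: str
    n_per_tertile: Dict[str, int] = field(default_factory=dict)
    dc_per_tertile: Dict[str, int] = field(default_factory=dict)
    raw_p: Dict[Tuple[str, str], float] = field(default_factory=dict)
    adjusted_p: Dict[Tuple[str, str], float] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def min_adjusted_p(self) -> float:
        if self.excluded or not self.adjusted_p:
            return float("nan")
        return min(self.adjusted_p.values())

    def dc_rate(self, tertile: str) -> float:
        n = self.n_per_tertile.get(tertile, 0)
        return self.dc_per_tertile.get(tertile, 0) / n if n else float("nan")


def screen_categories(ranks: pd.DataFrame,
                      labels: pd.Series,
                      catalog: Mapping[str, Sequence[str]],
                      thresholds: Thresholds = DEFAULT_THRESHOLDS,
                      holm_family: str = "category",
                      reference=None) -> List[ScreenResult]:
    """Run the tertile DC-rate screen over every catalog category.

    Parameters
    ----------
    ranks : genes x samples rank matrix (0-100).
    labels : response label per sample; only DC/NDC entries are used and
        must be a subset of the rank matrix columns.
    catalog : category name -> member genes.
    holm_family : "category" adjusts the 3 pairwise p-values within each
        category (default); "global" adjusts across all tested categories
        at once (3 x n_tested tests).
    reference : optional ReferencePopulation. When given, each category
        score is re-ranked against the reference population's own score
        distribution for that category before the fixed tertile cuts are
        applied — the same convention proliferation status uses — so every
        category is read on the reference-rank scale. Without it the cuts
        apply to the raw mean of member-gene ranks.

    Returns results sorted by min adjusted p (excluded categories last).
    """
    if not catalog:
        raise ValueError("empty gene-set catalog")
    if holm_family not in ("category", "global"):
        raise ValueError("holm_family must be 'category' or 'global'")
    use = labels[labels.isin(["DC", "NDC"])]
    missing = use.index.difference(ranks.columns)
    if len(missing):
        raise KeyError(f"labelled samples absent from rank matrix: {list(missing)[:5]}")
    is_dc = (use == "DC")
    ref_self = reference.self_ranks() if reference is not None else None

    results: List[ScreenResult] = []
    flat_p: List[float] = []
    flat_owner: List[Tuple[ScreenResult, Tuple[str, str]]] = []
    for name, genes in catalog.items():
        res = ScreenResult(category=name)
        scores = signature_score_cohort(ranks[use.index], genes)
        if ref_self is not None:
            ref_scores = signature_score_cohort(ref_self, genes)
            scores = pd.Series(rank_transform(scores.to_numpy(), ref_scores),
                               index=scores.index)
        tert = tertile_of_cohort(scores, thresholds)
        for t in TERTILES:
            members = tert.index[tert == t]
            res.n_per_tertile[t] = int(len(members))
            res.dc_per_tertile[t] = int(is_dc[members].sum())
        if min(res.n_per_tertile.values()) == 0:
            res.excluded = True
            empty = [t for t in TERTILES if res.n_per_tertile[t] == 0]
            res.exclusion_reason = f"empty tertile ({', '.join(empty)}): lack of dynamic range"
        else:
            for a, b in TERTILE_PAIRS:
                _, p = pairwise_prop_test(res.dc_per_tertile[a], res.n_per_tertile[a],
                                          res.dc_per_tertile[b], res.n_per_tertile[b])
                res.raw_p[(a, b)] = p
                flat_p.append(p)
                flat_owner.append((res, (a, b)))
            if holm_family == "category":
                adj = holm_adjust([res.raw_p[pair] for pair in TERTILE_PAIRS])
                res.adjusted_p = dict(zip(TERTILE_PAIRS, adj))
        results.append(res)

    if holm_family == "global" and flat_p:
        adj = holm_adjust(flat_p)
        for (res, pair), a in zip(flat_owner, adj):
            res.adjusted_p[pair] = a

    results.sort(key=lambda r: (r.excluded, r.min_adjusted_p if not r.excluded else 0.0,
                                r.category))
    return results


def screen_table(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Flatten screen results to one row per category (ranked report)."""
    rows = []
    for r in results:
        row = {"category": r.category, "excluded": r.excluded,
               "exclusion_reason": r.exclusion_reason,
               "min_adjusted_p": r.min_adjusted_p}
        for t in TERTILES:
            row[f"n_{t}"] = r.n_per_tertile.get(t, 0)
            row[f"dc_{t}"] = r.dc_per_tertile.get(t, 0)
            row[f"dc_rate_{t}"] = r.dc_rate(t)
        for a, b in TERTILE_PAIRS:
            row[f"p_{a}_vs_{b}"] = r.raw_p.get((a, b), float("nan"))
            row[f"adj_p_{a}_vs_{b}"] = r.adjusted_p.get((a, b), float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def significant_categories(results: Sequence[ScreenResult],
                           alpha: float = 0.05) -> List[str]:
    """Categories whose minimum Holm-adjusted p falls below alpha."""
    return [r.category for r in results
            if not r.excluded and r.min_adjusted_p < alpha]
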