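"""Nonparametric cohort statistics for per-sample IHC measurements.

Score and index distributions in IHC cohorts are skewed and bounded,
so the chain is rank-based throughout: descriptives, Spearman rank
correlations (overall and per subtype), a Kruskal-Wallis test across
subtypes, and Dunn's pairwise post-hoc test with Bonferroni
adjustment.  Significance is two-sided at alpha = 0.05.

Dunn's z statistic for groups i, j with mean ranks R_i, R_j over the
pooled sample of size N is

    z_ij = (R_i - R_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),

with the tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie
groups of size t.  Raw two-sided p-values are multiplied by the number
of pairs k(k-1)/2 and capped at 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Descriptives",
    "CorrelationResult",
    "describe",
    "spearman",
    "kruskal_wallis",
    "dunn_bonferroni",
    "sex_ratio",
    "analyze_cohort",
]

ALPHA = 0.05
MIN_N_CORRELATION = 3  # below this a correlation is flagged, not computed

SEX_CATEGORIES = ("female_neutered", "female_entire", "male_neutered", "male_entire")


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float  # sample SD (n-1); NaN for a single value
    median: float
    min: float
    max: float


@dataclass(frozen=True)
class CorrelationResult:
    rs: float
    p: float
    n: int
    flag: str = ""  # "low number" / "constant input" when not computed


def describe(values: Sequence[float]) -> Descriptives:
    """Mean, sample SD, median (mid-two average), min, max."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("cannot describe an empty sample")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return Descriptives(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rank correlation with tie-aware average ranks.

    rs is the Pearson correlation of the average ranks; the two-sided
    p-value uses the t approximation with n - 2 degrees of freedom.
    Pairs with a missing value are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < MIN_N_CORRELATION:
        return CorrelationResult(float("nan"), float("nan"), n, flag="low number")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, flag="constant input")
    rs, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rs), float(p), n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dunn_bonferroni(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Dunn's pairwise post-hoc test with Bonferroni adjustment.

    Returns one row per group pair with the z statistic, the raw
    two-sided p-value, and the Bonferroni-adjusted p (multiplied by
    the number of pairs, capped at 1).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term
    k = len(arrays)
    n_pairs = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        se = math.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:  # every pooled value tied
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": z,
                "p_raw": p_raw,
                "p_adj": min(1.0, p_raw * n_pairs),
            }
        )
    return pd.DataFrame(rows)


def sex_ratio(counts: Mapping[str, int]) -> tuple[float, str]:
    """Female-to-male ratio over neutered + entire animals.

    Returns the ratio rounded to two decimals and its ``"F:1"``
    rendering, e.g. ``(0.96, "0.96:1")``.
    """
    unknown = set(counts) - set(SEX_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown sex categories: {sorted(unknown)}")
    females = counts.get("female_neutered", 0) + counts.get("female_entire", 0)
    males = counts.get("male_neutered", 0) + counts.get("male_entire", 0)
    if males == 0:
        warnings.warn("no males in the cohort; ratio undefined", stacklevel=2)
        return float("nan"), "undefined"
    ratio = round(females / males, 2)
    return ratio, f"{ratio:.2f}:1"


MEASURES = ("ki67_li", "opn_ihc", "allred", "opn_area_percent")


def analyze_cohort(
    table: pd.DataFrame,
    measures: Iterable[str] = ("opn_ihc", "allred", "ki67_li"),
    correlate_with: str = "ki67_li",
) -> dict:
    """Full statistics report for a cohort table.

    Expects columns ``subtype`` plus the measure columns.  Produces
    per-subtype descriptives for each measure, Spearman correlations
    of each score against ``correlate_with`` overall and per subtype
    (subtypes with n < 3 flagged "low number"), and Kruskal-Wallis +
    Dunn-Bonferroni across subtypes for each measure.  Missing values
    are dropped pairwise for correlations and per measure for group
    tests.
    """
    measures = [m for m in measures if m in table.columns]
    subtypes = list(pd.unique(table["subtype"]))
    report: dict = {"n": int(len(table)), "subtypes": {}, "correlations": {}, "group_tests": {}}

    for st in subtypes:
        sub = table[table["subtype"] == st]
        report["subtypes"][st] = {
            "n": int(len(sub)),
            "descriptives": {m: describe(sub[m]) for m in measures if sub[m].notna().any()},
        }

    for m in measures:
        if m == correlate_with:
            continue
        entry = {"overall": spearman(table[correlate_with], table[m]), "by_subtype": {}}
        for st in subtypes:
            sub = table[table["subtype"] == st]
            entry["by_subtype"][st] = spearman(sub[correlate_with], sub[m])
        report["correlations"][f"{correlate_with}_vs_{m}"] = entry

    eligible = [st for st in subtypes if (table["subtype"] == st).sum() >= 2]
    if len(eligible) >= 2:
        for m in measures:
            groups, labels = [], []
            for st in eligible:
                vals = table.loc[table["subtype"] == st, m].dropna().to_numpy()
                if vals.size >= 2:
                    groups.append(vals)
                    labels.append(st)
            if len(groups) >= 2:
                h, p = kruskal_wallis(groups)
                report["group_tests"][m] = {
                    "kruskal_H": h,
                    "kruskal_p": p,
                    "dunn": dunn_bonferroni(groups, labels),
                }
    return report
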