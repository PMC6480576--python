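"""Nonparametric group comparison of the per-subject features.

Descriptive statistics with t-based 95% confidence intervals, the
Mann–Whitney U test, the Kruskal–Wallis H test (tie-corrected, chi-square
reference with k−1 df) and Dunn's post-hoc pairwise z tests with
Bonferroni correction.  Count-derived features are heavily tied, so tie
correction is applied in both H and the Dunn standard error; adjusted
p-values are capped at 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

__all__ = [
    "DescriptiveStats",
    "TestResult",
    "descriptive",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_bonferroni",
    "stats_report",
]


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    mean: float
    ci_low: float
    ci_high: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float


def descriptive(values: Sequence[float]) -> DescriptiveStats:
    """Mean with 95% t confidence interval, SD, min and max.

    CI = mean ± t_{0.975, n−1} · sd/√n.  The t (not z) interval matters at
    the very small healthy-group sizes typical of retrospective cohorts.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("descriptive statistics require n >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(sps.t.ppf(0.975, x.size - 1) * sd / np.sqrt(x.size))
    return DescriptiveStats(
        n=int(x.size),
        mean=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        sd=sd,
        min=float(x.min()),
        max=float(x.max()),
    )


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U with tie-corrected normal approximation.

    The statistic is U of the first sample: the number of (a_i, b_j) pairs
    with a_i > b_j plus half the ties.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return TestResult(statistic=float(res.statistic), df=None, p_value=float(res.pvalue))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal–Wallis H; p from chi-square with k−1 df."""
    arrays = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    h, p = sps.kruskal(*arrays)
    return TestResult(statistic=float(h), df=len(arrays) - 1, p_value=float(p))


def dunn_bonferroni(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks, Bonferroni-adjusted.

    z_ij = (R̄_i − R̄_j) / SE with the pooled, tie-corrected standard error
    SE = sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)), T = Σ(t³−t)/(12(N−1));
    two-sided normal p multiplied by the number of pairs, capped at 1.
    Returns one row per unordered pair (group1, group2, z, p, p_adjusted);
    z is antisymmetric under pair order, p symmetric.
    """
    arrays = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(float(ranks[start : start + a.size].mean()))
        sizes.append(a.size)
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "z": float(z),
                "p": float(p),
                "p_adjusted": float(min(1.0, p * n_pairs)),
            }
        )
    return pd.DataFrame(rows)


def stats_report(table: pd.DataFrame, features: Sequence[str] = FEATURE_NAMES) -> dict:
    """Full statistical summary of a feature table with a ``stage`` column.

    Per feature: one DescriptiveStats block per stage, the Kruskal–Wallis
    result, and the Dunn–Bonferroni pairwise table.  JSON-serializable.
    """
    stages = [s for s in ("healthy", "mild", "severe") if s in set(table["stage"])]
    report: dict = {"stages": stages, "features": {}}
    for feat in features:
        groups = [table.loc[table["stage"] == s, feat].to_numpy() for s in stages]
        block = {
            "descriptive": {s: asdict(descriptive(g)) for s, g in zip(stages, groups)},
        }
        if len(groups) >= 2:
            kw = kruskal_wallis(groups)
            block["kruskal_wallis"] = asdict(kw)
            block["dunn_bonferroni"] = dunn_bonferroni(groups, labels=stages).to_dict(
                orient="records"
            )
        report["features"][feat] = block
    return report
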