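"""Cohort-level statistical testing.

The testing conventions: paired two-group data use the two-sided Wilcoxon
signed-rank test, unpaired two-group data the two-sided rank-sum
(Mann-Whitney) test; more than two groups use the Friedman test (paired)
or Kruskal-Wallis (unpaired), followed by uncorrected Dunn's post-hoc
tests.  Contingency tables use Pearson's chi-square without continuity
correction, and correlations use Pearson or Spearman coefficients with
complete-case rows.  All p-values are two-sided.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import StatsError


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: dict = field(default_factory=dict)
    groups: tuple = ()


def chi2_2x2(table, continuity: bool = False) -> TestResult:
    """Pearson chi-square on a 2×2 contingency table (1 df, two-sided).

    No continuity correction by default.  Both margins must be positive.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise StatsError("table must be 2x2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise StatsError("table must hold nonnegative integer counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise StatsError("zero margin in contingency table")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=continuity)
    return TestResult(test="chi2", statistic=float(stat), p_value=float(p),
                      n={"total": int(arr.sum())})


def rank_tests(groups, design: str = "unpaired") -> TestResult:
    """Dispatch the appropriate rank test for ``groups`` (list of arrays).

    Two groups: signed-rank (paired) or rank-sum (unpaired).  More than two:
    Friedman (paired) or Kruskal-Wallis (unpaired).  Paired designs require
    complete blocks (all groups the same length).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    ns = {f"group_{i}": len(g) for i, g in enumerate(groups)}
    if design == "paired":
        lengths = {len(g) for g in groups}
        if len(lengths) != 1:
            raise StatsError(
                f"paired design requires complete blocks; group sizes {sorted(ns.values())}")
        if len(groups) == 2:
            res = stats.wilcoxon(groups[0], groups[1], alternative="two-sided")
            name = "signed_rank"
        else:
            res = stats.friedmanchisquare(*groups)
            name = "friedman"
    elif design == "unpaired":
        if len(groups) == 2:
            res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            name = "rank_sum"
        else:
            res = stats.kruskal(*groups)
            name = "kruskal_wallis"
    else:
        raise StatsError("design must be 'paired' or 'unpaired'")
    return TestResult(test=name, statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=ns)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def dunns_uncorrected(groups, context: str = "kruskal") -> list[TestResult]:
    """Pairwise uncorrected Dunn's tests after an omnibus rank test.

    ``context='kruskal'``: z from pooled mean ranks with tie-corrected
    variance, SE = sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) where
    T = Σ(t³−t) / (12(N−1)).  ``context='friedman'``: z from within-block
    rank sums, SE = sqrt(n·k(k+1)/6).  Two-sided normal p-values, no
    multiplicity adjustment.  Empty groups are excluded with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    keep = [i for i, g in enumerate(groups) if len(g) > 0]
    if len(keep) < len(groups):
        import logging
        logging.getLogger("timetopo.stats").warning(
            "excluding %d empty groups from Dunn's tests", len(groups) - len(keep))
    groups = [groups[i] for i in keep]
    if len(groups) < 3:
        raise StatsError("Dunn's post-hoc needs at least three groups")
    results = []
    if context == "kruskal":
        pooled = np.concatenate(groups)
        N = len(pooled)
        ranks = _midranks(pooled)
        mean_ranks, ns = [], []
        start = 0
        for g in groups:
            mean_ranks.append(ranks[start:start + len(g)].mean())
            ns.append(len(g))
            start += len(g)
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
        base_var = N * (N + 1) / 12.0 - tie_term
        for i, j in combinations(range(len(groups)), 2):
            se = np.sqrt(base_var * (1.0 / ns[i] + 1.0 / ns[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            results.append(TestResult(test="dunn_kruskal", statistic=float(z),
                                      p_value=float(p),
                                      n={"group_i": ns[i], "group_j": ns[j]},
                                      groups=(keep[i], keep[j])))
    elif context == "friedman":
        k = len(groups)
        lengths = {len(g) for g in groups}
        if len(lengths) != 1:
            raise StatsError("Friedman context requires complete blocks")
        n = lengths.pop()
        block_matrix = np.column_stack(groups)  # n blocks × k treatments
        within = np.apply_along_axis(_midranks, 1, block_matrix)
        rank_sums = within.sum(axis=0)
        se = np.sqrt(n * k * (k + 1) / 6.0)
        for i, j in combinations(range(k), 2):
            z = (rank_sums[i] - rank_sums[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            results.append(TestResult(test="dunn_friedman", statistic=float(z),
                                      p_value=float(p), n={"blocks": n},
                                      groups=(keep[i], keep[j])))
    else:
        raise StatsError("context must be 'kruskal' or 'friedman'")
    return results


def correlation_matrix(table: pd.DataFrame, method: str = "pearson"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation matrix over the columns of ``table`` with pairwise p-values.

    Rows with any missing value are excluded first (complete cases); fewer
    than four complete cases is refused.  Returns (correlations, p-values);
    the correlation matrix is symmetric with unit diagonal, the p-value
    diagonal is NaN.
    """
    complete = table.dropna(axis=0)
    if len(complete) < 4:
        raise StatsError(f"only {len(complete)} complete cases; need at least 4")
    cols = list(complete.columns)
    corr = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise StatsError("method must be 'pearson' or 'spearman'")
    for a, b in combinations(cols, 2):
        r, p = fn(complete[a].to_numpy(dtype=float), complete[b].to_numpy(dtype=float))
        corr.loc[a, b] = corr.loc[b, a] = float(r)
        pval.loc[a, b] = pval.loc[b, a] = float(p)
    return corr, pval
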