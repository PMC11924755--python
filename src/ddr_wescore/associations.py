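"""Cluster-association statistics.

Two families of tests tie DDR cluster assignments to sample annotations:

* chi-square independence tests on label x label contingency tables, with
  an asymptotic p-value and a Monte-Carlo p-value from tables sampled
  uniformly with both margins fixed (Patefield's algorithm, mirroring R's
  ``chisq.test(..., simulate.p.value=TRUE)``); Pearson residuals
  (O - E)/sqrt(E) localize which cells drive the association.
* two-sided Wilcoxon tests (rank-sum unpaired, signed-rank paired) for
  continuous scores compared across clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterSolution

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "GroupComparisonResult",
    "contingency",
    "chisq_test",
    "wilcoxon",
    "score_by_cluster",
]

ALPHA = 0.05  # conventional significance threshold reported alongside p-values


@dataclass
class ContingencyTable:
    """Counts of samples cross-classified by two categorical labelings."""

    counts: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(int)

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_asymptotic: float
    p_simulated: float
    n_sim: int
    pearson_residuals: pd.DataFrame
    expected: pd.DataFrame
    seed: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_asymptotic": self.p_asymptotic,
            "p_simulated": self.p_simulated,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "pearson_residuals": self.pearson_residuals.to_dict(),
            "expected": self.expected.to_dict(),
        }


@dataclass
class GroupComparisonResult:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    paired: bool = False
    alternative: str = "two-sided"
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.p_value < ALPHA


def contingency(
    labels_a: Mapping[str, str] | pd.Series,
    labels_b: Mapping[str, str] | pd.Series,
) -> ContingencyTable:
    """Cross-tabulate two sample labelings over their shared sample set.

    Samples missing either label are dropped; the drop count is recorded.
    """
    a = pd.Series(dict(labels_a)) if not isinstance(labels_a, pd.Series) else labels_a
    b = pd.Series(dict(labels_b)) if not isinstance(labels_b, pd.Series) else labels_b
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between the two labelings")
    dropped = len(a.index.union(b.index)) - len(shared)
    tab = pd.crosstab(a.loc[shared], b.loc[shared])
    tab.index.name = getattr(a, "name", None) or "rows"
    tab.columns.name = getattr(b, "name", None) or "cols"
    return ContingencyTable(counts=tab, n_dropped=dropped)


def _chi2_stats(tables: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Pearson chi-square statistic for a stack of tables against fixed E."""
    return ((tables - expected) ** 2 / expected).sum(axis=(-2, -1))


def chisq_test(
    table: ContingencyTable, n_sim: int = 2000, seed: int = 0
) -> ChiSquareResult:
    """Pearson chi-square with asymptotic and Monte-Carlo p-values.

    The simulated p draws ``n_sim`` tables uniformly conditional on both
    margins (Patefield sampling) and applies the add-one estimator
    p = (1 + #{chi2_sim >= chi2_obs}) / (n_sim + 1), which never returns 0.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    obs = table.counts.to_numpy(dtype=float)
    rows = table.row_margins.to_numpy()
    cols = table.col_margins.to_numpy()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi-square requires strictly positive row and column margins")
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("chi-square requires at least a 2x2 table")
    stat, p_asym, df, expected = stats.chi2_contingency(obs, correction=False)
    residuals = (obs - expected) / np.sqrt(expected)

    rng = np.random.default_rng(seed)
    dist = stats.random_table(rows, cols)
    sims = dist.rvs(n_sim, method="patefield", random_state=rng)
    sim_stats = _chi2_stats(sims, expected)
    exceed = int(np.sum(sim_stats >= float(stat) - 1e-12))
    p_sim = (1 + exceed) / (n_sim + 1)

    idx, colx = table.counts.index, table.counts.columns
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_asymptotic=float(p_asym),
        p_simulated=float(p_sim),
        n_sim=n_sim,
        pearson_residuals=pd.DataFrame(residuals, index=idx, columns=colx),
        expected=pd.DataFrame(expected, index=idx, columns=colx),
        seed=seed,
    )


def _pair_test(
    x: np.ndarray, y: np.ndarray, paired: bool
) -> tuple[float, float]:
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length matched vectors")
        d = x - y
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p=1", stacklevel=3)
            return 0.0, 1.0
        res = stats.wilcoxon(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    # exact rank-sum null when small and tie-free, else normal approx with
    # average ranks and tie-corrected variance (scipy's asymptotic path)
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) == 1:  # all values identical: no evidence either way
        return len(x) * len(y) / 2.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon(
    groups: Mapping[str, np.ndarray], paired: bool = False
) -> list[GroupComparisonResult]:
    """Two-sided pairwise Wilcoxon tests between named groups.

    Unpaired pairs use the rank-sum (Mann-Whitney) test; ``paired=True``
    requires exactly two matched equal-length vectors and uses the
    signed-rank test.
    """
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, v in clean.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has n < 2")
    if paired and len(clean) != 2:
        raise ValueError("paired mode compares exactly two groups")
    out = []
    for a, b in combinations(clean, 2):
        stat, p = _pair_test(clean[a], clean[b], paired)
        out.append(
            GroupComparisonResult(group_a=a, group_b=b, statistic=stat,
                                  p_value=p, paired=paired)
        )
    return out


def score_by_cluster(
    scores: pd.Series, sol: ClusterSolution
) -> tuple[list[GroupComparisonResult], pd.DataFrame]:
    """Compare a per-sample score across cluster labels.

    Returns pairwise Wilcoxon results plus a per-cluster summary (n,
    median, Q1, Q3).  Clusters with fewer than 2 scored samples are
    excluded with a warning.
    """
    labels = sol.label_series
    shared = scores.index.intersection(labels.index)
    groups: dict[str, np.ndarray] = {}
    rows = []
    for idx in range(sol.k):
        name = sol.labels[idx]
        members = labels.index[labels == name].intersection(shared)
        vals = scores.loc[members].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"cluster {name!r} has n<2 scored samples; excluded",
                          stacklevel=2)
            continue
        groups[name] = vals
        rows.append({
            "label": name,
            "n": len(vals),
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
        })
    if len(groups) < 2:
        raise ValueError("scores cover fewer than 2 clusters")
    return wilcoxon(groups), pd.DataFrame(rows)
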