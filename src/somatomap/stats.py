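"""Group-level and single-case statistics.

Implements the single-case t-test against a control sample, percentile
bootstrap of group means, Benjamini-Hochberg FDR, Spearman correlations of
typicality with clinical covariates, and rank-based group comparisons with a
seeded permutation substitute for the factorial interaction test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats


@dataclass(frozen=True)
class SingleCaseResult:
    case_value: float
    control_mean: float
    control_sd: float
    n_controls: int
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class BootstrapDistribution:
    means: np.ndarray
    ci_low: float
    ci_high: float
    ci_level: float
    group: str
    seed: int

    def contains(self, x: float) -> bool:
        return self.ci_low <= x <= self.ci_high


@dataclass(frozen=True)
class CorrelationReport:
    covariate: str
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p: float
    groups: Tuple[str, ...]
    n: Tuple[int, ...]


def crawford_howell(x: float, controls: Sequence[float]) -> SingleCaseResult:
    """Single-case t-test of ``x`` against a control sample.

    t = (x - mean) / (sd * sqrt((n + 1) / n)), df = n - 1, two-sided p.
    """
    c = np.asarray(controls, dtype=float)
    n = c.size
    if n < 2:
        raise ValueError("need at least 2 control values")
    sd = c.std(ddof=1)
    if sd == 0:
        raise ValueError("control sample has zero variance")
    t = (x - c.mean()) / (sd * np.sqrt((n + 1) / n))
    p = 2.0 * _stats.t.sf(abs(t), df=n - 1)
    return SingleCaseResult(
        case_value=float(x),
        control_mean=float(c.mean()),
        control_sd=float(sd),
        n_controls=n,
        t=float(t),
        df=n - 1,
        p=float(p),
    )


def bootstrap_mean(
    sample: Sequence[float],
    n_reps: int = 10_000,
    ci_level: float = 0.95,
    seed: int = 0,
    group: str = "",
) -> BootstrapDistribution:
    """Percentile bootstrap of the sample mean, with replacement, seeded."""
    s = np.asarray(sample, dtype=float)
    if s.size == 0:
        raise ValueError("empty sample")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, s.size, size=(n_reps, s.size))
    means = s[idx].mean(axis=1)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return BootstrapDistribution(
        means=means, ci_low=float(lo), ci_high=float(hi),
        ci_level=ci_level, group=group, seed=seed,
    )


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (reject flags, adjusted p-values).  Adjusted p-values are the
    usual monotone step-up values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    # step-up rejection: largest k with p_(k) <= k*q/m, reject all smaller ranks
    thresh = np.arange(1, m + 1) * q / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        reject[order[: k + 1]] = True
    return reject, adj


def correlate_typicality(
    scores: Mapping[str, float], covariates: pd.DataFrame
) -> List[CorrelationReport]:
    """Spearman rho of (Fisher-z) typicality against each covariate column.

    ``covariates`` is indexed by subject id.  Uncorrected two-sided p-values
    by design (the correlational analysis is exploratory).  Constant
    covariates yield rho = nan.
    """
    common = [s for s in covariates.index if s in scores]
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    y = np.array([scores[s] for s in common], dtype=float)
    out: List[CorrelationReport] = []
    for col in covariates.columns:
        x = covariates.loc[common, col].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        if keep.sum() < 3 or np.all(x[keep] == x[keep][0]):
            out.append(CorrelationReport(col, float("nan"), float("nan"), int(keep.sum())))
            continue
        rho, p = _stats.spearmanr(x[keep], y[keep])
        out.append(CorrelationReport(col, float(rho), float(p), int(keep.sum())))
    return out


def group_compare(
    values_by_group: Mapping[str, Sequence[float]], paired: bool = False
) -> GroupComparison:
    """Rank-based comparison: Wilcoxon (paired pair), Mann-Whitney U (two
    independent groups), or Kruskal-Wallis H (three or more groups)."""
    names = tuple(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    ns = tuple(a.size for a in arrays)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if len(arrays) == 2 and paired:
        stat, p = _stats.wilcoxon(arrays[0], arrays[1])
        return GroupComparison("wilcoxon", float(stat), float(p), names, ns)
    if len(arrays) == 2:
        stat, p = _stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return GroupComparison("mannwhitneyu", float(stat), float(p), names, ns)
    stat, p = _stats.kruskal(*arrays)
    return GroupComparison("kruskal", float(stat), float(p), names, ns)


def permutation_interaction(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    category: str = "category",
    subject: str = "subject",
    n_perms: int = 10_000,
    seed: int = 0,
) -> GroupComparison:
    """Seeded permutation test for a group x category interaction.

    Subjects' group labels are permuted; the statistic is the sum of squared
    interaction cell effects of the group x category mean table.  Substitutes
    for a robust mixed ANOVA.
    """
    df = table[[subject, group, category, value]].copy()
    subs = df[subject].unique()
    sub_group = df.drop_duplicates(subject).set_index(subject)[group]

    def stat_of(labels: pd.Series) -> float:
        d = df.assign(_g=df[subject].map(labels))
        cell = d.groupby(["_g", category], observed=True)[value].mean()
        piv = cell.unstack()
        resid = piv.sub(piv.mean(axis=1), axis=0).sub(piv.mean(axis=0), axis=1)
        resid += piv.to_numpy().mean()
        return float((resid.to_numpy() ** 2).sum())

    observed = stat_of(sub_group)
    rng = np.random.default_rng(seed)
    labels = sub_group.loc[subs].to_numpy()
    hits = 0
    for _ in range(n_perms):
        perm = pd.Series(rng.permutation(labels), index=subs)
        if stat_of(perm) >= observed:
            hits += 1
    p = (hits + 1) / (n_perms + 1)
    groups = tuple(sorted(sub_group.unique()))
    ns = tuple(int((sub_group == g).sum()) for g in groups)
    return GroupComparison("permutation_interaction", observed, float(p), groups, ns)
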