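"""Downstream validation statistics for candidate hub genes.

Median-split Kaplan-Meier survival with a two-group log-rank test,
ROC/AUC for tumor-vs-normal discrimination, Welch two-group t-tests,
one-way ANOVA across multi-level factors, and inter-gene correlation.

Kaplan-Meier estimation goes through lifelines; the log-rank test is
computed directly from the risk table so the per-group observed and
expected event counts are part of the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from ._stats import corr_with_p
from .datamodel import ExpressionMatrix, SurvivalTable

__all__ = [
    "KMCurve",
    "LogRankResult",
    "ROCResult",
    "median_split",
    "kaplan_meier",
    "logrank_test",
    "roc_auc",
    "two_group_ttest",
    "oneway_anova",
    "gene_pair_correlation",
]


@dataclass
class KMCurve:
    group: str
    times: np.ndarray  # distinct observed times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # product-limit S(t) at each time


@dataclass
class LogRankResult:
    statistic: float  # chi-square, 1 df for two groups
    p_value: float
    observed: dict  # group -> observed events
    expected: dict  # group -> expected events under H0


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray  # 1 - specificity at every threshold, starts 0 ends 1
    tpr: np.ndarray  # sensitivity
    thresholds: np.ndarray


def median_split(values: pd.Series) -> pd.Series:
    """Label samples "high" (value > median) or "low" (ties go to low)."""
    if len(values) < 2:
        raise ValueError("need at least 2 samples for a median split")
    med = float(np.median(values.to_numpy(dtype=float)))
    return pd.Series(
        np.where(values.to_numpy(dtype=float) > med, "high", "low"),
        index=values.index,
        name="group",
    )


def kaplan_meier(surv: SurvivalTable, groups: pd.Series | None = None) -> dict:
    """Product-limit survival curve per group (one "all" curve if None)."""
    if groups is None:
        groups = pd.Series("all", index=surv.data.index)
    groups = groups.loc[surv.data.index]
    curves = {}
    for g in sorted(groups.unique()):
        mask = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask])
        times = np.unique(surv.time[mask])
        et = kmf.event_table.loc[times]
        curves[g] = KMCurve(
            group=str(g),
            times=times,
            at_risk=et["at_risk"].to_numpy(dtype=int),
            events=et["observed"].to_numpy(dtype=int),
            survival=kmf.survival_function_at_times(times).to_numpy(dtype=float),
        )
    return curves


def logrank_test(surv: SurvivalTable, groups: pd.Series) -> LogRankResult:
    """Two-group log-rank test from the pooled risk table.

    At each distinct event time the expected events per group come from
    the hypergeometric mean d * n_g / n, with variance
    d (n1/n)(n2/n)(n-d)/(n-1); the statistic is (O1-E1)^2 / sum(V) on one
    degree of freedom.
    """
    groups = groups.loc[surv.data.index]
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError(f"log-rank test needs exactly 2 non-empty groups, got {names}")
    time, event = surv.time, surv.event
    g1 = (groups == names[0]).to_numpy()
    event_times = np.unique(time[event == 1])
    o1 = e1 = v = 0.0
    obs = {names[0]: float(event[g1].sum()), names[1]: float(event[~g1].sum())}
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
    if v == 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(statistic, df=1))
    exp = {names[0]: float(e1), names[1]: float(obs[names[0]] + obs[names[1]] - e1)}
    return LogRankResult(statistic=float(statistic), p_value=p, observed=obs, expected=exp)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and AUC (midrank/Mann-Whitney estimate under ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"ROC needs exactly 2 classes, got {classes}")
    y = (labels == classes.max()).astype(int) if labels.dtype.kind in "ifb" else (labels == classes[1]).astype(int)
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thr = roc_curve(y, scores)
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr)


def two_group_ttest(values: np.ndarray, labels: np.ndarray, equal_var: bool = False):
    """Welch two-sample t-test (pooled variance behind ``equal_var``).

    Returns ``(t, df, two-sided p)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = np.unique(labels)
    if len(names) != 2:
        raise ValueError(f"t-test needs exactly 2 groups, got {names}")
    a, b = values[labels == names[0]], values[labels == names[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def oneway_anova(values: np.ndarray, factor: np.ndarray):
    """Fixed-effects one-way ANOVA. Returns ``(F, (df1, df2), p)``.

    With zero between- and within-group variance the decomposition is
    degenerate; F is defined as 0 with a warning.
    """
    values = np.asarray(values, dtype=float)
    factor = np.asarray(factor)
    levels = np.unique(factor)
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least 2 factor levels")
    groups = [values[factor == lev] for lev in levels]
    small = [str(lev) for lev, g in zip(levels, groups) if len(g) < 2]
    if small:
        raise ValueError(f"factor levels with fewer than 2 observations: {small}")
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = len(levels) - 1, len(values) - len(levels)
    if ssw == 0:
        if ssb == 0:
            warnings.warn("all values identical; ANOVA degenerate, F defined as 0", stacklevel=2)
            return 0.0, (df1, df2), 1.0
        return float("inf"), (df1, df2), 0.0
    F = (ssb / df1) / (ssw / df2)
    return float(F), (df1, df2), float(stats.f.sf(F, df1, df2))


def gene_pair_correlation(expr: ExpressionMatrix, genes: list):
    """Pairwise Pearson r and p over samples for the listed genes.

    Uses the same correlation kernel as the adjacency step, so the two
    agree exactly.
    """
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise ValueError(f"unknown genes: {missing}")
    X = expr.data.loc[genes].to_numpy(dtype=float).T
    if (X.std(axis=0) == 0).any():
        raise ValueError("zero-variance gene in correlation request")
    r, p = corr_with_p(X)
    return (
        pd.DataFrame(r, index=genes, columns=genes),
        pd.DataFrame(p, index=genes, columns=genes),
    )
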