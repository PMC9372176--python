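"""Serology (ELISA titer) statistics.

Nonparametric group comparisons (Mann-Whitney for two groups,
Kruskal-Wallis with Dunn's pairwise post-hoc for more), empirical ROC
analysis with the Youden cutoff and positive likelihood ratio, and the 2x2
odds ratio linking a titer threshold to remission of proteinuria.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _group_summary(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    rows = []
    for g, sub in table.groupby(group_col, sort=False):
        t = sub["titer"].to_numpy()
        q1, med, q3 = np.percentile(t, [25, 50, 75])
        rows.append((g, len(t), med, q1, q3))
    return pd.DataFrame(rows, columns=["group", "n", "median", "q1", "q3"])


def dunn_posthoc(
    samples: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's rank-sum pairwise test after a Kruskal-Wallis analysis.

    Mid-ranks over the pooled data with the usual tie correction; two-sided
    normal p-values, Bonferroni-adjusted across the pairs by default.
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    ranks = stats.rankdata(pooled)
    n = pooled.size
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (n - 1))
    mean_rank, sizes = {}, {}
    pos = 0
    for g in names:
        k = samples[g].size
        mean_rank[g] = ranks[pos : pos + k].mean()
        sizes[g] = k
        pos += k
    rows = []
    pairs = list(itertools.combinations(names, 2))
    for a, b in pairs:
        se = math.sqrt(
            (n * (n + 1) / 12.0 - tie) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, z, p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(pairs), 1.0)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def compare_groups(table: pd.DataFrame, group_col: str = "group") -> dict:
    """Compare titers across groups.

    Two groups: Mann-Whitney U (two-sided).  More: Kruskal-Wallis followed
    by Dunn's pairwise test with Bonferroni adjustment.  Medians and IQR
    are reported per group.
    """
    groups = {g: sub["titer"].to_numpy() for g, sub in table.groupby(group_col, sort=False)}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    summary = _group_summary(table, group_col)
    if len(groups) == 2:
        (a, va), (b, vb) = groups.items()
        stat, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        return {
            "test": "mann-whitney",
            "statistic": float(stat),
            "p": float(p),
            "summary": summary,
        }
    stat, p = stats.kruskal(*groups.values())
    return {
        "test": "kruskal-wallis",
        "statistic": float(stat),
        "p": float(p),
        "posthoc": dunn_posthoc(groups),
        "summary": summary,
    }


@dataclass
class RocSummary:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    lr_positive: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_analysis(
    table: pd.DataFrame, positive_group: str, group_col: str = "group"
) -> RocSummary:
    """Empirical ROC of titer as a classifier for ``positive_group``.

    AUC by the trapezoid rule over all observed cutoffs (equal to the
    Mann-Whitney U statistic divided by n1*n2); the reported cutoff
    maximises Youden's J = sensitivity + specificity - 1, with ties broken
    toward the lowest cutoff.  LR+ = sens / (1 - spec) at the cutoff
    (infinite under perfect specificity).
    """
    y = (table[group_col] == positive_group).to_numpy()
    scores = table["titer"].to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.unique(scores)[::-1]  # descending; rule: positive if titer >= t
    tpr = np.array([(scores[y] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[~y] >= t).mean() for t in thresholds])
    fpr_full = np.r_[0.0, fpr, 1.0]
    tpr_full = np.r_[0.0, tpr, 1.0]
    auc = float(np.trapezoid(tpr_full, fpr_full))
    j = tpr - fpr
    best_j = j.max()
    # ties toward the lowest cutoff: thresholds descending, take last argmax
    best = np.flatnonzero(j == best_j)[-1]
    sens, spec = float(tpr[best]), float(1.0 - fpr[best])
    lr = sens / (1.0 - spec) if spec < 1.0 else math.inf
    return RocSummary(
        auc=auc,
        cutoff=float(thresholds[best]),
        sensitivity=sens,
        specificity=spec,
        youden_j=float(best_j),
        lr_positive=lr,
        fpr=fpr_full,
        tpr=tpr_full,
        thresholds=thresholds,
    )


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_fisher: float
    table: np.ndarray
    continuity_corrected: bool


def odds_ratio_2x2(table: np.ndarray) -> OddsRatioResult:
    """Odds ratio of a 2x2 contingency table ``[[a, b], [c, d]]``.

    OR = ad/bc with a Woolf (log-normal) 95% CI
    ``exp(ln OR +- 1.96 sqrt(1/a + 1/b + 1/c + 1/d))`` and a two-sided
    Fisher exact p.  If any cell is zero, the Haldane-Anscombe 0.5
    correction is applied to OR and CI (flagged); the Fisher p uses the raw
    counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("every margin of the 2x2 table must be positive")
    corrected = bool((t == 0).any())
    w = t + 0.5 if corrected else t
    a, b, c, d = w.ravel()
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se)
    _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return OddsRatioResult(
        odds_ratio=float(or_), ci_low=float(lo), ci_high=float(hi),
        p_fisher=float(p), table=np.asarray(table), continuity_corrected=corrected,
    )


def remission_odds_ratio(
    table: pd.DataFrame, titer_cutoff: float, outcome_col: str = "outcome"
) -> OddsRatioResult:
    """Odds of non-remission above versus below a titer cutoff.

    Builds the 2x2 table (titer > cutoff vs <= cutoff) x (no_remission vs
    remission) and delegates to :func:`odds_ratio_2x2`.
    """
    if outcome_col not in table.columns:
        raise ValueError(f"missing outcome column {outcome_col!r}")
    sub = table.dropna(subset=[outcome_col])
    high = sub["titer"] > titer_cutoff
    no_rem = sub[outcome_col] == "no_remission"
    counts = np.array(
        [
            [int((high & no_rem).sum()), int((high & ~no_rem).sum())],
            [int((~high & no_rem).sum()), int((~high & ~no_rem).sum())],
        ]
    )
    return odds_ratio_2x2(counts)
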