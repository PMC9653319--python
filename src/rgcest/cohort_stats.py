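"""Inferential statistics for small unbalanced clinical cohorts.

The group comparisons this package mirrors involve three groups of unequal
size and variance (healthy, glaucoma-suspect and preperimetric-glaucoma
eyes), so the toolkit is the unequal-variance one: one-way ANOVA with eta²
as effect size for the omnibus test, Games-Howell pairwise comparisons
(Welch standard errors + the studentized-range distribution) post hoc, Welch
t-tests for two-group contrasts, Pearson correlations for associations, and
ROC/AUC (Mann-Whitney concordance) for discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "RocResult",
    "one_way_anova",
    "games_howell",
    "pearson_r2",
    "welch_t",
    "roc_auc",
]


def _grouped(values, labels) -> dict:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-d arrays")
    return {lab: values[labels == lab] for lab in dict.fromkeys(labels.tolist())}


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    eta_squared: float
    df_between: int
    df_within: int


def one_way_anova(values, labels) -> AnovaResult:
    """One-way fixed-effects ANOVA with eta² effect size.

    Classical between/within sum-of-squares decomposition;
    ``eta² = SS_between / SS_total`` (proportion of variance explained by
    group membership).  Requires at least two groups with at least two
    values each.
    """
    groups = _grouped(values, labels)
    if len(groups) < 2 or any(len(g) < 2 for g in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_values = np.concatenate(list(groups.values()))
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    ss_total = ss_between + ss_within
    df_b = len(groups) - 1
    df_w = all_values.size - len(groups)
    if ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    eta2 = 0.0 if ss_total == 0 else float(ss_between / ss_total)
    return AnovaResult(float(f), p, eta2, df_b, df_w)


@dataclass(frozen=True)
class PairwiseComparison:
    """One Games-Howell contrast between two groups."""

    group_a: str
    group_b: str
    mean_difference: float  # reported as |mean_a - mean_b|
    signed_difference: float  # mean_a - mean_b
    se: float  # Welch standard error sqrt(s²a/na + s²b/nb)
    df: float  # Welch-Satterthwaite degrees of freedom
    statistic: float  # studentized-range q = |diff|*sqrt(2)/se
    p_value: float


def _welch_se_df(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    return float(np.sqrt(se2)), float(df)


def games_howell(values, labels, group_order: Sequence[str] | None = None):
    """Games-Howell post hoc pairwise comparisons.

    For each pair of groups the standard error and degrees of freedom are the
    Welch ones (no pooled variance, so unequal group variances and sizes are
    respected) and the statistic ``q = |Δmean|·√2 / se`` is referred to the
    studentized-range distribution with ``k`` groups, giving family-aware
    p-values without assuming homoscedasticity.

    Returns a list of :class:`PairwiseComparison`, one per unordered pair in
    ``group_order`` (observed order by default).
    """
    groups = _grouped(values, labels)
    if group_order is not None:
        missing = set(group_order) - set(groups)
        if missing:
            raise ValueError(f"groups not present in data: {sorted(missing)}")
        groups = {g: groups[g] for g in group_order}
    if len(groups) < 2 or any(len(g) < 2 for g in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    out: list[PairwiseComparison] = []
    for ga, gb in combinations(groups, 2):
        a, b = groups[ga], groups[gb]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            raise ValueError(
                f"zero within-group variance in both {ga!r} and {gb!r}; "
                "Games-Howell is undefined"
            )
        se, df = _welch_se_df(a, b)
        diff = float(a.mean() - b.mean())
        q = abs(diff) * np.sqrt(2.0) / se
        p = float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))
        out.append(
            PairwiseComparison(
                group_a=str(ga),
                group_b=str(gb),
                mean_difference=abs(diff),
                signed_difference=diff,
                se=se,
                df=df,
                statistic=float(q),
                p_value=p,
            )
        )
    return out


def pearson_r2(x, y) -> tuple[float, float]:
    """Squared Pearson correlation with its t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r) ** 2, float(p)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test (variances not assumed equal).

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom and a
    two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class RocResult:
    """AUC of a score for separating two classes, with Mann-Whitney p."""

    auc: float
    p_value: float
    direction: str  # e.g. "PPG < healthy": positives score lower/higher
    positive_label: str
    negative_label: str
    n_positive: int
    n_negative: int


def roc_auc(scores, labels, positive_label=None) -> RocResult:
    """ROC area via the Mann-Whitney concordance identity.

    AUC is the fraction of between-class pairs in which the positive class
    scores higher, counting ties half — identically ``U/(n₁n₂)``.  The
    p-value tests AUC = 0.5 with the normal approximation to the Mann-Whitney
    statistic (tie-corrected).  If ``positive_label`` is not given the
    orientation with AUC >= 0.5 is reported and recorded in ``direction``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"exactly two classes required, got {uniq}")
    flip_allowed = positive_label is None
    pos_lab = uniq[0] if positive_label is None else positive_label
    if pos_lab not in uniq:
        raise ValueError(f"positive_label {pos_lab!r} not among {uniq}")
    neg_lab = next(u for u in uniq if u != pos_lab)

    def _auc(pos_lab, neg_lab):
        pos = scores[labels == pos_lab]
        neg = scores[labels == neg_lab]
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
        auc = float(u.statistic) / (pos.size * neg.size)
        p = float(u.pvalue)
        if not np.isfinite(p):  # all observations tied: variance 0
            p = 1.0
        return auc, p, pos.size, neg.size

    auc, p, n_pos, n_neg = _auc(pos_lab, neg_lab)
    if flip_allowed and auc < 0.5:
        pos_lab, neg_lab = neg_lab, pos_lab
        auc, p, n_pos, n_neg = _auc(pos_lab, neg_lab)
    direction = f"{pos_lab} > {neg_lab}"
    return RocResult(
        auc=auc,
        p_value=p,
        direction=direction,
        positive_label=str(pos_lab),
        negative_label=str(neg_lab),
        n_positive=n_pos,
        n_negative=n_neg,
    )
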