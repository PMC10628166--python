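"""Cohort-level statistics: one-way ANOVA across status groups, Student's t
post-hoc pairs with Bonferroni correction, per-shell comparison families, and
Pearson correlation of morphology with clinical covariates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_ORDER = ("H", "T1", "T2", "T3")


def significance_stars(p: float) -> str:
    """Conventional significance stars: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Degenerate case: when the within-group mean square is zero the F ratio is
    reported as ``inf`` with p = 0 if group means differ, and as 0 with p = 1
    if all values are identical.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than two values")
    grand = np.concatenate(arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    ssb = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in arrays)
    if ssw == 0.0:
        return (float("inf"), 0.0) if ssb > 0 else (0.0, 1.0)
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def student_t(a: np.ndarray, b: np.ndarray, welch: bool = False) -> tuple[float, float, bool]:
    """Two-sample t-test; pooled-variance Student form by default.

    Returns ``(t, p, degenerate)`` where ``degenerate`` flags a zero pooled
    variance (t is then 0/±inf by the equal/unequal-means convention).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    pooled_ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if pooled_ss == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, True
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0, True
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), False


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m·p)."""
    return min(1.0, m * p)


@dataclass
class GroupComparisonResult:
    """ANOVA + all-pairs post-hoc for one feature across status groups."""

    feature: str
    f_statistic: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, t, p_raw, p_adj, stars, degenerate


def compare_groups(
    table: pd.DataFrame,
    feature: str,
    group_col: str = "group",
    welch: bool = False,
) -> GroupComparisonResult:
    """One-way ANOVA over all groups plus Bonferroni-corrected pairwise
    Student's t-tests on ``feature``."""
    labels = [g for g in GROUP_ORDER if g in set(table[group_col])]
    if len(labels) < 2:
        labels = sorted(set(table[group_col]))
    values = {g: table.loc[table[group_col] == g, feature].to_numpy(float) for g in labels}
    f, p = anova_oneway([values[g] for g in labels])
    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for ga, gb in pairs:
        t, praw, degen = student_t(values[ga], values[gb], welch=welch)
        padj = bonferroni(praw, len(pairs))
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "t": t,
                "p_raw": praw,
                "p_adj": padj,
                "stars": significance_stars(padj),
                "degenerate": degen,
            }
        )
    return GroupComparisonResult(feature, f, p, pd.DataFrame(rows))


def shell_comparisons(
    shell_table: pd.DataFrame,
    component: str = "overall",
    group_col: str = "group",
    outcome_col: str = "outcome",
    t1_label: str = "T1",
    n_shells: int = 8,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-shell comparison family for one component (overall or nuclear).

    For each shell k: a one-way ANOVA of density across the status groups,
    and a Student's t-test of survivors vs non-survivors within T1.  Each
    family (8 ANOVAs; 8 t-tests) is Bonferroni-corrected over the shells.
    """
    sub = shell_table[shell_table["component"] == component]
    groups_present = set(sub[group_col])
    missing = [g for g in GROUP_ORDER if g not in groups_present]
    if missing:
        raise ValueError(f"missing status groups: {missing}")
    t1 = sub[sub[group_col] == t1_label]
    outcomes = set(t1[outcome_col]) - {"not-applicable"}
    has_outcome = {"survivor", "non-survivor"} <= outcomes
    rows = []
    for k in range(1, n_shells + 1):
        col = f"d{k}"
        grouped = [
            sub.loc[sub[group_col] == g, col].to_numpy(float) for g in GROUP_ORDER
        ]
        f, p_anova = anova_oneway(grouped)
        row = {
            "shell": k,
            "component": component,
            "f_statistic": f,
            "anova_p_raw": p_anova,
            "anova_p_adj": bonferroni(p_anova, n_shells),
        }
        if has_outcome:
            surv = t1.loc[t1[outcome_col] == "survivor", col].to_numpy(float)
            nons = t1.loc[t1[outcome_col] == "non-survivor", col].to_numpy(float)
            t, p_t, degen = student_t(surv, nons, welch=welch)
            row.update(
                t1_outcome_t=t,
                t1_outcome_p_raw=p_t,
                t1_outcome_p_adj=bonferroni(p_t, n_shells),
                t1_outcome_degenerate=degen,
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["anova_stars"] = out["anova_p_adj"].map(significance_stars)
    if has_outcome:
        out["t1_outcome_stars"] = out["t1_outcome_p_adj"].map(significance_stars)
    return out


@dataclass
class CorrelationResult:
    covariate: str
    rho: float
    n_pairs: int
    mode: str


def correlate_features(
    morphology: pd.DataFrame,
    covariates: list[str],
    feature: str = "mean_overall_ri",
    mode: str = "timepoint_means",
    group_col: str = "group",
    subject_col: str = "subject_id",
) -> list[CorrelationResult]:
    """Pearson correlation of a morphology feature with clinical covariates.

    ``timepoint_means`` pairs the per-status-group means of the feature and
    of each covariate (one point per group — a small-n pairing that mirrors
    per-time-point cohort averages); ``per_subject`` pairs per-subject means.
    Requires at least 3 pairs.
    """
    if mode == "timepoint_means":
        agg = morphology.groupby(group_col)[[feature] + covariates].mean()
    elif mode == "per_subject":
        agg = morphology.groupby(subject_col)[[feature] + covariates].mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    results = []
    for cov in covariates:
        sub = agg[[feature, cov]].dropna()
        if len(sub) < 3:
            raise ValueError(
                f"need at least 3 pairs for correlation with {cov}, got {len(sub)}"
            )
        rho = float(sps.pearsonr(sub[feature], sub[cov]).statistic)
        results.append(CorrelationResult(cov, rho, len(sub), mode))
    return results
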