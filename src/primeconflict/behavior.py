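"""Behavioral filtering, PCE, efficiency, group split and study statistics.

The positive compatibility effect (PCE) is the per-subject difference in
mean hit RT between incompatible and compatible prime trials; subjects are
dichotomized at the sample median (ties to the small group).  The mixed
2 (compatibility) x 2 (congruency) x 2 (group) ANOVA is computed exactly via
1-df contrast scores, so every within-subject F equals the square of the
corresponding t statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TestResult", "GroupAssignment", "filter_trials", "exclude_subjects",
           "compute_pce", "efficiency_score", "median_split", "mixed_anova",
           "chi_square_2x2", "pearson_r", "independent_t"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple
    p: float
    effect_size: float | None = None   # partial eta squared where defined
    epsilon: float | None = None       # Greenhouse-Geisser (1.0 for 2-level factors)

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class GroupAssignment:
    groups: pd.Series          # subject -> "small" | "large"
    split_value_ms: float

    @property
    def sizes(self):
        c = self.groups.value_counts()
        return int(c.get("small", 0)), int(c.get("large", 0))


def filter_trials(table: pd.DataFrame, rt_bounds_ms=(100.0, 1000.0)) -> pd.DataFrame:
    """Correct trials with RT in the closed interval [100, 1000] ms."""
    lo, hi = rt_bounds_ms
    mask = table["correct"].astype(bool) & table["rt_ms"].between(lo, hi, inclusive="both")
    return table[mask].reset_index(drop=True)


def exclude_subjects(table: pd.DataFrame, threshold: float = 0.75) -> list:
    """Subjects with mean accuracy <= threshold (computed on all trials)."""
    acc = table.groupby("subject")["correct"].mean()
    return sorted(acc.index[acc <= threshold].tolist())


def compute_pce(filtered: pd.DataFrame) -> pd.Series:
    """Per-subject mean hit RT(incompatible) - mean hit RT(compatible), ms."""
    m = filtered.groupby(["subject", "compatibility"])["rt_ms"].mean().unstack()
    return (m["incompatible"] - m["compatible"]).rename("pce_ms")


def efficiency_score(table: pd.DataFrame, rt_bounds_ms=(100.0, 1000.0)) -> pd.DataFrame:
    """Accuracy (percent) divided by mean hit RT (ms), per subject and cell.

    Accuracy uses all trials of the cell; hit RT only correct, RT-filtered ones.
    A perfect cell at 400 ms mean RT scores 100/400 = 0.25.
    """
    acc = table.groupby(["subject", "compatibility", "congruency"])["correct"].mean()
    hits = filter_trials(table, rt_bounds_ms)
    rt = hits.groupby(["subject", "compatibility", "congruency"])["rt_ms"].mean()
    out = (100.0 * acc / rt).rename("efficiency").reset_index()
    return out


def median_split(pce: pd.Series) -> GroupAssignment:
    """Split at the median PCE; values <= median go to the small group."""
    med = float(np.median(pce.to_numpy()))
    groups = pd.Series(np.where(pce > med, "large", "small"), index=pce.index, name="group")
    if (groups == "small").all():
        warnings.warn("degenerate median split: all subjects in the small group")
    return GroupAssignment(groups, med)


def _contrast_anova(values: np.ndarray, groups: np.ndarray | None, intercept: bool):
    """F-tests on a 1-df contrast score, optionally with a 2-level between factor.

    With groups: unweighted-means (type III) tests of the grand contrast mean
    (within effect) and the group difference (within x group interaction),
    both on the pooled residual with N-2 df.  Without groups: one-sample test,
    F = paired-t**2 with N-1 error df.
    Returns (F_effect, F_interaction_or_None, df_error).
    """
    if groups is None:
        n = values.size
        mean = values.mean()
        se2 = values.var(ddof=1) / n
        if se2 == 0:
            return (0.0 if mean == 0 else np.inf), None, n - 1
        return mean ** 2 / se2, None, n - 1
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("between factor must have exactly 2 levels")
    a, b = values[groups == levels[0]], values[groups == levels[1]]
    n1, n2 = a.size, b.size
    df_err = n1 + n2 - 2
    ss_err = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    grand = 0.5 * (a.mean() + b.mean())          # unweighted grand mean
    diff = a.mean() - b.mean()
    c = 0.25 * (1.0 / n1 + 1.0 / n2)
    if ms_err == 0:
        f_main = 0.0 if grand == 0 else np.inf
        f_int = 0.0 if diff == 0 else np.inf
    else:
        f_main = grand ** 2 / (c * ms_err)
        f_int = (diff / 2.0) ** 2 / (c * ms_err)
    return f_main, f_int, df_err


def _result(F, df_err):
    F = float(F)
    p = float(stats.f.sf(F, 1, df_err)) if np.isfinite(F) else 0.0
    eta = F / (F + df_err) if np.isfinite(F) else 1.0
    return TestResult(F, (1, df_err), p, effect_size=float(eta), epsilon=1.0)


def mixed_anova(measures: pd.DataFrame, dv: str = "value",
                within=("compatibility", "congruency"),
                between: str | None = "group") -> dict:
    """2 x 2 (x 2) mixed ANOVA on per-subject cell means.

    ``measures`` holds one row per subject x within-cell with columns
    ``subject``, the two within factors, ``dv`` and (optionally) the between
    factor.  Subjects with incomplete cells are dropped listwise.  Returns a
    dict effect-name -> :class:`TestResult` covering all main effects and
    interactions of the design.
    """
    w1, w2 = within
    cells = measures.pivot_table(index="subject", columns=[w1, w2], values=dv)
    complete = cells.dropna()
    if len(complete) < len(cells):
        warnings.warn(f"{len(cells) - len(complete)} subjects dropped (incomplete cells)")
    l1 = sorted(measures[w1].unique())
    l2 = sorted(measures[w2].unique())
    if len(l1) != 2 or len(l2) != 2:
        raise ValueError("both within factors must have exactly 2 levels")
    c11, c12 = complete[(l1[0], l2[0])], complete[(l1[0], l2[1])]
    c21, c22 = complete[(l1[1], l2[0])], complete[(l1[1], l2[1])]
    contrasts = {
        w1: ((c21 + c22) - (c11 + c12)) / 2.0,
        w2: ((c12 + c22) - (c11 + c21)) / 2.0,
        f"{w1}:{w2}": (c22 - c21) - (c12 - c11),
    }
    subj_mean = (c11 + c12 + c21 + c22) / 4.0

    groups = None
    if between is not None:
        gmap = measures.drop_duplicates("subject").set_index("subject")[between]
        groups = gmap.reindex(complete.index).to_numpy()

    out = {}
    for name, scores in contrasts.items():
        f_main, f_int, df_err = _contrast_anova(scores.to_numpy(), groups, True)
        out[name] = _result(f_main, df_err)
        if f_int is not None:
            out[f"{name}:{between}"] = _result(f_int, df_err)
    if groups is not None:
        levels = np.unique(groups)
        a = subj_mean.to_numpy()[groups == levels[0]]
        b = subj_mean.to_numpy()[groups == levels[1]]
        n1, n2 = a.size, b.size
        df_err = n1 + n2 - 2
        ss_err = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        ms_err = ss_err / df_err
        num = (a.mean() - b.mean()) ** 2 / (1.0 / n1 + 1.0 / n2)
        F = 0.0 if num == 0 else (np.inf if ms_err == 0 else num / ms_err)
        out[between] = _result(F, df_err)
    return out


def chi_square_2x2(counts) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    res = stats.chi2_contingency(counts, correction=False)
    return TestResult(float(res[0]), (1,), float(res[1]))


def pearson_r(x, y) -> TestResult:
    """Product-moment correlation with the t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), (x.size - 2,), float(p))


def independent_t(x, y, welch: str = "auto") -> TestResult:
    """Two-sample t; Welch correction when variances differ (Levene p < .05)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    use_welch = welch is True or (welch == "auto" and stats.levene(x, y)[1] < 0.05)
    if use_welch:
        res = stats.ttest_ind(x, y, equal_var=False)
        v1, v2 = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (v1 + v2) ** 2 / (v1 ** 2 / (x.size - 1) + v2 ** 2 / (y.size - 1))
    else:
        res = stats.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    return TestResult(float(res.statistic), (float(df),), float(res.pvalue))
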