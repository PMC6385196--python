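"""Descriptive group comparisons and phase-trend tests.

Operationalises the usual "as appropriate" test choices of a clinical
baseline table so they are explicit, logged and reproducible:

* categorical: Pearson chi-square *without* continuity correction when all
  expected cell counts are >= 5, Fisher's exact test otherwise;
* two-group continuous: Student's t when a Shapiro-Wilk check (alpha = 0.05)
  passes in both groups, Mann-Whitney U otherwise;
* paired continuous: paired t vs Wilcoxon signed-rank by the same check on
  the differences;
* within-subject phase trends (early/middle/late): Friedman test by
  default — robust for skewed spectral powers — with repeated-measures
  ANOVA available behind a flag.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

NORMALITY_ALPHA = 0.05


@dataclasses.dataclass(frozen=True)
class StatTest:
    test: str
    statistic: float
    pvalue: float
    note: str = ""


def _is_normal(x: np.ndarray, alpha: float = NORMALITY_ALPHA) -> bool:
    """Shapiro-Wilk normality heuristic; constant samples are non-normal."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def compare_categorical(table) -> StatTest:
    """Compare group proportions from a contingency table of counts.

    Uses the Pearson chi-square (no continuity correction) when every
    expected count is >= 5; Fisher's exact test otherwise (2x2 only — a
    larger sparse table falls back to chi-square with a note).
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or np.any(table != np.floor(table)):
        raise ValueError("contingency table must hold nonnegative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty margin")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if np.all(expected >= 5):
        return StatTest("chi-square", float(chi2), float(p))
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table)
        return StatTest("fisher-exact", float("nan"), float(p), "expected count < 5")
    return StatTest(
        "chi-square", float(chi2), float(p),
        "expected count < 5 but table is not 2x2; chi-square retained",
    )


def compare_continuous(x, y, normality_alpha: float = NORMALITY_ALPHA) -> StatTest:
    """Two-group comparison: Student's t when both groups pass the
    normality check, Mann-Whitney U otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        warnings.warn("both groups constant and equal; p = 1 by convention")
        return StatTest("degenerate", 0.0, 1.0, "zero variance in both groups")
    if _is_normal(x, normality_alpha) and _is_normal(y, normality_alpha):
        t, p = stats.ttest_ind(x, y, equal_var=True)
        return StatTest("t-test", float(t), float(p))
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return StatTest("mann-whitney", float(u), float(p))


def paired_comparison(pre, post, normality_alpha: float = NORMALITY_ALPHA) -> StatTest:
    """Pre/post comparison: paired t when the differences pass the
    normality check, Wilcoxon signed-rank otherwise."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D vectors")
    if pre.size < 2:
        raise ValueError("paired comparison needs at least 2 pairs")
    d = post - pre
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1 by convention")
        return StatTest("degenerate", 0.0, 1.0, "all differences zero")
    if _is_normal(d, normality_alpha):
        t, p = stats.ttest_rel(post, pre)
        return StatTest("paired-t", float(t), float(p))
    w, p = stats.wilcoxon(post, pre)
    return StatTest("wilcoxon", float(w), float(p))


def phase_trend_test(values, method: str = "friedman") -> StatTest:
    """Within-subject trend across the early/middle/late phases.

    ``values`` is an (n_subjects, 3) array or DataFrame of complete
    triples.  ``method`` is ``"friedman"`` (default) or ``"rm_anova"``
    (one-way repeated-measures ANOVA via statsmodels).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("values must be n_subjects x 3 (early, middle, late)")
    if arr.shape[0] < 3:
        raise ValueError("at least 3 subjects are required")
    if np.isnan(arr).any():
        raise ValueError("phase triples must be complete (no NaN)")
    if np.all(np.ptp(arr, axis=1) == 0):
        warnings.warn("no within-subject variation across phases; p = 1")
        return StatTest("degenerate", 0.0, 1.0, "constant within subjects")
    if method == "friedman":
        chi2, p = stats.friedmanchisquare(arr[:, 0], arr[:, 1], arr[:, 2])
        return StatTest("friedman", float(chi2), float(p))
    if method == "rm_anova":
        from statsmodels.stats.anova import AnovaRM

        n = arr.shape[0]
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 3),
                "phase": np.tile(["early", "middle", "late"], n),
                "value": arr.ravel(),
            }
        )
        res = AnovaRM(long, "value", "subject", within=["phase"]).fit()
        row = res.anova_table.iloc[0]
        return StatTest("rm-anova", float(row["F Value"]), float(row["Pr > F"]))
    raise ValueError(f"unknown method {method!r}")


def summarize_groups(
    df: pd.DataFrame,
    group_col: str,
    continuous: tuple[str, ...] = (),
    categorical: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Baseline-table style summary of a two-group cohort.

    Continuous variables show mean ± SD when normal in both groups (and are
    tested by t), median (IQR) otherwise (Mann-Whitney); categorical
    variables show n (%) with the chi-square/Fisher rule.  Returns one row
    per variable with per-group summaries, the test used and its p-value.
    """
    groups = df[group_col].unique()
    if len(groups) != 2:
        raise ValueError("summarize_groups expects exactly two groups")
    g0 = df[df[group_col] == groups[0]]
    g1 = df[df[group_col] == groups[1]]
    rows = []
    for var in continuous:
        x, y = g0[var].dropna().to_numpy(), g1[var].dropna().to_numpy()
        res = compare_continuous(x, y)
        if res.test == "t-test":
            summ = [f"{v.mean():.2f} ± {v.std(ddof=1):.2f}" for v in (x, y)]
        else:
            summ = [
                f"{np.median(v):.2f} ({np.percentile(v, 25):.2f}–{np.percentile(v, 75):.2f})"
                for v in (x, y)
            ]
        rows.append((var, *summ, res.test, res.pvalue))
    for var in categorical:
        counts = np.array(
            [
                [int(g[var].sum()), int(len(g) - g[var].sum())]
                for g in (g0, g1)
            ]
        )
        res = compare_categorical(counts)
        summ = [
            f"{c[0]} ({100.0 * c[0] / c.sum():.1f}%)" for c in counts
        ]
        rows.append((var, *summ, res.test, res.pvalue))
    return pd.DataFrame(
        rows,
        columns=["variable", str(groups[0]), str(groups[1]), "test", "p"],
    )
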