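"""Demographic and clinical statistics of the cohort.

Group comparisons follow the conventions the printed p-values pin down:
Pearson chi-square *without* continuity correction for the 2x2 sex table
(Yates' correction would give ~0.92 instead of the printed 0.71), and the
pooled-variance Student t-test for age/education (Welch would give ~0.36
instead of the printed 0.31 on the education row).  A Pearson correlation
links per-subject cluster means to symptom severity scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "chi_square_2x2",
    "pooled_t_test_from_summary",
    "t_test_from_raw",
    "correlate_with_symptoms",
    "summarize_cohort",
]


@dataclass
class TestResult:
    """One statistical test: statistic, degrees of freedom, two-sided p."""

    statistic: float
    df: float | tuple
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def chi_square_2x2(counts) -> TestResult:
    """Pearson chi-square on a 2x2 contingency table, df = 1, two-sided.

    No continuity correction is applied.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) <= 0).any() or (table.sum(axis=1) <= 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), dof, float(p), "pearson-chi2")


def pooled_t_test_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = True,
) -> TestResult:
    """Two-sample t-test from group summaries.

    Pooled-variance Student t by default (df = n1 + n2 - 2); set
    ``equal_var=False`` for Welch.
    """
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df: float = n1 + n2 - 2
        name = "pooled-t"
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        name = "welch-t"
    return TestResult(float(t), df, float(p), name)


def t_test_from_raw(
    table: pd.DataFrame, column: str, group_col: str = "group", equal_var: bool = True
) -> TestResult:
    """Two-sample t-test on a raw subject-table column.

    Agrees exactly with :func:`pooled_t_test_from_summary` computed from the
    same data's summaries.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(groups)}")
    x = table.loc[table[group_col] == groups[0], column].to_numpy(float)
    y = table.loc[table[group_col] == groups[1], column].to_numpy(float)
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    df = len(x) + len(y) - 2 if equal_var else None
    if df is None:
        v1, v2 = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        df = (v1 + v2) ** 2 / (v1**2 / (len(x) - 1) + v2**2 / (len(y) - 1))
    return TestResult(float(t), df, float(p), "pooled-t" if equal_var else "welch-t")


def correlate_with_symptoms(cluster_values, scores) -> TestResult:
    """Pearson correlation between per-subject cluster means and symptom scores.

    Two-sided p via the t transform with df = n - 2.
    """
    x = np.asarray(cluster_values, float)
    y = np.asarray(scores, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), len(x) - 2, float(p), "pearson-r")


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Demographics summary in the style of a clinical Table 1.

    Per group: n, sex counts, mean +/- SD of age / education / symptom score,
    with the between-group test p-values (chi-square for sex, pooled t
    otherwise) in the final column.
    """
    groups = sorted(table["group"].unique())
    out_rows = []
    ns = {g: int((table["group"] == g).sum()) for g in groups}
    out_rows.append(("n", *[str(ns[g]) for g in groups], ""))
    sex_counts = {
        g: (
            int(((table["group"] == g) & (table["sex"] == 1)).sum()),
            int(((table["group"] == g) & (table["sex"] == 0)).sum()),
        )
        for g in groups
    }
    if len(groups) == 2:
        contingency = [list(sex_counts[g]) for g in groups]
        sex_p = f"{chi_square_2x2(contingency).p_value:.2f}"
    else:
        sex_p = ""
    out_rows.append(
        ("sex (male/female)", *[f"{m}/{f}" for m, f in sex_counts.values()], sex_p)
    )
    for col in ("age", "education", "symptom_score"):
        cells = []
        has = []
        for g in groups:
            vals = table.loc[table["group"] == g, col].dropna()
            if len(vals):
                cells.append(f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}")
                has.append(g)
            else:
                cells.append("")
        if len(groups) == 2 and len(has) == 2:
            p = f"{t_test_from_raw(table.dropna(subset=[col]), col).p_value:.2f}"
        else:
            p = ""
        out_rows.append((col, *cells, p))
    cols = ["characteristic", *[f"group_{g}" for g in groups], "p_value"]
    return pd.DataFrame(out_rows, columns=cols)
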