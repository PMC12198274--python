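"""Descriptive group comparisons for the cohort characteristics table.

Binary traits are compared by the chi-squared test on 2x2 tables with
Yates continuity correction (each observed count moved toward its
expected value by at most 0.5, never past it), continuous measures by
unpaired two-sample t-tests (pooled or Welch), and ordinal sum scores by
the Mann-Whitney U test with the first-sample orientation (W counts
pairs where x exceeds y, ties counted one half) and a tie-corrected
normal approximation for the p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["chi2_2x2", "two_sample_t", "mann_whitney_w", "compare_groups"]


def chi2_2x2(
    table, correction: bool = True
) -> tuple[float, int, float]:
    """Chi-squared test of association on a 2x2 contingency table.

    ``table`` is [[a, b], [c, d]] with rows = groups and columns = trait
    present/absent. With ``correction`` (Yates), each |O - E| is reduced
    by min(0.5, |O - E|) before summing (O - E)^2 / E, so the adjusted
    deviation is never negative. Returns ``(statistic, df=1, p_value)``.
    """
    O = np.asarray(table, dtype=float)
    if O.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {O.shape}")
    if np.any(O < 0):
        raise ValueError("counts must be nonnegative")
    n = O.sum()
    if n < 1:
        raise ValueError("grand total must be >= 1")
    row, col = O.sum(axis=1), O.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin: expected counts undefined")
    E = np.outer(row, col) / n
    dev = np.abs(O - E)
    if correction:
        dev = dev - np.minimum(0.5, dev)
    statistic = float((dev**2 / E).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, 1, p


def two_sample_t(x, y, variant: str = "pooled") -> tuple[float, float, float]:
    """Unpaired two-sample t-test; ``variant`` 'pooled' or 'welch'.

    Returns ``(t, df, p)``; pooled df is n1 + n2 - 2, Welch df by
    Satterthwaite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    if variant == "pooled":
        res = stats.ttest_ind(x, y, equal_var=True)
        df = len(x) + len(y) - 2
    elif variant == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
        df = float(res.df)
    else:
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    return float(res.statistic), float(df), float(res.pvalue)


def mann_whitney_w(x, y) -> tuple[float, float]:
    """Mann-Whitney statistic W counting pairs with x > y (ties as 1/2).

    p-value from the tie-corrected normal approximation. The identity
    W(x, y) + W(y, x) = n1 * n2 holds (exactly, also under ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each sample needs n >= 1")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _median_iqr(v: np.ndarray) -> str:
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return f"{med:g} ({q1:g}-{q3:g})"


def compare_groups(
    df: pd.DataFrame,
    group_col: str,
    group_a: str,
    group_b: str,
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
    ordinal: list[str] | None = None,
    t_variant: str = "pooled",
) -> pd.DataFrame:
    """Characteristics-table comparison of two groups.

    Continuous variables get mean +/- SD and a t-test, binary variables
    counts/percentages and the continuity-corrected chi-squared test,
    ordinal variables median (IQR) and the Mann-Whitney test. Rows with
    missing values are dropped per variable.
    """
    a_mask = df[group_col] == group_a
    b_mask = df[group_col] == group_b
    rows = []
    for var in continuous or []:
        x = df.loc[a_mask, var].dropna().to_numpy()
        y = df.loc[b_mask, var].dropna().to_numpy()
        t, dfree, p = two_sample_t(x, y, variant=t_variant)
        rows.append(
            {
                "variable": var, "type": "continuous",
                "summary_a": f"{x.mean():.1f} ± {x.std(ddof=1):.1f}",
                "summary_b": f"{y.mean():.1f} ± {y.std(ddof=1):.1f}",
                "test": f"t({dfree:g})" + (f" [{t_variant}]" if t_variant != "pooled" else ""),
                "statistic": round(t, 2), "p_value": p,
            }
        )
    for var in binary or []:
        x = df.loc[a_mask, var].dropna().astype(int)
        y = df.loc[b_mask, var].dropna().astype(int)
        table = [[int(x.sum()), int((1 - x).sum())], [int(y.sum()), int((1 - y).sum())]]
        stat, _, p = chi2_2x2(table)
        rows.append(
            {
                "variable": var, "type": "binary",
                "summary_a": f"{x.sum()} ({100 * x.mean():.1f}%)",
                "summary_b": f"{y.sum()} ({100 * y.mean():.1f}%)",
                "test": "chi2(1)", "statistic": round(stat, 2), "p_value": p,
            }
        )
    for var in ordinal or []:
        x = df.loc[a_mask, var].dropna().to_numpy()
        y = df.loc[b_mask, var].dropna().to_numpy()
        w, p = mann_whitney_w(x, y)
        rows.append(
            {
                "variable": var, "type": "ordinal",
                "summary_a": _median_iqr(x), "summary_b": _median_iqr(y),
                "test": "W", "statistic": w, "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["groups"] = (group_a, group_b)
    return out
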