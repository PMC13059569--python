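"""Group-level comparison of per-cell features between conditions.

Per-feature two-sample t-tests between a perturbed and a control group,
category-level significance summaries (fraction of features with p below a
raw screen, default 1e-2, no multiple-testing correction by default), and
the box-plot IQR outlier-trimming rule used only for visualization — group
statistics are always computed on untrimmed data, which is enforced by
construction: the comparison functions take no trimming parameter.

The default test is the independent two-sample equal-variance Student's t
(two-tailed); Welch's correction is available via ``equal_var=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "compare_features",
    "category_significance",
    "iqr_trim",
]

DEFAULT_ALPHA = 1e-2


@dataclass(frozen=True)
class GroupComparison:
    """Result of one feature's two-sample t-test between conditions."""

    feature: str
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    category: str | None = None


def compare_features(table: pd.DataFrame, group_a: str, group_b: str,
                     condition_col: str = "condition",
                     feature_cols: list[str] | None = None,
                     equal_var: bool = True) -> list[GroupComparison]:
    """Per-feature independent two-sample t-tests between two conditions.

    Missing values are dropped per feature; a feature with fewer than two
    non-missing values in either group is skipped with a warning. Two
    identical degenerate groups (zero pooled variance, equal means) give
    t = 0, p = 1; zero pooled variance with different means is reported as
    the 0-limit (t = +-inf, p = 0) with a warning.
    """
    non_feature = {condition_col, "cell_id", "channel"}
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in non_feature
                        and pd.api.types.is_numeric_dtype(table[c])]
    a_rows = table[table[condition_col] == group_a]
    b_rows = table[table[condition_col] == group_b]
    out: list[GroupComparison] = []
    for feat in feature_cols:
        a = a_rows[feat].dropna().to_numpy(dtype=float)
        b = b_rows[feat].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"feature {feat!r}: fewer than 2 values in a group; "
                          "skipped", stacklevel=2)
            continue
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                t, p = 0.0, 1.0
            else:
                warnings.warn(f"feature {feat!r}: zero within-group variance "
                              "with unequal means; p reported as 0-limit",
                              stacklevel=2)
                t = np.inf if np.mean(a) > np.mean(b) else -np.inf
                p = 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        out.append(GroupComparison(
            feature=feat, t_statistic=float(t), p_value=float(p),
            mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
            n_a=len(a), n_b=len(b)))
    return out


def category_significance(comparisons: list[GroupComparison],
                          categories: dict[str, str],
                          alpha: float = DEFAULT_ALPHA) -> dict[str, float]:
    """Per-category fraction of features significant at the raw p < alpha screen.

    Every compared feature must map to exactly one category; an unmapped
    feature raises. No multiple-testing correction is applied (the screen is
    a raw threshold); apply statsmodels' multipletests upstream if desired.
    """
    counts: dict[str, int] = {}
    hits: dict[str, int] = {}
    for comp in comparisons:
        if comp.feature not in categories:
            raise KeyError(f"feature {comp.feature!r} has no category mapping")
        cat = categories[comp.feature]
        counts[cat] = counts.get(cat, 0) + 1
        hits[cat] = hits.get(cat, 0) + (comp.p_value < alpha)
    return {cat: hits[cat] / counts[cat] for cat in counts}


def iqr_trim(values) -> np.ndarray:
    """Single-pass box-plot outlier trim for visualization only.

    Removes values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR]; quartiles by
    linear interpolation (numpy default). Fences are computed once on the
    input — the function is deliberately single-pass and is never applied
    before group statistics. Fewer than 4 values are returned unchanged
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values: IQR trim skipped", stacklevel=2)
        return values.copy()
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return values[(values >= lo) & (values <= hi)]
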