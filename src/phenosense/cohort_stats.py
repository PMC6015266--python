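"""Group-difference and pre/post statistics.

Per-feature two-group comparisons use a normality screen (Shapiro-Wilk on
each group) to choose between the two-sample t-test and the Mann-Whitney
U test, with Benjamini-Hochberg false-discovery-rate adjustment across
all tested features.  Paired pre/post comparisons and Pearson correlation
round out the questionnaire-level checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupTestResult:
    feature: str
    test: str  # "t" or "mann_whitney", or "skipped"
    statistic: float
    p_value: float
    q_value: float
    mean_high: float
    mean_low: float
    median_high: float
    median_low: float
    skipped: bool = False


def _is_normalish(x: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk screen; tiny or constant samples are treated as non-normal."""
    if x.size < 3 or np.ptp(x) == 0:
        return False
    try:
        return stats.shapiro(x).pvalue >= alpha
    except ValueError:
        return False


def group_feature_tests(features: pd.DataFrame, labels,
                        normality_alpha: float = 0.05) -> list[GroupTestResult]:
    """Two-group tests per feature with BH-FDR q-values.

    ``labels`` is a LabelSet or a Series mapping participant id -> {0, 1}
    (1 = high group).  Features constant in both groups are skipped and
    flagged (their p and q are NaN); q-values are computed across the
    tested features only.
    """
    y = labels.series() if hasattr(labels, "series") else pd.Series(labels)
    ids = [i for i in y.index if i in features.index]
    if not ids:
        raise ValueError("no labeled participants found in the feature matrix")
    y = y.loc[ids]
    hi_ids = y.index[y == 1]
    lo_ids = y.index[y == 0]
    if len(hi_ids) == 0 or len(lo_ids) == 0:
        raise ValueError("both groups must be nonempty")

    results: list[GroupTestResult] = []
    pvals, tested_idx = [], []
    for j, col in enumerate(features.columns):
        a = features.loc[hi_ids, col].dropna().to_numpy(dtype=float)
        b = features.loc[lo_ids, col].dropna().to_numpy(dtype=float)
        summary = dict(
            mean_high=float(np.mean(a)) if a.size else np.nan,
            mean_low=float(np.mean(b)) if b.size else np.nan,
            median_high=float(np.median(a)) if a.size else np.nan,
            median_low=float(np.median(b)) if b.size else np.nan,
        )
        if a.size < 2 or b.size < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
            results.append(GroupTestResult(feature=col, test="skipped", statistic=np.nan,
                                           p_value=np.nan, q_value=np.nan, skipped=True,
                                           **summary))
            continue
        if _is_normalish(a, normality_alpha) and _is_normalish(b, normality_alpha):
            stat, p = stats.ttest_ind(a, b, equal_var=False)
            test = "t"
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann_whitney"
        results.append(GroupTestResult(feature=col, test=test, statistic=float(stat),
                                       p_value=float(p), q_value=np.nan, **summary))
        pvals.append(float(p))
        tested_idx.append(len(results) - 1)

    if pvals:
        q = benjamini_hochberg(np.array(pvals))
        for idx, qv in zip(tested_idx, q):
            results[idx].q_value = float(qv)
    return results


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def paired_prepost(pre, post, test: str = "paired_t") -> tuple[float, float]:
    """Paired pre/post comparison; pairs with a missing value are dropped.

    ``test`` is ``paired_t`` or ``wilcoxon``.  An all-zero difference
    vector under Wilcoxon raises a degenerate-result error.
    """
    pre = pd.Series(pre).astype(float)
    post = pd.Series(post).astype(float)
    if pre.shape[0] != post.shape[0]:
        raise ValueError("pre and post vectors must have equal length")
    ok = pre.notna() & post.notna()
    a, b = pre[ok].to_numpy(), post[ok].to_numpy()
    if a.size < 2:
        raise ValueError("need at least 2 complete pairs")
    if test == "paired_t":
        res = stats.ttest_rel(b, a)
    elif test == "wilcoxon":
        if np.all(b - a == 0):
            raise ValueError("degenerate result: all paired differences are zero")
        res = stats.wilcoxon(b, a)
    else:
        raise ValueError(f"unknown test '{test}'")
    return float(res.statistic), float(res.pvalue)


def pearson_corr(x, y) -> float:
    """Complete-case Pearson correlation (requires >= 3 complete pairs)."""
    x = pd.Series(x).astype(float)
    y = pd.Series(y).astype(float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal length")
    ok = x.notna() & y.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    return float(stats.pearsonr(x[ok], y[ok]).statistic)


def results_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    """Tabular view of group test results, one row per feature."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "test": r.test,
                "statistic": r.statistic,
                "p": r.p_value,
                "q": r.q_value,
                "mean_high": r.mean_high,
                "mean_low": r.mean_low,
                "direction": (
                    "higher_in_high" if (r.mean_high or 0) > (r.mean_low or 0) else "lower_in_high"
                ),
            }
            for r in results
        ]
    )
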