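"""Per-feature univariate statistics: Mann-Whitney AUC, q-values, t-tests
with a Levene variance gate, and intraclass correlation for repeatability.

AUC orientation: values are oriented so that AUC > 0.5 means the feature
is higher in the diseased (label 1) group; the label-flip antisymmetry
auc(y) + auc(1 - y) = 1 holds with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

FEATURE_CATEGORIES = (
    "clinical",
    "serum",
    "saliva",
    "condylar_radiomics",
    "fossa_radiomics",
    "joint_space",
)


def mann_whitney_auc(values, labels) -> tuple[float, float]:
    """Mann-Whitney AUC and two-sided p-value for a binary contrast.

    AUC = U / (n1 * n0) with ties counted 1/2, where U is the number of
    (diseased, control) pairs won by the diseased value.  The p-value uses
    the normal approximation with tie correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    x1 = values[labels == 1]
    x0 = values[labels == 0]
    if x1.size == 0 or x0.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = sps.rankdata(values)
    r1 = ranks[labels == 1].sum()
    u1 = r1 - x1.size * (x1.size + 1) / 2.0
    auc = float(u1 / (x1.size * x0.size))
    if np.all(values == values[0]):
        return auc, 1.0
    p = float(
        sps.mannwhitneyu(x1, x0, alternative="two-sided", method="asymptotic").pvalue
    )
    return auc, p


def mann_whitney_auc_matrix(X: np.ndarray, labels) -> np.ndarray:
    """Vectorised Mann-Whitney AUC of every column of a matrix.

    Same statistic as :func:`mann_whitney_auc` (ties 1/2) computed for all
    columns at once via average ranks along axis 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = sps.rankdata(X, axis=0)
    r1 = ranks[labels == 1].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def q_values(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_t_test(values, labels, levene_alpha: float = 0.05) -> dict:
    """Independent-samples t-test with a Levene gate on equal variances.

    Levene's test (center='mean') at ``levene_alpha`` decides between the
    pooled-variance t-test and Welch's t-test; the branch taken is
    reported alongside t and p.  Two constant equal groups return p = 1
    with a ``degenerate`` flag.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    x1 = values[labels == 1]
    x0 = values[labels == 0]
    if x1.size < 2 or x0.size < 2:
        raise ValueError("need at least 2 observations per class")
    if np.var(x1) == 0 and np.var(x0) == 0:
        if x1.mean() == x0.mean():
            return {
                "t": 0.0,
                "p": 1.0,
                "equal_variance_assumed": True,
                "levene_p": 1.0,
                "degenerate": True,
            }
        # Zero variance but different means: infinite separation.
        return {
            "t": float("inf") if x1.mean() > x0.mean() else float("-inf"),
            "p": 0.0,
            "equal_variance_assumed": True,
            "levene_p": 1.0,
            "degenerate": True,
        }
    levene_p = float(sps.levene(x1, x0, center="mean").pvalue)
    equal_var = levene_p >= levene_alpha
    res = sps.ttest_ind(x1, x0, equal_var=equal_var)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "equal_variance_assumed": equal_var,
        "levene_p": levene_p,
        "degenerate": False,
    }


@dataclass
class ICCResult:
    """Two-way absolute-agreement single-measurement intraclass correlation."""

    icc: float
    n_subjects: int
    n_repeats: int
    defined: bool = True


def icc(measurements) -> ICCResult:
    """ICC(A,1): two-way mixed, absolute agreement, single measurement.

    Parameters
    ----------
    measurements : array-like, shape (n_subjects, n_repeats)
        One row per subject, one column per repeat/rater.

    Notes
    -----
    Computed from the two-way ANOVA mean squares:

        ICC(A,1) = (MS_R - MS_E) /
                   (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    with MS_R the between-subject, MS_C the between-repeat and MS_E the
    residual mean square.  Constant data leave the denominator at zero;
    the result is then flagged undefined.
    """
    Y = np.asarray(measurements, dtype=float)
    if Y.ndim != 2:
        raise ValueError("expected a subjects x repeats table")
    n, k = Y.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 repeats")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom <= 0:
        return ICCResult(icc=float("nan"), n_subjects=n, n_repeats=k, defined=False)
    return ICCResult(
        icc=float((ms_r - ms_e) / denom), n_subjects=n, n_repeats=k, defined=True
    )


def icc_gate(icc_values: dict[str, float], threshold: float = 0.8) -> list[str]:
    """Feature names passing the repeatability gate (ICC > threshold)."""
    return [name for name, v in icc_values.items() if np.isfinite(v) and v > threshold]


def screen_features(
    table: pd.DataFrame,
    labels,
    categories: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Univariate screening table: AUC, p and BH q per feature, sorted by AUC.

    ``table`` holds one subject per row and one feature per column.
    """
    labels = np.asarray(labels).astype(int)
    rows = []
    for name in table.columns:
        auc, p = mann_whitney_auc(table[name].to_numpy(), labels)
        rows.append(
            {
                "feature": name,
                "category": (categories or {}).get(name, "unknown"),
                "auc": auc,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = q_values(out["p_value"].to_numpy())
    return out.sort_values("auc", ascending=False, ignore_index=True)
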