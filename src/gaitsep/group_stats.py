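"""Inferential layer: per-variable group comparisons and PC-variable correlations.

Per-variable two-sample t-tests (pooled variance by default, Welch by flag)
with Holm step-down adjustment controlling the family-wise alpha across all
tested variables, and Pearson correlations between selected PC score columns
and the discrete variables with conventional strength categories
(moderate |r| >= 0.36, strong |r| > 0.67).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pca import CovariancePCA
from .variables import VARIABLE_NAMES

STRONG_R = 0.67  # strong: |r| strictly greater
MODERATE_R = 0.36  # moderate: |r| greater or equal


def holm_adjust(
    p_values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p-values and rejection flags.

    Sorted ascending, p_(i) is multiplied by (m - i + 1), enforced monotone
    non-decreasing along the sorted order and capped at 1; hypotheses are
    rejected while the adjusted p stays <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return adjusted, reject


def two_sample_tests(
    table: pd.DataFrame,
    labels=None,
    group_order: tuple[str, str] = ("male", "female"),
    welch: bool = False,
    alpha: float = 0.05,
    variables=None,
) -> pd.DataFrame:
    """Per-variable two-sample t-tests with Holm-adjusted p-values.

    The t statistic is signed as first-listed group minus second (default
    male - female). The multiple-testing family is all tested variables.
    """
    if labels is None:
        labels = table["gender"]
    labels = np.asarray(labels)
    variables = list(variables) if variables is not None else [
        v for v in VARIABLE_NAMES if v in table.columns
    ]
    a_lab, b_lab = group_order
    mask_a, mask_b = labels == a_lab, labels == b_lab
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("both groups need at least 2 observations")
    recs = []
    for v in variables:
        a = table.loc[mask_a, v].to_numpy(float)
        b = table.loc[mask_b, v].to_numpy(float)
        res = stats.ttest_ind(a, b, equal_var=not welch)
        df = res.df if welch else a.size + b.size - 2
        recs.append(
            (
                v,
                a.mean(),
                a.std(ddof=1),
                b.mean(),
                b.std(ddof=1),
                float(res.statistic),
                float(df),
                float(res.pvalue),
            )
        )
    out = pd.DataFrame(
        recs,
        columns=[
            "variable",
            f"{a_lab}_mean",
            f"{a_lab}_sd",
            f"{b_lab}_mean",
            f"{b_lab}_sd",
            "t",
            "df",
            "p_raw",
        ],
    )
    out["p_holm"], out["significant"] = holm_adjust(out["p_raw"], alpha=alpha)
    return out


def correlation_category(r: float) -> str:
    """Strength label for a correlation magnitude."""
    a = abs(r)
    return "strong" if a > STRONG_R else "moderate" if a >= MODERATE_R else "weak"


def pc_variable_correlations(
    pca: CovariancePCA,
    pcs: list[int],
    table: pd.DataFrame,
    variables=None,
) -> pd.DataFrame:
    """Pearson correlations between selected PC scores and the variables.

    ``pcs`` are 1-based PC indices (eigenvalue order). Returns one row per
    variable with, per PC, the correlation magnitude ``r_PCj``, the signed
    value, the two-sided p and the strength category.
    """
    variables = list(variables) if variables is not None else [
        v for v in VARIABLE_NAMES if v in table.columns
    ]
    for j in pcs:
        if not 1 <= j <= pca.n_components_:
            raise ValueError(f"PC {j} not in decomposition (k={pca.n_components_})")
    out = pd.DataFrame({"variable": variables})
    for j in pcs:
        score = pca.scores_[:, j - 1]
        r_vals, p_vals = [], []
        for v in variables:
            x = table[v].to_numpy(float)
            if np.std(x) == 0 or np.std(score) == 0:
                raise ValueError(f"constant column in correlation: {v}")
            r, p = stats.pearsonr(score, x)
            r_vals.append(r)
            p_vals.append(p)
        out[f"r_PC{j}"] = np.abs(r_vals)
        out[f"r_signed_PC{j}"] = r_vals
        out[f"p_PC{j}"] = p_vals
        out[f"category_PC{j}"] = [correlation_category(r) for r in r_vals]
    return out
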