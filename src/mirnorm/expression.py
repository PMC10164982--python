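"""Relative quantification by the 2^-ΔΔCt method.

ΔΔCt for a sample is its ΔCt minus the mean ΔCt of the control group; the
per-sample relative expression is 2^-ΔΔCt, so the control-group average is
1 by construction.  The group-level fold change is summarised as
2^-(mean tumor ΔΔCt) — a geometric-mean-type summary on the linear scale —
and reported with the signed convention common in the clinical literature:
ratios below 1 are written as the negative reciprocal (0.25 -> -4.0), so
|reported FC| is always >= 1 and down-regulation carries a minus sign.

Group differences are tested on the log-scale values: Shapiro-Wilk
normality on each group decides between Student's t-test (both normal)
and the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix

__all__ = [
    "fold_change_reported",
    "ddct_fold_change",
    "group_test",
    "classify_significance",
    "quantify",
]


def fold_change_reported(fc_linear: float) -> float:
    """Signed fold-change convention: x >= 1 -> x, x < 1 -> -1/x."""
    if fc_linear <= 0:
        raise ValueError("linear fold change must be > 0")
    return fc_linear if fc_linear >= 1.0 else -1.0 / fc_linear


def ddct_fold_change(
    normalized: NormalizedMatrix,
    tumor: Sequence[str],
    control: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene ΔΔCt summary and the per-sample ΔΔCt matrix.

    Returns ``(summary, ddct)`` where summary has per gene the mean tumor
    ΔΔCt, the linear group fold change 2^-(mean ΔΔCt) and its signed
    reported form, and ``ddct`` is the gene x sample ΔΔCt matrix
    (control-mean-centred ΔCt).
    """
    if len(control) == 0 or len(tumor) == 0:
        raise ValueError("both groups must be nonempty")
    dct = normalized.delta_ct
    missing = [s for s in list(tumor) + list(control) if s not in dct.columns]
    if missing:
        raise KeyError(f"samples absent from ΔCt matrix: {missing}")
    ctrl_mean = dct[list(control)].mean(axis=1)
    ddct = dct[list(tumor) + list(control)].sub(ctrl_mean, axis=0)
    mean_ddct = ddct[list(tumor)].mean(axis=1)
    fc_linear = np.power(2.0, -mean_ddct)
    summary = pd.DataFrame(
        {
            "mean_ddct_tumor": mean_ddct,
            "fc_linear": fc_linear,
            "fc_reported": [fold_change_reported(x) for x in fc_linear],
        }
    )
    return summary, ddct


def group_test(
    a: Sequence[float],
    b: Sequence[float],
    alpha_norm: float = 0.05,
) -> tuple[float, str]:
    """Two-group comparison with normality-based test dispatch.

    Shapiro-Wilk is run on each group's (log-scale) values; if both pass
    at ``alpha_norm`` a two-sided Student's t-test is used, otherwise the
    two-sided Mann-Whitney U test.  Returns ``(p_value, test_used)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    normal = all(
        stats.shapiro(x)[1] > alpha_norm if np.ptp(x) > 0 else False
        for x in (a, b)
    )
    if normal:
        p = float(stats.ttest_ind(a, b).pvalue)
        return p, "t-test"
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return p, "mann-whitney"


def classify_significance(
    results: pd.DataFrame,
    p_max: float = 0.05,
    fc_min: float = 2.0,
) -> pd.DataFrame:
    """Apply the joint significance rule: p < p_max and |reported FC| >= fc_min."""
    out = results.copy()
    out["significant"] = (out["p_value"] < p_max) & (out["fc_reported"].abs() >= fc_min)
    direction = np.where(out["fc_reported"] >= 1, "up", "down")
    out["direction"] = np.where(out["significant"], direction, "ns")
    return out


def quantify(
    normalized: NormalizedMatrix,
    tumor: Sequence[str],
    control: Sequence[str],
    p_max: float = 0.05,
    fc_min: float = 2.0,
    alpha_norm: float = 0.05,
) -> pd.DataFrame:
    """Full relative-quantification table for every gene in the ΔCt matrix.

    Combines the ΔΔCt fold-change summary, the dispatched group test on
    the per-sample ΔΔCt values, Benjamini-Hochberg adjusted p-values
    (reported for transparency; the significance verdict uses the raw p,
    as is conventional for small validated qPCR panels), and the
    significance verdict.
    """
    summary, ddct = ddct_fold_change(normalized, tumor, control)
    pvals, tests = [], []
    for g in summary.index:
        p, used = group_test(
            ddct.loc[g, list(tumor)], ddct.loc[g, list(control)],
            alpha_norm=alpha_norm,
        )
        pvals.append(p)
        tests.append(used)
    summary["p_value"] = pvals
    summary["test_used"] = tests
    summary["p_adjusted"] = multipletests(pvals, method="fdr_bh")[1]
    return classify_significance(summary, p_max=p_max, fc_min=fc_min)
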