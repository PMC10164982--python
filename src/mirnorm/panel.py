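"""Multi-miRNA logistic diagnostic panel with ROC evaluation.

The panel is a maximum-likelihood logistic regression of the tumor label
on per-sample log-scale relative expression (-ΔΔCt) of the selected
miRNAs, fitted and evaluated in-sample.  The ROC curve is swept over the
fitted probabilities; AUC is the trapezoidal area, which equals the
concordance probability.  A fixed probability cutoff (0.5 by default,
boundary counted positive) yields the confusion matrix and the
sensitivity / specificity percentages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "PanelFit",
    "fit_panel",
    "roc_curve",
    "ConfusionResult",
    "confusion_at_cutoff",
    "PanelResult",
    "evaluate_panel",
]


@dataclass
class PanelFit:
    coefficients: pd.Series      # per feature, plus "intercept"
    scores: pd.Series            # fitted probability per sample
    separation_flagged: bool


def fit_panel(features: pd.DataFrame, labels: pd.Series) -> PanelFit:
    """Fit the logistic panel; fall back to a ridge fit under separation.

    ``features`` is samples x miRNAs (log-scale relative expression);
    ``labels`` is 1 for tumor, 0 for control.  The unpenalised
    maximum-likelihood fit is attempted first (the problem is convex, so
    the result is deterministic); if the classes are perfectly separated
    the MLE diverges, and a lightly ridge-penalised fit is returned
    instead with ``separation_flagged=True``.
    """
    labels = labels.loc[features.index].astype(int)
    if labels.nunique() != 2:
        raise ValueError("labels must contain both classes")
    if labels.value_counts().min() < 2:
        raise ValueError("need at least 2 samples per class")
    if not np.isfinite(features.to_numpy()).all():
        raise ValueError("panel features must be finite")

    x = sm.add_constant(features.to_numpy(dtype=float), has_constant="add")
    separated = False
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # perfect separation surfaces as a warning
        try:
            res = sm.Logit(labels.to_numpy(), x).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.isfinite(res.params).all() \
                    and np.abs(res.params).max() < 1e6:
                params = res.params
            else:
                separated = True
        except Exception:
            separated = True
    if params is None:
        clf = LogisticRegression(C=100.0, solver="lbfgs", max_iter=1000)
        clf.fit(features.to_numpy(dtype=float), labels.to_numpy())
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        separated = True
    coef = pd.Series(params, index=["intercept"] + list(features.columns))
    logit = x @ params
    scores = pd.Series(1.0 / (1.0 + np.exp(-logit)), index=features.index)
    return PanelFit(coefficients=coef, scores=scores, separation_flagged=separated)


def roc_curve(scores: Sequence[float], labels: Sequence[int]
              ) -> tuple[pd.DataFrame, float]:
    """ROC points (1-specificity, sensitivity) and trapezoidal AUC."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    points = pd.DataFrame(
        {"fpr": fpr, "tpr": tpr, "threshold": thresholds}
    )
    return points, float(_trapezoid_auc(fpr, tpr))


@dataclass
class ConfusionResult:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity_percent(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity_percent(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity_percent": self.sensitivity_percent,
            "specificity_percent": self.specificity_percent,
        }


def confusion_at_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    cutoff: float = 0.5,
) -> ConfusionResult:
    """Tally the confusion matrix at a probability cutoff (score >= cutoff
    predicts positive)."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    labels = np.asarray(labels, dtype=int)
    pred = np.asarray(scores, dtype=float) >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return ConfusionResult(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class PanelResult:
    fit: PanelFit
    roc_points: pd.DataFrame
    auc: float
    confusion: ConfusionResult
    cutoff: float

    def to_json_dict(self) -> dict:
        return {
            "coefficients": {k: float(v) for k, v in self.fit.coefficients.items()},
            "separation_flagged": bool(self.fit.separation_flagged),
            "auc": float(self.auc),
            "cutoff": float(self.cutoff),
            "confusion": self.confusion.as_dict(),
        }

    def write(self, report_path: str | Path, roc_path: str | Path | None = None) -> None:
        Path(report_path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True))
        if roc_path is not None:
            self.roc_points.to_csv(roc_path, sep="\t", index=False)


def evaluate_panel(
    features: pd.DataFrame,
    labels: pd.Series,
    cutoff: float = 0.5,
) -> PanelResult:
    """Fit the panel and evaluate ROC/AUC and the cutoff confusion matrix."""
    fit = fit_panel(features, labels)
    lab = labels.loc[features.index].astype(int)
    points, auc_value = roc_curve(fit.scores, lab)
    confusion = confusion_at_cutoff(fit.scores, lab, cutoff=cutoff)
    return PanelResult(fit=fit, roc_points=points, auc=auc_value,
                       confusion=confusion, cutoff=cutoff)
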