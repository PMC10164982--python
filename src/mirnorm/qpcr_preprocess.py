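"""From raw triplicate Ct values to a clean, normalized per-sample matrix.

Processing order (configurable pieces, fixed default order):

1. :func:`collapse_replicates` — average detected replicates, QC-flag noisy
   triplicates.
2. :func:`detection_filter` — discard genes that fail detection
   (undetected, or Ct above the limit) in at least one sample.
3. :func:`interrun_calibrate` — remove per-run offsets using the pooled
   inter-run calibrator, per gene.
4. :func:`delta_ct` — normalize target Cts to an endogenous control
   (single gene or geometric-mean combination), yielding ΔCt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CtDataset, NormalizedMatrix

__all__ = [
    "collapse_replicates",
    "detection_filter",
    "DetectionResult",
    "interrun_calibrate",
    "delta_ct",
]


def collapse_replicates(
    dataset: CtDataset, max_sd: float = 0.5, method: str = "mean"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse replicate Cts to one value per (gene, sample).

    The collapsed value is the arithmetic mean (or ``method="median"``) of
    the *detected* replicates; a QC flag is raised where the replicate
    sample SD (n-1 denominator) exceeds ``max_sd`` cycles.  A cell whose
    replicates are all undetected stays undetected (NaN).

    Returns ``(matrix, flags)``, both genes x samples.
    """
    if dataset.ct.empty:
        raise ValueError("empty Ct dataset")
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    grouped = dataset.ct.T.groupby(level="sample", sort=False)
    matrix = (grouped.median() if method == "median" else grouped.mean()).T
    sd = grouped.std(ddof=1).T
    flags = (sd > max_sd).fillna(False)
    matrix = matrix[dataset.samples]
    return matrix, flags[dataset.samples]


@dataclass
class DetectionResult:
    retained: list[str]
    discarded: list[str]
    # gene -> samples in which it failed detection
    discard_log: dict[str, list[str]]


def detection_filter(
    matrix: pd.DataFrame,
    limit: float = 40.0,
    tolerance: float = 0.0,
) -> DetectionResult:
    """Discard genes not detected in (essentially) all samples.

    A gene is discarded when the fraction of samples in which it is
    undetected (NaN) or above ``limit`` exceeds ``tolerance`` (default 0:
    a single failing sample discards the gene).  The discard log names the
    offending samples per gene.
    """
    failing = matrix.isna() | (matrix > limit)
    frac = failing.mean(axis=1)
    discarded = list(matrix.index[frac > tolerance])
    retained = [g for g in matrix.index if g not in set(discarded)]
    log = {
        g: list(matrix.columns[failing.loc[g]]) for g in discarded
    }
    if not retained:
        import warnings

        warnings.warn("detection filter retained no genes", stacklevel=2)
    return DetectionResult(retained=retained, discarded=discarded, discard_log=log)


def interrun_calibrate(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Remove run-to-run offsets using the inter-run calibrator, per gene.

    For each gene and run the calibrator's Ct is compared with the mean
    calibrator Ct over all runs; that difference is subtracted from every
    sample of the run.  Calibrator samples are dropped from the output.
    With a single run (or identical calibrator Cts) the data pass through
    unchanged.
    """
    meta = meta.loc[matrix.columns]
    cal = meta.index[meta["is_calibrator"]]
    runs = sorted(meta["run"].unique())
    cal_by_run: dict = {}
    for r in runs:
        cands = [s for s in cal if meta.loc[s, "run"] == r]
        if not cands:
            raise ValueError(f"run {r} has no inter-run calibrator sample")
        # multiple calibrator wells in a run are averaged
        cal_by_run[r] = matrix[cands].mean(axis=1)
    cal_ct = pd.DataFrame(cal_by_run)  # genes x runs
    offsets = cal_ct.sub(cal_ct.mean(axis=1), axis=0)  # genes x runs
    keep = [s for s in matrix.columns if s not in set(cal)]
    out = matrix[keep].copy()
    for s in keep:
        out[s] = out[s] - offsets[meta.loc[s, "run"]]
    return out


def _geometric_mean_ct(matrix: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """Per-sample geometric mean of the Ct values of *genes*.

    Combining reference Cts by geometric mean follows the field's
    combination convention for multi-gene normalizers; it is applied to the
    Ct values themselves (a deliberate choice — Ct is already a log-scale
    quantity, so this is not a geometric mean of linear abundances).
    """
    sub = matrix.loc[list(genes)]
    if len(genes) == 1:  # exact: avoid exp(log(x)) round-off
        return sub.iloc[0]
    return np.exp(np.log(sub).mean(axis=0))


def delta_ct(
    matrix: pd.DataFrame,
    normalizer: str | Sequence[str],
    targets: Sequence[str] | None = None,
) -> NormalizedMatrix:
    """Normalize Cts to an endogenous control: ΔCt = Ct_target - Ct_norm.

    ``normalizer`` may be a single gene or a combination; a combination is
    collapsed per sample by geometric mean of its member Cts.  Undetected
    normalizer values are an error (they would silently poison every
    target in that sample).
    """
    if isinstance(normalizer, str):
        normalizer = (normalizer,)
    normalizer = tuple(normalizer)
    missing_genes = [g for g in normalizer if g not in matrix.index]
    if missing_genes:
        raise KeyError(f"normalizer genes absent from matrix: {missing_genes}")
    norm_block = matrix.loc[list(normalizer)]
    bad = norm_block.columns[norm_block.isna().any(axis=0)]
    if len(bad):
        raise ValueError(
            f"normalizer undetected in samples: {list(bad)}"
        )
    n_s = _geometric_mean_ct(matrix, normalizer)
    if targets is None:
        targets = list(matrix.index)
    delta = matrix.loc[list(targets)].sub(n_s, axis=1)
    return NormalizedMatrix(delta_ct=delta, normalizer=normalizer)
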