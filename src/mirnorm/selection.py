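"""Comprehensive ranking and endogenous-control selection.

Aggregates the four method-wise stability rankings into a single
"stability value" (geometric mean of ranks, the comprehensive-ranking
convention popularised by RefFinder), expands the candidate set with
geometric-mean combinations, applies the coefficient-of-variation
exclusion rule, and picks the endogenous control.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GROUP_CONTROL
from .stability import StabilityReport

__all__ = [
    "aggregate_ranks",
    "make_combinations",
    "combination_members",
    "cv_of_candidates",
    "SelectionResult",
    "select_endogenous_control",
]

COMBO_SEP = "+"


def aggregate_ranks(report: StabilityReport | pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean rank aggregation across the four methods.

    Within each method, candidates are ranked ascending by the method's
    stability statistic (ties get the average rank); geNorm uses its
    stepwise-exclusion ranking, in which the terminal pair is tied at
    1.5/1.5.  The comprehensive stability value of a candidate is the
    geometric mean of its four ranks; the result is sorted ascending
    (lower = more stable).

    ``report`` is a :class:`StabilityReport` or a bare per-gene statistics
    table with columns ``genorm_rank``, ``normfinder_rho``,
    ``bestkeeper_sd`` and ``deltact_sd``.
    """
    t = report if isinstance(report, pd.DataFrame) else report.table
    required = ["genorm_rank", "normfinder_rho", "bestkeeper_sd", "deltact_sd"]
    for col in required:
        if t[col].isna().any():
            bad = list(t.index[t[col].isna()])
            raise ValueError(f"missing {col} for candidates: {bad}")
    ranks = pd.DataFrame(
        {
            "rank_genorm": t["genorm_rank"],
            "rank_normfinder": stats.rankdata(t["normfinder_rho"]),
            "rank_bestkeeper": stats.rankdata(t["bestkeeper_sd"]),
            "rank_deltact": stats.rankdata(t["deltact_sd"]),
        },
        index=t.index,
    )
    ranks["stability_value"] = stats.gmean(ranks.to_numpy(), axis=1)
    return ranks.sort_values("stability_value", kind="stable")


def make_combinations(matrix: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Append k-gene pseudo-genes: per-sample geometric mean of member Cts.

    Pseudo-genes are named ``"geneA+geneB"``; the original single genes are
    kept.  With n genes and k=2 this appends C(n, 2) rows.
    """
    if k < 2:
        raise ValueError("combination size k must be >= 2")
    if k > matrix.shape[0]:
        raise ValueError("k exceeds the number of genes")
    rows = {}
    for combo in itertools.combinations(matrix.index, k):
        name = COMBO_SEP.join(combo)
        rows[name] = np.exp(np.log(matrix.loc[list(combo)]).mean(axis=0))
    extended = pd.concat([matrix, pd.DataFrame(rows).T])
    extended.index.name = matrix.index.name
    return extended


def combination_members(candidate: str) -> tuple[str, ...]:
    """Member genes of a (possibly single-gene) candidate name."""
    return tuple(candidate.split(COMBO_SEP))


def cv_of_candidates(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    mode: str = "self-vs-calibrator",
    targets: list[str] | None = None,
    mean_epsilon: float = 0.05,
) -> pd.DataFrame:
    """Coefficient of variation of candidate ΔCt over control samples.

    Two readings of "ΔCt of the control samples" are supported:

    * ``"self-vs-calibrator"`` (default): ΔCt_s = candidate Ct in control
      sample s minus the candidate's Ct on the pooled inter-run calibrator
      of that sample's run.  ``matrix`` must therefore still contain the
      calibrator columns.
    * ``"targets-vs-candidate"``: ΔCt values of a designated target gene
      set normalized to the candidate, pooled over targets and control
      samples.  Rows of ``matrix`` named in ``targets`` serve only as
      targets — they are not evaluated as candidates.

    CV = 100 * SD(ΔCt) / |mean(ΔCt)|.  Candidates whose |mean ΔCt| falls
    below ``mean_epsilon`` are flagged ``unstable_by_construction``: their
    CV is dominated by the vanishing denominator, not by real variability.
    """
    meta = meta.loc[matrix.columns.intersection(meta.index)]
    controls = [
        s for s in matrix.columns
        if s in meta.index and meta.loc[s, "group"] == GROUP_CONTROL
        and not meta.loc[s, "is_calibrator"]
    ]
    if len(controls) < 3:
        raise ValueError("need at least 3 control samples for a CV")

    candidates = [c for c in matrix.index if not targets or c not in set(targets)]
    out = {}
    for cand in candidates:
        if mode == "self-vs-calibrator":
            cal = meta.index[meta["is_calibrator"]]
            if len(cal) == 0:
                raise ValueError("matrix has no calibrator samples for CV mode "
                                 "'self-vs-calibrator'")
            cal_by_run = {meta.loc[s, "run"]: matrix.loc[cand, s] for s in cal}
            dct = np.array(
                [matrix.loc[cand, s] - cal_by_run[meta.loc[s, "run"]] for s in controls]
            )
        elif mode == "targets-vs-candidate":
            if not targets:
                raise ValueError("targets required for CV mode 'targets-vs-candidate'")
            member_set = set(combination_members(cand))
            tgt = [t for t in targets if t not in member_set]
            dct = (
                matrix.loc[tgt, controls] - matrix.loc[cand, controls]
            ).to_numpy().ravel()
        else:
            raise ValueError(f"unknown CV mode: {mode!r}")
        dct = dct[~np.isnan(dct)]
        mean = float(np.mean(dct))
        sd = float(np.std(dct, ddof=1))
        flagged = abs(mean) < mean_epsilon
        cv = np.inf if mean == 0 else 100.0 * sd / abs(mean)
        out[cand] = {"cv_percent": cv, "mean_delta_ct": mean, "flagged": flagged}
    return pd.DataFrame(out).T.astype(
        {"cv_percent": float, "mean_delta_ct": float, "flagged": bool}
    )


@dataclass
class SelectionResult:
    verdicts: pd.DataFrame  # ranks, stability_value, cv_percent, verdict, reason
    selected: str
    shortlist: list[str]    # survivors under the stability screening threshold

    def write(self, path) -> None:
        self.verdicts.to_csv(path, sep="\t", index_label="candidate")


def select_endogenous_control(
    ranking: pd.DataFrame,
    cvs: pd.DataFrame,
    cv_max: float = 200.0,
    stability_max: float = 5.0,
) -> SelectionResult:
    """Pick the endogenous control from aggregated ranks and CVs.

    Candidates with CV above ``cv_max`` percent (or a degenerate near-zero
    mean ΔCt) are excluded; among survivors the minimal comprehensive
    stability value wins, with lower CV breaking ties.  The shortlist
    collects survivors whose stability value is below ``stability_max``.
    """
    missing = set(ranking.index).symmetric_difference(cvs.index)
    if missing:
        raise ValueError(f"ranking and CV tables disagree on candidates: {sorted(missing)}")
    table = ranking.join(cvs)
    reasons = pd.Series("", index=table.index, dtype=object)
    excluded = table["cv_percent"] > cv_max
    reasons[excluded] = f"CV > {cv_max:g}%"
    degenerate = table["flagged"] & ~excluded
    excluded |= table["flagged"]
    reasons[degenerate] = "mean ΔCt ≈ 0 (CV unstable by construction)"
    survivors = table.loc[~excluded]
    if survivors.empty:
        raise ValueError(
            "all candidates excluded by the CV rule; review cv_max or the CV mode"
        )
    ordered = survivors.sort_values(
        ["stability_value", "cv_percent"], kind="stable"
    )
    selected = ordered.index[0]
    verdict = pd.Series("excluded", index=table.index, dtype=object)
    verdict[~excluded] = "candidate"
    verdict[selected] = "selected"
    table = table.assign(verdict=verdict, reason=reasons)
    shortlist = list(
        ordered.index[ordered["stability_value"] < stability_max]
    )
    return SelectionResult(
        verdicts=table.sort_values(["stability_value"], kind="stable"),
        selected=selected,
        shortlist=shortlist,
    )
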