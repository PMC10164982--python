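"""Small-RNA-seq screening: RPM normalization, candidate and DE filters.

Counts are consumed as a generic miRNA x sample matrix; differential-
expression result tables from external callers (edgeR / voom / DESeq2
style) are consumed as generic tables with columns
``id, baseMean, log2FC, pvalue, padj`` — the callers themselves are out of
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "rpm_normalize",
    "ExpressionFilterResult",
    "expression_filter",
    "group_rpm_stats",
    "ec_candidate_screen",
    "ConsensusResult",
    "de_consensus",
]


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million: count / library size * 1e6, per sample."""
    totals = counts.sum(axis=0)
    zero = list(totals.index[totals <= 0])
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    return counts.div(totals, axis=1) * 1e6


@dataclass
class ExpressionFilterResult:
    retained: list[str]
    discarded: list[str]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_discarded(self) -> int:
        return len(self.discarded)


def expression_filter(counts: pd.DataFrame) -> ExpressionFilterResult:
    """Discard miRNAs with zero counts in every sample."""
    zero = counts.sum(axis=1) == 0
    # guard against negative entries masking as "expressed"
    if (counts < 0).any().any():
        raise ValueError("count matrix contains negative values")
    return ExpressionFilterResult(
        retained=list(counts.index[~zero]),
        discarded=list(counts.index[zero]),
    )


def group_rpm_stats(
    rpm: pd.DataFrame,
    tumor: Sequence[str],
    control: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Base mean and tumor/control log2 fold change per miRNA.

    base_mean is the mean RPM across all samples; log2fc is computed on
    the group mean RPMs with *pseudocount* added to both means so that a
    zero group yields a finite value.
    """
    if len(tumor) == 0 or len(control) == 0:
        raise ValueError("both groups must be nonempty")
    all_samples = list(tumor) + list(control)
    base_mean = rpm[all_samples].mean(axis=1)
    mt = rpm[list(tumor)].mean(axis=1)
    mc = rpm[list(control)].mean(axis=1)
    log2fc = np.log2(mt + pseudocount) - np.log2(mc + pseudocount)
    return pd.DataFrame({"base_mean": base_mean, "log2fc": log2fc})


def ec_candidate_screen(
    rpm: pd.DataFrame,
    tumor: Sequence[str],
    control: Sequence[str],
    base_min: float = 100.0,
    lfc_max: float = 2.0,
    top_n: int = 5,
    pseudocount: float = 0.5,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Screen sequencing data for endogenous-control candidates.

    miRNAs with base mean below ``base_min`` or |log2FC| above ``lfc_max``
    are discarded; survivors are ranked by |log2FC| ascending (the most
    group-indifferent first) and the top ``top_n`` returned.  With
    ``two_sided=False`` the fold-change gate uses the signed log2FC > lfc_max
    instead of the absolute value.
    """
    stats_ = group_rpm_stats(rpm, tumor, control, pseudocount=pseudocount)
    mag = stats_["log2fc"].abs() if two_sided else stats_["log2fc"]
    keep = (stats_["base_mean"] >= base_min) & (mag <= lfc_max)
    survivors = stats_.loc[keep].copy()
    survivors["abs_log2fc"] = survivors["log2fc"].abs()
    survivors = survivors.sort_values(["abs_log2fc", "base_mean"],
                                      ascending=[True, False], kind="stable")
    if len(survivors) < top_n:
        warnings.warn(
            f"only {len(survivors)} candidates survive the screen (top_n={top_n})",
            stacklevel=2,
        )
    return survivors.head(top_n)


@dataclass
class ConsensusResult:
    per_table_counts: list[int]
    intersection: list[str]          # significant in every table
    consensus: list[str]             # after the base-mean filter
    dropped_low_expression: list[str]

    @property
    def n_intersection(self) -> int:
        return len(self.intersection)


_DE_COLUMNS = {"id", "baseMean", "log2FC", "pvalue", "padj"}


def de_consensus(
    tables: Sequence[pd.DataFrame],
    base_min: float = 100.0,
    alpha: float = 0.05,
) -> ConsensusResult:
    """Intersect significant calls across DE tables, then filter low expression.

    A miRNA is significant in a table when ``padj < alpha`` (an explicit
    boolean ``significant`` column takes precedence).  The consensus is the
    intersection across all tables, minus ids whose ``baseMean`` in the
    first table is below ``base_min``.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 DE tables for a consensus")
    sig_sets = []
    for i, t in enumerate(tables):
        if t.empty:
            raise ValueError(f"DE table {i} is empty")
        missing = _DE_COLUMNS - set(t.columns)
        if missing:
            raise ValueError(f"DE table {i} lacks columns {sorted(missing)}")
        if "significant" in t.columns:
            sig = t.loc[t["significant"].astype(bool), "id"]
        else:
            sig = t.loc[t["padj"] < alpha, "id"]
        sig_sets.append(set(sig))
    inter = set.intersection(*sig_sets)
    first = tables[0].set_index("id")
    low = {m for m in inter if first.loc[m, "baseMean"] < base_min}
    # sort by first-table order for reproducible output
    order = {m: i for i, m in enumerate(tables[0]["id"])}
    return ConsensusResult(
        per_table_counts=[len(s) for s in sig_sets],
        intersection=sorted(inter, key=order.get),
        consensus=sorted(inter - low, key=order.get),
        dropped_low_expression=sorted(low, key=order.get),
    )
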