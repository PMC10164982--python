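"""Reference-gene stability statistics.

Implements the four classical candidate-reference stability measures on a
clean Ct matrix (genes x samples, no missing cells).  All computations run
directly on Ct, which is already a log2-scale quantity (one PCR cycle =
one doubling), so pairwise Ct differences are log2 expression ratios.

* geNorm (Vandesompele et al. 2002): gene-stability measure M = average
  standard deviation of the log-ratio to every other candidate, with
  stepwise exclusion of the worst gene and the pairwise-variation series
  V(n/n+1).
* NormFinder (Andersen et al. 2004): model-based decomposition into
  intra-group variance and inter-group bias, combined into a single
  stability value (lower = more stable).
* BestKeeper (Pfaffl et al. 2004): per-gene SD and CV of Ct plus the
  Pearson correlation with the BestKeeper index (per-sample geometric mean
  Ct).
* Comparative delta-Ct (Silver et al. 2006): mean, over all partner genes,
  of the SD of the pairwise Ct difference across samples.

Sample SDs use the n-1 denominator throughout, matching the original
publications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenormResult",
    "genorm",
    "normfinder",
    "BestKeeperResult",
    "bestkeeper",
    "deltact_stability",
    "StabilityReport",
    "stability_report",
]


def _check_matrix(matrix: pd.DataFrame, min_genes: int, min_samples: int) -> None:
    if matrix.isna().any().any():
        raise ValueError("Ct matrix contains missing cells; filter or impute first")
    if matrix.shape[0] < min_genes:
        raise ValueError(f"need at least {min_genes} genes, got {matrix.shape[0]}")
    if matrix.shape[1] < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {matrix.shape[1]}")


def _pairwise_sd_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """SD across samples of Ct_j - Ct_k for every gene pair (j, k).

    Uses Var(X_j - X_k) = Var_j + Var_k - 2 Cov_jk on the gene covariance
    matrix, so the whole pair grid costs one covariance computation.
    """
    x = matrix.to_numpy(dtype=float)
    cov = np.cov(x, ddof=1)
    cov = np.atleast_2d(cov)
    v = np.diag(cov)
    var_diff = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(var_diff, 0.0)
    sd = np.sqrt(np.clip(var_diff, 0.0, None))
    return pd.DataFrame(sd, index=matrix.index, columns=matrix.index)


def _m_values(matrix: pd.DataFrame) -> pd.Series:
    """geNorm M per gene: mean over partners of the pairwise log-ratio SD."""
    sd = _pairwise_sd_matrix(matrix)
    k = len(sd)
    m = (sd.sum(axis=1)) / (k - 1)
    return m


@dataclass
class GenormResult:
    m_values: pd.Series          # full-panel M per gene
    exclusion_order: list[str]   # worst first
    ranking: pd.Series           # 1.5/1.5 for the terminal pair, then 3, 4, ...
    v_series: pd.Series          # V(n/n+1) indexed "V2/3", "V3/4", ...


def genorm(matrix: pd.DataFrame) -> GenormResult:
    """geNorm stability analysis with stepwise exclusion.

    At each pass the gene with the largest M is removed and M values are
    recomputed, until two genes remain; those two are inseparable by the
    procedure and share ranks 1-2 (average rank 1.5 each).  The pairwise
    variation V(n/n+1) is the SD across samples of the difference between
    log-scale normalization factors (mean Ct of the n and n+1 top-ranked
    genes — the geometric mean on the linear scale).
    """
    _check_matrix(matrix, min_genes=3, min_samples=2)
    full_m = _m_values(matrix)

    remaining = list(matrix.index)
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = _m_values(matrix.loc[remaining])
        # deterministic tie-break: first gene in current order with max M
        worst = m.index[int(np.argmax(m.to_numpy()))]
        exclusion.append(worst)
        remaining.remove(worst)

    ranking = pd.Series(index=matrix.index, dtype=float)
    ranking.loc[remaining] = 1.5
    for pos, gene in enumerate(reversed(exclusion)):
        ranking.loc[gene] = 3.0 + pos

    by_rank = list(remaining) + list(reversed(exclusion))
    v = {}
    for n in range(2, len(by_rank)):
        nf_n = matrix.loc[by_rank[:n]].mean(axis=0)
        nf_n1 = matrix.loc[by_rank[: n + 1]].mean(axis=0)
        v[f"V{n}/{n + 1}"] = float((nf_n - nf_n1).std(ddof=1))
    return GenormResult(
        m_values=full_m,
        exclusion_order=exclusion,
        ranking=ranking,
        v_series=pd.Series(v, dtype=float),
    )


def normfinder(matrix: pd.DataFrame, groups: pd.Series | None = None) -> pd.Series:
    """NormFinder stability value per gene (lower = more stable).

    Model-based variance decomposition on the log (Ct) scale.  Per-sample
    averages across genes are removed; for each group the per-gene
    intra-group variance is estimated with the bias correction for the
    finite gene count, and the inter-group expression difference is shrunk
    toward zero in proportion to its sampling noise.  The stability value
    averages, with equal group weights,

        |shrunken group difference| + sqrt(intra-group variance / n_group).

    With ``groups=None`` (or identical per-group data, where all group
    differences vanish) the value reduces to the estimated per-gene SD.
    """
    _check_matrix(matrix, min_genes=3, min_samples=2)
    if groups is None:
        sig2 = _normfinder_variance(matrix)
        return pd.Series(np.sqrt(sig2), index=matrix.index)

    groups = groups.loc[matrix.columns]
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups for group-wise NormFinder")
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")

    k = matrix.shape[0]
    zbar = {}
    sig2 = {}
    n_g = {}
    for lev in levels:
        sub = matrix.loc[:, groups.index[groups == lev]]
        z = sub - sub.mean(axis=0)  # remove per-sample gene average
        zbar[lev] = z.mean(axis=1)
        sig2[lev] = _normfinder_variance(sub)
        n_g[lev] = sub.shape[1]

    zbar_df = pd.DataFrame(zbar)          # genes x groups
    d = zbar_df.sub(zbar_df.mean(axis=1), axis=0)  # inter-group differences
    sig2_df = pd.DataFrame(sig2, index=matrix.index)
    n_vec = pd.Series(n_g)

    g_count = len(levels)
    samp_var = sig2_df.div(n_vec, axis=1)
    tau2 = max(
        0.0,
        float((d**2).to_numpy().sum()) / ((k - 1) * (g_count - 1))
        - float(samp_var.to_numpy().mean()),
    )
    shrink = tau2 / (tau2 + samp_var) if tau2 > 0 else samp_var * 0.0
    d_shrunk = d * shrink
    rho = (d_shrunk.abs() + np.sqrt(samp_var)).mean(axis=1)
    return rho


def _normfinder_variance(matrix: pd.DataFrame) -> np.ndarray:
    """Bias-corrected per-gene variance after removing per-sample averages.

    With k genes, the naive variance of the sample-centered values
    underestimates the true per-gene variance; the moment correction
    sigma^2_i = (s^2_i - S/k^2) * k / (k - 2), with S the (corrected) sum
    over genes, restores unbiasedness.  Negative estimates clip to 0.
    """
    k = matrix.shape[0]
    if k < 3:
        raise ValueError("NormFinder variance estimation needs >= 3 genes")
    z = matrix - matrix.mean(axis=0)
    s2 = z.var(axis=1, ddof=1).to_numpy()
    total = s2.sum() / (1.0 - 1.0 / k)
    sig2 = (s2 - total / k**2) * k / (k - 2)
    return np.clip(sig2, 0.0, None)


@dataclass
class BestKeeperResult:
    index: pd.Series  # per-sample geometric mean Ct
    table: pd.DataFrame  # per gene: sd, cv_percent, r


def bestkeeper(matrix: pd.DataFrame) -> BestKeeperResult:
    """BestKeeper descriptive statistics per gene.

    The BestKeeper index is the per-sample geometric mean of all candidate
    Cts; each candidate is characterised by its Ct SD, CV (percent of the
    mean Ct) and Pearson correlation with the index.  Candidates are
    ranked by SD ascending (a constant gene has undefined r but is still
    the best by SD).
    """
    _check_matrix(matrix, min_genes=2, min_samples=3)
    index = pd.Series(
        np.exp(np.log(matrix).mean(axis=0)), index=matrix.columns, name="bestkeeper_index"
    )
    sd = matrix.std(axis=1, ddof=1)
    cv = 100.0 * sd / matrix.mean(axis=1)
    r = pd.Series(index=matrix.index, dtype=float)
    for g in matrix.index:
        if sd.loc[g] == 0 or index.std(ddof=1) == 0:
            r.loc[g] = np.nan  # undefined for a constant series
        else:
            r.loc[g] = float(stats.pearsonr(matrix.loc[g], index)[0])
    table = pd.DataFrame({"sd": sd, "cv_percent": cv, "r": r})
    return BestKeeperResult(index=index, table=table)


def deltact_stability(matrix: pd.DataFrame) -> pd.Series:
    """Comparative delta-Ct stability: mean pairwise-difference SD per gene.

    For every partner k of gene j the SD across samples of Ct_j - Ct_k is
    computed; a gene that keeps a constant offset to its partners scores 0.
    """
    _check_matrix(matrix, min_genes=2, min_samples=2)
    sd = _pairwise_sd_matrix(matrix)
    k = len(sd)
    return sd.sum(axis=1) / (k - 1)


@dataclass
class StabilityReport:
    """Per-gene statistics from all four methods, one row per gene."""

    table: pd.DataFrame
    genorm: GenormResult
    bestkeeper: BestKeeperResult

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def stability_report(matrix: pd.DataFrame, groups: pd.Series | None = None
                     ) -> StabilityReport:
    """Run all four stability methods on a clean Ct matrix."""
    gn = genorm(matrix)
    nf = normfinder(matrix, groups)
    bk = bestkeeper(matrix)
    dc = deltact_stability(matrix)
    table = pd.DataFrame(
        {
            "genorm_m": gn.m_values,
            "genorm_rank": gn.ranking,
            "normfinder_rho": nf,
            "bestkeeper_sd": bk.table["sd"],
            "bestkeeper_cv": bk.table["cv_percent"],
            "bestkeeper_r": bk.table["r"],
            "deltact_sd": dc,
        }
    )
    return StabilityReport(table=table, genorm=gn, bestkeeper=bk)
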