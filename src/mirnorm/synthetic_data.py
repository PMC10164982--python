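"""Synthetic qPCR and small-RNA-seq data with known ground truth.

The generators emulate the two measurement layers of a typical
endogenous-control study:

* :func:`simulate_ct_dataset` draws replicate-level qPCR Ct values from an
  additive model on the cycle scale,

  .. math::

     Ct_{g,s,r} = b_g + a_s + \\beta_g\\,\\mathrm{I}(s\\in\\text{tumor})
                  + \\delta_{run(s)} + \\eta_{g,s} + \\varepsilon_{g,s,r},

  with per-gene baselines ``b_g``, exchangeable sample effects
  ``a_s ~ N(0, sample_effect_sd)``, per-gene group shifts ``beta_g``
  (zero for a stable reference candidate), per-run offsets ``delta``,
  optional per-(gene, sample) biological noise ``eta`` and triplicate
  technical noise ``epsilon ~ N(0, replicate_sd)``.  Reactions crossing the
  detection limit (40 cycles by default) are recorded as undetected (NaN).
  One pooled inter-run calibrator pseudo-sample is measured on every run.

* :func:`simulate_count_matrix` draws negative-binomial sequencing counts
  with per-miRNA base abundances (RPM scale) and group log2 fold changes.

* :func:`simulate_de_tables` fabricates differential-expression result
  tables (id, baseMean, log2FC, pvalue, padj) with controlled per-method
  sensitivity/specificity, standing in for external DE callers whose
  outputs the screening stage consumes as generic tables.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    GROUP_CONTROL,
    GROUP_POOL,
    GROUP_TUMOR,
    CtDataset,
)

__all__ = [
    "CtSimSpec",
    "CountSimSpec",
    "simulate_ct_dataset",
    "simulate_count_matrix",
    "simulate_de_tables",
]


@dataclass
class CtSimSpec:
    """Parameters of the Ct generative model.

    ``gene_baselines`` maps gene name -> baseline Ct (typically 20-35
    cycles).  ``group_effects`` maps gene -> tumor-vs-control shift in
    cycles (omitted genes are stable, i.e. shift 0).  ``gene_noise_sd``
    maps gene -> SD of per-(gene, sample) biological noise, used to plant
    unstable reference candidates.  ``run_offsets`` gives one additive Ct
    offset per run; if None, ``n_runs`` offsets are drawn
    ``N(0, run_offset_sd)``.  ``dropout_genes`` are forced undetected in at
    least one sample.
    """

    gene_baselines: Mapping[str, float]
    n_tumor: int
    n_control: int
    group_effects: Mapping[str, float] = field(default_factory=dict)
    gene_noise_sd: Mapping[str, float] = field(default_factory=dict)
    sample_effect_sd: float = 0.25
    replicate_sd: float = 0.2
    n_replicates: int = 3
    n_runs: int = 1
    run_offsets: Sequence[float] | None = None
    run_offset_sd: float = 0.5
    detection_limit: float = 40.0
    dropout_genes: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 samples")
        for name, sd in [("sample_effect_sd", self.sample_effect_sd),
                         ("replicate_sd", self.replicate_sd),
                         ("run_offset_sd", self.run_offset_sd)]:
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(sd < 0 for sd in self.gene_noise_sd.values()):
            raise ValueError("gene_noise_sd values must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.run_offsets is not None and len(self.run_offsets) != self.n_runs:
            raise ValueError("run_offsets length must equal n_runs")
        if not self.gene_baselines:
            raise ValueError("at least one gene baseline required")
        if self.detection_limit <= max(self.gene_baselines.values()):
            raise ValueError("detection_limit must exceed the largest baseline")
        unknown = set(self.dropout_genes) - set(self.gene_baselines)
        if unknown:
            raise ValueError(f"dropout_genes not in gene_baselines: {sorted(unknown)}")


def simulate_ct_dataset(spec: CtSimSpec) -> CtDataset:
    """Draw a replicate-level Ct dataset (with calibrator pools) from *spec*."""
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_baselines)
    baselines = np.array([spec.gene_baselines[g] for g in genes])
    beta = np.array([spec.group_effects.get(g, 0.0) for g in genes])
    gnoise_sd = np.array([spec.gene_noise_sd.get(g, 0.0) for g in genes])

    tumor = [f"T{i + 1:03d}" for i in range(spec.n_tumor)]
    control = [f"C{i + 1:03d}" for i in range(spec.n_control)]
    samples = tumor + control
    n_s = len(samples)
    is_tumor = np.array([1.0] * spec.n_tumor + [0.0] * spec.n_control)

    if spec.run_offsets is not None:
        delta = np.asarray(spec.run_offsets, dtype=float)
    elif spec.n_runs == 1:
        delta = np.zeros(1)
    else:
        delta = rng.normal(0.0, spec.run_offset_sd, size=spec.n_runs)
    run_of = np.arange(n_s) % spec.n_runs  # round-robin run assignment

    a = rng.normal(0.0, spec.sample_effect_sd, size=n_s)
    eta = rng.normal(0.0, 1.0, size=(len(genes), n_s)) * gnoise_sd[:, None]
    eps = rng.normal(0.0, spec.replicate_sd,
                     size=(len(genes), n_s, spec.n_replicates))

    mean = (baselines[:, None]
            + a[None, :]
            + beta[:, None] * is_tumor[None, :]
            + delta[run_of][None, :]
            + eta)
    ct = mean[:, :, None] + eps

    # calibrator pool per run: the gene baseline plus the run offset
    cal_samples = [f"CAL_run{r + 1}" for r in range(spec.n_runs)]
    cal_eps = rng.normal(0.0, spec.replicate_sd,
                         size=(len(genes), spec.n_runs, spec.n_replicates))
    cal_ct = (baselines[:, None] + delta[None, :])[:, :, None] + cal_eps

    values = np.concatenate([ct, cal_ct], axis=1)
    all_samples = samples + cal_samples
    columns = pd.MultiIndex.from_tuples(
        [(s, r + 1) for s in all_samples for r in range(spec.n_replicates)],
        names=["sample", "replicate"],
    )
    frame = pd.DataFrame(
        values.reshape(len(genes), -1), index=pd.Index(genes, name="gene"),
        columns=columns,
    )
    frame = frame.mask(frame > spec.detection_limit)

    for g in spec.dropout_genes:
        victim = samples[int(rng.integers(0, n_s))]
        frame.loc[g, victim] = np.nan

    meta = pd.DataFrame(
        {
            "group": [GROUP_TUMOR] * spec.n_tumor
            + [GROUP_CONTROL] * spec.n_control
            + [GROUP_POOL] * spec.n_runs,
            "run": list(run_of + 1) + list(range(1, spec.n_runs + 1)),
            "is_calibrator": [False] * n_s + [True] * spec.n_runs,
        },
        index=pd.Index(all_samples, name="sample_id"),
    )
    return CtDataset(ct=frame, meta=meta, detection_limit=spec.detection_limit)


@dataclass
class CountSimSpec:
    """Parameters of the negative-binomial count model.

    ``base_means`` are expected control-group abundances on the
    reads-per-million scale; ``group_log2fc`` maps miRNA -> tumor/control
    log2 fold change; ``dispersion`` is the NB dispersion alpha in
    ``Var = mu + alpha * mu^2``.  ``library_sizes`` is either one total per
    sample or a scalar applied to all samples.  ``de_lfc_threshold``
    defines which planted fold changes count as true differential
    expression in the truth table (|log2fc| >= threshold); smaller
    planted shifts model ordinary biological drift, not DE.
    """

    base_means: Mapping[str, float]
    n_tumor: int
    n_control: int
    group_log2fc: Mapping[str, float] = field(default_factory=dict)
    dispersion: float = 0.1
    library_sizes: Sequence[float] | float = 2_000_000.0
    de_lfc_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_means.values()):
            raise ValueError("base_means must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_tumor < 1 or self.n_control < 1:
            raise ValueError("each group needs at least 1 sample")
        libs = self._libs()
        if np.any(libs <= 0):
            raise ValueError("library sizes must be > 0")

    def _libs(self) -> np.ndarray:
        n = self.n_tumor + self.n_control
        if np.isscalar(self.library_sizes):
            return np.full(n, float(self.library_sizes))
        libs = np.asarray(self.library_sizes, dtype=float)
        if libs.shape != (n,):
            raise ValueError("library_sizes must match total sample count")
        return libs


def simulate_count_matrix(spec: CountSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (count matrix miRNA x sample, truth table).

    Counts are NB-distributed with mean
    ``base_mean / 1e6 * 2**(log2fc * is_tumor) * library_size``.
    """
    rng = np.random.default_rng(spec.seed)
    mirnas = list(spec.base_means)
    base = np.array([spec.base_means[m] for m in mirnas])
    lfc = np.array([spec.group_log2fc.get(m, 0.0) for m in mirnas])
    libs = spec._libs()
    samples = [f"T{i + 1:03d}" for i in range(spec.n_tumor)] + [
        f"C{i + 1:03d}" for i in range(spec.n_control)
    ]
    is_tumor = np.array([1.0] * spec.n_tumor + [0.0] * spec.n_control)

    mu = (base[:, None] / 1e6) * np.power(2.0, lfc[:, None] * is_tumor[None, :]) * libs[None, :]
    r = 1.0 / spec.dispersion
    p = r / (r + mu)
    counts = np.where(mu > 0, rng.negative_binomial(r, np.where(mu > 0, p, 1.0)), 0)
    matrix = pd.DataFrame(counts, index=pd.Index(mirnas, name="mirna"), columns=samples)
    truth = pd.DataFrame(
        {
            "base_mean": base,
            "log2fc": lfc,
            "is_de": np.abs(lfc) >= spec.de_lfc_threshold,
        },
        index=pd.Index(mirnas, name="mirna"),
    )
    return matrix, truth


def simulate_de_tables(
    truth: pd.DataFrame,
    n_methods: int = 3,
    sensitivity: float | Sequence[float] = 1.0,
    specificity: float | Sequence[float] = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Mock DE result tables with controlled call quality.

    Each table carries columns ``id, baseMean, log2FC, pvalue, padj``.  A
    truly-DE miRNA is called significant (padj < alpha) with probability
    *sensitivity*; a non-DE miRNA with probability 1 - *specificity*.
    """
    if n_methods < 1:
        raise ValueError("n_methods must be >= 1")
    sens = np.broadcast_to(np.asarray(sensitivity, dtype=float), (n_methods,))
    spec_ = np.broadcast_to(np.asarray(specificity, dtype=float), (n_methods,))
    if np.any((sens < 0) | (sens > 1) | (spec_ < 0) | (spec_ > 1)):
        raise ValueError("sensitivity and specificity must be in [0, 1]")

    rng = np.random.default_rng(seed)
    is_de = truth["is_de"].to_numpy()
    tables = []
    for m in range(n_methods):
        call_prob = np.where(is_de, sens[m], 1.0 - spec_[m])
        significant = rng.random(len(truth)) < call_prob
        padj = np.where(
            significant,
            rng.uniform(0.0, alpha * (1 - 1e-9), size=len(truth)),
            rng.uniform(alpha, 1.0, size=len(truth)),
        )
        pvalue = padj * rng.uniform(0.2, 1.0, size=len(truth))
        log2fc = truth["log2fc"].to_numpy() + rng.normal(0.0, 0.1, size=len(truth))
        tables.append(
            pd.DataFrame(
                {
                    "id": truth.index,
                    "baseMean": truth["base_mean"].to_numpy(),
                    "log2FC": log2fc,
                    "pvalue": pvalue,
                    "padj": padj,
                }
            )
        )
    return tables
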