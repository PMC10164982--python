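"""Shared fixtures: small, programmatically built datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirnorm.containers import CtDataset
from mirnorm.synthetic_data import CtSimSpec, simulate_ct_dataset


def build_dataset(
    ct_by_sample: dict[str, dict[str, list[float]]],
    groups: dict[str, str],
    runs: dict[str, int] | None = None,
    calibrators: set[str] | None = None,
) -> CtDataset:
    """Assemble a CtDataset from {gene: {sample: [replicates]}}."""
    genes = list(ct_by_sample)
    samples = list(next(iter(ct_by_sample.values())))
    n_rep = max(len(v) for row in ct_by_sample.values() for v in row.values())
    cols = pd.MultiIndex.from_tuples(
        [(s, r + 1) for s in samples for r in range(n_rep)],
        names=["sample", "replicate"],
    )
    data = np.full((len(genes), len(cols)), np.nan)
    for i, g in enumerate(genes):
        for j, s in enumerate(samples):
            reps = ct_by_sample[g][s]
            for r, v in enumerate(reps):
                data[i, j * n_rep + r] = v
    ct = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=cols)
    calibrators = calibrators or set()
    meta = pd.DataFrame(
        {
            "group": [groups[s] for s in samples],
            "run": [(runs or {}).get(s, 1) for s in samples],
            "is_calibrator": [s in calibrators for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return CtDataset(ct=ct, meta=meta)


@pytest.fixture
def toy_ct_matrix() -> pd.DataFrame:
    """4 genes x 5 samples, hand-picked Cts for oracle checks."""
    rng = np.random.default_rng(42)
    data = np.array(
        [
            [24.1, 24.8, 23.9, 24.5, 24.3],
            [26.0, 26.9, 25.7, 26.6, 26.2],
            [29.5, 28.7, 30.2, 29.1, 29.8],
            [22.3, 23.4, 22.1, 23.0, 22.6],
        ]
    ) + rng.normal(0, 0.05, size=(4, 5))
    return pd.DataFrame(
        data,
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene"),
        columns=[f"s{i}" for i in range(1, 6)],
    )


@pytest.fixture
def simulated_dataset() -> CtDataset:
    """A mid-size simulated cohort with a planted unstable gene (G5)."""
    spec = CtSimSpec(
        gene_baselines={f"G{i}": 24.0 + i for i in range(6)},
        group_effects={"G5": 2.0},
        n_tumor=30,
        n_control=30,
        replicate_sd=0.2,
        sample_effect_sd=0.25,
        n_runs=2,
        seed=11,
    )
    return simulate_ct_dataset(spec)
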