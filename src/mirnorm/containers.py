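"""In-memory containers and plain-text (TSV) round-tripping.

Conventions used throughout the package:

* Ct matrices are :class:`pandas.DataFrame` objects with genes (miRNAs) in
  rows and samples in columns.  Replicate-level data use a two-level column
  index ``(sample, replicate)``.
* An undetected reaction (no amplification before the detection limit) is
  stored as ``NaN`` — never as a numeric sentinel such as 40 — so that
  detection-based discard rules remain testable.
* Sample metadata is a DataFrame indexed by sample id with columns
  ``group`` (``tumor`` / ``control`` / ``pool`` for the inter-run
  calibrator), ``run`` and ``is_calibrator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

GROUP_TUMOR = "tumor"
GROUP_CONTROL = "control"
GROUP_POOL = "pool"

_REP_SEP = "__r"


@dataclass
class CtDataset:
    """Replicate-level Ct measurements plus per-sample metadata.

    ``ct`` is genes x (sample, replicate); ``meta`` is indexed by sample id
    and must cover every sample present in ``ct``.
    """

    ct: pd.DataFrame
    meta: pd.DataFrame
    detection_limit: float = 40.0

    def __post_init__(self) -> None:
        if self.ct.empty:
            raise ValueError("CtDataset requires a non-empty Ct table")
        samples = self.ct.columns.get_level_values(0).unique()
        missing = set(samples) - set(self.meta.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.ct.index)

    @property
    def samples(self) -> list[str]:
        return list(self.ct.columns.get_level_values(0).unique())

    def write(self, directory: str | Path, prefix: str = "ct") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        flat = self.ct.copy()
        flat.columns = [f"{s}{_REP_SEP}{r}" for s, r in self.ct.columns]
        flat.to_csv(directory / f"{prefix}_replicates.tsv", sep="\t", index_label="gene")
        meta = self.meta.copy()
        meta.to_csv(directory / f"{prefix}_meta.tsv", sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "ct",
             detection_limit: float = 40.0) -> "CtDataset":
        directory = Path(directory)
        flat = pd.read_csv(directory / f"{prefix}_replicates.tsv", sep="\t", index_col="gene")
        cols = [tuple(c.rsplit(_REP_SEP, 1)) for c in flat.columns]
        flat.columns = pd.MultiIndex.from_tuples(
            [(s, int(r)) for s, r in cols], names=["sample", "replicate"]
        )
        meta = pd.read_csv(directory / f"{prefix}_meta.tsv", sep="\t", index_col="sample_id")
        meta["is_calibrator"] = meta["is_calibrator"].astype(bool)
        return cls(ct=flat, meta=meta, detection_limit=detection_limit)


@dataclass
class NormalizedMatrix:
    """ΔCt values (gene x sample) relative to an endogenous-control normalizer.

    ``normalizer`` records the gene (or gene combination) whose per-sample
    geometric-mean Ct was subtracted from every target Ct.
    """

    delta_ct: pd.DataFrame
    normalizer: tuple[str, ...]

    def write(self, path: str | Path) -> None:
        self.delta_ct.to_csv(path, sep="\t", index_label="gene")


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path, index_label: str = "gene") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_label)


def split_groups(meta: pd.DataFrame, samples: Sequence[str] | None = None
                 ) -> tuple[list[str], list[str]]:
    """Return (tumor, control) sample lists, excluding calibrator pools."""
    meta = meta.loc[~meta["is_calibrator"]]
    if samples is not None:
        meta = meta.loc[meta.index.intersection(list(samples))]
    tumor = list(meta.index[meta["group"] == GROUP_TUMOR])
    control = list(meta.index[meta["group"] == GROUP_CONTROL])
    return tumor, control
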