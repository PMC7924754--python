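"""Central data container for untargeted LC-MS feature tables.

A :class:`FeatureTable` bundles three aligned pandas DataFrames:

* ``features`` — one row per mass feature (index ``feature_id``) with the
  feature's mass-to-charge ratio ``mz`` (Da) and retention time ``rt``
  (minutes);
* ``intensities`` — raw peak areas, features x samples (same index as
  ``features``, columns are sample ids);
* ``samples`` — per-sample metadata (index ``sample_id``) with the design
  factors ``root_type`` (``embryonic`` / ``postembryonic``), ``genotype``
  (``WT`` / ``bx1``) and ``replicate``.

On disk the table is a pair of CSV files: the feature table proper
(``feature_id, mz, rt, <sample columns...>``) and a sample-metadata sidecar
(``sample_id, root_type, genotype, replicate``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

ROOT_TYPES = ("embryonic", "postembryonic")
GENOTYPES = ("WT", "bx1")

FEATURES_CSV = "features.csv"
SAMPLES_CSV = "samples.csv"


@dataclass
class FeatureTable:
    features: pd.DataFrame
    intensities: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # ---------------------------------------------------------------- basics
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    def validate(self) -> None:
        feats = self.features
        if not feats.index.is_unique:
            raise ValueError("feature_ids must be unique")
        for col in ("mz", "rt"):
            if col not in feats.columns:
                raise ValueError(f"features frame is missing column {col!r}")
        if (feats["rt"] < 0).any():
            raise ValueError("retention times must be non-negative")
        if not feats.index.equals(self.intensities.index):
            raise ValueError("features and intensities must share one index")
        vals = self.intensities.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("intensities must be finite")
        if (vals < 0).any():
            raise ValueError("intensities must be non-negative")
        missing = self.intensities.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        if not self.samples.index.is_unique:
            raise ValueError("sample_ids must be unique")

    # ------------------------------------------------------------- selection
    def subset_features(self, ids: Iterable[str]) -> "FeatureTable":
        ids = pd.Index(ids)
        return FeatureTable(
            self.features.loc[ids].copy(),
            self.intensities.loc[ids].copy(),
            self.samples.copy(),
        )

    def subset_samples(self, where: dict | None) -> "FeatureTable":
        """Restrict to samples whose metadata match every key of *where*.

        ``where={"genotype": "WT"}`` keeps the wild-type columns only;
        ``where=None`` returns a copy with all samples.
        """
        if not where:
            return FeatureTable(
                self.features.copy(), self.intensities.copy(), self.samples.copy()
            )
        mask = pd.Series(True, index=self.samples.index)
        for key, val in where.items():
            mask &= self.samples[key] == val
        keep = self.samples.index[mask]
        return FeatureTable(
            self.features.copy(),
            self.intensities[keep].copy(),
            self.samples.loc[keep].copy(),
        )

    # ---------------------------------------------------------------- on disk
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        merged = pd.concat([self.features[["mz", "rt"]], self.intensities], axis=1)
        merged.to_csv(path / FEATURES_CSV, index_label="feature_id")
        self.samples.to_csv(path / SAMPLES_CSV, index_label="sample_id")

    @classmethod
    def from_dir(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        merged = pd.read_csv(path / FEATURES_CSV, index_col="feature_id")
        samples = pd.read_csv(path / SAMPLES_CSV, index_col="sample_id")
        features = merged[["mz", "rt"]]
        intensities = merged.drop(columns=["mz", "rt"])
        return cls(features, intensities, samples)

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.features.equals(other.features)
            and self.intensities.equals(other.intensities)
            and self.samples.equals(other.samples)
        )
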