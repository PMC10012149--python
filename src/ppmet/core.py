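"""Core containers shared by every pipeline stage.

A :class:`FeatureTable` is the samples x features intensity matrix of an
untargeted LC-MS experiment together with its crossover-design metadata
(participant, meal, nominal postprandial time, covariates, batch/injection
bookkeeping and pooled-QC flags). Every stage of the pipeline consumes and
produces this one object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Meal codes of the three-arm crossover: water control, low protein (12.5 g
#: whey protein isolate) and high protein (50 g).
MEALS = ("WC", "LP", "HP")

#: Nominal sampling times in minutes (fasted baseline plus four postprandial).
TIMES = (0, 30, 60, 120, 240)

META_COLUMNS = (
    "participant_id",
    "meal",
    "time_min",
    "age",
    "bmi",
    "batch",
    "injection_order",
    "is_qc",
)


class SpecificationError(ValueError):
    """An input specification violates one of its documented invariants."""


@dataclass
class FeatureTable:
    """Wide intensity matrix plus row-aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per feature
        (``mz<m/z>_rt<seconds>`` naming).
    meta
        DataFrame with the same index carrying at least the columns in
        :data:`META_COLUMNS`; class-label columns (e.g. ``ethnicity``) ride
        along untouched.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise SpecificationError("values and meta must share an identical sample index")

    # -- convenience views -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def qc_mask(self) -> pd.Series:
        if "is_qc" in self.meta:
            return self.meta["is_qc"].fillna(False).astype(bool)
        return pd.Series(False, index=self.meta.index)

    def qc_rows(self) -> "FeatureTable":
        m = self.qc_mask
        return FeatureTable(self.values.loc[m], self.meta.loc[m])

    def study_rows(self) -> "FeatureTable":
        """Rows that are real study samples (QC injections excluded)."""
        m = ~self.qc_mask
        return FeatureTable(self.values.loc[m], self.meta.loc[m])

    def select_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[:, list(feature_ids)], self.meta.copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.meta.copy())

    # -- I/O: the wide CSV + metadata CSV dialect --------------------------
    def write(self, directory: str | Path, prefix: str = "table") -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        vpath = directory / f"{prefix}_features.csv"
        mpath = directory / f"{prefix}_metadata.csv"
        self.values.to_csv(vpath, index_label="sample_id")
        self.meta.to_csv(mpath, index_label="sample_id")
        return vpath, mpath

    @classmethod
    def read(cls, values_path: str | Path, meta_path: str | Path) -> "FeatureTable":
        values = pd.read_csv(values_path, index_col="sample_id")
        meta = pd.read_csv(meta_path, index_col="sample_id")
        if "is_qc" in meta:
            meta["is_qc"] = meta["is_qc"].astype(bool)
        for col in ("time_min", "injection_order", "batch"):
            if col in meta:
                meta[col] = pd.array(np.asarray(meta[col], dtype=float)).astype("Float64")
        return cls(values, meta)


def check_no_missing(table: FeatureTable, context: str = "operation") -> None:
    if table.values.isna().to_numpy().any():
        raise ValueError(f"{context} requires a complete table; missing values present")
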