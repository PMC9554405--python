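"""The pipeline's central exchange object: a flagged concentration matrix.

Bead-array quantification yields pg/ml concentrations that may be invalid for
a cell: left-censored below the analyte's limit of detection (LOD), falling
on a standard-curve region that failed recovery QC, or saturated above the
upper asymptote.  Flags travel with the values so downstream stages can apply
censoring-aware rules instead of silently consuming substituted numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FLAG_OK = "ok"
FLAG_BELOW_LOD = "below_lod"
FLAG_OUT_OF_RECOVERY = "out_of_recovery"
FLAG_SATURATED = "saturated"
VALID_FLAGS = frozenset({FLAG_OK, FLAG_BELOW_LOD, FLAG_OUT_OF_RECOVERY, FLAG_SATURATED})

__all__ = [
    "ConcentrationMatrix",
    "FLAG_OK",
    "FLAG_BELOW_LOD",
    "FLAG_OUT_OF_RECOVERY",
    "FLAG_SATURATED",
]


@dataclass
class ConcentrationMatrix:
    """Samples x analytes concentrations (pg/ml) with per-cell validity flags.

    Parameters
    ----------
    values : DataFrame
        Rows are sample ids, columns analyte symbols.  Cells whose flag is not
        ``ok`` may be NaN (no numeric value is emitted for flagged cells by
        the quantification stage).
    flags : DataFrame
        Same shape/labels as ``values``; entries drawn from
        ``{ok, below_lod, out_of_recovery, saturated}``.
    lod : Series
        Per-analyte lower limit of detection in pg/ml (positive).
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    lod: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.flags.index) or not self.values.columns.equals(
            self.flags.columns
        ):
            raise ValueError("values and flags must share index and columns")
        bad = set(np.unique(self.flags.to_numpy())) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown flags: {sorted(bad)}")
        self.lod = self.lod.reindex(self.values.columns)
        censored_cols = self.values.columns[(self.flags == FLAG_BELOW_LOD).any(axis=0)]
        lod_c = self.lod.loc[censored_cols]
        if lod_c.isna().any() or (lod_c <= 0).any():
            raise ValueError("every censored analyte needs a positive LOD")

    # -- basic introspection -------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def analytes(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ConcentrationMatrix":
        return ConcentrationMatrix(self.values.copy(), self.flags.copy(), self.lod.copy())

    def equals(self, other: "ConcentrationMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and self.flags.equals(other.flags)
            and self.lod.equals(other.lod)
        )

    # -- I/O ------------------------------------------------------------------
    def to_csv(self, values_path, flags_path, lod_path) -> None:
        self.values.rename_axis("sample_id").to_csv(values_path)
        self.flags.rename_axis("sample_id").to_csv(flags_path)
        self.lod.rename_axis("analyte").to_frame("lod").to_csv(lod_path)

    @classmethod
    def from_csv(cls, values_path, flags_path, lod_path) -> "ConcentrationMatrix":
        values = pd.read_csv(Path(values_path), index_col="sample_id")
        flags = pd.read_csv(Path(flags_path), index_col="sample_id")
        lod = pd.read_csv(Path(lod_path), index_col="analyte")["lod"]
        return cls(values, flags, lod)
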