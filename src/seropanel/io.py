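"""Table I/O with schema validation for the pipeline's CSV conventions."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .catalogue import load_catalogue
from .matrix import ConcentrationMatrix

METADATA_SCHEMA = [
    "sample_id", "diagnosis", "status", "treatment_group",
    "binet", "rai", "ighv", "age", "sex",
]

__all__ = ["read_tables", "read_metadata", "write_metadata", "SchemaError"]


class SchemaError(ValueError):
    """An input table does not match the documented header or sample set."""


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(Path(path), dtype={"rai": str})
    missing = [c for c in METADATA_SCHEMA if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"duplicate sample ids: {dupes}")
    return meta.set_index("sample_id", drop=False)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    cols = METADATA_SCHEMA + [c for c in metadata.columns if c not in METADATA_SCHEMA]
    metadata[cols].to_csv(Path(path), index=False)


def read_tables(
    metadata_path, values_path, flags_path, lod_path, catalogue: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, ConcentrationMatrix, pd.DataFrame]:
    """Load and cross-validate metadata + concentration matrix + catalogue.

    Raises :class:`SchemaError` naming any offending column and listing
    orphan samples present in one table but not the other.
    """
    metadata = read_metadata(metadata_path)
    matrix = ConcentrationMatrix.from_csv(values_path, flags_path, lod_path)
    if catalogue is None:
        catalogue = load_catalogue()

    meta_ids = set(metadata.index)
    matrix_ids = set(matrix.samples)
    only_meta = sorted(meta_ids - matrix_ids)
    only_matrix = sorted(matrix_ids - meta_ids)
    if only_meta or only_matrix:
        raise SchemaError(
            "sample id mismatch between metadata and concentration matrix: "
            f"metadata-only={only_meta}, matrix-only={only_matrix}"
        )
    unknown = [a for a in matrix.analytes if a not in catalogue.index]
    if unknown:
        raise SchemaError(f"analytes not in catalogue: {unknown}")
    return metadata, matrix, catalogue
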