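"""Analyte catalogue for the 103-plex serum soluble-immune-factor panel.

The panel pools three bead-array assays: a 65-plex of cytokines, chemokines,
growth/regulatory factors and soluble receptors (group 1), plus two
immuno-oncology checkpoint panels split into T-cell–related (group 2) and
NK-cell–related (group 3) soluble checkpoints.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_catalogue", "panel_groups", "CatalogueError"]

#: Row excluded by default so that the shipped panel matches the study's
#: stated sizes (65 group-1 analytes, 38 checkpoints, 103 total).  The raw
#: table as assembled here carries one extra checkpoint row; see
#: docs/methods.md for the reconciliation.
_DEFAULT_EXCLUDED = ("sVISTA/sB7-H5",)


class CatalogueError(KeyError):
    """An analyte referenced by the pipeline is absent from the catalogue."""


def load_catalogue(full: bool = False) -> pd.DataFrame:
    """Load the analyte catalogue.

    Parameters
    ----------
    full : bool
        When True, return every stored row (104 analytes).  By default one
        checkpoint row is excluded so the panel sizes are 65 + 22 + 16 = 103.

    Returns
    -------
    DataFrame indexed by analyte ``symbol`` with columns
    ``group`` (1/2/3), ``target``, ``uniprot`` and ``gene``.
    """
    with resources.files("seropanel.data").joinpath("analyte_catalogue.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        cat = pd.read_csv(fh)
    if not full:
        cat = cat[~cat["symbol"].isin(_DEFAULT_EXCLUDED)]
    cat = cat.set_index("symbol", verify_integrity=True)
    return cat


def panel_groups(catalogue: pd.DataFrame) -> dict[int, list[str]]:
    """Map each panel group (1, 2, 3) to its list of analyte symbols."""
    return {int(g): list(sub.index) for g, sub in catalogue.groupby("group")}


def require_analytes(catalogue: pd.DataFrame, analytes) -> None:
    """Raise :class:`CatalogueError` if any analyte is not catalogued."""
    missing = [a for a in analytes if a not in catalogue.index]
    if missing:
        raise CatalogueError(f"analytes not in catalogue: {missing}")
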