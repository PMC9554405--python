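"""Censoring-aware preprocessing of quantified concentrations.

Left-censored cells (below the limit of detection) are substituted by 10% of
the analyte's minimum uncensored value, concentrations move to log10 where
all downstream statistics operate, and per-panel deviation-from-average
profiles summarise which analytes sit above or below their panel group's
grand mean within each clinical group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import FLAG_BELOW_LOD, FLAG_OK, ConcentrationMatrix

log = logging.getLogger(__name__)

__all__ = ["substitute_below_lod", "log10_transform", "deviation_profile"]


def substitute_below_lod(
    matrix: ConcentrationMatrix, per_group: pd.Series | None = None
) -> ConcentrationMatrix:
    """Replace below-LOD cells by 10% of the analyte's minimum measured value.

    The minimum is taken over uncensored (``ok``-flagged) values across the
    full sample set; pass ``per_group`` (a sample -> group Series) to use
    per-group minima instead.  An analyte with no uncensored value at all is
    substituted by 10% of its LOD and a warning is logged.  Flags are
    preserved for provenance, so the operation is idempotent.
    """
    out = matrix.copy()
    groups = (
        [(None, out.samples)]
        if per_group is None
        else [(g, idx) for g, idx in out.values.groupby(per_group).groups.items()]
    )
    for _, rows in groups:
        vals = out.values.loc[rows]
        flags = out.flags.loc[rows]
        for analyte in out.analytes:
            censored = flags[analyte] == FLAG_BELOW_LOD
            if not censored.any():
                continue
            ok = flags[analyte] == FLAG_OK
            if ok.any():
                fill = 0.1 * vals.loc[ok, analyte].min()
            else:
                fill = 0.1 * out.lod[analyte]
                log.warning(
                    "analyte %s fully censored; substituting 0.1 x LOD = %g", analyte, fill
                )
            out.values.loc[censored[censored].index, analyte] = fill
    return out


def log10_transform(matrix: ConcentrationMatrix) -> ConcentrationMatrix:
    """Elementwise log10 of all concentrations; flags are untouched.

    Requires strictly positive, non-missing values, which substitution
    guarantees; otherwise the pipeline was run out of order.
    """
    vals = matrix.values.to_numpy()
    if np.isnan(vals).any() or (vals <= 0).any():
        raise ValueError(
            "non-positive or missing concentrations: run substitute_below_lod first"
        )
    return ConcentrationMatrix(np.log10(matrix.values), matrix.flags.copy(), matrix.lod.copy())


def deviation_profile(
    log10_values: pd.DataFrame,
    clinical_groups: pd.Series,
    catalogue: pd.DataFrame,
    dead_band: float = 0.0,
) -> pd.DataFrame:
    """Deviation of each analyte's mean from its panel group's grand mean.

    For every clinical group and every panel group (1/2/3), each analyte's
    mean log10 concentration is compared against the grand mean over the
    analytes of that panel group; the signed difference and an above/below
    direction call (with optional dead band, default 0) are returned.

    Returns a tidy frame ``clinical_group, panel_group, analyte, mean,
    grand_mean, deviation, direction`` whose signed deviations sum to zero
    within each (clinical group, panel group) block by construction.
    """
    missing = [a for a in log10_values.columns if a not in catalogue.index]
    if missing:
        raise KeyError(f"analytes missing from catalogue: {missing}")
    clinical_groups = clinical_groups.reindex(log10_values.index)
    rows = []
    for cg, sub in log10_values.groupby(clinical_groups):
        means = sub.mean(axis=0)
        panel = catalogue.loc[means.index, "group"]
        for pg, analytes in means.groupby(panel):
            grand = analytes.mean()
            for analyte, m in analytes.items():
                dev = m - grand
                if dev > dead_band:
                    direction = "above"
                elif dev < -dead_band:
                    direction = "below"
                else:
                    direction = "none"
                rows.append((cg, int(pg), analyte, m, grand, dev, direction))
    return pd.DataFrame(
        rows,
        columns=[
            "clinical_group",
            "panel_group",
            "analyte",
            "mean",
            "grand_mean",
            "deviation",
            "direction",
        ],
    )


def deviation_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Fraction of analytes above/below the panel average per block."""
    rows = []
    for (cg, pg), block in profile.groupby(["clinical_group", "panel_group"]):
        n = len(block)
        rows.append(
            (
                cg,
                pg,
                n,
                int((block["direction"] == "above").sum()),
                int((block["direction"] == "below").sum()),
                (block["direction"] == "above").mean(),
                (block["direction"] == "below").mean(),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clinical_group",
            "panel_group",
            "n_analytes",
            "n_above",
            "n_below",
            "frac_above",
            "frac_below",
        ],
    )
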