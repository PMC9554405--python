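"""Five-parameter logistic (5PL) standard curves for bead-array immunoassays.

The response model is

    y = a + (b - a) / (1 + (x / c)^d)^f

with ``y`` the net median fluorescence intensity (MFI), ``x`` the
concentration in pg/ml, ``c > 0`` an inflection-scale concentration,
``d != 0`` the slope and ``f > 0`` the asymmetry.  At ``x -> 0`` the response
tends to ``b`` and at ``x -> inf`` to ``a``; the curve is strictly monotone
between the two asymptotes for every valid coefficient set, so a closed-form
inverse exists.  Back-calculated standards must recover 70-130% of their
nominal concentration; samples falling on curve regions that fail this QC
are flagged rather than quantified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .matrix import (
    FLAG_BELOW_LOD,
    FLAG_OK,
    FLAG_OUT_OF_RECOVERY,
    FLAG_SATURATED,
    ConcentrationMatrix,
)

log = logging.getLogger(__name__)

RECOVERY_LOW = 70.0
RECOVERY_HIGH = 130.0
DUPLICATE_CV_LIMIT = 0.30

__all__ = [
    "StandardCurve",
    "RecoveryRecord",
    "FitError",
    "OutOfRangeError",
    "evaluate_5pl",
    "invert_5pl",
    "fit_5pl",
    "percent_recovery",
    "standard_recovery",
    "quantify_plate",
]


class FitError(RuntimeError):
    """5PL least-squares fit failed or produced a degenerate curve."""


class OutOfRangeError(ValueError):
    """Intensity outside the curve's open asymptote interval.

    ``side`` is ``"below_range"`` (beyond the zero-concentration asymptote)
    or ``"saturated"`` (beyond the infinite-concentration asymptote).
    """

    def __init__(self, side: str, y: float):
        self.side = side
        super().__init__(f"intensity {y} out of curve range ({side})")


@dataclass(frozen=True)
class StandardCurve:
    a: float
    b: float
    c: float
    d: float
    f: float
    lod_low: float = float("nan")
    lod_high: float = float("nan")
    analyte: str = ""
    residual_norm: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("c must be positive")
        if self.d == 0:
            raise ValueError("d must be nonzero")
        if not self.f > 0:
            raise ValueError("f must be positive")

    @property
    def y_at_zero(self) -> float:
        """Asymptotic response as concentration -> 0."""
        return self.b if self.d > 0 else self.a

    @property
    def y_at_inf(self) -> float:
        """Asymptotic response as concentration -> infinity."""
        return self.a if self.d > 0 else self.b


@dataclass(frozen=True)
class RecoveryRecord:
    level: float
    observed: float
    expected: float
    percent: float
    in_range: bool


def evaluate_5pl(curve: StandardCurve, x):
    """Response at concentration ``x`` (pg/ml, strictly positive)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentration must be strictly positive")
    y = curve.a + (curve.b - curve.a) / (1.0 + (x / curve.c) ** curve.d) ** curve.f
    return float(y) if y.ndim == 0 else y


def invert_5pl(curve: StandardCurve, y: float) -> float:
    """Closed-form inverse: concentration at response ``y``.

    ``y`` must lie strictly between the curve's asymptotes; otherwise an
    :class:`OutOfRangeError` reports on which side it falls.
    """
    a, b, c, d, f = curve.a, curve.b, curve.c, curve.d, curve.f
    lo, hi = min(a, b), max(a, b)
    if not (lo < y < hi):
        outside_zero_end = abs(y - curve.y_at_zero) <= abs(y - curve.y_at_inf)
        raise OutOfRangeError("below_range" if outside_zero_end else "saturated", y)
    return c * (((b - a) / (y - a)) ** (1.0 / f) - 1.0) ** (1.0 / d)


def percent_recovery(observed: float, expected: float, level: float | None = None) -> RecoveryRecord:
    """Standard recovery: (observed / expected) x 100, accepted in [70, 130]."""
    if not expected > 0:
        raise ValueError("expected concentration must be positive")
    pct = 100.0 * observed / expected
    return RecoveryRecord(
        level=expected if level is None else level,
        observed=observed,
        expected=expected,
        percent=pct,
        in_range=RECOVERY_LOW <= pct <= RECOVERY_HIGH,
    )


def _5pl_residuals(params, x, y):
    a, b, c, d, f = params
    return a + (b - a) / (1.0 + (x / c) ** d) ** f - y


def fit_5pl(standards, analyte: str = "", lod_low: float = float("nan"),
            lod_high: float = float("nan")) -> StandardCurve:
    """Least-squares 5PL fit to ``standards`` = [(concentration, intensity)].

    Needs at least six distinct standard levels.  Initialisation takes the
    asymptotes from the intensities at the extreme levels, ``c`` from the
    level nearest mid-response, ``d = +/-1`` (both signs tried, best kept)
    and ``f = 1``.  Raises :class:`FitError` on flat data or non-convergence.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (concentration, intensity) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 6:
        raise ValueError("need at least 6 distinct standard levels")
    if np.ptp(y) <= 1e-12 * max(1.0, abs(np.mean(y))):
        raise FitError("flat standard series: no response range to fit")

    order = np.argsort(x)
    b0 = y[order[0]]  # response at lowest concentration
    a0 = y[order[-1]]
    mid = 0.5 * (a0 + b0)
    c0 = x[np.argmin(np.abs(y - mid))]
    if c0 <= 0:
        c0 = np.median(x[x > 0])

    best = None
    for d0, d_bounds in ((1.0, (1e-9, np.inf)), (-1.0, (-np.inf, -1e-9))):
        lower = [-np.inf, -np.inf, 1e-12, d_bounds[0], 1e-9]
        upper = [np.inf, np.inf, np.inf, d_bounds[1], np.inf]
        try:
            res = least_squares(
                _5pl_residuals,
                x0=[a0, b0, c0, d0, 1.0],
                bounds=(lower, upper),
                args=(x, y),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=20000,
            )
        except Exception:  # numerical failure on one branch is not fatal
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("5PL fit did not converge")
    a, b, c, d, f = best.x
    return StandardCurve(
        a=a, b=b, c=c, d=d, f=f,
        lod_low=lod_low, lod_high=lod_high, analyte=analyte,
        residual_norm=float(np.linalg.norm(best.fun)),
    )


# ---------------------------------------------------------------------------
# Plate quantification
# ---------------------------------------------------------------------------

def _averaged_standards(std_rows: pd.DataFrame, analyte: str) -> pd.Series:
    """Mean MFI per standard level; duplicates disagreeing > 30% CV logged."""
    grouped = std_rows.groupby("level")["mfi"]
    means = grouped.mean()
    for level, g in grouped:
        if len(g) > 1 and g.mean() != 0:
            cv = g.std(ddof=1) / abs(g.mean())
            if cv > DUPLICATE_CV_LIMIT:
                log.warning(
                    "analyte %s standard level %g duplicates disagree (CV=%.2f)",
                    analyte, level, cv,
                )
    return means.sort_index()


def standard_recovery(readings: pd.DataFrame, curves: dict[str, StandardCurve]) -> pd.DataFrame:
    """Back-calculate every standard level through its curve.

    Duplicate standard wells are averaged before inversion.  Returns a tidy
    frame ``analyte, level, observed, percent, in_range``; levels whose mean
    intensity cannot be inverted fail recovery.
    """
    std = readings[readings["level"].notna()]
    rows = []
    for analyte, sub in std.groupby("analyte", sort=False):
        curve = _require_curve(curves, analyte)
        for level, mfi in _averaged_standards(sub, analyte).items():
            try:
                obs = invert_5pl(curve, mfi)
                rec = percent_recovery(obs, float(level))
                rows.append((analyte, float(level), obs, rec.percent, rec.in_range))
            except OutOfRangeError:
                rows.append((analyte, float(level), math.nan, math.nan, False))
    return pd.DataFrame(rows, columns=["analyte", "level", "observed", "percent", "in_range"])


def _require_curve(curves: dict[str, StandardCurve], analyte: str) -> StandardCurve:
    if analyte not in curves:
        raise KeyError(f"no standard curve configured for analyte {analyte!r}")
    return curves[analyte]


def _segment_valid(conc: float, levels: np.ndarray, passed: np.ndarray) -> bool:
    """Validity of the inter-standard segment a concentration falls in.

    Standards bound segments of the curve; a sample is accurate only if the
    standards bracketing its concentration both passed recovery (below the
    lowest / above the highest level, the nearest standard alone governs).
    """
    if conc < levels[0]:
        return bool(passed[0])
    if conc >= levels[-1]:
        return bool(passed[-1])
    i = int(np.searchsorted(levels, conc, side="right") - 1)
    return bool(passed[i] and passed[i + 1])


def quantify_plate(
    readings: pd.DataFrame, curves: dict[str, StandardCurve]
) -> ConcentrationMatrix:
    """Convert a plate of MFI readings to a flagged concentration matrix.

    ``readings`` columns: ``well, sample_id, analyte, level, mfi`` with
    ``level`` set (expected pg/ml) for standard wells and empty for samples.
    Sample wells are inverted through their analyte's curve; intensities
    outside the asymptotes are flagged ``below_lod`` / ``saturated``, values
    below the manufacturer's lower detection limit are flagged ``below_lod``,
    and samples landing on curve segments whose bounding standards failed the
    70-130% recovery window are flagged ``out_of_recovery``.  Flagged cells
    never carry a numeric concentration.
    """
    recovery = standard_recovery(readings, curves)
    samples = readings[readings["level"].isna()]
    for analyte in samples["analyte"].unique():
        _require_curve(curves, analyte)

    sample_ids = list(dict.fromkeys(samples["sample_id"]))
    analytes = list(dict.fromkeys(samples["analyte"]))
    values = pd.DataFrame(np.nan, index=pd.Index(sample_ids, name="sample_id"), columns=analytes)
    flags = pd.DataFrame(FLAG_OK, index=values.index, columns=analytes)

    rec_by_analyte = {a: g.sort_values("level") for a, g in recovery.groupby("analyte")}
    for _, row in samples.iterrows():
        analyte, sid = row["analyte"], row["sample_id"]
        curve = curves[analyte]
        try:
            conc = invert_5pl(curve, row["mfi"])
        except OutOfRangeError as err:
            flags.loc[sid, analyte] = (
                FLAG_BELOW_LOD if err.side == "below_range" else FLAG_SATURATED
            )
            continue
        if not math.isnan(curve.lod_low) and conc < curve.lod_low:
            flags.loc[sid, analyte] = FLAG_BELOW_LOD
            continue
        rec = rec_by_analyte.get(analyte)
        if rec is not None and len(rec) and not _segment_valid(
            conc, rec["level"].to_numpy(), rec["in_range"].to_numpy()
        ):
            flags.loc[sid, analyte] = FLAG_OUT_OF_RECOVERY
            continue
        values.loc[sid, analyte] = conc

    lod = {}
    for a in analytes:
        lod_a = curves[a].lod_low
        if math.isnan(lod_a):
            # no manufacturer limit supplied: fall back to the lowest standard
            rec = rec_by_analyte.get(a)
            lod_a = float(rec["level"].min()) if rec is not None and len(rec) else math.nan
        lod[a] = lod_a
    return ConcentrationMatrix(values, flags, pd.Series(lod, name="lod"))
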