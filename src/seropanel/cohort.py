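"""Seeded synthetic cohorts emulating a CLL/MBLhi serum profiling study.

The generator draws per-analyte concentrations log-normally: on the log10
scale each value is a per-analyte baseline mean plus an additive clinical
group shift, optional age/sex covariate effects, a biological spread term and
measurement noise.  Values landing below the analyte's limit of detection are
left-censored (flag + recorded LOD, never a substituted number).  The default
configuration mirrors the margins of the published 67-patient cohort
(10 MBLhi / 57 CLL; 29 F / 38 M; 45 mutated / 22 unmutated IGHV; Binet
54/6/7; Rai 45/5/10/1/6; 42 stable vs 15 progressing), with planted group
effects on the analytes the study's biomarker panels single out.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .catalogue import load_catalogue
from .matrix import FLAG_BELOW_LOD, FLAG_OK, ConcentrationMatrix
from .quantification import StandardCurve, evaluate_5pl

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "default_config",
    "generate_cohort",
    "simulate_plate_readings",
    "summarize_cohort",
    "round_half_up",
]

GROUPS = ("MBLhi", "c-CLL", "p-CLL", "CLL-PFT", "CLL-TFT")

METADATA_COLUMNS = [
    "sample_id", "diagnosis", "status", "treatment_group",
    "binet", "rai", "ighv", "age", "sex",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (matching printed-table style percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Recipe for one synthetic cohort.

    ``effect_table`` maps analyte -> {group: additive log10 shift}; a group
    absent from an analyte's map sits at baseline, so any pairwise contrast's
    true effect is the difference of the two group entries.
    """

    group_sizes: dict[str, int]
    analytes: tuple[str, ...]
    base_log10_mean: dict[str, float]
    lod: dict[str, float]
    base_log10_sd: float = 0.35
    noise_sd: float = 0.15
    effect_table: dict[str, dict[str, float]] = field(default_factory=dict)
    ighv_effects: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    metadata_quotas: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ConfigurationError("at least one clinical group required")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ConfigurationError(f"group {g!r} needs n >= 2, got {n}")
        if not self.base_log10_sd > 0:
            raise ConfigurationError("base_log10_sd must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        for a in self.analytes:
            if a not in self.base_log10_mean:
                raise ConfigurationError(f"no baseline mean for analyte {a!r}")
            if not self.lod.get(a, 0) > 0:
                raise ConfigurationError(f"LOD for analyte {a!r} must be positive")
        for a, shifts in self.effect_table.items():
            if a not in self.analytes:
                raise ConfigurationError(f"effect on unknown analyte {a!r}")
            for g in shifts:
                if g not in self.group_sizes:
                    raise ConfigurationError(f"effect on unknown group {g!r}")
        for a in self.ighv_effects:
            if a not in self.analytes:
                raise ConfigurationError(f"IGHV effect on unknown analyte {a!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects of a synthetic cohort, for recovery checks."""

    effects: pd.DataFrame  # tidy: analyte, group, shift
    discriminative: dict[str, tuple[str, ...]]  # task name -> analytes

    def shift_between(self, analyte: str, group_a: str, group_b: str) -> float:
        sub = self.effects[self.effects["analyte"] == analyte].set_index("group")["shift"]
        return float(sub.get(group_a, 0.0) - sub.get(group_b, 0.0))


# ---------------------------------------------------------------------------
# Default study-sized configuration
# ---------------------------------------------------------------------------

#: Analytes the published biomarker panels put forward, used as the planted
#: discriminative sets of the default cohort.
STAGE_PANEL = ("sCD47/sIAP", "sCD27", "sTIMD-4", "sIL-2R", "sULBP-1")
EVOLUTION_PANEL = ("sCD48/sBLAST-1", "sCD27", "sArginase-1", "sLAG-3", "IL-4", "sIL-2R")
TREATMENT_PANEL = ("sIL-2R", "sTIMD-4", "sSiglec-9", "IFN gamma", "sPD-L1",
                   "sCD48/sBLAST-1", "sLAG-3")
IGHV_PANEL = ("CXCL10/IP-10", "sCD134/sOX40", "sULBP-1", "sLAG-3")

TABLE1_QUOTAS = {
    "sex": {"F": 29, "M": 38},
    "ighv": {"mutated": 45, "unmutated": 22},
    "binet": {"A": 54, "B": 6, "C": 7},
    "rai": {"0": 45, "I": 5, "II": 10, "III": 1, "IV": 6},
    "age_le_65": 24,
}


def default_config(seed: int = 0) -> CohortConfig:
    """The 67-sample x 103-analyte default cohort.

    Five mutually exclusive clinical groups (10/42/5/5/5); progressing
    patients split evenly between untreated (p-CLL), pre-first-line (CLL-PFT)
    and post-first-line (CLL-TFT) sampling.  Baseline log10 means are spread
    over roughly 10-10,000 pg/ml; panel analytes carry 0.5-log10 group
    shifts; LODs sit 2.5 baseline SDs below each analyte's mean so a small
    tail of values is left-censored.
    """
    cat = load_catalogue()
    analytes = tuple(cat.index)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0BA5E]))
    base = {a: float(m) for a, m in zip(analytes, rng.uniform(1.0, 4.0, len(analytes)))}
    sd = 0.35
    lod = {a: 10 ** (base[a] - 2.5 * sd) for a in analytes}

    effects: dict[str, dict[str, float]] = {a: {} for a in set(
        STAGE_PANEL + EVOLUTION_PANEL + TREATMENT_PANEL
    )}
    cll_groups = ("c-CLL", "p-CLL", "CLL-PFT", "CLL-TFT")
    for i, a in enumerate(STAGE_PANEL):
        shift = 0.5 if i % 2 == 0 else -0.5  # direction alternates across the panel
        for g in cll_groups:
            effects[a][g] = effects[a].get(g, 0.0) + shift
    for i, a in enumerate(EVOLUTION_PANEL):
        shift = 0.5 if i % 2 == 0 else -0.5
        for g in ("p-CLL", "CLL-PFT", "CLL-TFT"):
            effects[a][g] = effects[a].get(g, 0.0) + shift
    for i, a in enumerate(TREATMENT_PANEL):
        shift = 0.5 if i % 2 == 0 else -0.5
        effects[a]["CLL-TFT"] = effects[a].get("CLL-TFT", 0.0) + shift
    # IGHV-dependent shifts (applied to unmutated patients regardless of group)
    ighv_effects = {a: (0.5 if i % 2 == 0 else -0.5) for i, a in enumerate(IGHV_PANEL)}

    return CohortConfig(
        group_sizes={"MBLhi": 10, "c-CLL": 42, "p-CLL": 5, "CLL-PFT": 5, "CLL-TFT": 5},
        analytes=analytes,
        base_log10_mean=base,
        lod=lod,
        base_log10_sd=sd,
        noise_sd=0.15,
        effect_table=effects,
        ighv_effects=ighv_effects,
        metadata_quotas=TABLE1_QUOTAS,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _quota_assign(rng: np.random.Generator, n: int, counts: dict[str, int]) -> np.ndarray:
    """Shuffle a label vector with exact per-category counts."""
    total = sum(counts.values())
    if total != n:
        raise ConfigurationError(f"quota counts sum to {total}, expected {n}")
    labels = np.repeat(list(counts), list(counts.values()))
    rng.shuffle(labels)
    return labels


def _generate_metadata(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    sizes = config.group_sizes
    n = sum(sizes.values())
    group = np.repeat(list(sizes), list(sizes.values()))
    sample_id = [f"S{i + 1:03d}" for i in range(n)]

    diagnosis = np.where(group == "MBLhi", "MBLhi", "CLL")
    status = np.select(
        [group == "MBLhi", group == "c-CLL"], ["NA", "stable"], default="progression"
    )
    treatment = np.select(
        [group == "MBLhi", group == "CLL-PFT", group == "CLL-TFT"],
        ["NA", "PFT", "TFT"],
        default="untreated",
    )

    q = config.metadata_quotas
    if q is not None:
        sex = _quota_assign(rng, n, q["sex"])
        ighv = _quota_assign(rng, n, q["ighv"])
        binet = np.full(n, "NA", dtype=object)
        binet[:] = _quota_assign(rng, n, q["binet"])
        rai = _quota_assign(rng, n, q["rai"])
        n_young = q["age_le_65"]
        young = rng.permutation(n) < n_young
        age = np.where(
            young,
            np.floor(rng.uniform(36, 66, n)),
            np.floor(rng.uniform(66, 92, n)),
        ).astype(int)
    else:
        sex = rng.choice(["F", "M"], size=n)
        ighv = rng.choice(["mutated", "unmutated"], size=n)
        binet = rng.choice(["A", "B", "C"], size=n, p=[0.8, 0.1, 0.1])
        rai = rng.choice(["0", "I", "II", "III", "IV"], size=n, p=[0.65, 0.1, 0.15, 0.02, 0.08])
        age = np.floor(rng.uniform(36, 92, n)).astype(int)

    meta = pd.DataFrame(
        {
            "sample_id": sample_id,
            "diagnosis": diagnosis,
            "status": status,
            "treatment_group": treatment,
            "binet": binet,
            "rai": rai,
            "ighv": ighv,
            "age": age,
            "sex": sex,
            "group": group,
        }
    ).set_index("sample_id", drop=False)
    return meta


def _analyte_rng(seed: int, analyte: str) -> np.random.Generator:
    """Per-analyte substream keyed by name, so adding analytes is non-perturbing."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(analyte.encode("utf-8"))])
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, ConcentrationMatrix, GroundTruth]:
    """Draw metadata, true concentrations and ground truth for one cohort.

    Deterministic under ``config.seed``: identical configs give bit-identical
    outputs.  Cells whose pre-censoring concentration falls below the
    analyte's LOD are flagged ``below_lod`` and carry no value.
    """
    config.validate()
    meta_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x3E7A]))
    meta = _generate_metadata(config, meta_rng)
    n = len(meta)
    group = meta["group"].to_numpy()
    age_c = meta["age"].to_numpy(dtype=float) - meta["age"].mean()
    male = (meta["sex"] == "M").to_numpy(dtype=float)
    unmutated = (meta["ighv"] == "unmutated").to_numpy(dtype=float)

    values = pd.DataFrame(
        np.nan, index=meta.index.rename("sample_id"), columns=list(config.analytes)
    )
    flags = pd.DataFrame(FLAG_OK, index=values.index, columns=values.columns)
    for analyte in config.analytes:
        rng = _analyte_rng(config.seed, analyte)
        mu = np.full(n, config.base_log10_mean[analyte])
        for g, shift in config.effect_table.get(analyte, {}).items():
            mu[group == g] += shift
        if analyte in config.ighv_effects:
            mu += config.ighv_effects[analyte] * unmutated
        if analyte in config.covariate_effects:
            age_coef, male_shift = config.covariate_effects[analyte]
            mu += age_coef * age_c + male_shift * male
        log10_val = (
            mu
            + rng.normal(0.0, config.base_log10_sd, n)
            + rng.normal(0.0, config.noise_sd, n)
        )
        conc = 10.0 ** log10_val
        censored = conc < config.lod[analyte]
        values[analyte] = np.where(censored, np.nan, conc)
        flags.loc[censored, analyte] = FLAG_BELOW_LOD

    lod = pd.Series(config.lod, name="lod").reindex(values.columns)
    matrix = ConcentrationMatrix(values, flags, lod)

    effects = pd.DataFrame(
        [(a, g, s) for a, shifts in config.effect_table.items() for g, s in shifts.items()]
        + [(a, "IGHV:unmutated", s) for a, s in config.ighv_effects.items()],
        columns=["analyte", "group", "shift"],
    )
    truth = GroundTruth(
        effects=effects,
        discriminative={
            "stage": STAGE_PANEL,
            "evolution": EVOLUTION_PANEL,
            "treatment": TREATMENT_PANEL,
            "ighv": IGHV_PANEL,
        },
    )
    return meta, matrix, truth


# ---------------------------------------------------------------------------
# Plate simulation (inverse of quantification)
# ---------------------------------------------------------------------------

def simulate_plate_readings(
    matrix: ConcentrationMatrix,
    curves: dict[str, StandardCurve],
    noise_cv: float = 0.0,
    seed: int = 0,
    n_standards: int = 7,
) -> pd.DataFrame:
    """Forward-simulate MFI plate readings from true concentrations.

    Each sample well reads ``evaluate_5pl(curve, conc)`` with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``; a duplicated
    standard series (geometric levels centred on the curve's inflection
    scale ``c``) is appended per analyte, mimicking an assay plate.  Censored
    cells (no numeric value) produce no well.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51A7E]))
    rows = []
    well = 0
    for analyte in matrix.analytes:
        curve = curves[analyte]
        levels = curve.c * 4.0 ** np.arange(-(n_standards // 2), n_standards - n_standards // 2)
        for rep in range(2):  # standards run in duplicate
            for level in levels:
                mfi = evaluate_5pl(curve, level) * (1.0 + rng.normal(0.0, noise_cv))
                rows.append((f"W{well:05d}", "", analyte, level, mfi))
                well += 1
        for sid in matrix.samples:
            conc = matrix.values.loc[sid, analyte]
            if pd.isna(conc):
                continue
            if conc <= 0:
                raise ValueError(f"concentration out of curve domain: {analyte}/{sid}")
            mfi = evaluate_5pl(curve, conc) * (1.0 + rng.normal(0.0, noise_cv))
            rows.append((f"W{well:05d}", sid, analyte, np.nan, mfi))
            well += 1
    return pd.DataFrame(rows, columns=["well", "sample_id", "analyte", "level", "mfi"])


def synthetic_curves(config: CohortConfig) -> dict[str, StandardCurve]:
    """Plausible 5PL response curves for each configured analyte.

    Responses rise from a background of ~50 MFI to ~30,000 MFI with the
    inflection-scale concentration at the analyte's baseline mean, so every
    simulated concentration sits well inside the monotone range.
    """
    return {
        a: StandardCurve(
            a=50.0,
            b=30000.0,
            c=10.0 ** config.base_log10_mean[a],
            d=-1.3,
            f=1.2,
            lod_low=config.lod[a],
            analyte=a,
        )
        for a in config.analytes
    }


# ---------------------------------------------------------------------------
# Table-1 style summary
# ---------------------------------------------------------------------------

_SUMMARY_FIELDS = {
    "sex": ("F", "M"),
    "age_band": ("<=65", ">65"),
    "diagnosis": ("MBLhi", "CLL"),
    "status": ("stable", "progression"),
    "binet": ("A", "B", "C"),
    "rai": ("0", "I", "II", "III", "IV"),
    "treatment_group": ("PFT", "TFT", "untreated"),
    "ighv": ("mutated", "unmutated"),
}


def summarize_cohort(metadata: pd.DataFrame) -> pd.DataFrame:
    """Frequency/percentage summary of the cohort's categorical fields.

    Percentages are taken over the non-missing values of each field and
    rounded half-up to one decimal, the printed-table convention.  Returns a
    tidy frame ``field, category, n, pct``; an empty cohort yields an empty
    summary.
    """
    if metadata.empty:
        return pd.DataFrame(columns=["field", "category", "n", "pct"])
    meta = metadata.copy()
    meta["age_band"] = np.where(meta["age"] <= 65, "<=65", ">65")
    rows = []
    for fld, categories in _SUMMARY_FIELDS.items():
        if fld not in meta.columns:
            continue
        col = meta[fld].astype(str)
        col = col[col != "NA"]
        total = len(col)
        if total == 0:
            continue
        counts = col.value_counts()
        for cat in categories:
            c = int(counts.get(cat, 0))
            if c == 0 and cat not in counts:
                continue
            rows.append((fld, cat, c, round_half_up(100.0 * c / total, 1)))
    return pd.DataFrame(rows, columns=["field", "category", "n", "pct"])
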