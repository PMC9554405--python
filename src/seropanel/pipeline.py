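"""End-to-end pipeline runner chaining every analysis stage.

Stage order: (optional plate quantification) -> below-LOD substitution ->
log10 -> deviation profiling -> adaptive univariate statistics -> moderated
linear model -> mRMR stability ranking -> decision-tree panels.  Every
intermediate table is written as tidy CSV, a manifest records the config
hash, seed and output checksums, and a human-readable report collects the
headline results.  A single global seed fans out to per-stage sub-seeds, so
a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .adaptive import spearman_matrix, univariate_screen
from .catalogue import load_catalogue
from .cohort import (
    CohortConfig,
    default_config,
    generate_cohort,
    simulate_plate_readings,
    summarize_cohort,
    synthetic_curves,
)
from .io import read_tables, write_metadata
from .matrix import ConcentrationMatrix
from .moderated import SIG_THRESHOLDS, ModeratedLinearModel
from .mrmr import stability_select
from .preprocessing import (
    deviation_profile,
    deviation_summary,
    log10_transform,
    substitute_below_lod,
)
from .trees import extract_panel_rules, grow_tree, kfold_evaluate

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

#: classification tasks: name -> function(metadata) -> labels Series
def _diagnosis_labels(meta: pd.DataFrame) -> pd.Series:
    return meta["diagnosis"]


def _evolution_labels(meta: pd.DataFrame) -> pd.Series:
    lab = meta["group"].replace({"CLL-PFT": "p-CLL", "CLL-TFT": "p-CLL"})
    return lab


def _ighv_labels(meta: pd.DataFrame) -> pd.Series:
    return meta["ighv"]


TASKS = {
    "diagnosis": _diagnosis_labels,
    "evolution": _evolution_labels,
    "ighv": _ighv_labels,
}


@dataclass
class PipelineConfig:
    """Structured configuration for :func:`run_pipeline`.

    ``inputs`` is either ``{"synthetic": true}`` (default study-sized cohort)
    or a mapping of CSV paths ``{metadata, values, flags, lod}``.
    """

    seed: int = 0
    outdir: str = "seropanel_out"
    inputs: dict = field(default_factory=lambda: {"synthetic": True})
    quantify: dict = field(default_factory=lambda: {"enabled": False, "noise_cv": 0.0})
    stats: dict = field(default_factory=lambda: {"alpha": 0.05, "spearman": False})
    mrmr: dict = field(default_factory=lambda: {"n_rep": 1000, "frac": 0.8, "bins": 3, "k": 20})
    tree: dict = field(default_factory=lambda: {"max_depth": 4, "min_leaf": 3, "k": 5})
    tasks: list = field(default_factory=lambda: ["diagnosis", "evolution", "ighv"])
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls(**{k: v for k, v in raw.items() if k in known})
        return base

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _stage(name: str, t0: float, **info) -> None:
    log.info("stage=%s duration=%.2fs %s", name, time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in info.items()))


def _load_inputs(config: PipelineConfig):
    if config.inputs.get("synthetic", False):
        cohort_cfg = default_config(seed=config.seed)
        meta, matrix, truth = generate_cohort(cohort_cfg)
        return meta, matrix, load_catalogue(), cohort_cfg
    paths = config.inputs
    meta, matrix, cat = read_tables(
        paths["metadata"], paths["values"], paths["flags"], paths["lod"]
    )
    if "group" not in meta.columns:
        raise ValueError("metadata must carry a 'group' column for the analysis grouping")
    return meta, matrix, cat, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and write the report bundle.

    Returns a dict of in-memory results keyed by stage; all tables are also
    written under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    t0 = time.perf_counter()
    meta, matrix, catalogue, cohort_cfg = _load_inputs(config)
    write_metadata(meta, out / "metadata.csv")
    matrix.to_csv(out / "concentrations.csv", out / "flags.csv", out / "lod.csv")
    _stage("load", t0, samples=matrix.shape[0], analytes=matrix.shape[1])

    if config.quantify.get("enabled", False):
        if cohort_cfg is None:
            raise ValueError("plate quantification requires the synthetic input block")
        t0 = time.perf_counter()
        curves = synthetic_curves(cohort_cfg)
        plate = simulate_plate_readings(
            matrix, curves,
            noise_cv=float(config.quantify.get("noise_cv", 0.0)),
            seed=config.seed,
        )
        plate.to_csv(out / "plate.csv", index=False)
        from .quantification import quantify_plate

        quantified = quantify_plate(plate, curves)
        # censored wells produced no reading; restore their flags from the truth
        quantified.flags[matrix.flags == "below_lod"] = "below_lod"
        quantified.values = quantified.values.reindex(
            index=matrix.samples, columns=matrix.analytes
        )
        quantified.flags = quantified.flags.reindex(
            index=matrix.samples, columns=matrix.analytes
        ).fillna("below_lod")
        matrix = ConcentrationMatrix(quantified.values, quantified.flags, matrix.lod)
        matrix.to_csv(out / "quantified.csv", out / "quantified_flags.csv", out / "lod.csv")
        _stage("quantify", t0, wells=len(plate))

    t0 = time.perf_counter()
    table1 = summarize_cohort(meta)
    table1.to_csv(out / "cohort_summary.csv", index=False)
    imputed = substitute_below_lod(matrix)
    logm = log10_transform(imputed)
    logm.values.rename_axis("sample_id").to_csv(out / "log10.csv")
    results["log10"] = logm
    results["cohort_summary"] = table1
    _stage("preprocess", t0, censored=int((matrix.flags == "below_lod").sum().sum()))

    t0 = time.perf_counter()
    profile = deviation_profile(logm.values, meta["diagnosis"], catalogue)
    profile.to_csv(out / "deviation_profile.csv", index=False)
    dev_summary = deviation_summary(profile)
    dev_summary.to_csv(out / "deviation_summary.csv", index=False)
    results["deviation"] = dev_summary
    _stage("deviation", t0, blocks=len(dev_summary))

    alpha = float(config.stats.get("alpha", 0.05))
    stats_tables = {}
    t0 = time.perf_counter()
    for task in config.tasks:
        labels = TASKS[task](meta)
        tbl = univariate_screen(logm.values, labels, alpha=alpha)
        tbl.to_csv(out / f"stats_{task}.csv", index=False)
        stats_tables[task] = tbl
    if config.stats.get("spearman", False):
        rho, _ = spearman_matrix(logm.values)
        rho.to_csv(out / "spearman.csv")
    results["stats"] = stats_tables
    _stage("adaptive_tests", t0, tasks=len(stats_tables))

    t0 = time.perf_counter()
    model = ModeratedLinearModel.from_cohort(logm.values, meta, grouping="group")
    fit = model.fit()
    fit.contrast_frame().to_csv(out / "moderated_model.csv", index=False)
    results["moderated"] = fit
    _stage("moderated_linear", t0, prior_df=f"{fit.prior.df0:g}")

    t0 = time.perf_counter()
    mrmr_cfg = config.mrmr
    rankings = {}
    for task in config.tasks:
        labels = TASKS[task](meta)
        ranking = stability_select(
            logm.values,
            labels,
            n_rep=int(mrmr_cfg.get("n_rep", 1000)),
            frac=float(mrmr_cfg.get("frac", 0.8)),
            bins=int(mrmr_cfg.get("bins", 3)),
            k=int(mrmr_cfg.get("k", 20)),
            seed=config.seed,
        )
        ranking.table.to_csv(out / f"mrmr_{task}.csv")
        rankings[task] = ranking
    results["mrmr"] = rankings
    _stage("mrmr_stability", t0, n_rep=mrmr_cfg.get("n_rep", 1000))

    t0 = time.perf_counter()
    tree_cfg = config.tree
    panels = {}
    for task in config.tasks:
        labels = TASKS[task](meta)
        panel = rankings[task].top(5)
        values = imputed.values[panel]
        cv = kfold_evaluate(
            values, labels,
            k=int(tree_cfg.get("k", 5)),
            seed=config.seed,
            max_depth=int(tree_cfg.get("max_depth", 4)),
            min_leaf=int(tree_cfg.get("min_leaf", 3)),
        )
        tree = grow_tree(
            values, labels,
            max_depth=int(tree_cfg.get("max_depth", 4)),
            min_leaf=int(tree_cfg.get("min_leaf", 3)),
        )
        rules = extract_panel_rules(tree)
        cv.confusion.counts.to_csv(out / f"confusion_{task}.csv")
        (out / f"rules_{task}.txt").write_text("\n".join(rules) + "\n", encoding="utf-8")
        panels[task] = {"panel": panel, "cv": cv, "rules": rules}
    results["panels"] = panels
    _stage("panel_trees", t0, tasks=len(panels))

    report = _render_report(config, table1, dev_summary, fit, rankings, panels)
    (out / "report.txt").write_text(report, encoding="utf-8")
    manifest = _manifest(config, out)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    results["manifest"] = manifest
    return results


def _render_report(config, table1, dev_summary, fit, rankings, panels) -> str:
    lines = ["Serum soluble-immune-factor analysis report", "=" * 44, ""]
    lines.append("Cohort composition")
    for _, row in table1.iterrows():
        lines.append(f"  {row['field']}: {row['category']} n={row['n']} ({row['pct']}%)")
    lines.append("")
    lines.append("Deviation from panel-group average (fraction of analytes)")
    for _, row in dev_summary.iterrows():
        lines.append(
            f"  {row['clinical_group']} / group {row['panel_group']}: "
            f"{row['n_above']}/{row['n_analytes']} above, "
            f"{row['n_below']}/{row['n_analytes']} below"
        )
    lines.append("")
    lines.append(fit.summary())
    lines.append("")
    for task, ranking in rankings.items():
        top5 = ", ".join(ranking.top(5))
        lines.append(f"mRMR stability top-5 [{task}]: {top5}")
    lines.append("")
    for task, panel in panels.items():
        lines.append(f"Panel rules [{task}] (analytes: {', '.join(panel['panel'])})")
        for rule in panel["rules"]:
            lines.append(f"  {rule}")
        lines.append(panel["cv"].summary())
        lines.append("")
    return "\n".join(lines)


def _manifest(config: PipelineConfig, out: Path) -> dict:
    checksums = {}
    for path in sorted(out.glob("*.csv")) + sorted(out.glob("*.txt")):
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "outputs_sha256": checksums,
    }
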