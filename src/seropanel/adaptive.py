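"""Conditional (distribution-adaptive) univariate testing.

Each analyte/contrast is routed to the appropriate classical test by
distributional diagnostics: Shapiro-Wilk normality per group, then Bartlett
(all groups normal) or Fligner-Killeen (otherwise) for homoscedasticity.
Two normal homoscedastic groups get Student's t, normal heteroscedastic get
Welch's t, non-normal get Wilcoxon-Mann-Whitney; with more than two groups,
one-way ANOVA or Kruskal-Wallis, followed on rejection by Tukey HSD or
BH-adjusted pairwise Wilcoxon post-hocs.  Spearman's rank correlation covers
analyte-analyte association.  Significance level defaults to 5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import bh_adjust

ALPHA = 0.05
_EXACT_MAX_PER_GROUP = 10

__all__ = [
    "Diagnostics",
    "TestResult",
    "assess_distribution",
    "select_test",
    "compare_groups",
    "route_and_test",
    "spearman_matrix",
    "univariate_screen",
]


@dataclass(frozen=True)
class Diagnostics:
    shapiro_p: dict
    normal: bool
    normality_undecidable: bool
    variance_test: str  # "bartlett" or "fligner"
    variance_p: float
    homoscedastic: bool


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    diagnostics: Diagnostics | None = None
    post_hoc: list = field(default_factory=list)  # (pair, method, p)
    analyte: str = ""
    contrast: str = ""


def _as_groups(groups) -> dict:
    if isinstance(groups, dict):
        return {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    return {i: np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def assess_distribution(groups, alpha: float = ALPHA) -> Diagnostics:
    """Per-group Shapiro-Wilk plus a variance-homogeneity test.

    A group with fewer than 3 values or zero variance has undecidable
    normality and is treated as non-normal (routing falls through to the
    nonparametric branch).  Bartlett is applied when every group passes
    normality, Fligner-Killeen otherwise; degenerate all-constant input is
    reported homoscedastic without crashing.
    """
    gdict = _as_groups(groups)
    shapiro_p: dict = {}
    undecidable = False
    for name, vals in gdict.items():
        if len(vals) < 3 or np.ptp(vals) == 0:
            shapiro_p[name] = float("nan")
            undecidable = True
        else:
            shapiro_p[name] = float(stats.shapiro(vals).pvalue)
    normal = (not undecidable) and all(p >= alpha for p in shapiro_p.values())

    arrays = list(gdict.values())
    if len(arrays) < 2:
        variance_test, variance_p = "none", float("nan")
        return Diagnostics(
            shapiro_p=shapiro_p,
            normal=normal,
            normality_undecidable=undecidable,
            variance_test=variance_test,
            variance_p=variance_p,
            homoscedastic=True,
        )
    if all(np.ptp(v) == 0 for v in arrays):
        variance_test, variance_p = "degenerate", 1.0
    elif normal:
        variance_test = "bartlett"
        variance_p = float(stats.bartlett(*arrays).pvalue)
    else:
        variance_test = "fligner"
        variance_p = float(stats.fligner(*arrays).pvalue)
    return Diagnostics(
        shapiro_p=shapiro_p,
        normal=normal,
        normality_undecidable=undecidable,
        variance_test=variance_test,
        variance_p=variance_p,
        homoscedastic=variance_p >= alpha,
    )


def select_test(diagnostics: Diagnostics, n_groups: int) -> str:
    """Route to t / welch_t / wilcoxon (2 groups) or anova / kruskal (>2)."""
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if n_groups == 2:
        if diagnostics.normal:
            return "t" if diagnostics.homoscedastic else "welch_t"
        return "wilcoxon"
    if diagnostics.normal and diagnostics.homoscedastic:
        return "anova"
    return "kruskal"


def _mannwhitney(x: np.ndarray, y: np.ndarray):
    """Two-sided Mann-Whitney U; exact for small samples.

    Both groups <= 10 without ties: exact null distribution.  Small with
    ties: exact permutation enumeration (deterministic).  Otherwise the
    normal approximation with tie and continuity correction.
    """
    small = len(x) <= _EXACT_MAX_PER_GROUP and len(y) <= _EXACT_MAX_PER_GROUP
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if small and not has_ties:
        method = "exact"
    elif small:
        n_perm = comb(len(combined), len(x))
        method = stats.PermutationMethod(n_resamples=n_perm + 1, rng=0)
    else:
        method = "asymptotic"
    return stats.mannwhitneyu(x, y, alternative="two-sided", method=method)


def compare_groups(groups, test: str, alpha: float = ALPHA,
                   diagnostics: Diagnostics | None = None) -> TestResult:
    """Run the routed test; on an omnibus rejection with >2 groups, post-hocs.

    Post-hoc pairs after ANOVA use Tukey HSD (intrinsically adjusted); after
    Kruskal-Wallis, pairwise Wilcoxon with BH adjustment within the family.
    """
    gdict = _as_groups(groups)
    if any(len(v) == 0 for v in gdict.values()):
        raise ValueError("empty group")
    names = list(gdict)
    arrays = [gdict[k] for k in names]

    if test == "t":
        res = stats.ttest_ind(*arrays, equal_var=True)
    elif test == "welch_t":
        res = stats.ttest_ind(*arrays, equal_var=False)
    elif test == "wilcoxon":
        res = _mannwhitney(*arrays)
    elif test == "anova":
        res = stats.f_oneway(*arrays)
    elif test == "kruskal":
        res = stats.kruskal(*arrays)
    else:
        raise ValueError(f"unknown test {test!r}")
    statistic, p = float(res.statistic), float(res.pvalue)

    post_hoc = []
    if len(names) > 2 and p < alpha:
        if test == "anova":
            tk = stats.tukey_hsd(*arrays)
            for i, j in combinations(range(len(names)), 2):
                post_hoc.append(((names[i], names[j]), "tukey", float(tk.pvalue[i, j])))
        else:
            pairs = list(combinations(range(len(names)), 2))
            raw = [float(_mannwhitney(arrays[i], arrays[j]).pvalue) for i, j in pairs]
            adj = bh_adjust(raw)
            for (i, j), q in zip(pairs, adj):
                post_hoc.append(((names[i], names[j]), "wilcoxon", float(q)))
    return TestResult(
        test=test, statistic=statistic, p_value=p,
        diagnostics=diagnostics, post_hoc=post_hoc,
    )


def route_and_test(groups, alpha: float = ALPHA) -> TestResult:
    """Full adaptive routing: diagnostics, test selection and execution."""
    gdict = _as_groups(groups)
    diag = assess_distribution(gdict, alpha)
    test = select_test(diag, len(gdict))
    return compare_groups(gdict, test, alpha, diagnostics=diag)


def spearman_matrix(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyte x analyte Spearman correlation (midranks for ties) with p-values.

    Constant analytes have undefined correlation and are reported missing
    (NaN), not zero.  Diagonal is exactly 1 for non-constant analytes.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 samples")
    cols = values.columns
    k = len(cols)
    arr = values.to_numpy(dtype=float)
    if k == 1:
        constant = np.ptp(arr[:, 0]) == 0
        rho = np.array([[np.nan if constant else 1.0]])
        pval = np.array([[np.nan if constant else 0.0]])
    else:
        import warnings as _warnings

        with _warnings.catch_warnings():
            # constant columns are reported as missing below, not an anomaly
            _warnings.simplefilter("ignore", stats.ConstantInputWarning)
            res = stats.spearmanr(arr, axis=0)
        rho = np.atleast_2d(np.asarray(res.statistic, dtype=float))
        pval = np.atleast_2d(np.asarray(res.pvalue, dtype=float))
        if rho.shape == (1, 1):  # scipy collapses the 2-column case to scalars
            r = float(res.statistic)
            p = float(res.pvalue)
            rho = np.array([[1.0, r], [r, 1.0]])
            pval = np.array([[0.0, p], [p, 0.0]])
    constant = np.ptp(arr, axis=0) == 0
    for i in range(k):
        rho[i, i] = np.nan if constant[i] else 1.0
        pval[i, i] = np.nan if constant[i] else 0.0
        if constant[i]:
            rho[i, :], rho[:, i] = np.nan, np.nan
            pval[i, :], pval[:, i] = np.nan, np.nan
            rho[i, i] = np.nan
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


def univariate_screen(
    log10_values: pd.DataFrame, groups: pd.Series, alpha: float = ALPHA
) -> pd.DataFrame:
    """Routed test per analyte against a clinical grouping; tidy output.

    Columns: ``analyte, test, statistic, p, posthoc_pair, posthoc_method,
    posthoc_p`` (post-hoc columns repeated per pair, empty when none).
    """
    groups = groups.reindex(log10_values.index)
    rows = []
    for analyte in log10_values.columns:
        by_group = {
            g: sub.to_numpy() for g, sub in log10_values[analyte].groupby(groups)
        }
        result = route_and_test(by_group, alpha)
        if result.post_hoc:
            for pair, method, q in result.post_hoc:
                rows.append(
                    (analyte, result.test, result.statistic, result.p_value,
                     f"{pair[0]}|{pair[1]}", method, q)
                )
        else:
            rows.append(
                (analyte, result.test, result.statistic, result.p_value, "", "", np.nan)
            )
    return pd.DataFrame(
        rows,
        columns=["analyte", "test", "statistic", "p",
                 "posthoc_pair", "posthoc_method", "posthoc_p"],
    )
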