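"""Covariate-adjusted moderated linear models for log10 concentrations.

Each analyte's log10 concentration is regressed on a cell-means (no
intercept) clinical-group factor plus IGHV mutational status, age and sex.
Per-analyte residual variances s_g^2 with d_g degrees of freedom are shrunk
toward a pooled prior by empirical Bayes: the prior (d0, s0^2) is estimated
by closed-form moment matching of log s_g^2 under a scaled-F model, the
posterior variance is

    s_post^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and contrast t-statistics use s_post with d0 + d_g degrees of freedom.
Benjamini-Hochberg controls the FDR across analytes within each contrast,
with nested significance flags at adjusted p < 0.1, 0.05 and 0.01.

The model/results split follows the statsmodels idiom:

>>> model = ModeratedLinearModel.from_cohort(log10_values, metadata)
>>> results = model.fit()
>>> results.contrast_frame()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import digamma, polygamma

from .multitest import bh_adjust

__all__ = [
    "DesignMatrix",
    "ModerationPrior",
    "ModeratedLinearModel",
    "ModeratedLinearResults",
    "build_design",
    "fit_linear_model",
    "ebayes_moderate",
    "bh_adjust",
]

SIG_THRESHOLDS = (0.1, 0.05, 0.01)


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes variance prior: d0 degrees of freedom, s0^2 scale."""

    df0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.df0 < 0:
            raise ValueError("prior df must be >= 0 (inf permitted)")
        if not self.s0_sq > 0:
            raise ValueError("prior variance must be positive")


@dataclass
class DesignMatrix:
    """No-intercept design: group indicators + IGHV + centered age + sex."""

    frame: pd.DataFrame
    group_columns: list[str]

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def contrast_vector(self, positive: str, negative) -> np.ndarray:
        """Contrast ``positive - mean(negative)`` over group columns."""
        neg = [negative] if isinstance(negative, str) else list(negative)
        c = np.zeros(self.frame.shape[1])
        cols = list(self.frame.columns)
        c[cols.index(f"group:{positive}")] = 1.0
        for g in neg:
            c[cols.index(f"group:{g}")] -= 1.0 / len(neg)
        return c


def build_design(metadata: pd.DataFrame, grouping: str = "group") -> DesignMatrix:
    """Cell-means design ``~ 0 + group + IGHV + age + sex``.

    Age is centered so the group columns read as adjusted cell means.  Raises
    :class:`CollinearityError` naming the collinear columns when the design
    is rank deficient (e.g. a group perfectly confounded with IGHV).
    """
    required = [grouping, "ighv", "age", "sex"]
    missing = [c for c in required if c not in metadata.columns]
    if missing:
        raise KeyError(f"metadata missing covariates: {missing}")
    if metadata[required].isna().any().any():
        raise ValueError("missing covariate values in metadata")

    groups = metadata[grouping].astype(str)
    levels = list(dict.fromkeys(groups))
    cols = {f"group:{g}": (groups == g).astype(float) for g in levels}
    cols["ighv_unmutated"] = (metadata["ighv"] == "unmutated").astype(float)
    cols["age_centered"] = metadata["age"].astype(float) - metadata["age"].mean()
    cols["sex_male"] = (metadata["sex"] == "M").astype(float)
    frame = pd.DataFrame(cols, index=metadata.index)

    X = frame.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = linalg.qr(X, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        dropped = [frame.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        dropped += [frame.columns[j] for j in piv[len(diag):]]
        raise CollinearityError(f"rank-deficient design; collinear columns: {dropped}")
    return DesignMatrix(frame=frame, group_columns=[f"group:{g}" for g in levels])


def default_contrasts(design: DesignMatrix) -> dict[str, np.ndarray]:
    """The four pairwise clinical contrasts, restricted to groups present."""
    have = {c.removeprefix("group:") for c in design.group_columns}
    out: dict[str, np.ndarray] = {}
    cll = [g for g in ("c-CLL", "p-CLL", "CLL-PFT", "CLL-TFT") if g in have]
    if "MBLhi" in have and cll:
        out["MBLhi_vs_CLL"] = design.contrast_vector("MBLhi", cll)
    for other, name in (("p-CLL", "cCLL_vs_pCLL"), ("CLL-PFT", "cCLL_vs_PFT"),
                        ("CLL-TFT", "cCLL_vs_TFT")):
        if "c-CLL" in have and other in have:
            out[name] = design.contrast_vector("c-CLL", other)
    if not out and len(design.group_columns) == 2:
        a = design.group_columns[0].removeprefix("group:")
        b = design.group_columns[1].removeprefix("group:")
        out[f"{a}_vs_{b}"] = design.contrast_vector(a, b)
    return out


# ---------------------------------------------------------------------------
# Per-analyte OLS
# ---------------------------------------------------------------------------

@dataclass
class LinearFits:
    coefficients: pd.DataFrame  # analytes x design columns
    sigma2: pd.Series           # residual variance s_g^2 per analyte
    df_residual: float          # d_g = n - rank
    xtx_inv: np.ndarray


def fit_linear_model(log10_values: pd.DataFrame, design: DesignMatrix) -> LinearFits:
    """Ordinary least squares per analyte against a shared design."""
    X = design.matrix
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    Y = log10_values.reindex(design.frame.index).to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("log10 matrix contains missing values; impute first")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ X.T @ Y  # p x n_analytes
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    return LinearFits(
        coefficients=pd.DataFrame(
            beta.T, index=log10_values.columns, columns=design.frame.columns
        ),
        sigma2=pd.Series(sigma2, index=log10_values.columns, name="sigma2"),
        df_residual=float(dof),
        xtx_inv=xtx_inv,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_prior(sigma2, df_residual: float) -> ModerationPrior:
    """Moment-match (d0, s0^2) from the spread of log s_g^2.

    Under the scaled-F model, e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)
    has mean log s0^2 + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2); inverting the trigamma gives d0 in closed form.  A spread
    at or below the sampling noise yields an infinite prior df (all variances
    pooled to s0^2).
    """
    s2 = np.asarray(sigma2, dtype=float)
    if s2.size < 2:
        raise ValueError("need at least 2 analytes to pool variances")
    if np.all(s2 <= 0):
        raise ValueError("all residual variances are zero; moderation undefined")
    s2 = np.where(s2 <= 0, np.min(s2[s2 > 0]) * 1e-12, s2)
    dg = df_residual
    e = np.log(s2) - digamma(dg / 2.0) + np.log(dg / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, dg / 2.0))
    if evar > 0:
        df0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(df0 / 2.0) - np.log(df0 / 2.0)))
    else:
        df0 = float("inf")
        s0_sq = float(np.exp(emean))
    return ModerationPrior(df0=df0, s0_sq=s0_sq)


def posterior_variance(sigma2, df_residual: float, prior: ModerationPrior):
    """Shrink each s_g^2 toward the prior: (d0 s0^2 + d_g s_g^2)/(d0 + d_g)."""
    s2 = np.asarray(sigma2, dtype=float)
    if np.isinf(prior.df0):
        return np.full_like(s2, prior.s0_sq)
    if prior.df0 == 0:
        return s2.copy()
    return (prior.df0 * prior.s0_sq + df_residual * s2) / (prior.df0 + df_residual)


def ebayes_moderate(
    fits: LinearFits,
    contrasts: dict[str, np.ndarray],
    prior: ModerationPrior | None = None,
) -> tuple[pd.DataFrame, ModerationPrior]:
    """Moderated t, raw and BH-adjusted p per analyte and contrast.

    ``prior=None`` estimates (d0, s0^2) from the data; pass an explicit
    :class:`ModerationPrior` to force the limiting cases (df0=0 gives the
    ordinary t, df0=inf the fully pooled variance).
    """
    s2 = fits.sigma2.to_numpy()
    if np.all(s2 < 1e-20):  # numerically zero residuals: nothing to pool
        warnings.warn("all residual variances zero; falling back to raw t", RuntimeWarning)
        prior = ModerationPrior(df0=0.0, s0_sq=1.0)
        s_post = s2.copy()
        df_total = fits.df_residual
    else:
        if prior is None:
            prior = estimate_prior(s2, fits.df_residual)
        s_post = posterior_variance(s2, fits.df_residual, prior)
        df_total = fits.df_residual + prior.df0

    rows = []
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        est = fits.coefficients.to_numpy() @ c
        v = float(c @ fits.xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / np.sqrt(s_post * v)
        t = np.where(np.isnan(t) & (est == 0), 0.0, t)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        adj = bh_adjust(np.clip(p, 0.0, 1.0))
        for analyte, e_, t_, p_, q_ in zip(fits.coefficients.index, est, t, p, adj):
            rows.append((analyte, name, e_, t_, p_, q_))
    table = pd.DataFrame(
        rows, columns=["analyte", "contrast", "estimate", "t_mod", "p", "adj_p"]
    )
    for thr in SIG_THRESHOLDS:
        table[f"sig_{thr:.2f}".rstrip("0")] = table["adj_p"] < thr
    return table, prior


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class ModeratedLinearModel:
    """Moderated linear model of analyte abundances on clinical covariates."""

    def __init__(self, log10_values: pd.DataFrame, design: DesignMatrix):
        self.endog = log10_values
        self.design = design

    @classmethod
    def from_cohort(
        cls, log10_values: pd.DataFrame, metadata: pd.DataFrame, grouping: str = "group"
    ) -> "ModeratedLinearModel":
        design = build_design(metadata.loc[log10_values.index], grouping)
        return cls(log10_values, design)

    def fit(
        self,
        contrasts: dict[str, np.ndarray] | None = None,
        prior: ModerationPrior | None = None,
    ) -> "ModeratedLinearResults":
        fits = fit_linear_model(self.endog, self.design)
        if contrasts is None:
            contrasts = default_contrasts(self.design)
        table, used_prior = ebayes_moderate(fits, contrasts, prior)
        return ModeratedLinearResults(self, fits, contrasts, table, used_prior)


class ModeratedLinearResults:
    """Estimates, moderated statistics and FDR calls from a fitted model."""

    def __init__(self, model, fits: LinearFits, contrasts, table: pd.DataFrame,
                 prior: ModerationPrior):
        self.model = model
        self.coefficients = fits.coefficients
        self.sigma2 = fits.sigma2
        self.df_residual = fits.df_residual
        self.contrasts = contrasts
        self.prior = prior
        self._table = table

    def contrast_frame(self, contrast: str | None = None) -> pd.DataFrame:
        if contrast is None:
            return self._table.copy()
        return self._table[self._table["contrast"] == contrast].reset_index(drop=True)

    def significant(self, threshold: float = 0.05) -> pd.DataFrame:
        return self._table[self._table["adj_p"] < threshold].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Moderated linear model (empirical-Bayes shrunken variances)",
            f"  samples: {self.model.design.frame.shape[0]}"
            f"   design columns: {self.model.design.frame.shape[1]}",
            f"  analytes: {self.coefficients.shape[0]}"
            f"   residual df: {self.df_residual:g}",
            f"  prior df d0: {self.prior.df0:g}   prior variance s0^2: {self.prior.s0_sq:.4g}",
            "",
            "  significant analytes (BH-adjusted p):",
        ]
        for thr in SIG_THRESHOLDS:
            per = (
                self._table[self._table["adj_p"] < thr]
                .groupby("contrast")["analyte"].nunique()
            )
            desc = ", ".join(f"{c}={int(v)}" for c, v in per.items()) or "none"
            lines.append(f"    adj p < {thr}: {desc}")
        return "\n".join(lines)
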