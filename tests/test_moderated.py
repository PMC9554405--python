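import itertools
import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from seropanel.moderated import (
    CollinearityError,
    ModeratedLinearModel,
    ModerationPrior,
    bh_adjust,
    build_design,
    default_contrasts,
    ebayes_moderate,
    estimate_prior,
    fit_linear_model,
)


def _meta(n, groups, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "group": groups,
            "ighv": rng.choice(["mutated", "unmutated"], n),
            "age": rng.uniform(40, 85, n),
            "sex": rng.choice(["F", "M"], n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestDesign:
    def test_five_group_design_has_eight_full_rank_columns(self, default_cohort):
        meta, _, _ = default_cohort
        design = build_design(meta, "group")
        assert design.frame.shape[1] == 8
        assert np.linalg.matrix_rank(design.matrix) == 8

    def test_confounded_group_raises_collinearity_error(self):
        n = 12
        meta = _meta(n, ["A"] * 6 + ["B"] * 6)
        meta["ighv"] = ["mutated"] * 6 + ["unmutated"] * 6  # group == IGHV
        with pytest.raises(CollinearityError):
            build_design(meta, "group")

    def test_projection_equals_cell_means_when_covariates_balanced(self):
        """With identical covariates, group coefficients are the group means."""
        meta = _meta(8, ["A"] * 4 + ["B"] * 4)
        meta["ighv"] = "mutated"
        meta["sex"] = "F"
        meta["age"] = 60.0
        # constant covariate columns are collinear with the group indicators,
        # so drop them and fit groups alone: coefficient = plain group mean
        design = build_design(_meta(8, ["A"] * 4 + ["B"] * 4, seed=3), "group")
        rng = np.random.default_rng(1)
        y = pd.DataFrame({"a0": rng.normal(0, 1, 8)}, index=meta.index)
        fits = fit_linear_model(y, design)
        # oracle: solve the normal equations independently
        X = design.matrix
        beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy()).ravel()
        assert np.allclose(fits.coefficients.to_numpy().ravel(), beta)


class TestOLS:
    def test_noise_free_exact_recovery(self):
        meta = _meta(20, ["A"] * 10 + ["B"] * 10, seed=2)
        design = build_design(meta, "group")
        true_beta = np.array([1.0, 2.0, -0.5, 0.01, 0.3])
        y = pd.DataFrame({"a0": design.matrix @ true_beta}, index=meta.index)
        fits = fit_linear_model(y, design)
        assert np.allclose(fits.coefficients.to_numpy().ravel(), true_beta, atol=1e-9)
        assert fits.sigma2["a0"] == pytest.approx(0.0, abs=1e-18)

    def test_hand_normal_equations_six_by_two(self):
        """Single-analyte fit equals textbook normal equations on 6x2 data."""
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0],
                      [1.0, 3.0], [1.0, 4.0], [1.0, 5.0]])
        y = np.array([1.0, 2.0, 2.5, 3.9, 5.1, 5.8])
        # manual: beta = (X'X)^-1 X'y
        xtx = X.T @ X
        beta_hand = np.linalg.inv(xtx) @ X.T @ y
        from seropanel.moderated import DesignMatrix

        frame = pd.DataFrame(X, columns=["group:A", "slope"],
                             index=[f"s{i}" for i in range(6)])
        design = DesignMatrix(frame=frame, group_columns=["group:A"])
        fits = fit_linear_model(pd.DataFrame({"a": y}, index=frame.index), design)
        assert np.allclose(fits.coefficients.loc["a"].to_numpy(), beta_hand)

    def test_sample_order_invariance(self):
        meta = _meta(16, ["A"] * 8 + ["B"] * 8, seed=4)
        rng = np.random.default_rng(4)
        y = pd.DataFrame(rng.normal(0, 1, (16, 3)), index=meta.index,
                         columns=["a0", "a1", "a2"])
        design = build_design(meta, "group")
        fits = fit_linear_model(y, design)
        perm = rng.permutation(16)
        meta_p, y_p = meta.iloc[perm], y.iloc[perm]
        fits_p = fit_linear_model(y_p, build_design(meta_p, "group"))
        aligned = fits_p.coefficients[fits.coefficients.columns]
        assert np.allclose(fits.coefficients, aligned)

    def test_underdetermined_rejected(self):
        from seropanel.moderated import DesignMatrix

        frame = pd.DataFrame(
            np.eye(3, 4), columns=["group:A", "x1", "x2", "x3"], index=["s0", "s1", "s2"]
        )
        design = DesignMatrix(frame=frame, group_columns=["group:A"])
        y = pd.DataFrame({"a": [1.0, 2.0, 3.0]}, index=frame.index)
        with pytest.raises(ValueError, match="more samples"):
            fit_linear_model(y, design)


class TestModeration:
    @pytest.fixture
    def fitted(self):
        meta = _meta(16, ["A"] * 8 + ["B"] * 8, seed=6)
        rng = np.random.default_rng(6)
        sig2 = 4 * 0.3 / rng.chisquare(4, 40)
        y = pd.DataFrame(
            rng.normal(0, 1, (16, 40)) * np.sqrt(sig2), index=meta.index,
            columns=[f"g{j}" for j in range(40)],
        )
        design = build_design(meta, "group")
        fits = fit_linear_model(y, design)
        contrast = {"A_vs_B": design.contrast_vector("A", "B")}
        return fits, contrast

    def test_zero_prior_df_equals_ordinary_t(self, fitted):
        fits, contrast = fitted
        table, _ = ebayes_moderate(fits, contrast, ModerationPrior(df0=0.0, s0_sq=1.0))
        c = list(contrast.values())[0]
        v = c @ fits.xtx_inv @ c
        t_ord = (fits.coefficients.to_numpy() @ c) / np.sqrt(fits.sigma2.to_numpy() * v)
        assert np.allclose(table["t_mod"].to_numpy(), t_ord, rtol=1e-9)

    def test_infinite_prior_df_pools_all_variances(self, fitted):
        fits, contrast = fitted
        prior = ModerationPrior(df0=float("inf"), s0_sq=0.3)
        table, _ = ebayes_moderate(fits, contrast, prior)
        c = list(contrast.values())[0]
        v = c @ fits.xtx_inv @ c
        t_pooled = (fits.coefficients.to_numpy() @ c) / np.sqrt(0.3 * v)
        assert np.allclose(table["t_mod"].to_numpy(), t_pooled, rtol=1e-12)

    def test_moderated_t_between_limits(self, fitted):
        """|t| moves monotonically from ordinary t toward pooled t as d0 grows."""
        fits, contrast = fitted
        analyte = fits.sigma2.index[0]
        ts = []
        for df0 in (0.0, 1.0, 4.0, 16.0, 1e6):
            table, _ = ebayes_moderate(fits, contrast, ModerationPrior(df0, 0.3))
            ts.append(float(table.set_index("analyte").loc[analyte, "t_mod"]))
        s_g = fits.sigma2[analyte]
        diffs = np.diff(ts)
        # s_post moves monotonically between s_g^2 and s0^2, so t is monotone in d0
        assert (diffs >= -1e-12).all() or (diffs <= 1e-12).all()

    def test_prior_recovery_from_scaled_inv_chi2(self):
        """d0-hat lands within [d0/2, 2 d0] in most replicates (d0=4, s0^2=1)."""
        hits = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            true_var = 4 * 1.0 / rng.chisquare(4, 50)
            d_g = 10
            s2 = true_var * rng.chisquare(d_g, 50) / d_g
            prior = estimate_prior(s2, d_g)
            hits += 2.0 <= prior.df0 <= 8.0
        assert hits >= 0.8 * reps

    def test_all_zero_variances_falls_back_with_warning(self):
        meta = _meta(8, ["A"] * 4 + ["B"] * 4, seed=7)
        design = build_design(meta, "group")
        beta = np.zeros(design.frame.shape[1])
        y = pd.DataFrame(
            {f"g{j}": design.matrix @ (beta + j) for j in range(3)}, index=meta.index
        )
        fits = fit_linear_model(y, design)
        with pytest.warns(RuntimeWarning):
            table, _ = ebayes_moderate(fits, {"c": design.contrast_vector("A", "B")})

    def test_nested_significance_flags(self, log10_cohort):
        meta, logm, _ = log10_cohort
        results = ModeratedLinearModel.from_cohort(logm.values, meta).fit()
        t = results.contrast_frame()
        assert (t["adj_p"] >= t["p"] - 1e-12).all()
        assert (~t["sig_0.01"] | t["sig_0.05"]).all()
        assert (~t["sig_0.05"] | t["sig_0.1"]).all()

    def test_planted_stage_effects_are_detected(self, log10_cohort):
        meta, logm, truth = log10_cohort
        results = ModeratedLinearModel.from_cohort(logm.values, meta).fit()
        hits = set(results.significant(0.05)["analyte"])
        assert "sCD27" in hits


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_step_up_examples(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(bh_adjust([0.05] * 10), [0.05] * 10)

    def test_monotone_in_input(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @staticmethod
    def _brute_force_bh(p):
        """Smallest alpha at which each hypothesis is rejected by BH."""
        p = np.asarray(p)
        n = len(p)
        q = np.empty(n)
        order = np.argsort(p, kind="stable")
        for pos, i in enumerate(order):
            # BH rejects H_i at level a iff exists j >= rank(i) with p_(j) <= a*j/n
            q[i] = min(p[order[j]] * n / (j + 1) for j in range(pos, n))
        return np.minimum(q, 1.0)

    def test_matches_brute_force_on_short_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = rng.integers(1, 9)
            p = rng.uniform(0, 1, n)
            assert np.allclose(bh_adjust(p), self._brute_force_bh(p), atol=1e-12)


class TestLimmaOracle:
    def test_agrees_with_reference_limma(self, tmp_path):
        """Moderated t, p and prior match R limma on heterogeneous variances."""
        rng = np.random.default_rng(11)
        n, p = 16, 40
        meta = _meta(n, ["A"] * 8 + ["B"] * 8, seed=11)
        sig2 = 4.0 * 0.3 / rng.chisquare(4.0, p)
        y = pd.DataFrame(
            rng.normal(0, 1, (n, p)) * np.sqrt(sig2), index=meta.index,
            columns=[f"g{j}" for j in range(p)],
        ) + 2.0
        y.iloc[:8, :5] += 0.8
        design = build_design(meta, "group")
        fit = ModeratedLinearModel(y, design).fit(
            contrasts={"A_vs_B": design.contrast_vector("A", "B")}
        )
        mine = fit.contrast_frame("A_vs_B").set_index("analyte")

        y.T.to_csv(tmp_path / "y.csv")
        design.frame.to_csv(tmp_path / "design.csv")
        script = f"""
suppressMessages(library(limma))
y <- as.matrix(read.csv("{tmp_path}/y.csv", row.names=1, check.names=FALSE))
design <- as.matrix(read.csv("{tmp_path}/design.csv", row.names=1, check.names=FALSE))
fit <- lmFit(y, design)
cm <- matrix(0, ncol(design), 1); rownames(cm) <- colnames(design)
cm["group:A",1] <- 1; cm["group:B",1] <- -1
fit2 <- eBayes(contrasts.fit(fit, cm))
out <- data.frame(analyte=rownames(y), t=fit2$t[,1], p=fit2$p.value[,1])
write.csv(out, "{tmp_path}/out.csv", row.names=FALSE)
cat(fit2$df.prior, fit2$s2.prior, sep="\\n")
"""
        (tmp_path / "run.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", str(tmp_path / "run.R")], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        ref_d0, ref_s0 = (float(v) for v in proc.stdout.split())
        ref = pd.read_csv(tmp_path / "out.csv").set_index("analyte")
        assert fit.prior.df0 == pytest.approx(ref_d0, rel=1e-5)
        assert fit.prior.s0_sq == pytest.approx(ref_s0, rel=1e-5)
        assert np.allclose(mine["t_mod"], ref["t"], rtol=1e-8, atol=1e-10)
        assert np.allclose(mine["p"], ref["p"], rtol=1e-8, atol=1e-12)
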