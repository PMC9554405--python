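# Methods

This note documents the models, parameter choices and numerical conventions
behind `seropanel`, and what the synthetic cohort does and does not emulate.

## The measurement model

Bead-array immunoassays report net median fluorescence intensity (MFI) per
well. The response of analyte concentration *x* (pg/ml) is the
five-parameter logistic

y = a + (b − a) / (1 + (x/c)^d)^f,  c > 0, d ≠ 0, f > 0,

whose response runs from *b* (as x → 0) to *a* (as x → ∞); either
orientation is supported through the sign of *d*, and the curve is strictly
monotone for every valid coefficient set, giving the closed-form inverse

x = c · (((b − a)/(y − a))^(1/f) − 1)^(1/d).

Numerics: `fit_5pl` uses bounded least squares with asymptotes initialised
from the extreme standard levels, *c* from the level nearest mid-response,
*f* = 1 and both signs of *d* tried (best cost kept); tolerances 1e-15,
at least six distinct standard levels required. Flat standard series and
non-convergence raise a fit error rather than returning a degenerate curve.

QC follows assay practice: duplicate standards are averaged (disagreement
above 30% CV is logged), each standard level is back-calculated through the
fitted curve, and recovery = 100·observed/expected must fall in the closed
interval [70, 130]. A sample concentration is accepted only if the
standards bracketing it on the curve both passed; below the lowest / above
the highest level the nearest standard alone governs. Readings beyond the
asymptotes are flagged `below_lod` / `saturated`; flagged cells never carry
a numeric concentration, only the flag plus the analyte's LOD.

## Censoring and transformation

Left-censored cells (below the LOD) are substituted by 10% of the analyte's
minimum uncensored value across the full sample set — the common convention
for cytokine panels; per-group minima are available as an option. An
analyte with no uncensored value at all falls back to 10% of its LOD with a
warning (the convention is silent on this case). Substitution preserves
flags, making it idempotent and auditable. All analysis then runs on log10
concentrations.

Deviation profiles are computed on the log10 scale: within each clinical
group and panel group (1 = cytokines/chemokines/receptors, 2 = T-cell
checkpoints, 3 = NK-cell checkpoints), each analyte's mean is compared to
the grand mean over that panel group's analytes; any nonzero deviation
counts as above/below (a configurable dead band, default 0, is provided).
Signed deviations sum to zero within a block by construction.

## Adaptive univariate testing

Normality is judged per group by Shapiro–Wilk at α = 0.05; a contrast
counts as normal only if no group rejects, and groups with fewer than three
values or zero variance are undecidable and routed nonparametric.
Homoscedasticity uses Bartlett when all groups are normal and
Fligner–Killeen otherwise. Routing: two normal homoscedastic groups →
Student's t; normal heteroscedastic → Welch's t (the standard remedy);
otherwise Wilcoxon–Mann–Whitney. More than two groups: ANOVA when normal
and homoscedastic, else Kruskal–Wallis. Post-hocs run only after an
omnibus rejection: Tukey HSD after ANOVA (intrinsically adjusted), pairwise
Wilcoxon with BH adjustment within the analyte's family after
Kruskal–Wallis. Small-sample Wilcoxon (both groups ≤ 10) uses the exact
null distribution, or exact permutation enumeration when ties preclude it;
larger samples use the normal approximation with tie and continuity
corrections. Spearman correlation uses midranks; constant analytes are
reported missing, not zero.

## Moderated linear model

Each analyte's log10 concentration is regressed on a cell-means design:
one indicator per clinical group (no intercept), an unmutated-IGHV
indicator, centered age, and a male indicator (8 columns for the default
five-group cohort). Rank deficiency (e.g. a group perfectly confounded
with IGHV) raises an error naming the collinear columns.

Residual variances s²_g with d_g = n − p degrees of freedom are pooled by
empirical Bayes. The prior (d0, s0²) is estimated by closed-form moment
matching of log s²_g under a scaled-F model: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess variance of e over
ψ′(d_g/2) equals ψ′(d0/2), inverted by Newton iteration; a spread at or
below sampling noise yields d0 = ∞ (full pooling). Posterior variances
s²_post = (d0·s0² + d_g·s²_g)/(d0 + d_g) feed moderated t statistics with
d0 + d_g degrees of freedom; d0 = 0 reproduces the ordinary t exactly and
d0 = ∞ the fully pooled statistic (both covered by tests, and the whole
stage is cross-checked against the reference R implementation of the
framework on a shared fixture). BH step-up adjustment is applied across
analytes within each contrast, with nested significance flags at adjusted
p < 0.1, 0.05, 0.01.

Default contrasts: MBL^hi^ vs the average of the CLL groups, and stable
CLL (c-CLL) vs each of progressing (p-CLL), pre-first-line (CLL-PFT) and
post-first-line (CLL-TFT).

## mRMR stability ranking

Concentrations are discretized per analyte into equal-frequency terciles
(robust for ~67 samples with skewed distributions; bin count configurable).
Tie blocks straddling a bin boundary drop entirely to the lower bin, making
labels deterministic. Relevance and redundancy are plug-in mutual
information in bits; selection is greedy MID (relevance minus mean
redundancy against the selected set — the difference form; the quotient
form is not implemented), with exact ties broken by catalogue order.

Stability: 1,000 replicates each draw ⌈80%⌉ of patients per class without
replacement — stratified, because plain subsampling of 67 patients could
empty the 10-patient MBL^hi^ class — re-discretize, and run mRMR with
k = 20. Each analyte's top-5 and top-20 memberships are counted; the final
score orders lexicographically by (top-5 count, top-20 count), a concrete
choice where the source procedure says only that a score combines the two.
Replicate r derives its seed as `seed + r` for auditability. With fewer
than 20 analytes, k saturates at the analyte count.

## Decision-tree panels

CART with Gini impurity; candidate cutoffs are midpoints between
consecutive distinct values, `value < cutoff` goes left and
`value ≥ cutoff` right (matching the published rule phrasing), growth stops
at depth 4, leaves of 3, purity or zero gain. Leaf ties prefer the class
more prevalent in the training set, then label order. Splitting operates
on pg/ml directly — Gini splits are invariant under monotone transforms, so
this only fixes the scale on which cutoffs are reported. Panels are the
top-5 stability analytes by default; evaluation uses stratified k-fold
(k = 5 default, lowered with a warning when a class is smaller than k)
pooled into a confusion matrix. "Per-class success" is out-of-fold recall;
training-set rates are also retained since the convention is ambiguous in
this field's reports.

## The synthetic cohort

`default_config()` emulates the study design the analysis assumes:

- **Size and margins.** 67 samples; diagnosis 10 MBL^hi^ / 57 CLL; sex
  29 F / 38 M; age 24 ≤65 / 43 >65 (uniform within each band over 36–91
  years); IGHV 45 mutated / 22 unmutated; Binet 54/6/7; Rai 45/5/10/1/6;
  status 42 stable / 15 progression. Quotas are assigned exactly and
  shuffled, so the composition table is deterministic.
- **Groups.** Five mutually exclusive analysis groups: MBL^hi^ (10),
  c-CLL (42), p-CLL (5), CLL-PFT (5), CLL-TFT (5). The source cohort's
  treatment split overlaps its progression split in a way that cannot be
  mapped onto exclusive groups of size ≥ 2 together with all printed
  margins; the 15 progressors are therefore split evenly between untreated,
  pre- and post-first-line sampling. This is the one margin (treatment
  percentages) the generator does not reproduce.
- **Concentrations.** log10 value = per-analyte baseline mean (uniform in
  1–4, i.e. 10–10,000 pg/ml) + group shift + IGHV shift + biological
  spread N(0, 0.35²) + measurement noise N(0, 0.15²). Panel analytes from
  the published stage/evolution/treatment/IGHV panels carry ±0.5 log10
  shifts (≈3-fold, the scale of the reported cutoff separations); these
  constitute the generator's ground truth for recovery tests.
- **Censoring.** Per-analyte LOD at 2.5 baseline SDs below the mean, so a
  small left tail censors; down-shifted groups censor more, which is
  exactly the regime the 10%-of-minimum substitution rule addresses.
- **Streams.** One seed; metadata and each analyte use substreams keyed by
  name, so adding analytes does not perturb existing draws, and identical
  configs are bit-identical.

What the generator does **not** emulate: inter-plate batch effects beyond a
single multiplicative term, bead-level physics, analyte-analyte correlation
beyond shared group structure, non-lognormal tails, and survival outcomes.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated model, not robustness to real-world assay
artifacts.

The catalogue ships 104 stored analyte rows; by default one T-cell
checkpoint row (sVISTA/sB7-H5) is excluded so the panel sizes match the
study's stated counts (65 cytokines/chemokines + 38 checkpoints = 103);
`load_catalogue(full=True)` returns all rows.

## Problem sizes and determinism

Default pipeline: 67 × 103 cohort, 1,000 mRMR resamples per task, three
tasks (diagnosis, evolution, IGHV), 5-fold CV — about 10 s on one core,
bit-reproducible under a fixed seed (the manifest records config hash and
output checksums). Test-suite simulations use reduced replicate counts
(20–200) chosen to keep Monte-Carlo acceptance bands at least 3 SEs wide.

## Known limitations

- The 5PL fit is unweighted; 1/y² weighting common in immunoassay software
  is out of scope, so very low standards carry less influence than they
  would there.
- Exact mRMR score combination and the treatment-margin overlap (above)
  are resolved by documented package conventions.
- Decision trees have no surrogate splits: a missing value on a decision
  path is an error, consistent with the fully imputed pipeline input.
- BH adjustment assumes the usual positive-dependence conditions; no
  Benjamini–Yekutieli fallback is provided.
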