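# Methods

## The replication-error model

The toolkit treats DNA-methylation change at selected CpGs as a counter of
stem-cell divisions. Divisions per stem cell accumulate as

    TNSC(s,t) = A(s) · [IR(t) + E(s)·ER(t)]

where A(s) is chronological age in years, IR(t) the tissue's intrinsic
stem-cell division rate (divisions per stem cell per year), E(s) ≥ 0 an
individual exposure level and ER(t) the extrinsic division rate that one
unit of exposure induces in tissue t. Assumptions this inherits:

* errors accumulate linearly with divisions (no saturation within the
  modelled range; the simulator clips at the [0,1] beta boundary and
  reports when it does);
* IR depends only on tissue, not on the individual — genetic modulation of
  division rate is ignored;
* the clock is an intensive quantity (a mean over CpGs and cells), so only
  within-tissue comparisons of division counts are meaningful. Nothing in
  the toolkit compares risk across tissues, and no cancer-risk function is
  computed: the link from division counts to risk is assumed monotone and
  left unspecified.

Each clock CpG c drifts from its fetal ground state g_c at a per-division
rate ξ_c: mean beta = g_c + ξ_c·TNSC (hyper direction; minus for hypo).
Averaging over n clock CpGs gives the score, linear in TNSC and hence — in
healthy samples of one tissue, where E ≈ 0 — linear in age with intercept
α′ ≈ mean(g_c) and slope γ′ ≈ mean(ξ_c)·IR.

## Clock construction

CpGs are selected from a covariate-adjusted age EWAS followed by a
conjunctive filter cascade. Choices that the underlying description left
open, and how this implementation resolves them:

* **Regression direction.** Each probe's beta is the response, age the
  predictor (with plate, sex and cell-fraction covariates). This makes the
  per-probe error model standard OLS and the age coefficient directly
  interpretable as methylation drift per year.
* **Cell fractions as covariates.** Fractions lie on the simplex and sum
  to one, so one cell type is dropped from the design to keep it full rank
  alongside the intercept. Collinear covariate pairs (|r| > 0.9999) abort
  with an error naming the pair rather than silently dropping one.
* **FDR scope.** Benjamini–Hochberg q-values are computed over all probes
  tested in the EWAS, not over post-filter subsets, so the FDR statement
  refers to the age association itself.
* **Ground-state bounds.** The fetal filter is applied per fetal sample
  (not per tissue-type mean): a hyper candidate needs beta < 0.2 in
  *every* fetal sample (strict), a hypo candidate ≥ 0.3 in every sample
  (inclusive). Probes missing from the fetal matrix are excluded and
  audited.
* **TSS200/"unambiguous".** A probe qualifies when annotated to exactly
  one gene with a TSS200 relation; the annotation table carries this as a
  boolean, so upstream ambiguity resolution is the annotator's concern.
* **Audit.** Filters are conjunctive, so membership is order-independent;
  the audit counts (probes removed per step) do depend on the documented
  cascade order: FDR → direction → TSS200 → fetal availability → fetal
  bound → PRC2 (hyper only).

## Scoring, calibration, inversion

The score is the arithmetic mean of non-missing betas over clock CpGs.
Samples whose clock coverage falls below `min_coverage` (default 0.95) are
flagged and left unscored — scores are only comparable when probe support
matches. Calibration is plain OLS of score on age; a non-positive fitted
slope is reported with a warning because the inversion
TNSC = (score − α′)·IR/γ′ then has no meaning. Negative division estimates
(score below α′) are returned unclipped with a warning: truncation would
hide calibration misfit. The ratio operation
(score₁ − α′)/(score₂ − α′) is provided for tissues with no IR estimate
and agrees with the quotient of inversions whenever IR is present.

`excess_divisions` implements the published arithmetic verbatim — the
division-count *ratio* times the lesion's stem-cell count,
(TNSC_lesion/TNSC_normal)·fraction·total — although "additional divisions"
would more naturally be a difference; the docstring notes the discrepancy
rather than resolving it.

Shipped constants: the blood (α′ = 0.052, γ′ = 0.000345), breast-normal
(0.053, 0.000165) and lung-normal (0.021, 0.000588) calibrations, and the
literature table of intrinsic division rates (colon/rectum 73, esophagus
17.4, head-and-neck 21.5, liver 0.9125, lung 0.07, pancreas 1, thyroid
0.087 divisions/stem cell/year). Users can override any of them.

## Cell-type deconvolution

Bulk betas are modelled as a convex combination of reference profiles;
weights minimise the squared residual over shared probes subject to w ≥ 0,
Σw = 1 (equality, because fractions are compositional). The solver runs
non-negative least squares on a penalty-augmented system to identify the
active set, then solves the equality-constrained KKT system exactly on the
support, dropping the most negative coordinate and re-solving if the
equality solution leaves the feasible set. This is deterministic and
recovers vertices and exact convex combinations to machine precision.
Missing betas are dropped per sample from the objective rather than
imputed; samples missing more than half the shared probes are rejected
(NaN row, listed in `rejected`). Identical reference columns produce a
warning — the split between the duplicated types is then arbitrary but
deterministic (column order).

## Validation statistics

* **Age-adjusted association**: OLS of y on x and age, reporting the x
  coefficient; the one-sided p halves the two-sided p when the coefficient
  carries the hypothesized sign.
* **One-tailed rank tests**: Wilcoxon rank-sum for unpaired groups, the
  signed-rank test for paired data (the paired analogue — rank-sum has no
  paired form). Exact enumeration when the pooled (or pair-difference)
  sample is ≤ 20 without ties/zeros; otherwise the normal approximation
  with tie correction. The two paths agree to ~0.02 at the boundary.
* **Age adjustment of a rank test** is not a standard object; it is
  implemented as rank testing of residuals from a pooled OLS of value on
  age, with the unadjusted p reported alongside so the effect of the
  adjustment is visible.
* **ROC/AUC**: the Mann–Whitney probability with ties counted ½. The
  default CI is DeLong's (midrank structural components; deterministic);
  a stratified bootstrap (2,000 resamples, explicit seed) is available.
  The CI method behind published intervals of this kind is typically
  unstated; DeLong is the common deterministic default.
* **Age matching**: greedy nearest-age matching without replacement,
  smallest gap first, ties broken by sample ID, pairs beyond the tolerance
  (default 5 years) discarded. Greedy matching is not globally optimal but
  is deterministic and transparent.
* **Significance-count comparison**: a sign test on discordant types under
  Binomial(n_discordant, ½), one-sided.

## The simulator

`epitoc.simulate` generates full cohorts from the model above: planted
hyper/hypo clock CpGs with per-CpG ground states and drift rates, static
background probes, cell-type marker probes mixed by age-trending
proportions (the confounder that motivates deconvolution), a fetal
ground-state matrix obeying the construction bounds by construction, a
matching cell reference with true fractions, and a nine-gene proliferation
expression panel linear in the division rate.

Default parameters, chosen once as field-plausible values:

| parameter | default | rationale |
|---|---|---|
| blood intrinsic rate | 12 divisions/stem cell/yr | order of magnitude of hematopoietic turnover; the published rate table has no blood entry |
| drift ξ_c | U(1e-5, 5e-5) per division | mean(ξ)·IR ≈ 3.6e-4/yr, the order of the published blood slope γ′ |
| hyper/hypo ground states | U(0.05, 0.15) / U(0.45, 0.70) | inside the < 0.2 / ≥ 0.3 construction bounds with drift headroom |
| measurement noise | beta-family, precision 1000 | mean-preserving on [0,1]; per-probe sd ≈ 0.01–0.016, array-like |
| fetal matrix | 52 samples, sd 0.01 around g_c, bounds enforced | mirrors a multi-tissue fetal panel |
| cell mixture | 5 types, softmax logits with age trend ±0.5 and per-sample noise 0.3 | realistic compositional drift plus individual variation (without the noise term, fractions are a rank-1 function of age and degenerate) |
| cohort | n = 500, ages 20–100, 2,000 probes, 50+50 planted clock CpGs | large healthy single-tissue design at desk scale |

Scenario presets cover the validation designs: `healthy-blood`
(construction setting), `multi-tissue-normal` (eight tissues with the
published division-rate table), `tumor-vs-normal` (age-sharing pairs,
log-normal tumor exposure), `lesion-progression` (normal/lesion/progressed
with increasing exposure), `exposure-dose` (identically aged samples, e.g.
pack-years 0–50 at age 53).

**What the simulator does not emulate** — and therefore what passing tests
do not demonstrate about real data: array probe-type bias and batch/chip
artifacts, non-linear or saturating drift, genetic variation in division
rates, absolute stem-cell numbers, spatial/clonal structure, and realistic
correlation structure among probes (probes are conditionally independent
given the model). Simulated effect sizes make direction and machinery
checkable; real-data effect sizes (e.g. the published R² ≈ 0.45 against
division estimates in normal tissue) are not reproduced at desk scale, and
the published 385/656-CpG probe lists require the original cohorts and
annotations, which are deliberately out of scope.

## Numerical notes

* Constant probes are detected by zero range (max = min), not zero
  variance, to survive floating-point mean round-off; they are skipped and
  flagged.
* The EWAS solves all complete probes against the shared design in one
  vectorised pass (pinv of XᵀX); probes with missing cells fall back to a
  per-probe complete-case fit with a minimum-observations floor of one
  residual degree of freedom plus one.
* BH q-values come from `statsmodels.stats.multitest`; the test suite
  checks them against a brute-force step-up oracle.
* Sample floors: EWAS requires (number of extra covariates + 3) complete
  samples; calibration requires 3 scored, aged samples and distinct ages.

## Problem sizes

The shipped tests and the acceptance script run at the design sizes above
(n = 500 cohorts, 2,000 probes, 10–50 seeded replicates per check), which
completes in a few minutes on one CPU while keeping every statistical
check well-powered.
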