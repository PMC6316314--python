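# Methods

## Scope and model

The package implements the analysis chain of a two-visit, single-arm
nutrigenetic intervention design: genotype → risk score → median split →
postprandial indices → group/visit comparisons. It treats the published
summary statistics of such studies as reconstruction targets and ships
a generative model of the whole design so the chain can be validated by
simulation.

## Genetic risk scores

Dosage recoding is strict: an allele call outside a locus's two defined
alleles raises an error naming the subject and locus; a missing call is
a typed missing-data signal, never a silent zero. Subjects with any
incomplete locus are excluded from scoring with a logged warning
(per-protocol analysis); nothing is imputed. Allele comparison is
case-insensitive after trimming, and no strand flipping is attempted —
the panel is defined on the reported strand.

The weighted score uses w = ln(OR). Published per-locus ORs for the
motivating loci were never printed in the study this design follows, so
the package refuses to hard-code "real" weights: `load_panel` requires a
user-supplied JSON panel, and the bundled defaults
(`examples/snp_panel_synthetic.json`, `simulate.SYNTHETIC_PANEL`) are
clearly-labelled synthetic values on the plausible 1.15–1.30 range for
East Asian T2DM GWAS loci.

Median split: the cutoff is the sample median (mean of the two middle
order statistics for even n); ties at the cutoff go to the low-risk
group, matching the ≤-median convention of the motivating study. If all
scores are identical the entire cohort is assigned low with a warning.

Hardy–Weinberg testing is the standard 1-df Pearson chi-square with
allele frequency estimated from the tested counts, computed on the
pooled cohort (one test per locus). A monomorphic locus yields a
degenerate result with statistic 0 rather than an error. Note: the
motivating study's printed HWE p-values are not reproducible from its
printed genotype counts by this (standard) test — e.g. its KCNQ1-style
pooled counts (11, 16, 5) give χ² = 0.042, p = 0.84 — and its prose and
footnote contradict each other about whether equilibrium held; the
package implements the standard test and makes no attempt to chase the
printed values. The same caveat applies to its genotype-by-group
p-values: the printed 2×3 tables give χ² = 8.41, p = 0.015 under
Pearson's test (cross-checked against scipy) where 0.012 was printed.

## Index computation

AUC windows require both endpoints to be sampled timepoints: there is
no extrapolation and no silent interpolation of window edges
(`GridError` otherwise). Incremental mode subtracts the fasting (t = 0)
value from every point and keeps negative increments, so window
additivity is exact in both modes. Incremental is the default reporting
mode: printed AUC magnitudes of the motivating study (≈ 944 mg/dL·min
over 30 min ⇒ ≈ 31 mg/dL average excursion) are only consistent with
baseline-subtracted areas.

Insulin units are deliberately opaque. The study's formulas mix μg/mL
and μg/L labels while behaving numerically like conventional μU/mL; the
package treats insulin as one consistent unit and uses the printed
constants verbatim (405 denominator for HOMA-IR, 360 numerator for
HOMA-β). No unit auto-conversion is attempted.

Undefined indices — HOMA-β at the FPG ≤ 63 pole, IGI with a flat 0–30
glucose excursion, ratios over a zero incremental area, 1/FSI at zero
insulin — become NaN with a logged warning and are excluded listwise
from the affected comparison only. Batch computation therefore always
returns one row per subject-visit.

The incremental insulin/glucose response is implemented as the ratio of
incremental areas (not the area of the pointwise ratio); the printed
group means of the motivating study cannot discriminate the two
readings, and the ratio-of-areas form is the one that propagates the
trapezoid rule's additivity. Similarly the oral disposition index is
computed per subject as IGI/FSI; group means of a nonlinear per-subject
quantity will not equal the product of the group means of its factors,
and no reconciliation with printed tables is attempted.

## Statistics

Paired and unpaired t tests are authored directly (mean/SD arithmetic,
CIs from the t quantile) and cross-checked in the test suite against
scipy's `ttest_rel`/`ttest_ind` and, for the paired test, against exact
sign-flip enumeration of the t statistic at n ≤ 12. The unpaired
default is the classical pooled-variance Student t (the "equal
variances assumed" line of SPSS-style output); Welch is a flag.
Zero-variance inputs yield flagged degenerate results rather than
exceptions.

Pearson chi-square uses no continuity correction by default (Yates is a
flag for 2×2). Empty margins are errors that name the offending
row/column.

ANCOVA fits outcome ~ group + covariates by OLS; adjusted group means
are model predictions at covariate grand means over the analysis sample
(after listwise deletion), SEs come from the coefficient covariance,
and the group p-value is the group-coefficient t test (equivalent to
the two-group F). Binary covariates (sex, family history) enter as 0/1.
One deliberate deviation from a strict design contract: covariates that
are constant in the analysis sample (e.g. `sex` in an all-female draw
of 32 subjects) are dropped with a warning instead of raising a
rank-deficiency error, because small cohorts produce such draws
routinely; genuinely collinear non-constant columns still raise. The
rank check runs on a column-normalized design matrix so covariate scale
differences (kcal/day vs indicator) cannot masquerade as collinearity.

Power/sample size for the paired t uses the noncentral t distribution
with noncentrality dz·√n, bracketing then bisecting on n. The study
anchor — dz = 0.54, α = 0.05, power 0.80 → n = 29 — is a consistency
check, not a reproduction: the study stated its power in terms of an
18% AUC difference whose SD it never printed, so the operation takes
the standardized effect directly.

No multiple-testing adjustment is applied anywhere (matching the
analysis style reproduced); reports annotate the number of tests run.

## Synthetic cohort generator

The generator emulates the study conditions: n = 32, five loci with
risk-allele frequencies equal to the motivating cohort's pooled
genotype counts, two visits, curves on the grid {0, 30, 60, 90, 120}
min.

Curves are a fasting level plus a unimodal piecewise-linear bump
peaking at 30 min and returning to baseline at 120 min — not a
physiological ODE — because the design being emulated reports only AUC
summaries, and a polyline with knots on the sampling grid makes
trapezoid oracles exact. Per-subject incremental glucose AUC is
mean 1750 mg/dL·min × (1 + β_g·(wGRS − mean)) × exp(η), η ~ N(0, 0.35²);
insulin uses an attenuation factor (1 − β_i·(wGRS − mean)) floored at
0.05 around a 360-unit·min mean. β_g = 1.0 and β_i = 2.0 per wGRS unit
put the expected baseline H−L glucose-AUC gap near 800 mg/dL·min and
suppress early insulin in the high-risk group, the magnitudes the
motivating tables print; this is calibration of the simulation's
defaults, not a claim about ground truth. The intervention multiplies
the glucose amplitude by 0.79 (a 21% reduction) and shifts fasting
insulin by −1.55 units, by default only in subjects above the median
wGRS. Fasting glucose/insulin get small per-visit wobble (SD 2.5 mg/dL
/ 0.6 units) so paired tests on fasting measures are non-degenerate;
curve values get i.i.d. measurement noise (SD 4 mg/dL glucose, 1 unit
insulin), with the t = 0 sample anchored to the fasting draw.

A single `numpy.random.default_rng(seed)` stream drives the whole
cohort; identical config + seed reproduce byte-identical files. Latent
per-subject noise-free AUCs and the full config are echoed into
`ground_truth.json` for parameter-recovery tests.

What the generator does **not** emulate: linkage disequilibrium between
loci, realistic curve shapes (biphasic responses, late peaks), diurnal
or assay drift, questionnaire item structure, dropout, or any
microbiome mechanism. Passing tests on synthetic data therefore
demonstrate that the pipeline recovers effects *of the configured
form*, not that the biological claims of any particular study are
correct.

## Problem sizes and numerical choices

Simulation-based checks run at deliberately modest sizes chosen to make
Monte-Carlo bands tight enough to be meaningful: 2,000 null cohorts of
n = 200 for the HWE type-I error (binomial SE ≈ 0.005 at α = 0.05),
1,000 subjects (≈ 500/group) for parameter recovery judged within 2
Monte-Carlo SEs, and 500 zero-effect cohorts of n = 32 for the
pipeline's false-positive rate (SE ≈ 0.01, acceptance band
0.025–0.075). Exact enumeration backs the paired t at n ≤ 12 (≤ 4,096
sign flips).

Report tables round half-away-from-zero at the configured precision;
all statistics are kept at full precision in `stats.json`. Dataset
validation enforces sanity ranges (glucose 30–400 mg/dL, insulin
0–300), requires the 0/30/120-min samples per curve, warns when the
clinical fasting glucose disagrees with the curve's t = 0 value by more
than 5 mg/dL, and excludes subjects missing from any required table
(logged, per-protocol) rather than aborting.

## Known limitations

* The ANCOVA group test assumes homogeneous slopes (no group×covariate
  interaction is fitted), mirroring the reproduced analysis style.
* The VCF reader is a minimal GT-only subset (diploid, phasing ignored,
  no INFO/quality handling) intended for small plain-text panels.
* With all odds ratios equal, the weighted score is an exact multiple
  of the count score and the median split degenerates to count ties.
* Printed-table targets are reconstruction checks on summary arithmetic;
  they cannot validate subject-level computations against the original
  raw data, which were never released.
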