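# Methods

## The problem and the score

Hepatic steatosis screening at population scale cannot rely on imaging
alone. The fatty liver index (FLI) summarizes four routinely collected
measurements — triglycerides, BMI, GGT and waist circumference — into a
logistic score on (0, 100):

    L   = 0.953·ln(TG) + 0.139·BMI + 0.718·ln(GGT) + 0.053·WC − 15.745
    FLI = 100·σ(L),  σ the standard logistic.

All coefficients are positive, so the score is strictly increasing in
each input; σ's reflection symmetry means inputs with linear predictors
L and −L give scores summing to 100. Scores are held at full floating
precision; rounding (half-up, one decimal for percentages and
likelihood ratios, mirroring clinical table style) happens only in the
reporting layer.

The package validates this score against two binary reference
standards: a radiologist's ultrasound diagnosis, taken as a given label
(sonographic criteria are image-level and out of scope), and
CAP-defined steatosis, `CAP ≥ 248 dB/m` with an inclusive boundary.
Liver-stiffness reliability (≥10 valid measurements and IQR/median
< 0.3, or median < 7.1 kPa; strict inequalities) is computed and
logged but does not gate the CAP analysis by default, because exams
with ten valid measurements are retained in the emulated design; a
switch enables gating.

## Cohort model and exclusions

Cohorts are pandas DataFrames with a fixed column schema; ingestion
coerces cells defensively (unparseable, negative, or implausible
values — CAP outside [100, 400] dB/m — become missing and are counted,
never silently dropped). The exclusion cascade runs in the fixed order
HBV → HCV → alcohol → missing required field, each subject attributed
to the *first* matching reason, so the per-reason counts are disjoint
and satisfy `n_final = n_initial − Σ counts` by construction (the log
class enforces the identity). Alcohol exactly at the threshold is
retained (strict `>`). The "missing" bucket defaults to the
analysis-critical fields — sex, the four FLI inputs, and the
ultrasound label; subjects missing only CAP are instead dropped
per-analysis by the reference-label builder, to avoid double counting.
The required-field set and alcohol thresholds are parameters.

Comorbidity flags use three-valued (Kleene) logic: one decisive True
settles a flag even when another component is missing; a flag is
missing only when nothing can decide it.

MDRD eGFR uses the IDMS-traceable 4-variable form (175 multiplier,
0.742 female factor, no ethnicity coefficient — the emulated population
is homogeneous). It is descriptive only and feeds nothing downstream.

## Diagnostic accuracy

Test-positive is `score ≥ cutoff`. The AUC is the Mann–Whitney
estimator (ties ½), computed from midranks; it equals the trapezoidal
area under the empirical ROC, and label inversion maps it to its
complement. Confidence intervals:

- **DeLong** (default): placement-value variance
  `var = s₁₀/m + s₀₁/n`, normal interval clipped to [0, 1].
  Deterministic, standard for paired ROC work.
- **Stratified percentile bootstrap**: positives and negatives
  resampled separately (a resample therefore always contains both
  classes), ≥100 replicates, seeded and reproducible.

The optimal cutoff maximizes Youden's J over a grid — by default the
integers 0–100, matching the scale cutoffs are reported on; an
"observed" grid (every distinct score) is available and is equivariant
under strictly increasing transforms of the score. Ties in J break
toward the smallest cutoff, which maximizes sensitivity at equal J.
Degenerate inputs (single-class labels, empty strata) raise or skip
with a warning rather than returning sentinel numbers; infinite
likelihood ratios are `inf` and undefined quantities `nan`, explicitly.

In the fixed-cutoff report table, the per-row AUC is the AUC of the
*dichotomized* test (the binarized score as the marker), which equals
(Se + Sp)/2 — the quantity conventionally printed beside fixed-cutoff
rows — while the optimal-cutoff table reports the full-ROC AUC. Both
carry DeLong intervals by default.

Predictive values at an external prevalence p come from Bayes' rule
(`PPV = se·p/(se·p + (1−sp)(1−p))`, analogously NPV); with p equal to
the sample prevalence these reproduce the empirical values exactly,
which the tests assert.

## Synthetic cohort generator

The generator emulates an asymptomatic checkup cohort published only
as group summaries: for each (sex × ultrasound-status) stratum, means
± SD for age, blood pressure, BMI, WC, AST, ALT and GGT; medians with
quartiles for triglycerides and CAP; comorbidity proportions. Defaults:
n = 4009, male fraction 0.835, ultrasound-steatosis prevalence
2162/3349 (male) and 301/661 (female).

Marginals: BMI, WC, age, pressures and aminotransferases are normal,
truncated at physiologic floors (BMI ≥ 12, WC ≥ 40, age ≥ 18 — an
adult checkup population — others > 0) via inverse-CDF mapping, so
truncation costs no determinism. Triglycerides and CAP are log-normal
fitted from median and quartiles (μ = ln median,
σ = (ln q₃ − ln q₁)/(2·z₀.₇₅)); GGT is log-normal moment-matched from
mean ± SD. The five variables (BMI, WC, TG, GGT, CAP) are joined by a
Gaussian copula; since the source publishes no correlations, the
copula correlation is an explicit knob, default 0.3 pairwise among the
four FLI inputs and 0.2 between CAP and each of them — mid-range
values for anthropometric/metabolic covariation.

The ultrasound label *is* the latent stratum assignment; CAP steatosis
arises implicitly when the simulated CAP crosses 248 dB/m. With the
default marginals this yields an overall CAP prevalence near 55–57 %
against a configured ultrasound prevalence near 61 %, and the two
references disagree on a minority of subjects — the imperfect
concordance seen in real cohorts. Fasting glucose is drawn conditional
on the diabetes flag (treated subjects at or above 126 mg/dL) so the
derived flag recovers the simulated one; blood pressure is drawn from
its published marginal independently of the hypertension flag, so the
derived hypertension prevalence slightly exceeds the configured
treated-proportion — a documented simplification. Creatinine uses
adult reference ranges (it is not published per stratum and is
descriptive only). Serology and alcohol are set so every synthetic
subject survives the exclusion cascade.

A single integer seed drives generation, split into one child stream
per stratum plus one for the assignment, so per-stratum draws are
reproducible; identical configuration gives byte-identical cohorts.

### What passing the simulation tests does and does not show

The generator reproduces the published *marginals* and prevalences,
and the pipeline on it reproduces the qualitative findings — a pooled
ultrasound AUC in the 0.79–0.82 neighborhood across seeds and a female
optimal cutoff well below the male one (roughly 16–21 vs 25–36 across
seeds, around published values of 18 and 31). It cannot reproduce the
exact published AUC of 0.82 or the exact cutoffs 29/31/18, because the
real inter-variable correlations, tails and measurement error are
unpublished; the acceptance band for the pooled AUC ([0.70, 0.92] in
≥90 % of seeds) and the cutoff ordering property state exactly what
the synthetic conditions can support. Passing them shows the pipeline
is faithful, not that the generator is a substitute for subject-level
data.

## Reporting layer

The baseline descriptive table mirrors the sex- and status-stratified
layout: mean ± SD for approximately normal variables, median (IQR) for
triglycerides and CAP (compared by t-test on the log scale, as skewed
variables are conventionally log-transformed first), count (%) with
Pearson chi-square (no continuity correction) for flags. All group
comparisons are two-group, so the t-test is the ANOVA special case
used throughout. Degenerate groups mark their p-values unavailable.

`run_pipeline` chains read → exclude → score → label → evaluate →
stratify, writes the exclusion log, baseline table, fixed- and
optimal-cutoff tables, ROC vertex TSVs and a JSON manifest (package
and library versions, full configuration, seed, stage counts). A
failed stage removes partial outputs and re-raises with the stage
name; a manifest alone reproduces the run byte for byte.

## Problem sizes and numerical choices

Tests and the acceptance script use the default n = 4009 cohort where
the emulated cohort's conditions matter (prevalence recovery, cutoff ordering,
AUC band over 25 seeds; about a second in total, vectorized), and
smaller n (400–1500) for plumbing checks. The FLI implementation is
checked against a 50-digit arbitrary-precision oracle to 1e−9 relative
error on 1000 random inputs; the AUC against brute-force pair counting
(≤200 subjects) and scikit-learn; the Youden optimizer against an
exhaustive grid scan (≤500 subjects). Bootstrap CIs in tests use
200–500 replicates; the production default is 2000.

## Known limitations

- The generator does not model AST/ALT/GFR cross-correlations, the
  comorbidity–laboratory dependence structure, or measurement error in
  CAP/ultrasound; steatosis severity grades and fibrosis staging are
  out of scope.
- DeLong intervals are asymptotic; for very small strata prefer the
  bootstrap.
- The ultrasound reference is a label, not a re-derivable quantity;
  misclassification in it (ultrasound misses mild steatosis) is
  inherited, not modeled.
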