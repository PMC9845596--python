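# Methods

## The siMS score

The metabolic syndrome (MS) is conventionally diagnosed as a binary label
(IDF definition: mandatory central obesity plus at least two of four other
components). The siMS score replaces the binary label with a continuous
severity measure: each component is divided by its diagnostic reference
value and the ratios are summed, with waist circumference normalized by
height rather than by a fixed cutoff,

    siMS = 2·WC/height + Gly/5.6 + Tg/1.7 + SBP/130 − HDL/d,
    d = 1.03 (men) | 1.3 (women),

WC and height in cm, fasting glucose (Gly) and triglycerides (Tg) in
mmol/L, SBP in mmHg, HDL in mmol/L. A man at exactly every reference value
with WC = height/2 scores 3.0; the score is strictly increasing in WC, Gly,
Tg and SBP and strictly decreasing in HDL and height. Two conventions are
fixed here and worth stating because they are genuinely open choices:

* **Gly is the fasting (0-min OGTT) glucose.** The 5.6 mmol/L denominator
  is the IDF fasting-glycemia criterion, which is a fasting threshold; the
  30-min and 2-h OGTT values enter no score.
* **The female HDL denominator is 1.3**, as in the score's defining
  formula, even though the IDF female HDL *criterion* cutoff is 1.29. Both
  constants are kept as published and not reconciled; the same applies to
  the blood-pressure pair (classification uses SBP ≥ 135, the score
  normalizes by 130).

Companion indices: HOMA-IR = fasting insulin (mIU/L) × fasting glucose
(mmol/L) / 22.5, and the fatty liver index

    FLI = 100·e^z/(1+e^z),
    z = 0.953·ln Tg + 0.139·BMI + 0.718·ln GGT + 0.053·WC − 15.745.

FLI takes **triglycerides in mmol/L**, matching the units of the cohort
conventions this package follows. The original FLI literature uses mg/dL;
with mmol/L the linear predictor is smaller by 0.953·ln(88.5) ≈ 4.3, which
compresses the index (cohort medians ≈ 5 rather than tens). Comparisons
against mg/dL-based FLI values are therefore not meaningful without
reconversion. The "insulin average" is the unweighted mean of the 0/30/120
min OGTT samples (no weighting scheme is defined for the 3-point curve).

Height is rarely tabulated in cohort summaries that report weight and BMI;
`derive_height(weight, bmi) = 100·√(weight/bmi)` closes that gap and
round-trips with `compute_bmi` to 1e-9 relative.

Missing-data contract: per-record scoring produces *partial panels* —
each panel field is computed exactly when its inputs are present, and log
transforms are defined only for strictly positive sources. Missingness is
never an error at the record level; domain errors are reserved for
contract violations (non-positive measurements, unknown sex).

## Classification

IDF component flags (therapy counts toward the lipid criteria on both the
triglyceride and the HDL side, and antihypertensive therapy toward blood
pressure):

| flag | rule |
|---|---|
| wc   | WC ≥ 94 cm (M) / ≥ 80 cm (F) |
| tg   | Tg ≥ 1.7 mmol/L or lipid therapy |
| hdl  | HDL < 1.03 (M) / < 1.29 (F) mmol/L or lipid therapy |
| bp   | SBP ≥ 135 or DBP ≥ 85 mmHg or antihypertensive therapy |
| gly  | fasting glucose ≥ 5.6 mmol/L or known type-2 diabetes |

MS requires the waist flag plus ≥ 2 others (central obesity is mandatory
under IDF — a subject with four non-waist criteria is still pre-MS).
Pre-MS is ≥ 1 criterion without meeting the MS rule; `no_criteria` is kept
for generality although a study cohort selected for pre-MS/MS has ≥ 1 by
construction.

OGTT glycoregulation uses standard WHO/ADA cutoffs, since only the category
names are fixed by the reporting surface: DM if fasting ≥ 7.0 mmol/L or 2-h
≥ 11.1 or previously diagnosed; else IGT if 2-h ∈ [7.8, 11.1); else IFG if
fasting ∈ [5.6, 7.0); else normal. Precedence DM > IGT > IFG keeps labels
exclusive. A missing 2-h value is a missing label (None/NaN) unless
diabetes is already decidable from the fasting value or history.

Obesity uses strict inequalities (obese iff BMI > 30, overweight iff
BMI > 25); BMI ≤ 25 is labelled `out_of_cohort` rather than clamped. Age
groups split at 30 years inclusive (young ≤ 30 < older).

## Synthetic cohorts

The generator exists because the underlying patient-level data are not
publicly deposited: every downstream stage is exercised on surrogate
cohorts whose *marginals* are transcribed from the published per-age-group
summary columns and whose dependence is an explicit assumption.

**Marginals.** Mean ± SD rows are normals truncated below at physiologic
floors (e.g. HDL ≥ 0.4 mmol/L, fasting glucose ≥ 2.5); median (Q1–Q3) rows
(triglycerides, the three insulins, CRP, microalbuminuria, ALT, AST, GGT)
are log-normals with μ = ln median and σ = (ln Q3 − ln Q1)/(2·z₀.₇₅),
z₀.₇₅ = 0.67449. This closed form reproduces the median and the log-IQR
exactly; individual quartiles are reproduced exactly only when the printed
triple is log-symmetric (the published triples are within ~1%). The
*configured marginal is the truncated distribution*: parameter-recovery
tests compare sample means against the truncated distribution's own
mean/SE (via `scipy.stats.truncnorm`), not the untruncated nominal mean —
for floors ≥ 2 SD below the mean the two differ by more than a 3-SE band
at n = 10,000, so this is the only self-consistent check. Height is
normal(173.1, 9) / normal(169.7, 9) cm for the young/older group, the
means implied by the published weight and BMI means; weight is then
*derived* as BMI·(height/100)², never sampled. FLI is always computed
downstream from generated Tg/BMI/GGT/WC, keeping the pipeline
self-consistent.

**Dependence.** A Gaussian copula: latent multivariate normal with a
correlation matrix assembled from a sparse list of pairs, mapped through
each marginal's quantile function. The default pairs encode only
qualitative directions the field agrees on — adiposity with insulin,
glucose, lipids, liver enzymes, CRP, uric acid and PAI-1 positively, HDL
negatively — at moderate magnitudes (|ρ| 0.15–0.8). They are assumptions,
clearly overridable via `GeneratorConfig.correlation`, and make no claim
of matching the unpublished study correlations. The matrix is repaired to
positive definiteness by eigenvalue clipping (floor 1e-6) with rescaling
to unit diagonal; the repair is idempotent on PD input. Because truncation
is applied inside the quantile function, the map from latent normal to
observed value is monotone, so sample Spearman correlations recover the
copula's rank correlation (6/π)·arcsin(ρ/2) regardless of truncation;
recovery tests use the ±0.05 band at n = 10,000.

**Dysglycemia subgroups.** IFG/IGT/newly-found-DM fractions (defaults:
the published prevalences, young 2.4/4.8/0%, older 1.4/1.8/5.7%) are
induced after sampling by overwriting OGTT glucose for randomly chosen
disjoint subsets: IFG gets fasting glucose in [5.6, 6.9) with the 2-h
value capped below 7.8; IGT gets a 2-h value in [7.8, 11.0) plus a
moderately elevated fasting value (dysglycemia co-occurs across the OGTT
curve — this is also what makes induced IGT subjects score higher on
siMS); DM gets fasting ∈ [7, 10) and 2-h ∈ [11.1, 18). Tests of marginal
fidelity set these fractions to zero, since induction deliberately
distorts the glucose marginals.

**What the generator does not emulate.** Real anthropometric data are
skewed and bounded in ways a truncated normal only approximates; the
older group's 2-h glucose (5.4 ± 2.5, printed as mean ± SD) gets a heavy
right tail under a normal family, so ~19% of synthetic older records
carry a natural IGT label — far above the published 1.8% — and the
published category *prevalences* are therefore not reproduced, only the
category *ordering* of siMS means. No sex-specific marginal shifts are
modelled (the published summaries are pooled); sex enters only through
the score denominators and classification cutoffs. Therapy-flag
prevalences are not published and default to modest age-dependent guesses
(2/3% young, 10/15% older for lipid/antihypertensive therapy). Passing
tests demonstrate that the pipeline's algebra, classification logic and
statistical machinery are correct and that cohort-level siMS means are
insensitive to the assumed dependence structure — not that the synthetic
records are distributionally exchangeable with real patients.

**Determinism.** One `numpy.random.Generator` seeded from the config
drives latent draws, sex, age, therapy flags and induction; identical
configs give bit-identical cohorts.

## Statistical surface

Two-group comparisons follow the scale of each variable, with the
variable→test map shipped as package data (`table_layout.yaml`) rather
than code: pooled-variance t test for mean ± SD rows (Welch by flag),
Mann-Whitney U for median rows, Pearson chi-square without continuity
correction for the obesity proportion, and a 2×k Fisher-Freeman-Halton
exact test for the 4-level glycoregulation distribution. Mann-Whitney uses
the exact null when min(n, m) ≤ 8 and the data are tie-free, otherwise
the normal approximation with tie correction. The Freeman-Halton p-value
sums the conditional hypergeometric probabilities of all margin-preserving
tables no more probable than the observed one; enumeration runs over the
k−1 smallest column totals, which is fast for the contingency shapes this
surface produces (one dominant category). Degenerate continuous
comparisons (both groups constant and equal) report statistic 0, p 1.

Correlation screening pairs the siMS score with each biomarker using
Pearson or Spearman per the shipped map (Spearman for skewed raw markers,
Pearson for their log transforms and for approximately normal variables),
with listwise deletion per analysis and the used n recorded. Zero variance
yields an undefined correlation (None), not a number. Raw p-values are
reported; a Benjamini-Hochberg adjustment is available behind a flag and
defaults off, and the 0.05 threshold is used only to annotate reports,
never to filter rows.

## Problem sizes in tests

Copula parameter recovery uses n = 10,000 (3-SE band for means, ±0.05 for
Spearman); cohort-level siMS means average 20 seeded cohorts per age group
at the published sizes (167 young, 284 older); the glycoregulation
ordering check uses one n = 2,000 cohort with 5% induced IFG and IGT; the
t-test calibration uses 2,000 simulated null datasets of 50 per arm. These
sizes put Monte-Carlo noise well inside each acceptance band while keeping
the default suite fast.

## Known limitations

* The siMS *risk* score (the age/family-history-weighted companion index)
  is out of scope — its formula is not part of this surface.
* No unit auto-conversion: inputs are contractually SI (mmol/L, mIU/L).
* The generator's category prevalences for glycoregulation do not match
  the published ones (see above); only orderings and cohort-level score
  means are claimed.
* The 2×k exact test refuses tables whose enumeration would exceed
  ~5·10⁶ tables rather than silently approximating.
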