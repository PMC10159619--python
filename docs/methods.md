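# Methods

This note documents the statistical procedures `prseval` implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Scoring and harmonization

A score is Σ_k β_k x_k over the variants of a published weight file, with
x_k the effect-allele dosage in [0, 2]. Weights declared as odds ratios
are converted to natural logs at parse time so all downstream math is on
the log-odds scale; files weighted by excluded schemes (odds ratio over
expected risk, inverse-variance, unweighted) are rejected at validation.

Score variants are matched to the cohort panel by (chromosome, position) —
rsIDs are unreliable across builds; id-based matching is available by
option. Allele-pair resolution distinguishes four orientations: *direct*
(effect allele is the counted allele), *swapped* (dosage transform
x → 2−x), and the two strand-complement counterparts. Palindromic (A/T,
C/G) variants are dropped by default and counted separately: their strand
cannot be verified without frequency heuristics, and a silent strand error
corrupts the score; the permissive policy is available for audit. The five
harmonization counts (direct, swapped, complement, palindromic-dropped,
missing) always partition the score's variant list, and this is asserted.

Missing dosages are imputed at twice the sample effect-allele frequency,
the long-standing default of allelic-scoring tools; zero-fill is available
for audit. Standardization subtracts the mean and divides by the SD
(ddof = 1) of a configurable stratum — by default the sex-specific
analysis set, because all the analyses this package mirrors are
sex-stratified — and applies that affine map to every sample.

Variant QC retains variants with imputation INFO ≥ 0.8, MAF ≥ 1%,
HWE p ≥ 1e-6, call rate ≥ 95%, and exactly two alleles; every threshold is
configurable and every exclusion is logged with its reason.

## Discrimination

The case/non-case distribution shift is summarized by a Welch
(unequal-variance) two-sample t-test — the unequal-variance form is the
safer default when only "two-sample t-test" is specified. AUC is computed
as the Mann–Whitney concordance probability with ties counted ½; for a
single monotone predictor this equals the AUC of a logistic model on that
predictor. Its CI uses the DeLong placement-value variance estimator,
chosen over the bootstrap for determinism. The age-adjusted AUC ranks the
linear predictor of a two-covariate logistic model (score + age) instead
of the raw score. The time-to-event sensitivity metric is the
cumulative-case/dynamic-control AUC at 5 years with
inverse-probability-of-censoring weights from the Kaplan–Meier censoring
distribution (delegated to scikit-survival). Best-score selection is
argmax AUC, with ties broken by smaller missing-variant fraction, then
lexicographic id, and logged.

## Survival association

Follow-up runs from recruitment to the first of site-specific cancer,
death, or the administrative end, capped at 20 years; death and the cap
are censorings for the cancer endpoint. Quantile groups (K = 5 by
default) are formed by stable rank order so boundary ties cannot unbalance
group sizes beyond one subject; the middle group — the 40–60% band,
representing average population risk — is the referent. Cox models use
Efron tie handling (the modern default; fitted via lifelines) with Wald
CIs. The trend test enters the ordinal group code 1..K as a single
continuous covariate, age-adjusted, and reports its two-sided Wald p —
the ordinal coding is a choice; group-median coding would differ little
with near-equal groups. The proportional-hazards check is the
Grambsch–Therneau score test on scaled Schoenfeld residuals against the
identity time transform. Monotone-likelihood fits (e.g. a quantile group
with zero events) are flagged and returned with capped estimates rather
than raised, mirroring how degenerate strata appear in real evaluations.
The fully adjusted per-SD model takes age plus the lifestyle covariate
schema (dialect, education, BMI, smoking, alcohol, moderate and vigorous
physical activity, family history), dummy-coding categoricals against
their first level.

## Absolute risk under competing mortality

Inputs are registry-style tables of marginal cancer incidence λ_m(a) and
all-cause mortality m(a) per person-year on contiguous age bands,
expanded to 1-year steps by repetition (closed-form within-step integrals
and exact agreement with the simulator's discretization are the reason
for the 1-year grid). PRS bands are equal-percentile intervals (default
width 5%, 20 bands) with relative risk RR_g = exp(β·E[Z|band]), where β
is the per-SD log hazard ratio and E[Z|band] the truncated
standard-normal mean — the package's own construction, since published
evaluations rarely state how band RRs were derived from a per-SD effect.

The band-constrained baseline hazard solves

    λ_m(a) = Σ_g π_g(a) · λ₀(a) · RR_g

by fixed-point iteration: update λ₀ from the constraint under the current
at-risk weights; recompute group survival
S_g(a) = exp(−Σ_{u<a} [λ₀(u)RR_g + m(u)]) and weights
π_g(a) = π_g(a₀)S_g(a)/Σ_h π_h(a₀)S_h(a); stop when the largest change in
λ₀ falls below 1e-8 (typically < 10 iterations). Risk accumulation starts
at a₀, the youngest age in the rate table. The weighted mean RR is
computed as 1 + π·(RR−1), which makes the RR ≡ 1 case return λ₀ = λ_m
bit-exactly. The 5-year absolute risk treats death as a competing event
with piecewise-constant hazards:

    ar5(a,g) = Σ_{u=a}^{a+4} [h_g/(h_g+m)] (1−e^{−(h_g+m)})
               · exp(−Σ_{v=a}^{u−1}(h_g+m)),   h_g = λ₀·RR_g.

A consistency check compares the π-weighted mixture of band-level 5-year
risks against the 5-year risk computed directly from λ_m. In continuous
time the two are identical for a converged solution; on the 1-year grid a
residual of order (within-window hazard spread)² remains — about 4e-5 at
the steepest ages of the default rate table, and below 1e-6 at
registry-scale incidences of ~1e-3.

## Calibration

Subjects are split into PRS deciles (stable rank order); *expected* is the
mean model-predicted 5-year risk in the decile, the prediction taken from
the absolute-risk curve at the subject's (floored) age and PRS band;
*observed* is the proportion with the cancer within 5 years. Subjects who
die cancer-free within the window remain in the denominator — consistent
with a predictor that already accounts for competing death. Overall
calibration is the OLS slope of the 10 observed-on-expected points with a
t-based 95% CI: slope above 1 means the model underestimates absolute
risk, below 1 that it overestimates.

Goodness of fit uses the Hosmer–Lemeshow statistic
Σ_d (O_d−E_d)²/(E_d(1−E_d/n_d)). Because the predicted risks come from an
*external* model — nothing is estimated on the validation data — each cell
is asymptotically an independent χ²₁ and the reference distribution has
as many degrees of freedom as usable groups (10), not the classical
in-sample g−2 = 8; simulation confirms the nominal 5% type-I rate under
this convention, while g−2 would reject ~11% of well-calibrated runs. The
classical convention remains available (`n_fitted_params=2`), as does an
explicit `df`. Deciles with zero expected events (a real phenomenon: a
score can leave low bands event-free) are skipped with a warning and the
df reduced, rather than patched with pseudo-counts.

## The synthetic cohort

The generator emulates the statistical structure the evaluation assumes,
at the scale of a large Asian prospective cohort:

- **Genotypes**: hard calls in Hardy–Weinberg proportions, allele
  frequencies uniform on [0.01, 0.5], INFO = 1, exact-test HWE p, no
  missingness by default, non-palindromic allele pairs. No linkage
  disequilibrium, admixture, or genotyping error.
- **Scorefiles**: N(0, 0.05) log-odds weights, written in randomly
  shuffled orientations (direct/swapped/strand-complement) to exercise
  harmonization without changing the defined score.
- **Recruitment ages**: 45 + lognormal(μ, 1.0) truncated to [45, 74] by
  rejection, with μ solved so the truncated median is 54 (resulting IQR
  ≈ 49.9–60.2). A pragmatic fit to reported summaries, not a
  reconstruction.
- **Outcomes**: cancer hazard baseline(a)·exp(β·z) with default baseline
  2e-3·(a/60)⁴ per person-year (registry order of magnitude for a common
  cancer site), competing death at Gompertz 6e-5·e^{0.085a}, both
  piecewise-constant on 1-year steps since recruitment with exact
  within-step exponential sampling, administrative censoring at 20 years.
  Default per-SD hazard ratio 1.5, the mid-range of published per-SD HRs
  (≈1.2–2.1) for common cancers.
- **Covariates**: lifestyle variables drawn with realistic marginal
  frequencies but independent of outcome, so adjusted and unadjusted
  models agree in expectation; confounding can be injected for
  robustness experiments.
- **Registry table**: marginal incidence baseline(a)·exp(β²/2) — the
  expectation of exp(βZ) over fresh standard-normal scores — plus the
  configured mortality.

One caveat documented deliberately: the generator recruits subjects with
fresh N(0,1) scores at every age, so its registry marginal carries no
risk-score depletion, whereas the baseline-hazard solver models depletion
from a₀. The two descriptions agree to ~1% through the recruitment ages
(the divergence reaches ~4% by age 94 with the default rates), which is
why the baseline-recovery test is bounded to ages ≤ 65 while the solver's
own marginal constraint is verified to 1e-8 at every age. Passing tests
on this generator demonstrate correctness of the estimators under the
assumed proportional-hazards structure; they cannot demonstrate
robustness to LD, population structure, secular trends in registry rates,
or informative censoring, none of which are simulated.

## Determinism and problem sizes

All randomness flows from a single integer seed through
`numpy.random.default_rng`; pipeline reruns into fresh directories are
bit-identical. Simulation-based tests use 50–500 seeds at n = 5,000–20,000
(parameter-recovery, null-calibration, and coverage checks) and a 10⁶-
subject forward microsimulation for the absolute-risk oracle — sizes
chosen to give the binomial acceptance bands adequate power while keeping
the full suite comfortably runnable on one CPU.

## Known limitations

- No genome-build liftover or rsID resolution against external databases;
  positions must already be on one convention.
- Left truncation by age is not modelled: time-since-recruitment is the
  Cox time scale, with age as a covariate, as in the design this mirrors.
- No Fine–Gray competing-risks regression; competing death enters only
  the absolute-risk and calibration machinery.
- Absolute-risk curves carry no confidence intervals.
- The calibration of the HL test degrades when expected counts per decile
  fall below ~3; the package does not merge sparse deciles automatically.
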