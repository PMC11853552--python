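# Methods

## The score card

The default card bins eight office-based variables into ordinal points and
sums them into a composite risk score for bladder outlet obstruction:

| variable | 0 pt | 1 pt | 2 pt | 3 pt |
|---|---|---|---|---|
| age (years) | < 65 | ≥ 65 | — | — |
| IPSS V/S | < 1.0 | [1.0, 2.0) | ≥ 2.0 | — |
| Qmax (mL/s) | > 15 | [13, 15] | (10, 13) | ≤ 10 |
| voided volume (mL) | > 300 | [201, 300] | (150, 201) | ≤ 150 |
| TPV (mL) | < 30 | [30, 40) | [40, 50) | ≥ 50 |
| TZI | ≤ 0.30 | (0.30, 0.50) | ≥ 0.50 | — |
| IPP (cm) | < 0.5 | [0.5, 1.0) | ≥ 1.0 | — |
| PUV angle (°) | < 30 | [30, 40) | ≥ 40 | — |

The per-row maxima sum to a top score of **18**. (The published table prints a
nominal total of 0–20 alongside row maxima that sum to 18; the package keeps
the row-level values, which are the ones actually summed, and documents the
discrepancy rather than reconciling it. The published abstract also speaks of
"seven variables" while listing eight rows; the shipped `no_age` variant
covers the seven-variable reading — age being the only row that is neither a
symptom, prostate nor uroflowmetry parameter — without guessing which seven
were originally summed.)

**Gap-closing convention.** The published rows are printed at measurement
resolution ("13–15 / 11–12", "151–200 / 201–300") and leave real-valued
gaps. Bins are made contiguous by extending each interior bin up to (but
excluding) the next bin's printed lower bound: a Qmax of 12.5 falls in the
"11–12" bin (2 points), a voided volume of 200.5 in the "151–200" bin
(2 points). Printed inclusive boundaries (≤ 10, ≥ 65, …) are kept inclusive.
Every value of a variable's domain then matches exactly one bin; values
outside the domain (or non-finite) raise an error rather than scoring 0,
because a silent zero in a sum-score biases it low. Missing data are
likewise a hard error — no imputation.

Cards are serialized as JSON (variable, ordered bins with explicit endpoint
closedness, integer points), so alternative cards are configuration, not
code.

## Synthetic cohort generator

The generator emulates a cohort of 355 men with medication-refractory LUTS:

* **Labels.** Multinomial over eight VUDS subtypes with prevalences equal to
  the study counts/355 (BND 136, BPO 98, DV 28, PRES 26, DO 37, DU 14,
  STABLE 9, HSB 7). BND and BPO form the BOO group.
* **Continuous variables.** Conditional on group, the eleven clinical
  variables follow a Gaussian copula: latent MVN with a documented
  correlation matrix, scaled by the group-conditional means/SDs (BOO vs
  non-BOO; e.g. Qmax 9.4 ± 5.5 vs 12.4 ± 7.7 mL/s, TPV 40.7 ± 20.5 vs
  30.8 ± 13.4 mL). The correlation defaults encode qualitative physiology —
  flow falls with age, prostate size and protrusion; prostate variables
  (TPV, TZI, IPP, PUV) co-move; flow rises with voided volume — and are
  fully overridable. Only group-conditional marginals are calibrated
  targets; the joint structure is a modelling choice.
* **BPO vs BND contrast.** The published study reports only pooled BOO marginals,
  yet evaluates the score against BPO specifically, so BPO receives additive
  mean offsets on the prostate variables (defaults: TPV +5 mL, TZI +0.05,
  IPP +0.25 cm, PUV +7°, roughly half the BOO/non-BOO gap). Offsets are
  centred by subtype prevalence and the within-subtype SDs shrunk so the
  *pooled* BOO mean and SD remain exactly at the configured targets —
  contrast is added without moving the calibrated group marginals. Offsets
  large enough to exceed the pooled variance are a configuration error.
* **Truncation.** Rejection sampling keeps draws inside physiological
  bounds (age 40–95 y, TZI 0.05–0.95, IPP 0–3 cm, PUV 0–90°, flows and
  volumes ≥ 0, IPSS subscores within their scale ranges). Truncation
  distorts marginal moments (most visibly for IPP and PVR, whose means sit
  within one SD of zero), so *calibration* checks run with bounds widened
  (`GeneratorConfig.with_wide_bounds()`), where every group mean and SD is
  verified to land within 3 standard errors of its target at ~10⁵ per group.
  The 4-SE band in the routine unit test simply reduces false alarms across
  ~66 simultaneous seeded checks.
* **RNG contract.** One integer seed spawns the label stream, the copula
  stream and (in the pipeline) the split seed, in a fixed documented order;
  equal seeds give bit-identical cohorts and byte-identical artifacts.
* **Split.** Training size is `floor(fraction·n + 0.5)`; stratified by
  label (largest-remainder apportionment) by default. The study's partition
  of 355 patients is 285/70 — 80.3/19.7%, nominally "80/20"; nominal 0.80
  gives exactly 284/71 under any rounding rule, so the pipeline's default
  fraction is 285/355 to mirror the study.

**What the generator does not emulate:** urodynamic pressure–flow traces,
PSA, treatment response, measurement error structure, between-centre
heterogeneity, or any real joint-distribution features beyond the chosen
copula. Passing tests therefore demonstrate the correctness and calibration
of the pipeline's machinery on data with the study's printed structure —
not clinical performance on real patients.

## Card derivation

Candidate cutoffs for a variable are the midpoints of consecutive sorted
unique observed values (invariant to monotone measurement jitter), plus the
two infinities, which can never be selected. For an ascending grid of
target specificities the k-th cutoff is the least extreme candidate whose
specificity against the BOO label first reaches the k-th target; since
specificity is monotone and sensitivity anti-monotone in the cutoff, this
also maximises sensitivity among qualifying candidates and is fully
deterministic. Unreachable targets, collapsing targets (two targets mapping
to one cutoff) and constant variables raise derivation errors. An optional
Welch two-sample screen (α = 0.05) drops variables that do not differ
between BOO and non-BOO before derivation, mirroring the selection of
significantly different variables. The packaged default card is the
published one; derivation exists to build cards from new labelled cohorts,
not to re-derive the published cutoffs (whose patient-level data are
unavailable).

## Evaluation

* **AUC** is the Mann–Whitney concordance probability with tied pairs
  counted ½ — ties are pervasive because the score is a small integer. The
  implementation is rank-based; tests verify it against brute-force pairwise
  enumeration to 1e-12 and against scikit-learn.
* **Direction.** Targets flagged by *low* scores (`le`: BND, PRES, DV, DU,
  pooled HSB+normal) negate the score internally, so a reported AUC above
  0.5 always means the stated rule discriminates.
* **Youden threshold.** Maximises J over the observed score values; ties
  break toward higher sensitivity, then the smaller threshold. Thresholds
  are integers because the score is. They are chosen on the training split
  only and frozen for validation.
* **Confidence intervals.** DeLong's asymptotic variance from midrank
  structural components (verified against R's pROC to 1e-9 on fixtures, and
  by a 1,000-replicate coverage experiment at n = 285: empirical 95% CI
  coverage within [93%, 97%]). Perfect separation has zero estimated
  variance; the degenerate point interval is returned with a warning.
  Hanley–McNeil is available via `method="hanley-mcneil"`.
* **Subtype table.** One-vs-rest per target ("HSB_NORMAL" pools the
  hypersensitive and stable bladders into a single target); targets absent
  from a split produce a flagged row while the others are still reported.

On the default synthetic cohort the composite score's BPO one-vs-rest AUC
is around 0.63–0.73 depending on the seed — lower than the published 0.800,
as expected: the generator knows only pooled group marginals plus the
modest default BPO offsets, not the real within-BOO structure the original
card exploited. The end-to-end checks are accordingly directional and wide:
the composite AUC must beat chance by a documented margin of 0.10 and must
not fall more than two DeLong standard errors below any single constituent
variable's AUC (raw continuous IPP, being more granular than the 0–18
integer score, can sit within noise of it). The weak low-score rule for
detrusor underactivity is asserted only loosely (specificity < 0.8 at its
Youden point), as its exact landing depends on integer-threshold
discreteness.

## Numerical choices and degenerate inputs

* Specificity-target comparisons use a 1e-12 slack so exact rational ties
  are treated as ties in floating point; the minimum genuine J gap at the
  tested sizes is ≥ 1/900, far above the slack.
* Empty cohorts, single-class label vectors, fractions outside (0,1),
  non-positive-definite correlation matrices and non-summing prevalences
  all raise typed errors (`InputError`/`ConfigError` vs
  `UndefinedMetricError`/`DerivationError`), mapped to CLI exit codes 1
  and 2.
* Rejection sampling aborts after 1,000 rounds if truncation bounds are
  inconsistent with the configured marginals.
* Report CSVs fix numeric columns at 3 decimals, matching the usual
  presentation of diagnostic tables.

## Problem sizes used by the test suite

Simulation-based checks run at sizes chosen to make their statistical
assertions sharp but cheap: calibration at n = 3×10⁵ (≈10⁵ per group),
DeLong coverage with 1,000 replicates of n = 285, oracle checks on 1,000
instances of n ≤ 30, monotonicity on 10⁴ random patient pairs, and
end-to-end behaviour on a fixed-seed n = 2,000 cohort.

## Known limitations

* The generator's copula correlations and BPO offsets are modelling
  choices, not estimates; conclusions about real diagnostic accuracy cannot
  be drawn from synthetic performance.
* IPSS V/S is sampled as its own marginal rather than recomputed from the
  voiding and storage subscores, matching how the group statistics are
  reported; the three IPSS columns are therefore mutually consistent only
  in correlation, not algebraically.
* Truncated sampling changes marginal moments under the physiological
  default bounds; calibration statements hold for the untruncated
  configuration.
* The published per-cutoff sensitivities/specificities are treated as
  whole-cohort binary splits at each cutoff (the usual reading); within-bin
  rates are not modelled.
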