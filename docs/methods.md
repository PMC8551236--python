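# Methods

This note documents the statistical model the package implements, the
defaults it ships, what the synthetic cohorts do and do not emulate, and
the numerical choices made where the design was genuinely open.

## The gait model

Eight spatiotemporal variables are derived per subject from an electronic
walkway protocol of four self-paced walks of 6–8 steps each. Trial 1 is a
familiarisation trial and is always discarded; variables are computed per
trial on trials 2–4 and the three per-trial values averaged:

| variable | definition | units |
|---|---|---|
| gait speed | mean step velocity over the trial's steps | cm/s |
| step time | mean first-contact-to-first-contact interval | s |
| double support time | mean both-feet-on-ground interval | s |
| step length CV | sample SD / mean × 100 over the trial's step lengths | % |
| swing time CV | same, swing times | % |
| step velocity CV | same, step velocities | % |
| step time asymmetry | 100 × \|ln(left mean / right mean)\| | % |
| swing time asymmetry | same, swing times | % |

CVs use the sample SD (n − 1); with 6–8 steps per trial the population-SD
alternative would bias CVs down by ~8%. CVs and asymmetries are computed
**within** each trial and then averaged, not pooled across trials: pooling
would fold between-trial drift into the variability estimate. A
`pool_trials` switch provides the pooled alternative because the original
analysis does not state which convention it used.

The three factors collapse the eight variables. An exploratory factor
analysis of the 8 × 8 Pearson correlation matrix — principal-axis
extraction (squared-multiple-correlation priors, iterated communalities)
followed by raw varimax rotation, factor count fixed at three — assigns
each variable to every factor on which it loads |r| ≥ 0.40. The expected
allocation is pace/rhythm {gait speed, step time, double support time},
variability {three CVs, gait speed} and asymmetry {two asymmetries}, with
gait speed shared. The extraction/rotation recipe is a documented
assumption (the source model's exact recipe is not restated in the
literature the package follows); it is exposed via configuration, and the
test suite cross-checks the resulting allocation against an independent
maximum-likelihood factor analysis with varimax rotation (scikit-learn).

Factor scores use the weighted-sum-score convention: each variable is
z-scored against a reference sample and each factor's score is the sum of
its allocated z-scores multiplied by the sign of the loading, with the
factor's overall sign fixed so that impairment (slower gait, longer times,
larger CVs/asymmetries) increases the score. Unit weights are the default
reading of "weighted sum score" in the scoring literature this model
follows; |loading|-weighted sums are available (`weighting="loading"`).
The z reference is the pooled analysis sample (consistent with fitting the
EFA on the combined cohorts); HS-referenced z-scores, used for the
radar-chart export, divide by the healthy cohort's mean/SD instead. Which
reference the original factor scores used is not stated; both are
implemented and labelled.

The model score is the fitted probability from a maximum-likelihood
logistic regression (statsmodels, Newton/IRLS) of cohort membership on the
three factor scores. Complete or quasi-complete separation is flagged
(`separation=True`) rather than raised.

## Discrimination layer

- AUC: midrank (Mann–Whitney) estimator; ties count ½. Raw variables are
  oriented higher-is-impaired (gait speed negated) before any ROC quantity.
- 95% CI: DeLong placement-value variance with a normal approximation,
  truncated to [0, 1]; zero variance (perfect separation) gives a flagged
  point interval. A bootstrap CI is deliberately not the default: DeLong
  matches the nonparametric ROC estimation convention of the statistical
  packages this analysis mirrors.
- Correlated-AUC comparison: DeLong multi-score contrast, χ² with df equal
  to the rank of the contrast covariance.
- Optimal cutoff: Youden (maximal sensitivity + specificity) over midpoints
  between adjacent distinct scores plus outer sentinels; a subject is
  positive when score > cutoff. Ties break toward higher specificity, then
  toward the higher cutoff — deterministic and order-independent.
- Accuracy bands: > 0.90 high; 0.70–0.90 moderate (0.70 and 0.90 both
  moderate, matching the printed interval convention); 0.50–0.70 low;
  < 0.50 chance.
- `binormal_auc` gives the closed form Φ(|μ₁ − μ₂| / √(σ₁² + σ₂²)) used to
  validate the summary-statistics reconstruction.

## Staging layer

Cohen's d with the pooled SD, √(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)),
compares each stage group with the healthy cohort for all 12 measures
(8 variables, 3 factors, 1 model), a 72-cell grid. The sign is kept in the
export (`d_signed`; gait speed runs negative in impaired groups) but bands
are assigned on the magnitude: < 0.2 none, 0.2–0.49 small, 0.5–0.79
medium, 0.8–1.19 large, 1.2–1.99 very large, ≥ 2.0 huge (closed on the
left). One-way ANOVA per factor score across HS + stages is followed, when
significant at 0.05, by Fisher LSD pairwise t-tests (pooled within-group
MSE, df = N − k) with Bonferroni correction over the each-stage-vs-HS
family (m = 6); all-pairs correction is available via `family="all_pairs"`.
Stage labels are the modified Hoehn & Yahr decimals {1, 1.5, 2, 2.5, 3, 4};
stage 5 (wheelchair-bound) is rejected at input validation because the
model's validity domain excludes it.

## Synthetic cohorts

The generator replaces the unavailable clinical dataset. Subject level:
per subject, three latent factor scores f ~ N(0, I); each standardized
variable is Λf + u·ε with the 8 × 3 loading template Λ and unique SD
u = √(1 − Σλ²), then rescaled to the group's target mean/SD and clipped at
a positive floor of 1% of the group mean. Defaults:

- Group targets: the published per-variable means/SDs of the two cohorts
  (PD N = 298, HS N = 84).
- Loading template: ±0.75–0.80 on each variable's published factor, 0
  elsewhere, gait speed loading −0.65 on pace/rhythm and −0.55 on
  variability. The magnitudes are design parameters (the published
  supplement's loading values are not available); the gait-speed pair is
  chosen so that the *population* varimax solution keeps both loadings
  above the 0.40 threshold — a weaker cross-loading does not survive
  rotation and would fail to encode the published shared allocation.
- Stage gradient: per-stage means interpolate HS → pooled-PD offsets with
  severity multipliers (0.30, 0.45, 0.65, 1.00, 1.30, 2.00) for stages
  (1, 1.5, 2, 2.5, 3, 4); the multipliers are monotone and average ≈ 1
  under the published stage counts (7/27/60/99/93/12), so the stage
  mixture reproduces the pooled PD means. SDs interpolate the same way,
  floored at half the HS SD. Per-stage summary statistics were never
  published; this gradient is an illustrative construction and no claim
  of matching the published per-stage figures is made.
- Marginals are normal with positive clipping. This reproduces the
  published single-variable AUCs (see below) but explicitly does not model
  the right-skew real CV/asymmetry distributions; step time is the
  documented case where the normal model over-predicts the published AUC
  (0.61 analytic vs 0.55 published), so step time is excluded from the
  reconstruction set.

Step level: steps alternate feet over 4 trials. Side means carry
multiplicative offsets e^(±a/200), which invert the log-ratio asymmetry
formula exactly; within-side noise is sized so the pooled per-trial CV
hits its target after subtracting the between-side variance component;
step length is set to speed × step time; swing time defaults to 0.75 ×
step time (not itself a target); fields without a CV target get a 2%
step-to-step noise (`timing_noise_cv`); trial-1 means are shifted +5% so
the familiarisation-discard rule is observable. One root seed with
per-subject child streams makes cohorts byte-reproducible and
order-insensitive.

Round-trip accuracy (derive ∘ generate): timing and speed targets are
recovered within ~2% in aggregate; derived CVs sit a few percent below
target (small-sample SD bias at 6–8 steps/trial) and derived asymmetries a
few percent above (|ln| of a noisy ratio is a folded normal). The tests
assert the round trip at these documented Monte-Carlo tolerances. Passing
tests on these cohorts show the pipeline is self-consistent and recovers
planted structure; they do not show how the model behaves on real gait
data with skewed marginals, freezing episodes or walking-aid use, none of
which are simulated.

## Reconstruction of published AUCs

With only per-cohort means/SDs available, each variable's published AUC is
reconstructed by simulating both cohorts as independent normals at the
published sample sizes and averaging the midrank AUC over 500 replicate
draws (`pdgait.reconstruction`, exercised by `scripts/acceptance.py`).
Clipping is disabled there: the reconstruction's stated model is exact
normal marginals, and the floor would visibly shift the asymmetry AUCs
(≈18% of the PD step-time-asymmetry normal mass lies below zero). Seven of
the eight variables land within ±0.01 of their published values —
published model-level and factor-level AUCs are not reconstructable this
way because they depend on the unpublished between-variable correlations,
and are reported only as synthetic analogues with provenance labels.

## Problem sizes and numerics

Default test/acceptance problem sizes: 500 replicate draws for AUC
reconstruction and DeLong coverage, 20 replicates × n = 2000 for EFA
structure recovery, 150 step-level replicates for the generator round
trip, and the published cohort sizes (382 subjects) for pipeline runs;
these keep the full suite and the acceptance script in the tens of
seconds while leaving Monte-Carlo error well inside the asserted
tolerances. PAF iterates communalities to 10⁻⁶ (≤ 200 iterations) with
eigenvalues clipped at 0; varimax iterates the SVD fixed point to 10⁻¹⁰;
logistic fits fall back from Newton to BFGS and flag |β| > 50 as
quasi-separation; degenerate inputs (singular correlation, zero reference
SD, single-class labels, zero pooled SD with unequal means) raise typed
errors rather than propagating NaNs.

## Known limitations

- Normal marginals: no skew/kurtosis, hence no claim about step time's
  published AUC or about real CV/asymmetry tails.
- The stage gradient and loading magnitudes are constructed defaults, not
  published quantities; stage-wise z-scores and effect-size cell values
  are therefore synthetic analogues only.
- In-sample discrimination only (matching the original analysis); no
  cross-validation.
- No simulation of freezing of gait, walking aids, step-width variables,
  or age stratification.
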