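# Methods

This note documents the statistical model, the procedure, the synthetic
cohort generator, and the numerical and design choices behind `gdsirt`.

## 1. The 2PL measurement model

Binary (yes/no) item responses are modelled by the two-parameter logistic
item response model: subject *i* with latent severity θᵢ endorses item *j*
with probability

  P<sub>j</sub>(θ) = 1 / (1 + exp(−a<sub>j</sub>(θ − b<sub>j</sub>))).

The discrimination a<sub>j</sub> (> 0, unitless) controls how sharply the
item separates subjects above vs below its difficulty b<sub>j</sub> (in
latent-trait units; the 50%-endorsement point).  The *a(θ − b)*
parameterization is used throughout the public surface so b keeps this
interpretation; the fitter works internally in slope–intercept form
(z = c + dθ) for numerical stability and converts on output.

**Estimation.**  Marginal maximum likelihood via Bock–Aitkin EM.  The latent
trait is integrated against a standard-normal prior discretized on 61
equally spaced quadrature nodes over [−6, 6] with normal-density weights
renormalized to sum to one (a common IRT default; quadrature error is
negligible for pools of ≤ 30 binary items).  The E-step computes each
subject's posterior over the grid; the M-step refits each item's logistic
curve to the expected endorsement counts with a damped, vectorized Newton
solver.  Because the M-step fully maximizes the expected complete-data
likelihood, the marginal log-likelihood is non-decreasing across EM cycles
(asserted in the test suite).

* Convergence: maximum absolute parameter change < 1e−4, or 500 EM cycles.
* Bounds: a ∈ [0.05, 6], |b| ≤ 8, applied by clipping at convergence with a
  warning; this prevents divergence on quasi-Guttman items (whose MML
  likelihood increases without bound in *a*).
* Degenerate items (endorsed by everyone or no one) are excluded with a
  warning — their parameters are not identified.
* Missing responses are skipped item-wise in the likelihood
  (missing-at-random); all-missing rows are dropped.
* Standard errors are delta-method SEs from the per-item expected-count
  information at convergence.  They condition on the final posterior weights
  and therefore understate full-marginal uncertainty somewhat; they are used
  as ranking diagnostics, not for inference.

Known limitation: with very small item pools (J ≈ 2) MML retains a spurious
common slope for truly independent items (â ≈ 0.1–0.25 rather than the
lower bound), a familiar weak-identification effect; it is irrelevant at the
pool sizes the pipeline targets.

## 2. Scoring, ranking, reduction

Scale scores are **unit-weighted integer sums** of keyed responses, never
latent-trait estimates: clinicians use integer cutoffs, and the published
comparators (GDS30/GDS15/GDS4) are sum-scored.  The IRT model is used only
to *select* items, ranked by descending fitted discrimination (ties broken
by descending per-item AUC, then ascending item index).  Calibration uses
the development half only; parameters are frozen for all downstream steps.

The sequential reduction evaluates every k from the full pool down to
k_min = 4 (the smallest published GDS variant).  At each k the top-k scale
is compared against the full scale with the paired DeLong test within the
development and validation halves separately, and across halves with the
Hanley–McNeil independent-samples z using DeLong standard errors.  The
stopping rule is the dual criterion: a k "passes" when the DeLong p exceeds
α = 0.05 (two-sided) in *both* halves.  The selected k\* is the smallest
passing k whose predecessor k−1 fails in at least one half; if no k passes,
the full scale is returned with a no-reduction flag.  A development-only
rule is available as a configuration option.  The rule is local by design:
it finds the boundary where equivalence first breaks, and every p-value it
consults is logged in the run summary for audit.

The expected test information of each top-k scale — the sum of item
informations a²P(1−P) integrated against the standard-normal prior — is
recorded per step.  The elbow diagnostic reports the k maximizing the drop
in marginal information gain, Δ<sub>k</sub> − Δ<sub>k+1</sub> with
Δ<sub>k</sub> = I(k) − I(k−1); it never overrides the stopping rule.

## 3. ROC machinery and operating points

* AUC is the Mann–Whitney statistic with ties half-weighted; its variance
  comes from DeLong placement values, and the 95% CI is Wald on the AUC
  scale clipped to [0, 1] (the pROC "delong" default).  The implementation
  reproduces pROC's AUC, CI and paired-test z/p to at least six decimals on
  a frozen fixture.
* The paired DeLong test uses the placement-value covariance; identical
  score vectors are reported as Δ = 0, p = 1 with a degenerate flag.
* Youden cutoffs follow the convention "positive if score ≥ t", trying every
  observed score value; ties in J favour the higher cutoff (specificity).
* McNemar (paired accuracy): exact binomial below 25 discordant pairs,
  continuity-corrected chi-square otherwise.  Two-proportion comparisons use
  the continuity-corrected 2×2 chi-square.
* Predictive values are pure Bayes arithmetic from (sens, spec, prevalence);
  the cutoff sweep reports them under 3.8% (community), 13% (clinic) and
  20% (high-prevalence) scenarios.
* Internal computation is in fractions; percentages appear only in reports.

Small-sample caveat, established while validating against pROC: with ~10
cases per dataset the asymptotic paired DeLong test is mildly
anticonservative (measured type-I ≈ 0.077 at nominal 0.05 over 10,000 null
simulations; R pROC makes identical rejections on the same data).  At the
cohort sizes the pipeline targets (≥ 120 cases per half) this effect is
negligible.

## 4. Efficiency ratio

The efficiency ratio of a scale is AUC / (number of items).  Within one
sample, two scales are compared by resampling subjects with replacement
(pairing preserved), recomputing both AUCs and ratios per resample
(B = 1000 by default), and taking the 2.5th–97.5th percentile interval of
the differences; significance means the interval excludes zero.  A
supplementary two-sided bootstrap p, 2·min(F(0), 1−F(0)), is reported, but
the CI rule is the decision criterion.  Resamples that lose a diagnosis
class are redrawn (capped, with the redraw count logged).  Across
independent halves, efficiency is compared with
z = (eff_dev − eff_val)/√(SE²_dev + SE²_val) on bootstrap SEs.

## 5. Differential item and test functioning

Items are audited with the Mantel–Haenszel procedure, matching on the total
score of the scale under audit *including* the studied item — the classical
MH-DIF matcher (the choice is configurable in spirit; sparse strata with
fewer than 5 subjects are merged with the nearest score level).  The common
odds ratio applies the 0.5 continuity correction only to strata containing
a zero cell; the MH chi-square uses the standard continuity correction.
Effect sizes are expressed on the ETS delta scale, ΔMH = −2.35·ln(α_MH)
(the −2.35 constant is the external ETS convention), and classified
A (|ΔMH| < 1 or p ≥ 0.05), B (1 ≤ |ΔMH| < 1.5, p < 0.05),
C (|ΔMH| ≥ 1.5, p < 0.05).  Signed ΔMH and the favoured group are reported
explicitly, since the magnitude alone does not identify direction.  DIF is
audited on the combined sample by default (validation-only is a switch).
Scale-level impact (DTF) is the per-group AUC difference with DeLong CIs.

Caveat: on a 2PL (non-Rasch) scale the total score is not a sufficient
statistic for θ, so MH can flag *artifactual* DIF when groups differ
strongly in latent-trait distribution — e.g. community vs clinic recruits,
whose prevalences differ fourfold.  Null-calibration checks in the test
suite therefore use θ-matched groupings (sex, age).

## 6. The synthetic cohort generator

The generator emulates the statistical structure of the calibration cohort:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 6525 | calibration cohort size |
| clinic fraction | 0.061 | the only value consistent with 3.8% overall prevalence given per-source prevalences |
| prevalence | 3.2% community / 13% clinic (≈ 3.8% overall) | calibration cohort |
| θ | controls N(0, 1), cases N(1.7, 1) | latent-trait AUC Φ(1.7/√2) ≈ 0.885, placing the full-scale sum-score AUC near the reported 0.87–0.88; diagnosis-conditional score distributions are not published, so the case mean is calibrated to AUC rather than to moments |
| sex | 56.9% female | cohort composition |
| age ≥ 75 | 23% | implied by the cohort's age mean ≈ 70, SD ≈ 6.7 under normality |

Responses are drawn from the 2PL curves of a supplied item bank (the
packaged reference calibration by default), already keyed in the depressive
direction; reverse-wording is a presentation concern handled by the CSV
reader's keymap (items 1, 5, 7, 9, 15, 19, 21, 27, 29, 30).  Optional
per-group difficulty offsets enter as a(θ − b + shift), so a positive shift
makes the item easier for that group — the mechanism used to inject known
DIF.  Recruitment source shifts prevalence only, never the response model
(unless DIF offsets say otherwise).  The generator is complete-case: item
nonresponse mechanisms are deliberately out of scope (the fitter tolerates
missingness, the generator does not produce it).

**What passing tests do and do not show.**  The generator is 2PL-exact and
unidimensional.  Real questionnaire data are neither: real low-discrimination
items carry correlated nuisance variance and some unique validity.  One
visible consequence: in synthetic cohorts the unit-weighted top-7 scale is
already population-equivalent to the full 30-item scale, so the data-driven
k\* scatters well below and around 10 across seeds, whereas a real cohort
can break equivalence at 9 items.  Recovery results on synthetic data
therefore validate the *machinery* (calibration, testing, selection logic),
not the claim that any particular k is right for a real population.

## 7. Reproducibility and problem sizes

Every stochastic component takes an explicit seed (cohort, split,
bootstrap), and a pipeline run writes a config-hashed, byte-reproducible
JSON summary.  The test suite sizes its simulations to what the checked
property needs: oracle equivalences run exhaustively at n ≤ 12; type-I
calibration uses 1000 null datasets of n = 200; parameter recovery uses 10
cohorts of n = 5000; end-to-end selection uses 50 cohorts at the full
n = 6525; DIF power/size use 20 cohorts.  These sizes were chosen as the
smallest at which the corresponding sampling distributions are tight enough
for the assertions to be meaningful.
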