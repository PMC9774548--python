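# Methods

This note documents the models, algorithms and design choices behind
`gazebias`, and what the synthetic-data validation does and does not show.

## Fixation detection

Gaze events are segmented by a **lead-sample dispersion rule**, a variant
of dispersion-based (I-DT-family) detection in which membership is judged
against a fixed reference sample rather than the running window extent.
The first retained sample of a stream is a lead; every subsequent sample
joins the current run iff its Euclidean distance to the *lead* is at most
`dispersion_px` (default 37 px = 1° at the calibrated viewing distance on a
1920 × 1080 display); the first sample outside that circle becomes the next
lead.  Runs of at least `min_samples` (default 3) are emitted as
fixations.  Decisions worth recording:

* **Inclusive threshold.**  A sample exactly 37 px from the lead is a
  member ("no farther away than" reads as ≤).
* **Duration is count-based.**  `duration = n_samples × (1000 / rate)`,
  so three samples at 60 Hz make a 50 ms fixation.  A
  timestamp-difference definition would give 33.3 ms for the same run and
  is rejected; hardware timestamps jitter, sample counts do not.
* **Greedy single pass.**  A sample that leaves the current run always
  becomes the new lead, even when the aborted run was below `min_samples`;
  discarded sub-threshold samples are never revisited.  An alternative
  reading would re-test discarded samples against later leads; the greedy
  reading is simpler, deterministic, and fixed here.
* **Gap tolerance.**  "Consecutive" means consecutive *retained* samples
  (missing samples are dropped upstream).  A run closes when the time gap
  between neighbours, rounded to whole nominal sampling intervals, exceeds
  2 intervals — i.e. a single lost sample never splits a fixation, two or
  more in a row always do.  The rounding makes the rule robust to
  millisecond-scale timestamp jitter around the boundary.

The detector is verified against an independently written brute-force
implementation of the literal rule: exhaustively on every stream of length
≤ 12 over a three-point near/near/far alphabet (~800 k streams) and on
1,000 random walks with dropouts.

## AOI metrics and curation

Three disjoint rectangular AOIs cover the left stimulus, the right
stimulus and the central fixation cross.  The original study does not
print pixel bounds, so the defaults (left `[0, 860)`, right `[1060, 1920)`,
cross `[860, 1060) × [440, 640)`) are declared package defaults, not
inferred values.  A fixation accrues its **full duration to every AOI that
contains at least one of its member samples**.  This whole-fixation accrual
is what makes the combined AOI time of a border-gazing trial exceed the
slide duration — precisely the anomaly exclusion criterion (a) screens for
(combined time strictly over 5500 ms).  Criterion (b) removes trials whose
left or right AOI received no fixation at all; it never applies to the
cross.  First/second/third fixation durations are per-AOI ordinals (the
n-th fixation assigned to that AOI in time order).

Kept slides are collapsed over mirror pairs.  The schedule maps each
slide's left/right side to an animal category, metrics are re-keyed per
animal, and the two side-arrangements of a base pair are averaged — the
only reading under which mirror averaging cancels side preference.  Full
pairs get observation weight 1, lone survivors ½; the weight later scales
residual variance.  The curation report exposes both bookkeeping paths
(slide-level exclusions, and the additional half-pair drops that the count
model incurs) side by side without attempting to reconcile them.

## Mixed-effects models

All responses are modelled with a participant random intercept.  The
Gaussian engine fits

Var(ε_ij) = σ² · δ²_{nat(i)} / w_ij,

a per-nationality residual-SD multiplier (reference level fixed to 1, the
analogue of nlme's `varIdent`) combined with fixed inverse-weight variance
(`varFixed`).  β and σ² are profiled out in closed form; the remaining
variance parameters (log intercept-SD ratio, log multipliers) are
optimised numerically; reported fits use REML, model comparisons use ML.
The engine reproduces `nlme::lme` with `varComb(varIdent, varFixed)` to
~10⁻⁵ and collapses exactly onto `statsmodels` MixedLM when weights are 1
and a single stratum is present (both are test oracles).

Fixation counts are additionally fitted by a **Poisson log-link GLMM**
via adaptive Gauss–Hermite quadrature (15 nodes); the marginal likelihood
matches direct numerical integration to ~10⁻⁶ and `lme4::glmer` to ~10⁻⁴.
No weight-based variance structure exists for this model class, so the
count model uses only full-pair sums (integer responses, weight-1
observations), as the analysis plan prescribes.

**Inference.**  Factors are sum-to-zero coded; per-term Wald F statistics
are therefore marginal (Type-III-style).  Scalar contrasts — cell means
tested against zero, estimated marginal means and their pairwise
differences — carry **Satterthwaite denominator degrees of freedom**,
computed by the delta method from the REML Hessian of the variance
parameters.  This matters: cell estimates are dominated by between-
participant variance, and with single-digit participants per cell the
effective df is ~10–40, not the thousands of observations; residual-df
t-intervals under-cover by several percent in exactly that regime.
Multi-df term tests use residual df (immaterial at these sample sizes).
Tukey adjustment uses the studentized range over the factor's k levels.

**Reduction.**  Backward elimination starts from the full factorial:
at each step the maximal terms (those not contained in a retained
interaction — marginality is never violated) are candidates; the least
significant candidate is removed iff its ML likelihood-ratio p ≥ 0.05
*and* removal does not increase the ML AIC; the final model is refitted by
REML.  The α for elimination is a package choice.  Post-selection caveat:
confidence intervals from a *selected* model do not account for the
selection event; at small cohort sizes elimination of a weak main effect
visibly shrinks cell estimates toward pooled means.  The recovery and
calibration simulations therefore evaluate cell means under the
unreduced cell-means model, while reported tables follow the reduction
procedure (at the full 132-participant design the retained terms
stabilise and the two agree).

## Synthetic cohorts

The generator emulates the study conditions: a 132-participant roster
(24/41/35/32 in the Somali/Czech × woman/man cells), 36 slides (12 images
per category, colour-group-matched into 18 pairs, mirrored, presented in a
seeded pseudo-random order with mirror mates separated by ≥ 3 positions;
half the cohort sees the reversed order), 300 samples per 5-s trial,
binocular jitter, track loss (2%), occasional single-eye loss, and planted
curation violations (rates 19/4752 for criterion a, 346/4752 for b,
matching the exclusion totals the analysis is meant to produce).

**Bias is planted directly.**  Each trial draws latent fixation-time and
count differences from the configured cell mean plus the participant's
random intercept and a nationality-scaled residual, then *constructs* the
sample stream to realise that allocation: alternating fixations (log-normal
durations, median 250 ms) at jittered anchors inside the stimulus AOIs,
separated by blank saccade gaps longer than the detector's gap tolerance,
with planted sample budgets inflated by 1/(1 − loss rate).  Because the
detector provably recovers the planted segmentation (jitter SD 3 px ≪
37 px dispersion), the configured cell means are *exact* expectations of
the measured metrics — the property the recovery, coverage and bookkeeping
tests rest on.  An earlier design based on target-AOI choice probabilities
calibrated by a pre-run was discarded: it leaves percent-level gaps between
configured and realised truths that coverage tests would mistake for
estimator bias.  The default cell means are the attentional-bias point
estimates the analysis is expected to reproduce (e.g. a 618.20 ms
scorpion−spider difference for Somali men); mirror-averaging a weight-1
observation halves the trial-level residual variance, so the model's
σ²/w structure holds exactly by construction.

What the generator does *not* emulate: saccade kinematics and
saccade-landing samples (saccades appear as tracker dropouts, which is why
retained sample counts run ~250–270 of the nominal 300), image-content
salience, pupillometry, drift and calibration error, and any dependence of
total looking time on pair type (per-trial stimulus looking time is ~4050
ms for every pair type).  Fixation counts are mildly under-dispersed
relative to Poisson, so the Poisson GLMM is exercised under realistic
misspecification, not validated for exact frequentist calibration.
Passing tests therefore demonstrate pipeline correctness and estimator
calibration under the declared generative model — not robustness to
everything real eye-tracking data can do.

## Numerical and simulation choices

* Nelder–Mead on ≤ 3 profiled variance parameters (tolerance 10⁻⁷); BFGS
  with numerical gradients for the Poisson GLMM, warm-started at the GLM
  fit; quadrature mode found by vectorised Newton iterations.
* Degenerate inputs: empty streams → empty results; rank-deficient designs,
  single-level factors, non-integer counts and nonpositive weights raise;
  a single variance stratum drops the varIdent part with a warning;
  singular position-check fits are reported, not fatal.
* Simulation sizes: the coverage/α-calibration suite runs 200 cohorts of
  24 participants (6 per cell) — small enough to keep the suite within a
  routine CI run, large enough that binomial noise on a 95% coverage
  estimate is ±1.5%.  The heteroscedasticity-recovery suite plants the 2×
  nationality multiplier on a 600 ms base SD, because a 2 × 1200 ms
  trial-level SD exceeds what a 5-second trial can physically express
  (the realised differences would be truncated by the time budget and the
  recovered ratio attenuated to ~1.75 — an honest ceiling of the paradigm,
  not of the estimator).  The acceptance script averages estimates over 24
  full-size cohorts to shrink Monte-Carlo error of the *measurement*
  while leaving each cohort at the study's own scale.
* One `numpy.random.default_rng(seed)` stream drives everything derived
  from a cohort seed; schedules take their own seed so a presentation
  order can be reproduced independently of a cohort.

## Known limitations

* The exact denominator-df method behind the original analyses is unknown;
  numerical equality with published t/F statistics is not promised even
  with identical data, only agreement in kind.
* The Poisson GLMM reduction inherits the model's misspecification on
  under-dispersed counts; its LRT-based term selection is less stable than
  the Gaussian one.
* Whole-fixation accrual plus disjoint AOIs means per-AOI dwell times are
  not additive across AOIs by design; consumers must use the curation
  report, not column sums, for trial-time accounting.
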