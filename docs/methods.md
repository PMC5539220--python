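# Methods

`metasdt` re-implements, with fully synthetic observers, the analysis
pipeline of a two-group behavioral metacognition study: substance-dependent
individuals (SDI, n = 23) versus controls (n = 24), each performing a
2-interval contrast-oddball perceptual task (180 trials, staircase-controlled)
and an old/new word-recognition memory task (100 learned words, 200 test
probes), with a 6-point confidence rating after every choice.

## Type-1 model

Choices are modeled by Gaussian signal detection. For a stimulus pair
(S1, S2) with hit rate H = P(respond S2 | S2) and false-alarm rate
F = P(respond S2 | S1):

* equal variance: d′ = z(H) − z(F), criterion c = −[z(H) + z(F)]/2;
* unequal variance (recognition memory, where old items carry more
  evidence variance than new ones): the zROC — cumulative rating ROC with
  both axes z-transformed — is linear with slope s = σ_S1/σ_S2. s is
  estimated by ordinary least squares across the 2K−1 rating criteria
  (endpoints at 0/1 excluded), and sensitivity is
  d_a = sqrt(2/(1+s²)) · [z(H) − s·z(F)], which reduces to d′ at s = 1.

OLS on the zROC is used because it is the conventional unequal-variance
estimator; nothing in the analysis depends on the handful of alternative
slope estimators. Perceptual d′ is computed yes/no-style over the two
intervals (S1 = target in interval 1), not with the √2 2AFC correction:
at 71 % staircase accuracy the yes/no form gives d′ ≈ 1.1, matching the
magnitude this design reports, whereas the corrected form would give ≈ 0.78.

**Padding.** z-transforms diverge on empty cells, so whenever any
cumulative hit/FA proportion is 0 or 1 every cell of the table gains
1/(2K) pseudo-counts (the convention of the classic meta-d′ code family).
The scheme (`only-if-needed` / `always` / `none`) is configurable and
recorded in the fit provenance.

## Type-2 model (meta-d′ / meta-da)

Meta-d′ asks: what type-1 sensitivity would an SDT-ideal observer need so
that, placing confidence criteria freely, it reproduces the observed
confidence distributions *conditional on* (stimulus, response)? Fitting is
by multinomial maximum likelihood over those response-conditional rating
counts; type-1 choice behavior is fixed from the data and never refit.
Details:

* Evidence: S1 ~ N(−μ/2, 1), S2 ~ N(+μ/2, 1/s); μ is the candidate
  separation and s is pinned from the type-1 unequal fit (1 for the equal
  model). The reported meta-d is d_a(μ, s), i.e. meta-d′ when s = 1.
* The type-1 criterion enters at the same relative position as in the
  data: meta_c = (c/d′)·μ (the standard convention; the alternative of
  refitting c inside the type-2 likelihood is not used).
* K−1 confidence criteria per response side are parameterized as meta_c
  plus cumulative exponentiated increments, which enforces strict
  monotonicity inside an unconstrained optimizer.
* Optimization: L-BFGS-B with an analytic gradient (validated against
  finite differences), meta-d box [−5, 5], objective tolerance 1e-8,
  ≥3 starts (first at the type-1 sensitivity, the rest jittered with a
  seeded RNG). The `converged` flag reports the optimizer's own status at
  the best optimum; negative meta-d is returned as-is, never clipped.
  A conditional standard error for meta-d (criteria held at their optima)
  is reported from the profile curvature.
* Confidence levels a subject never used stay in the table as structural
  zeros (padding handles them), keeping K comparable across subjects.

M-ratio = meta-d′/d′ (equal) or meta-da/da (unequal) is the efficiency
measure; it is undefined at zero type-1 sensitivity and deliberately
preserved when negative.

Known limitation, inherited from the unequal-variance formulation: s is
estimated from choices *and* ratings, then held fixed in both models, so
the type-1 and type-2 levels are not fully independent there. The package
surfaces this in docstrings rather than attempting to resolve it.

## Synthetic observers

Each trial draws evidence x from the type-1 model. Two independent noise
channels control metacognition:

* confidence noise τ_m: the confidence variable is y = x + N(0, τ_m²);
  the choice is untouched. M-ratio falls continuously from 1 as τ_m grows.
* choice noise τ_c: the choice compares x + N(0, τ_c²) to the criterion
  while confidence reads the cleaner x. M-ratio rises above 1.

With both at zero, confidence is a deterministic function of the same
evidence as the choice and fitted M-ratio is 1. This is the simplest
generative pair that spans efficiencies on both sides of 1; no claim is
made that it is the mechanism behind human inefficiency. Because neither
channel has a closed-form M-ratio (the fit conditions on the realized
choice), the forward map noise → M-ratio is tabulated once by 2×10⁵-trial
simulation (`scripts/build_calibration.py`, seed-fixed) and inverted by
interpolation. Observed M-ratio under these mechanisms is close to
performance-independent (spread < 0.03 across d′ 0.8–1.6 at fixed noise),
which is exactly the property the measure is designed for, so a single
table at d′ ≈ 1.1 serves all cohort sensitivities.

Confidence criteria sit at fixed offsets from the decision criterion,
scaled by the confidence variable's SD so that the rating distribution is
stable across noise levels. The default offsets (0.06, 0.10, 0.17, 0.29,
0.50) were tuned once so simulated mean confidence lands in the observed
4.6–4.9 band at mid-range sensitivity; they live in the observer defaults,
not in the fitting code.

Negative observed M-ratios are *not* generated directly: generative
targets are truncated at ~0 (confidence noise drives efficiency to 0 from
above), and the occasional negative fitted values arise, as in the
original data, from estimation noise at 180–200 trials.

## Staircase and perceptual task

Distractor contrast is 0.20; the oddball starts at 0.40 and moves in
absolute steps of 0.03: up after each error, down after two consecutive
correct responses ("step 3 %" is read as 3 contrast percentage points;
relative stepping is a configurable alternative). The rule converges where
p² = ½, i.e. ~70.7 % correct, so overall accuracy is tightly clamped
(between-observer SD ≈ 1–1.5 points) while contrast thresholds vary freely.
The observer's psychometric function is a cumulative Gaussian in contrast
difference from 0.5 at zero difference to 1 − lapse (lapse 2 %), with its
threshold defined at the staircase convergence level; cohort thresholds
are truncated normals matched to the printed group summaries. Per trial,
the staircase contrast maps through the psychometric function to an
effective sensitivity 2·z(P(correct)), which then drives the same
SDT evidence/confidence machinery as the memory task. Threshold estimates
average the contrast difference over reversals, discarding the first 4;
the accuracy statistic uses all 180 trials with no burn-in, matching how
the summary was reported.

Outlier exclusion flags subjects whose perceptual accuracy falls below
mean − 8·SD, with the reference mean/SD computed leave-one-out: an
extreme candidate must not inflate the very SD used to judge it (with a
pooled SD and ~50 subjects an 8-SD fence could mathematically never
exclude anyone).

## Cohort generation and variance budgeting

Per-group generative means are the published behavioral summaries
(perceptual M-ratio 0.67 vs 1.01; memory d′ 0.92 vs 1.19; memory M-ratio
0.82 vs 0.93; contrast threshold 0.19 vs 0.16; the group RT/CT means).
Target distributions are truncated normals *recentered so the
post-truncation expectation equals the printed mean*. Published SDs
describe single-session estimates, which add measurement noise on top of
true between-subject spread; measured estimation SDs (≈0.19 for memory d′
at 200 trials, ≈0.35 for M-ratio at 180 trials) are subtracted in
quadrature to set the generative spreads. Memory evidence-SD ratio
s ~ 0.8 (old items more variable), memory criterion and perceptual
criterion jitter ~ N(0, 0.1–0.15) truncated — the latter is what gives
perceptual d′ its observed ≈0.1 between-subject spread at clamped accuracy.
RT and confidence-time are decorative lognormals (log-SD 0.3) whose
subject-level medians are drawn to match the group mean/SD targets; they
carry no diffusion-style coupling to accuracy or confidence, which is out
of scope. Imageability is a pure label by default (the design found no
imageability main effect); an optional `imageability_d_effect` knob shifts
high/low sensitivity for power exploration.

What the generator does *not* emulate: learning/forgetting dynamics over
the session, word-level linguistic structure, interval-confusion errors,
sequential dependencies, or any RT–accuracy coupling. Passing tests
therefore validate the estimators and the statistical battery under the
stated SDT generative model — not the full richness of human data.

## Group statistics

Levene's test (classic form, absolute deviations from the group mean)
gates each two-tailed two-sample t-test: pooled variances unless Levene
rejects at α = 0.05, Welch with fractional df otherwise. Mixed
Group × Task ANOVAs (pingouin) report F, p and partial η². The
metacognition ANOVA is run twice — mixed units (equal-variance perceptual
M-ratio with unequal-variance memory M-ratio) and all-equal-variance —
and labeled, since the mixed-unit version rests on the assumption that
the two efficiencies are commensurable. Pearson correlations use
two-tailed p. Negative-M-ratio subjects are retained by default (a config
switch drops them for sensitivity analysis). No multiple-testing
correction is applied anywhere, matching the original battery; interpret
the family of p-values accordingly.

## Problem sizes in the shipped checks

The packaged acceptance checks use 120–150 staircase observers; 10⁴-trial
observers (20 seeds) for ideal-metacognition recovery; 20 random 50–500
trial tables against a 0.005-step profile-likelihood grid oracle; 100
seeded cohort replicates for the dissociation pattern and 50 for null
calibration. These sizes give Monte-Carlo error comfortably inside each
stated tolerance while keeping a full run in the minutes range.

## Numerical notes and degenerate inputs

* All-zero tables, single-stimulus tables and all-constant confidence are
  rejected with specific errors; all-correct subjects yield NaN measures
  carried as missing.
* Response-conditional probabilities are floored at 1e-12 inside the
  likelihood; region areas at 1e-300 in the gradient.
* Ratio measures (M-ratio, especially unequal-variance at 200 trials) are
  heavy-tailed when the fitted denominator is small; group summaries can
  show large SDs in single cohorts. This mirrors the estimator, not a
  simulator defect.
* The truncated-normal samplers use simple rejection; `with_mean`
  recentring solves the post-truncation expectation by Brent's method.
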