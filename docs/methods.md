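# Methods

## Task and apparatus model

The package models an operant two-alternative forced-choice (2AFC)
contrast-discrimination task on a touchscreen masked into two equal
panels (side 1 = left, side 2 = right). Each trial presents a striped
target on one panel and a uniform gray control of the same mean
luminance on the other; a snout touch on the target panel dispenses one
pellet, a touch on the control ends the trial unrewarded. A
weight-sensitive mat gates trial onset: the screen activates only after
the animal has stepped off the mat (to collect its pellet) and back on,
so it faces the screen when the stimulus appears. That gating is what
makes the activation-to-touch latency a meaningful confidence proxy,
and it is preserved in the simulation as an arm/disarm token: the
engine refuses touches until a full off/on mat cycle has occurred. The
touchscreen's 1 cm² minimum contact area is modeled as a boolean
validity flag on touch events; invalid touches are ignored without
consuming the trial.

Physical hardware (drivers, pellet dispenser, video) is out of scope;
the two-panel geometry exists only logically as `target_side ∈ {1, 2}`.

## Stimuli

Targets are square-wave gratings (50 % duty cycle, hard edges) defined
by Michelson contrast on linear 8-bit gray levels:
`C = (L_max − L_min) / (L_max + L_min)`. For contrast `c` at mean
luminance `m`, stripe levels are `m(1+c)` and `m(1−c)`. The standard
series is 10 contrasts, 10 %–100 % in 10 % steps, plus the control.

Numerical choices:

- **Rounding**: non-integer gray levels round half-up (away from
  zero), applied identically to target and control. Because the two
  stripe levels' fractional parts are complementary (they sum to the
  integer-valued `2m` at the default `m = 127.5`), half-up rounds
  exactly one of them upward and keeps the image mean within half a
  gray level of the control. Half-even can round both levels downward
  (e.g. 178.5 → 178 and 76.5 → 76 at 40 % contrast), opening a full
  level of mean mismatch, and was rejected for that reason.
- **Quantization bound**: at the default mean the achieved contrast of
  the rounded levels is within 1/255 of nominal; in general the bound
  is `1/(L_max + L_min)`.
- **Duty cycle**: the exact mean match additionally requires the
  stripe-axis length to be a multiple of `2 × spatial_frequency`
  (true for the 512 px / 8-pair defaults); otherwise stripes differ by
  one pixel and the mean may drift by up to `255·sf/width` levels.
- **Gamma**: gray level is taken as proportional to luminance; display
  gamma is a deployment calibration concern, not modeled.
- Stripe orientation (default vertical), spatial frequency (default 8
  pairs/image) and image size (default 512 × 512) are free parameters;
  none is constrained by the protocol itself.

## Trial protocol and randomization

Sessions come in three computational phases: operator-guided training
(parsed from logs only, never simulated), self-run training (100 %
contrast vs control) and the experimental phase (the 10-level series,
each level presented `reps_per_contrast = 10` times, i.e. 100 trials).
Sessions of 50–100 trials are the norm; other sizes are accepted with a
warning.

Target sides are **counterbalanced within contrast** — each level's
repetitions split as evenly as possible between panels (an odd
remainder assigned at random) before a global seeded shuffle — rather
than i.i.d. fair coins, because unlucky Bernoulli runs would confound
the side-bias analysis; an `iid_sides` flag restores pure random
assignment. One schedule stream (keyed by the session seed) and one
observer stream (keyed by the observer seed) are independent
`numpy` generators, so either can be held fixed; identical seed pairs
reproduce bit-identical logs.

Non-response handling: the protocol itself has no timeout (the animal
can stand in front of the screen indefinitely), so
`response_timeout_s` defaults to none; when set, late touches are
recorded as aborted trials, which are excluded from every performance
denominator. Each arm cycle draws the next scheduled trial; whether a
real system would re-display an untouched stimulus is unknown, and this
is an explicit assumption.

## Simulated observer

The probability of a correct choice at contrast `c` is

    p(c) = (1 − b)[γ + (1 − γ − λ) F(c; α, β)] + b/2,
    F(c; α, β) = 1 / (1 + exp(−β(c − α)))

- `γ = 0.5` — guess rate, fixed by the two-choice design (read-only).
- `λ ∈ [0, 0.1]` — lapse rate; stimulus-independent errors capping the
  upper asymptote. Default 0.02.
- `α` — threshold (logistic midpoint) in contrast fraction; `β` —
  slope. The logistic is taken in **linear** contrast because the
  tested grid is linear 10–100 %; a log-contrast or Weibull form is a
  reasonable alternative for finer grids but is not needed here.
- `b ∈ [0, 1]` — side-bias mixture: with probability `b` the preferred
  panel is touched regardless of the stimulus. Under counterbalanced
  sides this contributes accuracy ½, so `b → 1` drives one-side touch
  percentage to 100 while accuracy falls to chance — reproducing the
  empirical coupling between side bias and wrong responses with a
  single mechanism. It is a modeling convenience, not a cognitive
  claim.

Latencies are log-normal (right-skewed like real response times) with
median `latency_median_correct_s` (default 8.6 s, a realistic correct
response time for a trained pig) for correct outcomes and that median
times `latency_ratio_incorrect` (default 3) for errors;
`latency_sigma = 0.5` sets the log-scale spread. Only medians and one
spread parameter are modeled because behavioral reports constrain means
and ratios, not shapes.

Fatigue is a hard stop after `fatigue_trials` completed trials (50–100
when set; presets default to none so full sessions are produced).
Learning is a per-session increment of `β` by `learning_rate`
(`advance_session`); `p(c)` is nondecreasing across sessions at
supra-threshold contrasts (`c > α`). The `learner` preset
(α = 0.95, β = 4, λ = 0.1, rate 30) starts near 71 % correct at full
contrast and climbs toward 90 % over six sessions, the trajectory of a
slow-learning animal; getting a sub-75 % start out of a logistic with
γ = 0.5 requires α near 1 and a lapse near its cap, which is why the
preset sits at those extremes.

Shipped presets: `good_cs` (α = 0.3), `weak_cs` (α = 0.6), `biased`
(b = 0.8), `learner`, `perfect` (effectively deterministic), `random`
(α = 2: the whole tested range sub-threshold, a flat chance-level
curve).

### What the generator does and does not emulate

It reproduces the behavioral structure that the analysis chain is
designed to detect: contrast-dependent accuracy, side bias coupled to
accuracy loss, outcome-dependent latencies, bounded session length, and
training improvement. It does **not** model inter-trial dependence
(beyond fatigue truncation), motivation or satiation dynamics within a
session, spatial-frequency-dependent acuity, stimulus memory, or
operator interaction. Passing tests therefore certify the pipeline's
correctness and statistical behavior under the stated model — not that
real animals satisfy the model.

## Analysis chain

- **Per-contrast performance**: non-aborted trials pooled across
  sessions per level; each level tested against the 50:50 null with the
  exact two-sided binomial test, minimum-likelihood two-sidedness (the
  p-value sums all outcomes no more likely than the observed one).
  Exactness matters at the small per-level n (≈ 40) this design
  produces. No multiple-testing correction across the 10 levels by
  default, matching per-level reporting conventions; Holm is available.
- **Side bias**: percent of touches on panel 1; the bias flag fires
  when the minority side falls below 25 %.
- **Bias–accuracy correlation**: Spearman rank correlation between
  per-session percent correct and bias magnitude
  `|side1 % − 50|`, mid-rank ties; undefined (raised) for constant
  inputs or fewer than 3 sessions.
- **Latency**: means per outcome, their ratio, and a two-sided
  Mann-Whitney U test — chosen over the t-test because latencies are
  skewed; Welch's t is available via flag.
- **Training success**: strictly greater than 75 % correct at 100 %
  contrast.
- **Psychometric fit**: binomial ML over `(α, log β, λ)` with γ fixed
  at 0.5, L-BFGS-B within bounds α ∈ [−0.5, 2], β ∈ [0.5, 500],
  λ ∈ [0, 0.1], probabilities clipped at 10⁻⁹ for the likelihood, and
  8 deterministic multi-starts (α ∈ {0.2, 0.4, 0.6, 0.9} ×
  β ∈ {5, 20}) with the best likelihood kept; non-convergence is
  flagged, never silently defaulted. The parameterization makes the
  fitted curve monotone by construction.
- **Thresholds**: the task's natural "recognized 50 % of the time"
  collides with the 50 % guessing floor, so both readings are
  computed. The literal 50 %-correct crossing (`threshold_raw`) is
  undefined for any γ = 0.5 curve on [0, 1] and reported as None with
  a note; the guessing-corrected threshold (`threshold_corrected`,
  75 % correct) is the headline value and equals α when λ is small. A
  threshold below the smallest tested contrast is flagged "below
  measurable range"; a curve that never reaches 75 % on [0, 1] yields
  None with "no measurable CS".

## Six-area classification

The (contrast, % correct) plane is tiled by a contrast split (default
0.5, the midpoint of the tested range — the split is a reconstruction,
exposed as a parameter rather than asserted) and two accuracy lines at
75 % and 50 %: A1/A2 at or above 75 % (good/moderate CS), A3/A4 in
[50, 75) (weak CS, training intact), A5/A6 below 50 % (weak training).
Tie-breaks: accuracy exactly 75 → upper band; exactly 50 → weak-CS
band; contrast exactly at the split → low-contrast column. The
partition is exhaustive and disjoint by construction.

## Validation problem sizes

The test suite and acceptance script run entirely on simulated data at
the protocol's native scale: 100-trial sessions, 4 sessions per
animal-analogue (40 presentations per contrast), 50 replicates for
parameter recovery, 100 replicates for the significance-pattern check,
and 100 seeds for schedule-composition sweeps. These sizes make every
stochastic check stable across seeds while keeping the full suite and
the acceptance script each under a minute on one CPU.

## Known limitations

- The logistic-in-linear-contrast family and the bias mixture are
  simulation conveniences; real psychometric data may prefer Weibull
  or log-contrast forms, and real side bias may be history-dependent.
- No mixed-effects pooling across animals, no Bayesian or adaptive
  (staircase) threshold estimation.
- Luminance is nominal 8-bit gray; photometric display calibration and
  gamma are external concerns.
- The A1–A6 contrast split at 50 % is a configurable reconstruction,
  not an empirically fixed boundary.
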