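# Methods

This note documents the models behind `pamsim`, the defaults and why they
were chosen, the numerical decisions in the fitter, and what the simulation
can and cannot say about data from real participants.

## 1. The game model

A session is `n_trials` reel trials (default 20). The engine deliberately
simulates **only the reel subtask**: the hook-positioning subtask of the
original game is abstracted away by assuming the agent always positions the
hook before a trial, because every per-condition summary measure concerns
reel outcomes.

**Recognition schedule.** Input imprecision is scheduled, not sampled
per-trial: exactly `round(success_rate · n_trials)` trials are recognized
(default `success_rate = 0.70`), with failure positions drawn from a seeded
uniform permutation. Rounding uses half-away-from-zero so that, e.g., 25% of
10 trials yields 3 scheduled successes. A configuration with
`success_rate ≥ 1`, or one whose rounding leaves no failure, is rejected:
every session must contain scheduled imprecision. Help flags mark exactly
the first `round(help_rate · n_trials)` trials of the trigger type
(failures for mitigated failure and input override, successes for augmented
success) in trial order.

**Fish dynamics.** A fish spawns in a lane drawn from
`spawn_lane_distribution` and needs `lane` successes to be caught (the catch
is the final reel). Each unhelped failure adds one unit of escape progress;
at `escape_threshold` (default 3) the fish is lost, and the loss *replaces*
the third unreel event so that unreels + losses always equal the unhelped
failures. Whether the three failures must be consecutive was an open
reading; the default is cumulative per fish (progress never resets), with
an `escape_reset_on_success` flag for the other reading — the per-condition
count identities are the same under both.

**Lane geometry.** The original game's geometry is not fully specified.
The default is 3 lanes with spawns uniform over lanes {2, 3}, i.e. 2.5
expected successes per catch, which makes 14 scheduled successes yield
about 5.3 catches in an unhelped session — consistent with the magnitudes
the measure tables report. Both the lane count and the spawn distribution
are configurable; the top lane gets zero spawn probability by default
because a fish hooked there would need no reel before the catch attempt.

**Help semantics.** Augmented success under the *constrained* activation
only fires when two full lanes can be reeled without catching; a scheduled
boost that cannot fire degrades to a plain player reel and is recorded as
an unconsumed help flag. This is why the constrained variant realizes far
less than its help budget (8% mean at the default geometry, per the README
example) — the effect the *redesigned* activation removes by letting the
boost also complete a catch. Mitigated failure leaves all fish state
unchanged; input override resolves exactly as a player success would.

**Durations** are reported in abstract ticks (`trial_ticks` +
`rest_ticks` per trial, plus `help_anim_ticks` when help feedback plays;
defaults 5/3/2), never wall-clock seconds.

## 2. Agent profiles

Per trial, an agent blinks at all with `compliance_probability`; a blinking
trial is in tracker range with `in_range_probability`; the blink count is
either constant or `1 + Poisson(λ)` truncated at `max_blinks`, matching the
"one or more blinks per attempted trial" behavior. Per-trial recognition is
therefore `compliance × in_range`. Presets:

| preset | recognition | mean blinks/trial | rationale |
|---|---|---|---|
| `ideal` | 1.00 | 1 | design-guarantee checks |
| `study1_patient` | 0.88 | 2.1 | patient cohort: occasional leaning out of range / forgotten blinks, ~42 blinks per 20-trial session |
| `study2_gamer` | 0.99 | 2.7 | game-savvy cohort: near-perfect tracking, blink conversion ≈ 26% |
| `absent` | 0.00 | 0 | screening-rule checks |

The patient preset splits its 0.88 recognition into compliance 0.95 ×
in-range 0.926; the two causes are not separable from the published
aggregates, so both knobs are exposed rather than guessing a split. Leaning
out of range is modeled as an independent per-trial Bernoulli, not a
temporal drift.

## 3. Session measures

- `blink_recognition`: fraction of trials containing at least one in-range
  blink (superfluous blinks in failed trials are ignored).
- `blink_conv_rate`: blink-caused reels and catches over total blinks
  across all trial windows. Catches count (the catch is the final reel);
  augmented-success double reels count (a blink caused them); override
  reels do **not** (no blink caused them) — this keeps conversion low in
  override sessions while reel + caught counts span nearly all trials.
- `pos_feedback`: positive trials (any reel or catch, by player or help)
  over `n_trials`; clamps are help feedback but not positive feedback.
- `help_rate`: trials whose outcome is any help event over `n_trials`.
- Counts: `fish_caught`, `fish_lost`, `fish_reel` (non-catch reel-ups),
  `fish_unreel`.

Screening mirrors the study rule: sessions at or below a recognition
threshold (default 0, i.e. only total recognition failures) are flagged for
exclusion. `prep_violin_data` maps ratings 1–7 to 0–1 and adds ±2% uniform
jitter, clipped to [−0.02, 1.02], for overplot-free violin overlays.

## 4. Generative rating model

Ratings are drawn from the generative inverse of the fitted cumulative link
mixed model: `u_i ~ N(0, σ²)` per participant, then a logistic latent
variable `xᵀβ + u_i + ε` is thresholded at the cutpoints. Default specs use
the published effects: perceived control `β(fish_reel) = 0.61`, `σ = 2.31`;
frustration `β(fish_reel) = −0.24`, `β(fish_lost) = 0.37`. Coefficients
apply to **raw counts**, matching the per-fish interpretation of the fitted
effects. Cutpoints are not published; the default is six equally spaced
cutpoints (spacing 1.0) centered on the linear predictor at reference
covariate means, which yields non-degenerate ratings across the simulator's
covariate ranges; the frustration center is shifted down the scale because
frustration was rated low throughout. The frustration σ is not published
either; 1.5 is assumed as moderate between-participant heterogeneity. The
`help_quantity` spec is illustrative only: its coefficient signs follow the
observed directional relationships, its magnitudes are not fitted values.

## 5. The CLMM fitter

**Likelihood.** Standard cumulative-logit parameterization with no separate
fixed intercept (absorbed into the cutpoints); the likelihood is invariant
under a joint shift of cutpoints and linear predictor, so no extra
identifiability constraint is needed. The random intercept is integrated
out per group by the Laplace approximation around the conditional mode,
found by damped Newton iterations vectorized across groups (the per-group
objective is strictly concave in `u`). At `σ = 0` the marginal reduces
exactly to the fixed-effects likelihood.

**Optimization.** L-BFGS-B over a transformed parameter vector: first
cutpoint raw, subsequent cutpoints as log-increments (keeping them strictly
increasing), slopes raw, and `log σ` (keeping the variance positive).
Initialization: cutpoints at the logit of empirical cumulative proportions,
slopes 0, `log σ = 0`. For the null model without a random effect this
initialization *is* the closed-form MLE, and the fitted cutpoints match
`logit(p̂_k)` to better than 1e-6.

**Degenerate inputs.** Unobserved rating categories are collapsed by
re-ranking the observed ones (a warning flags interior gaps); fewer than
two observed categories is an error; a slope exceeding 30 in absolute value
flags probable complete separation and marks the fit unconverged.
Non-convergence is always reported, never silent. Parameter counts are
`(#cutpoints) + (#slopes) + 1[random intercept]`, and `AIC = 2k − 2ℓ` by
construction. Slope standard errors, when requested, come from a
central-difference observed-information matrix at the optimum.

**Model comparison.** Likelihood-ratio tests require identical observations
(checked via a data fingerprint) and nested fixed-effect sets; the p-value
is the naive chi-square upper tail. For a test whose null pins the variance
at the boundary (`σ = 0`) the naive chi-square is anticonservative; this is
documented rather than corrected, matching common practice in the tooling
this reimplements. No multiple-testing correction is applied; the ranking
table reports per-test p-values and sorts by AIC with stable ties.

**Accuracy of the Laplace approximation.** The Laplace error per group is
O(σ²) for fixed group size. The test suite verifies agreement with 61-node
adaptive Gauss–Hermite quadrature to 1e-4 (σ = 0.1) and 1e-3 (σ ≤ 0.3) on
groups of 1–5 observations, and also *documents the bias*: at σ ≈ 2.3 with
singleton groups the approximation deviates from the exact marginal by
orders of magnitude more than in the small-σ regime. This is a known
property of Laplace-based mixed-model fitting with few observations per
group, and the reason adaptive quadrature exists. Despite the likelihood
bias, point estimation at the study's design remains well calibrated: the
acceptance suite generates ratings at `β = 0.61, σ = 2.31` for 200
participants × 4 conditions (covariates taken from simulated game sessions)
and recovers, across 100 seeds, a median slope within ±0.1 and a median σ
within ±0.3 of the generating values. The 200 × 4 size was fixed by pilot
simulation as the scale at which those tolerances are a meaningful
calibration check.

## 6. Reliability and auxiliary statistics

`icc3k` implements the two-way mixed, consistency, average-measures
intraclass correlation `(MS_items − MS_error)/MS_items` from the ANOVA
mean-square decomposition, rejecting incomplete matrices (no imputation).
`spearman_rho` is the Pearson correlation of midranks and rejects constant
vectors. `bartlett_sphericity` uses
`−(n − 1 − (2p + 5)/6) · ln det(R)` with `p(p−1)/2` degrees of freedom and
rejects singular correlation matrices.

## 7. What the synthetic data does and does not emulate

The simulator reproduces the *designed* structure of the paradigm: exact
scheduled recognition and help counts, the help mechanisms' outcome
semantics, cohort-level recognition and blink-count rates, and rating
distributions from the fitted ordinal model. It does **not** emulate
temporal dynamics within a session (fatigue, learning, drifting posture),
hardware artifacts, qualitative response content, wall-clock pacing, or any
correlation between a participant's game skill and their rating style
beyond what the random intercept captures. Passing tests therefore
demonstrate internal consistency of the design guarantees and calibration
of the estimators on model-generated data — not that real patients would
produce these numbers. Crossed random effects (fatigue, gender, condition
order) are out of scope; such variables can enter only as fixed covariates.
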