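# Methods

## Task geometry and angle conventions

All angles are degrees on the circle, wrapped to the half-open interval
(−180°, +180°]. The head frame places the front of the head at +180°,
directly behind at 0°, the left of the midline at negative angles and the
right at positive angles. The world frame is anchored to the training
orientation of the platform: the direction the head points at training is
+180° ("North"), so South = 0°, East = +90°, West = −90°. The platform
angle is the rotation applied relative to the training orientation, giving
the exact transform

    θ_HEAD = wrap(θ_WORLD − platform),   θ_WORLD = wrap(θ_HEAD + platform).

Whether positive rotation is called clockwise or counter-clockwise is pure
handedness and has no observable consequence; what matters is that the
left/right and North/South/East/West labels above are mutually consistent.
One consequence worth flagging: a responder that aims at the port 90°
clockwise of a head-centered sound — to the *right* of sounds from the
front, to the *left* of sounds from behind — has β_OFFSET = **+90°** under
this convention. Mirrored conventions flip that sign; the offset presets
ship with +90° because that is the model that succeeds at the
South→West / North→East discrimination.

The arena nominally has twelve peripheral slots at 30° intervals; the
physical rear slot at 0° carries no port, but since no task ever activates
it, the twelve-slot idealization has no behavioral consequence and keeps
the strategy geometry uniform.

## Choice models

Two sinusoid families give the activation of the primary response (West or
Left) as z = β₀ + β₁ cos(θ − β₂), with θ the speaker angle in the world or
head frame respectively; the alternative response has activation 1 − z.
The offset family instead aims at the head-frame location y = wrap(θ_HEAD −
β_OFFSET); expressed in the world frame the target is wrap(θ_WORLD −
β_OFFSET), which is *platform-independent* — the geometric reason this
family can discriminate world-fixed sound pairs without ever representing
the world frame. When the target is not an active port, a compensation
strategy produces activations for the two active ports:

- **guess** — (0.5, 0.5);
- **nearest** — all activation on the closer port by wrapped absolute
  angular distance, (0.5, 0.5) if equidistant;
- **weighted** — each port receives activation proportional to the
  distance from the target to the *other* port, aᵢ = d_other / (d₁ + d₂),
  so the nearer port is favored and equidistant targets degrade to the
  guess strategy. With equally spaced ports this makes the activation
  piecewise-linear in world angle, in contrast to the sinusoid families.

Activations are mapped to choice probabilities by a two-option softmax
with inverse temperature η: P(primary) = 1 / (1 + exp(−η(z₁ − z₂))). The
softmax is applied uniformly to all families (including compensated
activations); activations are treated as unconstrained real scores, so no
clipping is applied even though the fitting bounds allow z slightly
outside [0, 1] — clipping would create gradient plateaus without changing
any probability materially.

### Parameters

| parameter | meaning | bounds (fitting) | start distribution |
|---|---|---|---|
| β₀ | response bias (activation offset, unitless) | [0, 1] | uniform |
| β₁ | modulation depth (unitless) | [0, 0.5] | uniform |
| β₂ | peak response angle (deg) | [−180, 180] | uniform |
| η  | softmax inverse temperature (unitless) | [10⁻⁴, 20] | exponential |
| β_OFFSET | response offset angle (deg, offset family) | [−180, 180] | uniform |

The exponential for η uses scale 2.0, matching the magnitude used in the
shipped simulation presets; it emphasizes the moderate-determinism regime
where the parameter is informative. β₂ and β_OFFSET enter only through
cosines/wrapped differences, so the likelihood is periodic and the box
bounds are safe; recovery comparisons use circular distance.

### Identifiability

The sinusoid-plus-softmax model is over-parameterized: the choice
probability is logistic(a + b cos(θ − β₂)) with a = 2η(β₀ − ½) and
b = 2ηβ₁. Only (a, b, β₂) are identified; (β₁, η) trade off exactly along
a likelihood ridge (β₁ ∈ [b/40, 0.5] at the bounds). Parameter-recovery
experiments therefore assess the identified quantities — logit amplitude
b and peak angle β₂ — rather than β₁ or η individually; fitted values of
β₁ alone are reported but should not be interpreted. Likewise, the offset
family's decision boundary always consists of two world angles 180°
apart, which a world sinusoid can reproduce exactly, so offset-family and
world-family fits can be indistinguishable by argmax (single-trial
accuracy) even when their graded probabilities differ; held-out log loss
is reported alongside accuracy and is the discriminating metric in that
regime. Model-selection experiments on synthetic data use a biased,
phase-shifted world-model ground truth (β₀ = 0.7, β₂ = −30°) because a
perfectly symmetric generator places every family's decision boundary at
±90°, making the families provably tied in expected accuracy.

## Synthetic sessions

The generator emulates the study structure: one fixed platform angle per
session; test sounds drawn uniformly from the task's trained pair; probe
sounds at ≤ 10 % of trials (hard running cap), never among the first ten
trials of a session, drawn uniformly from the ten untrained angles in the
task-relevant frame; errors on test trials followed by correction trials
repeating the same condition until correct, capped at five (the cap bounds
session length; correction trials are flagged and excluded from every
analysis); probe responses always rewarded. Responses are single Bernoulli
draws from the agent's choice distribution. Reaction times are drawn from
a log-normal (μ = 0, σ = 0.4 on the log scale, seconds) purely so the
reaction-time transform has realistic positive input; no claim is made
about reaction-time generation. A configurable omission probability
(default 0) exercises the no-response discard path. Per-session seeds are
spawned from the master seed, so any session is independently
reproducible.

What the generator does **not** emulate: learning or adaptation across
trials or sessions, lapses, satiety and session termination, inter-subject
variability, motor costs, and any acoustic realism. Passing tests on this
synthetic data therefore validate the statistical machinery and the
self-consistency of the models, not claims about real subjects.

Scale note: at a 10 % probe rate spread over ten untrained angles, the 120
probe cells of the (head × world) grid fill slowly (expected probes per
cell ≈ N/1200 for N scheduled trials). Analyses that require every cell
populated (response maps, full-grid flattening) need either large
simulated experiments or the condition-balanced generator
(`balanced_trials_from_model`), which draws a fixed number of responses
per cell directly from the model.

## Statistics

- **Percent correct**: mean over 100 subsamples of 400 test trials drawn
  without replacement per platform angle (50 for first-ten-trials
  analyses); exact two-sided binomial test of the rounded mean correct
  count against p₀ = 0.5, Bonferroni-corrected across the twelve angles.
- **Response map**: 3 trials per grid cell resampled with replacement
  (432 total). Because resampling with replacement from a cell's 0/1
  responses makes the resampled count exactly Binomial(3, cell frequency),
  the map is generated by direct binomial draws — distributionally
  identical and vectorizable. Marginals over world and head angle average
  the joint over the complementary coordinate (36 resampled trials per
  angle).
- **Across-angle variance**: var = Σ_θ (x_θ − x̄)² / denom over the twelve
  marginal values. The printed-form denominator n − 1 = 11 is the default;
  the /n option exists because the 0.25 upper bound for probabilities in
  [0, 1] is exact only under /n (the n − 1 form reaches 3/11). Both are
  exposed.
- **Permutation test**: responses are shuffled against (head, world)
  condition-label *pairs* — jointly, because the two labels are physically
  coupled through the platform angle and shuffling frames independently
  would fabricate impossible conditions. Each of the 1000 shuffles
  recomputes the resampled map and |var_world − var_head|; the p-value
  uses the add-one convention (1 + #exceed)/(1 + n_shuffles), so the
  smallest attainable p is 1/1001. Type-I error at α = 0.05 calibrates to
  the nominal level under a frame-independent agent (checked over 500
  synthetic datasets with 200 shuffles each).
- **Adjusted response probability**: p′ = |p − 0.5| / 0.5 maps chance to 0
  and determinism to 1 for reaction-time analyses.

## Fitting protocol

20-fold cross-validation: analysable trials (corrections and omissions
removed; probes retained) are shuffled once with the config seed and split
into contiguous folds, unstratified. Each training split is flattened to
10 trials per populated grid cell (with replacement when a cell is short;
cells absent from the split are skipped unless a full grid is demanded).
The NLL — computed on per-condition response counts with probabilities
floored at 10⁻⁹ — is minimized by 20 bounded restarts of L-BFGS-B for the
smooth sinusoid families and Powell for the offset family (whose
discrete-port targeting makes the objective piecewise constant in
β_OFFSET); the restart with the lowest NLL wins. Held-out evaluation
predicts the response with the larger modeled probability; exact ties
score 0.5, keeping evaluation deterministic given a fit. Accuracy and mean
log loss are reported overall, for test and probe subsets, and per
condition; model comparison ranks families by median held-out accuracy
across folds with the log-loss ranking alongside (see Identifiability).

## Problem sizes

Test-suite and acceptance-script experiments use 12 platform angles ×
400–1000 scheduled trials (≈ 5k–13.5k trials), 20 folds × 20 restarts for
fits, 200–1000 permutation shuffles, and 300–500 replicate datasets for
calibration — sizes at which the Monte-Carlo error of each asserted
quantity is several times smaller than its assertion tolerance while the
full battery completes in minutes.

## Known limitations

- β₁ and η are not separately identifiable (exact likelihood ridge); only
  their product (the logit amplitude) and β₂ are estimable.
- The guess-strategy offset model has an almost-everywhere-flat likelihood
  in β_OFFSET (the target must hit an active port exactly), so its fitted
  offset is arbitrary; it functions as a near-chance reference model.
- Probe trials at ±90° under symmetric world models are at exact chance
  and cap attainable probe-prediction accuracy below the test-trial level.
- The permutation test's joint-shuffle scheme is one reading of
  "shuffling the labels of head and world-centered location"; shuffling
  frames independently is physically inconsistent and is not offered.
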