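# Methods

This note documents the models, the estimation choices, and the synthetic
data conditions implemented in `serialdep`, including the places where the
design was genuinely open and what the package chose.

## Orientation space and circular statistics

Orientation is 180°-periodic.  All circular computation uses the
doubled-angle device: an orientation θ maps to the angle 2θ·π/180 on the
full circle, resultants and means are computed there, and results map
back.  The circular SD is `sqrt(−2 ln R)` (R the mean resultant length)
converted back to orientation degrees, which recovers the generating σ of
wrapped-normal data.  Wrapped-normal densities are evaluated by truncated
wrap sums; the truncation keeps terms above 1e−12 of the peak (±2 wraps at
σ ≤ 25°, growing with σ).  Signed differences `ori_diff(a, b)` live in
[−90, 90); the boundary tie maps to −90.

## Bayesian observer

State: a probability mass function on a uniform grid over [0, 180)
(default step 0.5°; the posterior-update unit tests refine to 0.1° to
bound discretization error).  Each trial:

1. prior = previous posterior circularly convolved (FFT) with the
   transition mixture `p_same · C + (1 − p_same) · U`; the first trial uses
   a uniform prior and contributes no bias datapoint;
2. posterior ∝ wrapped-normal likelihood at the measurement × prior;
3. response = posterior circular mean (the linear grid mean would break at
   the 0/180 join).

**Kernel units.**  The transition kernel exponent `−|Δ|^γ / 2σ_s²` is not
scale-invariant for γ ≠ 2, so the unit of Δ matters.  The package
evaluates it with Δ and σ_s both converted degree→radian (no doubling).
In degrees the kernel would be far more concentrated (relative weight at
Δ = 30° of 0.04 instead of 0.34) and serial biases would be confined to
small dissimilarities; the radian convention produces the broad
attraction profile peaking at intermediate differences that the model is
meant to exhibit.  All reported quantities remain in orientation degrees.

**Noise assignment.**  Per-trial sensory noise is i.i.d. uniform over
{6, 9, 12}° (low noise models a prioritized item).  Measurements are
snapped to the belief grid (0.5° ≪ every noise level).  Simulating 10⁵
trials takes ~30 s on one CPU; the full 10⁶-trial protocol is a parameter
change.

Signature behaviors (asserted in tests at 10⁵ trials): peak attraction
strictly decreases in the previous trial's noise and strictly increases in
the current trial's noise over {6, 9, 12}°, and vanishes everywhere when
`p_same = 0`.

## Demixing Model

Generation: per trial, N = 100 bivariate measurements; component j ∈
{current, previous} chosen Bernoulli(π₁ = 0.5); orientation reading
wrapped-normal around the component's orientation mean (σ₁,₁ for the
current item, σ₁,₂ for the previous), temporal reading normal with shared
σ₂ = 20 and means ±(d′·σ₂)/2 = ±10 (d′ = 1).  The temporal means are
placed symmetrically; only their difference is identified by d′.

Estimation: EM on the two-component circular×linear mixture.

* E-step: exact responsibilities.
* M-step: weighted circular mean and resultant-based σ for orientation
  (floors 0.5°, cap 130° beyond which the wrapped normal is numerically
  uniform); weighted linear means and a pooled shared σ for the temporal
  dimension (floor 0.5).
* The resultant-based σ update approximates the exact wrapped-normal MLE,
  so the log-likelihood is monotone only up to a small slack (decreases up
  to ~0.1 observed for wide components); a decrease terminates the run at
  the approximate fixed point, and `em_fit` then polishes the best restart
  by direct Nelder–Mead ascent of the exact likelihood.  Restarts
  initialize the components from a random pair of measurements — markedly
  better-behaved than random responsibilities, which start EM at a nearly
  symmetric saddle.
* Readout: the orientation mean of the component with the larger estimated
  temporal mean; temporal ties break toward component 1 and are flagged.

**Mixing weight.**  `em_fit` estimates π by default (it is part of the
mixture's parameter set); the bias-grid simulation `simulate_dm_grid`
instead pins π at its generating value.  This is a deliberate asymmetry:
with π free, part of the misattribution between sources is absorbed into
the weight estimate, and the characteristic *inverted-U* dependence of the
bias on the current item's noise washes out (in high-statistics runs the
amplitude then rises monotonically over σ₁,₁ ∈ {12…28}° instead of
peaking at 24°).  An observer who knows that the two sources contribute
equally — true by construction here — recovers the non-monotonic
signature.  Both behaviors are reachable through the `pin_pi` argument.

With a free π the likelihood is also unbounded (a near-zero-weight
component can collapse onto a tight cluster of measurements); the σ floor
truncates this, but spiky local maxima remain.  The EM-vs-independent-
maximizer test therefore pins π as well, making the comparison a test of
optimizer correctness rather than of spike discovery.

**Simulation scale.**  The desk-scale grid uses dissimilarities
{5, 15, …, 85}° and 10 restarts per cell with EM tolerance 1e−3 (the bias
readout is insensitive to tighter tolerances; verified against 1e−6).
Amplitude per noise pair is the maximum of the mean-signed-bias curve
smoothed over dissimilarity with a Gaussian kernel (bandwidth 10°,
weighted by trial counts) — the same kernel logic the behavioral pipeline
uses; the parallel sign-based (asymmetry) curve is also emitted.  The
amplitude gaps between adjacent noise levels are small (~0.1–0.2°), so
argmax/ordering statements need per-level Monte-Carlo error below
~0.1°: the headline runs use 2000–4000 trials per cell, and within each
(σ₁,₂, Δ) cell the trial geometry, component assignments and z-deviates
are shared across σ₁,₁ levels (common random numbers), so between-level
differences are paired comparisons.  The full protocol (120 dissimilarity
steps, 10⁴ trials, 50 restarts) is a parameter change.

## Synthetic experiments

The generator emulates the data-generating statistics of three designs —
not timing, spatial layout, or rendering.

* **Streak design (exp1).**  324 streaks of two stimuli (648 trials);
  Stimulus 1 cued on 1/3 of streaks; rows per response: Response 1
  (Stimulus 1), Response 2 (Stimulus 2), Response 3 (cued streaks only:
  delayed re-report of Stimulus 1, response noise doubled to match the
  roughly doubled absolute error of delayed reports, no serial bias
  planted).  The inducer is the previous *reported* stimulus: Stimulus 1
  of the same streak for Response 2, the previous streak's Stimulus 2 for
  Response 1.  A row's condition label is the cue status of the streak
  containing its inducer, so "cued" means "the inducer was prioritized".
* **Congruence designs (exp2/exp3).**  720 trials, one target + one
  distractor per trial, congruent (cued = reported) with probability 0.75;
  condition label is the (previous, current) congruence pair cc/ci/ic/ii.
  ii pairs (~6 %, around 45 trials per participant) are generated but
  excluded from condition contrasts by the analysis, matching the design's
  own bookkeeping.  An optional distractor-bias profile plants additional
  bias toward the previous distractor.

Responses = stimulus + DoG bias toward the inducer + cardinal bias
(amplitude × sin(4θ), the simplest orientation-dependent bias the
preprocessing must remove; default 0) + wrapped-normal noise (default
σ = 9°, matching ~7–9° mean absolute errors); with probability
`outlier_rate` the response is replaced by a uniform draw.  The DoG is
`amplitude · (Δ/width) · exp(½ − Δ²/2width²)`, exactly `amplitude` at
Δ = width.  A per-participant amplitude offset (SD 0.5°, shared across
conditions so planted contrasts are exact within participant) models
between-participant variability; no published per-participant SD exists,
so this value is an assumption, exposed as a parameter.

What passing tests on these data do *not* show about real data: real
errors are heavier-tailed than wrapped normal, real cardinal biases are
not a single sinusoid, real serial dependence need not be DoG-shaped, and
real inter-trial dependencies (fatigue, drift) are absent.  The generator
validates the *machinery* (recovery, calibration, power), not the
empirical claims.

## Bias-analysis pipeline

1. **Cardinal-bias removal**: per participant, least-squares regression of
   the signed error on {1, sin 2θ, cos 2θ, sin 4θ, cos 4θ} (θ = stimulus
   orientation in radians) and subtraction of the fit.  The basis spans
   smooth 180°- and 90°-periodic biases; an injected 3° sinusoid leaves a
   residual below 0.3°.
2. **Exclusions**: trials with |corrected error| > 3 × participant
   circular SD; whole participants with error circular SD > 30°.
   Participants with fewer than 50 usable trials are skipped with a
   warning record.
3. **Signed bias**: error × sign(direction to the inducer); positive =
   attraction.  Rows whose inducer sits exactly at 0 or ±90° from the
   stimulus have no defined direction and are dropped (counted).
4. **Density-asymmetry curve**: at each integer dissimilarity Δ ∈ 0…90,
   every trial contributes with Gaussian weight exp(−(|Δᵢ|−Δ)²/2b²)
   (default b = 10°; the weighting is prescribed, the kernel and bandwidth
   are package choices).  The asymmetry is the weighted mean of
   sign(bias) — the excess probability of erring toward versus away from
   the inducer, in [−1, 1]; the weighted mean bias in degrees is computed
   in parallel.  Trial-resampling bootstrap CIs on request.  Asymmetry
   units and degree units are both reported and never converted into one
   another (no principled mapping exists).
5. **Tests**: per-participant means with one-sample t-tests; per-degree
   one-sample t per condition and one-way repeated-measures ANOVA across
   conditions (closed-form univariate F, cross-checked against pingouin;
   F = t² at two conditions).  Clusters are maximal contiguous significant
   runs, reported descriptively — deliberately no family-wise correction,
   so isolated degrees reach significance at the α rate under the null
   (the null-calibration test checks exactly this).
6. **Peak location**: argmax of the smoothed curve, with boundary and
   flat-curve flags.

## Power analysis

For each simulated dataset: generate via the synthetic-experiment module,
estimate per-participant per-condition DoG amplitudes — amplitude per
condition closed-form given the width, one width shared across conditions
within a participant (bounded scalar minimization in [10, 60]°; sharing
stabilizes a 1° contrast), Response-3 rows excluded — then apply the
design's test.  Power = rejection proportion with exact Clopper–Pearson
CI.

Effect structure (the modeled directional hypotheses):

* exp1: cued amplitude = baseline + effect, non-cued = baseline (a
  prioritized inducer bites harder); paired t-test.
* exp2/3: amplitude = baseline + effect·[previous congruent] −
  effect·[current congruent], i.e. cc = baseline, ci = baseline + effect,
  ic = baseline − effect; one-way repeated-measures ANOVA over (cc, ci,
  ic).

Defaults: baseline amplitude 2°, width 35°, response σ 9° (calibrated to
reported absolute-error levels; the original noise calibration source
prints no values, so these are assumptions exposed in `PowerConfig`),
18 participants, 648 trials, α = 0.05, 1000 simulations (300 in the test
suite's smoke checks).  Null calibration (effect 0 → rejection rate ≈ α)
and monotonicity in effect size and sample size are asserted in tests.

## Numerical and reproducibility choices

* One seed per run; named substreams (`substream_rng(seed, name)`) give
  each stage an independent, reproducible generator.  Identical seeds
  yield byte-identical trial tables.
* Belief grids renormalize whenever drift exceeds 1e−9; an all-zero
  likelihood-prior product raises a degenerate-posterior error rather
  than returning NaNs.
* The EM core is a numba-compiled kernel batched over trials × restarts
  (pure-python fallback if numba is absent); chunk size 8000 runs bounds
  memory.
* Degenerate cases: zero circular resultant → undefined-mean flag; flat
  bias curve → undefined peak flag; identical conditions → F defined as 0.

## Known limitations

* The Bayesian observer uses grid inference; extremely small noise
  (≲ grid step) would need a finer grid.
* The demixing EM's σ floor (0.5°) truncates but does not remove the
  mixture likelihood's degenerate spikes when π is free; fits flagged
  `degenerate` should be treated with suspicion.
* The power analysis inherits the generator's idealizations (exact DoG
  shape, wrapped-normal noise, between-participant offsets only in
  amplitude); absolute power values are conditional on that model, the
  comparative statements (monotonicity, design ranking) are more robust.
* Scaled-down Demixing-Model grids leave Monte-Carlo noise of ~0.1–0.3°
  on per-cell amplitudes; argmax-type statements near ties inherit that
  uncertainty.
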