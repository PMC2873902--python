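# Methods

This note documents the models implemented in `bubblegaze`, the design
choices made where the procedure was genuinely open, and what the synthetic
data do and do not establish.

## Coordinate conventions and geometry

All positions are degrees of visual angle, origin at the screen top-left,
x rightward, y downward; distances are Euclidean in degrees.  The default
screen is 1024 × 786 px at 33 px/degree (31.03° × 23.82°), matching a
typical CRT eye-tracking setup at 80 cm.  Bubbles are 6°-square patches
masked by an isotropic Gaussian envelope of sd 1.0° and filtered with a
space-variant blur whose sd grows linearly with eccentricity from the
patch center (default 0.1° of blur per degree of eccentricity).  The slope
is a free rendering parameter: published retinal-acuity filters exist, but
only the blur-with-eccentricity contract matters downstream — all of a
bubble's content is available from one central fixation, so scanning
within a bubble is unprofitable.

## Fixation bookkeeping

The first fixation of every trial reflects the preceding fixation cross
and is excluded from all analyses.  Each remaining fixation is assigned to
the nearest bubble center if within 3.0°; otherwise to the screen center
if within 1.5° of it (a radius we chose; only the center tendency itself
is a documented phenomenon); otherwise it counts as scattered.  Distance
ties break toward the lexicographically smallest bubble id so assignment
is deterministic.  A fixation entering a bubble from outside is *first*;
consecutive fixations in one bubble are *subsequent*.  The reference
distribution for these distances is the radial distance of draws from the
bubble envelope itself — a Rayleigh law with median σ√(2 ln 2) ≈ 1.18° at
σ = 1° — and group comparisons use two-sample Kolmogorov–Smirnov tests.

## Stimulus sets

Default composition: 4% full-field stimuli; of the rest, bubble counts mix
as 12/42/26/14/2% for 1–5 bubbles; conditions mix as 50% *same* (one
source image, including all singles), 15% *congruent* (one class, several
images), 15% *incongruent* (several classes), 16% *permuted* (positions
shuffled within a *same* combination).  Integer targets use
largest-remainder rounding, so sets of a size divisible by 100 match the
mix exactly.  Bubbles may not overlap; we enforce center separation
≥ 4.0°, at which two σ = 1° envelopes share under 5% of their mass.
Bubble usage is balanced by inverse-usage-squared sampling weights
(max/min usage ratio ≤ 2 in practice).

## Empirical salience

For stimulus S and bubble A the per-trial fraction of S's bubble-assigned
fixations landing on A is averaged over trials (trials with no
bubble-assigned fixation are skipped), giving f̄_S(A).  Context
independence implies E_A − f̄_S(A) Σ_{B∈S} E_B = 0 for every (S, A).  We
solve the stacked system by least squares with the scale constraint
Σ E = 1 eliminated exactly (substituting E_n = 1 − Σ others), so
consistent systems are reproduced to machine precision.  Each equation is
weighted by √n_trials of its stimulus — more-seen stimuli are more
reliable; this weighting is our choice.  Negative components (possible
under noise) are clipped to 10⁻⁶ and the vector renormalized, because the
downstream log transform needs positivity; clip events are logged.
Reconstruction accuracy is reported as 100·(1 − mean |f̂ − f̄|) over all
(stimulus, bubble) cells, with f̂_S(A) = E_A / Σ_{B∈S} E_B.  This metric
is our declaration of "accuracy"; other definitions are possible and we do
not claim equivalence with any particular published figure.

## Feature salience

Luminance contrast is the Gaussian-windowed local sd of luminance (window
= the bubble envelope, σ = 1°) divided by the mean luminance over all
images of a task — a task-level rather than per-image normalization, so
contrast values remain comparable across bubbles drawn from different
images.  Texture contrast applies the same windowed sd to an inner
luminance-contrast map computed with a quarter-size window and normalizes
by the task-mean inner contrast.  "Quarter size" is read as σ/4 = 0.25°
(the outer window is the bubble's Gaussian, so its size is its sd); the
alternative patch-based reading is available via the `sigma_inner_deg`
argument.  A bubble's feature values are the map values at its center
pixel, computed on the full-field source image.

Calibration uses free-viewing baseline data: feature values are split into
20 equal-population bins (edges at order statistics), making the feature
prior constant; the fixation probability per bin is then the bias-corrected
distribution of fixated bins — each fixation weighted inversely by the
central-bias density at its location, our mechanism for the stated
"corrected for spatial viewing biases".  Empty bins are floored at 10⁻⁶.
The per-image fixation-location prior is implemented as a constant with a
hook for category-specific priors.  The bubble's stimulus-dependent
salience is the product of its LC- and TC-based probabilities
(independence assumption), so log salience is additive in the two log
probabilities.

## Spatial-bias salience

The central-bias map (fixation positions) and saccade map (displacement
vectors) are per-trial histograms smoothed with a 0.5° Gaussian kernel,
normalized to unit mass, and averaged with equal weight per trial, so long
trials do not dominate.  The generative model is first-order (no
inhibition of return): per stimulus an intermediate map = central bias ×
bubble-position map; each next fixation is sampled from intermediate ×
saccade map aligned to the current fixation (screen center before the
first), renormalized.  The bubble-position map is the point-wise maximum
of the Gaussian envelopes (value 1 at each center); max rather than sum
avoids double-counting where tails meet.  The first simulated fixation of
each trial is flagged excluded, mirroring the convention for real data,
and simulated trial lengths are matched per-trial to the corresponding
original trials.

The sampling grid defaults to 0.25°/cell (continuous coordinates recovered
by uniform jitter within a cell).  We chose this resolution as a
deliberate trade-off: the bias maps are smoothed at 0.5° anyway, so a
finer raster adds cost without information; the raster is configurable
(`grid_step_deg`) up to the native 33 px/degree.  Simulated counts are
transformed to a global spatial-bias salience with exactly the
empirical-salience machinery.

## Bubble information and the p-model

A bubble's response distribution P_R(B) gives its information
I(B) = E_max − H(P_R(B)) in bits, with E_max = log₂ C (2 bit for the
four-class expression task, 1 bit for the binary tasks).  Stimulus
responses are modelled as i.i.d. draws from the normalized component-wise
product of the member bubbles' distributions (the p-model) — optimal
fusion of independent evidence.  The product is commutative and
associative, the flat distribution is its identity, and zero components
are absorbing; contradictory point masses (zero total mass) raise an
explicit degenerate-evidence error.  A max-model variant (stimulus
inherits its most informative bubble's distribution, first-index
tie-break) is provided for comparison.

The global fit maximizes Σ_trials log P_R(S)[response] over all bubbles
jointly, each bubble parameterized by C − 1 free logits through a softmax
(n_bubbles × (C − 1) free parameters; 94 four-class bubbles → 282).
Because each stimulus contributes one distribution-valued equation, the
scalar-equation count can be quoted per class (stimuli × C) or per
independent component (stimuli × (C − 1)); the fit reports both.
Probabilities are floored at 10⁻⁶ inside the log to keep boundary deltas
finite.  Optimization is L-BFGS with the analytic gradient
(∂ℓ/∂θ_{b,k} = Σ_{S∋b} n_{S,k} − N_S Z_S[k]) and 5 seeded restarts
(first start at the flat distribution), keeping the best likelihood;
convergence tolerance 10⁻⁸ on the objective.

Supporting analyses: the information-versus-bubble-count curve draws n
single-bubble distributions at random (class-independent), integrates and
averages over 1000 repetitions per count; prediction error is the mean
absolute difference between predicted and observed stimulus information,
with a finite-sample lower bound obtained by re-sampling responses from
the fitted distributions at the real per-stimulus trial counts; bootstrap
intervals are percentile intervals over within-cell resamples, two curves
differing at a cell when one point estimate leaves the other's interval;
and the permuted-position test simulates, per (normal, permuted) response
pair, the null distribution of the maximum absolute proportion difference
under a pooled multinomial, counting the fraction of pairs inside the
central 95% region.  The discreteness of that statistic makes the region
conservative (inside fractions at or slightly above the nominal level).

## Regression analysis

All predictors and the outcome are log transformed (natural log; the
correlations are base-invariant) after flooring at 10⁻⁶; floor events are
counted.  Per task we report pairwise Pearson correlations with two-sided
t-tests (n − 2 df), the multivariate OLS fit with intercept (R², overall
F-test), and semi-partial correlations computed from residuals of each
predictor on the others, with significance from the added-last t-test
t = sr·√(n − k − 1)/√(1 − R²_full) — the significance procedure for
semi-partials is our choice and is declared as such.  Shared variance
R² − Σ sr² is reported as-is; it can be negative under suppression and is
not clamped.  Tasks are analyzed separately, never pooled.

## Synthetic worlds

The generator's defaults are the study conditions: 75 participants × 280
trials (21000 trials), mean 6.2 analysis fixations per trial, free-viewing
baseline of 27 participants.  Per-trial fixation counts are Poisson
truncated to ≥ 1 with the rate solved so the truncated mean equals 6.2
(only the mean is documented; the distribution family is ours).  Landing
scatter is isotropic Gaussian with sd 0.45°, and within-bubble
refixations shrink toward the center by the factor that makes the mean
radial approach exactly 0.16°.  Three percent of fixations target the
screen center and three percent are scattered, reflecting reported
off-bubble fractions.  Bubble response distributions are symmetric
Dirichlet draws with concentration 0.5, which spreads bubble information
over its whole range.  The planted empirical salience follows the
regression's own structure: exp of a weighted sum of the log feature, log
information and log spatial components plus Gaussian log-noise (default
weights 0.3/0.5/0.7, noise sd 0.3); in `make_world` the spatial component
is the log central-bias density at the bubble's position so the generative
and regression structures agree.

What the generator does *not* emulate: photorealistic image content (and
hence any genuine correlation between image features and task
information), response times, inter-subject variability in salience,
temporal order effects, and inhibition of return.  Passing recovery tests
therefore establishes the estimators' correctness under the model's
assumptions, not the empirical validity of those assumptions for human
data.

## Problem sizes and numerical choices

Tests run the full 75 × 280 design where a property claims that scale
(salience recovery, fit bias) and smaller seeded worlds elsewhere; the
fit-recovery check uses 20 replicates at full scale, the regression
recovery 10 replicates at 25 × 120.  These sizes are the package's own
validation choices; all are parameters.  Fixed tolerances: distribution
sums checked at 10⁻⁹; probability and salience floors 10⁻⁶; bias-map
normalization 10⁻⁶; least-squares consistency asserted at 10⁻¹⁰.
Degenerate inputs are errors, not silent repairs: empty task image sets,
all-identical binning values, contradictory point-mass evidence,
zero-variance correlations and singleton bootstrap cells all raise.

## Known limitations

- The empirical-salience "accuracy" metric and the semi-partial
  significance test are declared definitions, not reproductions of any
  specific published computation.
- The equation-weighting by √n_trials and the inverse-density bias
  correction are reasonable but not unique choices; both are switchable.
- The global-fit likelihood surface is non-convex; 5 restarts have always
  sufficed in testing, but convergence to a global optimum is not
  guaranteed and the fit flags non-convergence.
- A "global model" integration variant capturing contra-factual evidence
  is not implemented; only the p-model and the max-model are.
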