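# Methods

## Models and conventions

All series live on the fixed FSIGT sampling grid of 28 times
{0, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 19, 22, 24, 25, 27, 30, 40, 50, 60,
70, 80, 90, 100, 120, 140, 160, 180} minutes; the three-state model is
integrated on the 16 post-bolus times (22…180), the two-state FFA model on
the full grid. Basal values G_b, F_b, I_b are the t = 0 measurements; G_b
and F_b are promoted to model parameters, while I_b always comes from the
insulin input curve in use. Input signals (insulin, and glucose for the
two-state model) are piecewise-linear interpolants of their samples;
queries outside the sampled span clamp to the endpoint values because an
adaptive solver may probe slightly past the final time.

Parameters and units: glucose in mg/dL, FFA in µmol/L, insulin in µU/mL,
rates in 1/min. In the three-state model S_G (glucose effectiveness,
1/min), S_I (insulin sensitivity, per µU/mL per min), C_X (remote-insulin
turnover, 1/min), C_F (FFA turnover, 1/min), L_2 (maximal lipolysis
suppression, µmol/L/min) and X_2 (half-saturation of the Hill suppression
term) must be non-negative, with X_2 > 0 because it appears squared in a
denominator. The remote compartment is driven only by insulin excursions
above basal (the positive-part clamp), so X can never go negative from a
non-negative start.

## Integration

The reference integrator is adaptive Runge–Kutta (Dormand–Prince RK45,
rtol 1e-8, atol 1e-10). Because the inputs are piecewise linear, the
right-hand side has derivative kinks exactly at the sampling times; the
solution is therefore advanced segment by segment between grid points, so
every step sees a smooth vector field. Two performance paths are validated
against this reference in the tests:

* a batch fixed-step RK4 on a refined mesh (default sub-step 0.1 min,
  aligned with the grid so kinks fall on step boundaries), vectorized
  across whole parameter batches — used for dataset generation and
  trajectory reconstruction;
* a per-subject fixed-step RK4 with all input-stage values precomputed and
  the stepping loop JIT-compiled — used inside the Nelder–Mead objective,
  where the same subject is integrated thousands of times.

At sub-step 0.1 min the concentration channels agree with the adaptive
reference to ~1e-7 relative; the latent X channel can show larger
*relative* deviations where it passes near zero, which is a denominator
artifact, so accuracy contracts are stated on the observable G/F channels.

## Subject fitting

The objective is the mean relative error |model − data| / data, averaged
over post-bolus time points for the three-state model (glucose and FFA
errors weighted equally — the natural symmetric choice; it is isolated in
one function) and over the full grid for FFA alone in the two-state model
(its glucose and insulin are inputs, not predictions). Positivity is
enforced by mapping every candidate through a componentwise absolute value
before evaluation, so the simplex explores an unconstrained space. A failed
integration returns a sentinel loss of 1e6, which makes the simplex
retreat.

Nelder–Mead uses the adaptive-simplex variant with simplex-size and
function-spread tolerances of 1e-8 and at most 5,000 iterations per run; up
to 3 restarts re-seed a fresh simplex from the incumbent and stop early
once a restart no longer improves the loss. When no starting point is
supplied, 5 log-uniform draws from a broad plausible box are tried and the
best kept. The initial value of the remote compartment at t = 22 (X22) is
treated as a free optimized quantity alongside the parameters for the
three-state model; pinning it to zero is a special case the caller can
impose through the initial vector.

## Gaussian-process input simulation

Cohort curves are standardized per time point (mean 0, sd 1 across
subjects, n−1 denominator — the usual sample convention) and modelled as a
zero-mean GP with a radial quasi-periodic kernel

k(t₁,t₂) = σ² · exp(−(t₁−t₂)²/(2ℓ²)) · exp(−2 sin²(π|t₁−t₂|/p)/ℓ_p²),

a product of a squared-exponential envelope and a periodic factor; the form
sits behind a single function so it can be swapped. Fitting is a stochastic
ascent: each iteration picks one random subject and takes one
gradient-ascent step (step 1e-2, finite-difference gradients in
log-hyperparameter space — exact enough at these 16–28-point kernel sizes)
on that subject's marginal log likelihood, stopping when the
cohort-averaged likelihood exceeds a threshold (default −0.5 per data
point) or an iteration cap is hit. Cholesky factorizations escalate jitter
from 1e-10 to 1e-6 before giving up. Simulated curves are draws from the
fitted process, denormalized, and clipped at a 0.1 concentration floor —
clipping rather than resampling because the negative tail is negligible for
these signal-to-noise ratios. Each drawn curve carries an id, and the
dataset builder marks ids as used so no two rows share an input curve.

## Parameter distribution and admissibility

Each parameter's physiological range is the closed min–max interval over
the included subject fits; the joint distribution is a multivariate
log-normal fitted to the elementwise logs (sample mean and covariance),
which captures the correlations induced by latent physiology. The
sampler draws from the log-normal and rejects vectors with any component
outside its range — rejection rather than clipping, to preserve the
distribution's shape inside the box. For the three-state model the
initial conditions (G22, F22, X22) are included as columns of the fit, so
they are sampled jointly with the parameters. The degenerate-covariance
case (exactly collinear columns) is handled by an eigendecomposition-based
sampler.

Simulated trajectories are kept only if admissible: all concentrations
non-negative, post-bolus glucose non-increasing until it comes within 5% of
basal, and FFA showing a single dip (non-increasing before its minimum,
non-decreasing after, each direction with a 2% relative tolerance band).
The exact shape rule is a package choice; it is isolated behind one
function with the tolerances in a rule dictionary so it can be replaced.
Train/validation/test tags (default 90/8/2) are assigned by hashing the row
index with the seed, so a row's split is independent of how many rows
follow it.

## Feature layouts and network

Input tensors stack rows in fixed pairs — (t,G),(t,I),(t,F),(G,I),(I,F),
(G,F), 12 rows — optionally followed by reciprocal pairs: +6 rows
(t,1/G),(t,1/I),(t,1/F) for the `recip_time` layout, +12 rows ending in
(1/G,1/I),(1/I,1/F),(1/G,1/F) for `mutual_recip`. A convolution with a
(2, 2) kernel and (2, 1) stride then reads exactly one pair per step, so it
can realize finite-difference stencils (e.g. dG/dt from the (t,G) pair);
reciprocals matter because the latent compartment appears in a denominator
of the three-state FFA equation. Three-state tensors have 16 time columns,
two-state 28. The `none` and `concat` layouts share one tensor and differ
only inside the network.

The network is a compact CNN written directly on NumPy with hand-derived
backpropagation (validated against central finite differences to 1e-4).
For the concat-family layouts a front convolution (2 channels) processes
the input first; its output channels are unrolled into extra rows and
concatenated onto the input (cropped by the one trailing time column the
valid convolution consumes), giving the trunk direct access to
derivative-like features. The trunk is conv(6 ch) → ReLU → time-axis
max-pool (1, 2) → conv(12 ch) → ReLU → pool → flatten → dense(64, tanh) →
dense(N_para) with a final ReLU or scaled tanh (tanh(x)+1)/2; the scaled
tanh maps into (0, 1) to match min–max-rescaled parameters. Pooling acts on
the time axis only, preserving the independence of engineered row pairs.
Channel counts and the dense width were sized so a full training run is
comfortable on a single CPU core; they are config fields, not constants.
Inputs are standardized per feature row (statistics from the training set,
stored in the checkpoint); parameters are min–max scaled to [0, 1] with the
physiological ranges riding along in the checkpoint.

Training is minibatch Adam (batch 256) under a learning-rate schedule fixed
by three quantities — the maximal rate (default 1e-3), the epoch at which
it is reached (default 10% of the budget), and the total epochs: linear
ramp to the peak, then half-cosine decay to 1/100 of the peak. Validation
MSE is recorded every epoch and the best-validation weights are kept.
Training is deterministic given the seed (weight init, shuffling and the
single-threaded kernels are all seeded).

## Evaluation

Parameter recovery is scored per parameter by ordinary least squares of
inferred on true values: R² = 1 − SS_res/SS_tot of the regression and the
slope-test p-value; a degenerate regression (zero variance on either axis)
reports R² = 0, p = 1 by convention. Trajectory reconstruction integrates
the model with the inferred parameters and the row's own input curves and
reports the per-row mean relative error on the observable channels.
Inference from optimized model-fitting curves feeds each subject's fitted
G/F curves plus measured insulin through the network and compares against
the optimized parameter values. A scenario sweep trains one model per
(training size, layout, activation, seed) cell against one shared test
split.

## Synthetic cohort

The generator emulates the FSIGT protocol shape, not its pharmacokinetics:
insulin is basal before the 20-minute bolus and then a gamma-shaped
transient peaking ~4 min later; glucose starts at basal, jumps to a
post-injection peak and decays slowly; FFA comes from integrating the
chosen model under hidden true parameters, with the two-state production
parameter tied to near-basal balance (S_Fb ≈ 0.92 · S_GF G_b F_b) so curves
start close to steady state. Measurement noise is multiplicative log-normal
(3% relative by default) on all channels — concentrations are positive and
assay error is relative. Defaults (21–25 subjects, basal glucose ~92 mg/dL,
basal FFA ~480 µmol/L, basal insulin ~8 µU/mL, bolus peak ~80 µU/mL above
basal) were chosen once as representative of FSIGT cohorts.

What passing tests on this cohort do show: the estimators, filters and the
network recover parameters that actually generated the data, end to end.
What they do not show: robustness to model misspecification, assay
artifacts, missing samples, or the pre-bolus glucose dynamics, none of
which the generator emulates.

## Problem sizes

The reference experiment (tests and the acceptance script) uses a
21-subject cohort, 40,000-curve GP pools, a 13,200-row filtered dataset
(10,000 train / ~1,000 validation / 2,000 test), and 300 training epochs
with the `recip_time` layout and scaled-tanh head; the data-size trend
check compares 500 against 4,000 training rows over three seeds and all
four layouts at 25 epochs. These sizes are the package's reference
configuration for single-core reproducibility; every stage scales to
larger cohorts, pools and datasets through the same interfaces.

## Known limitations

* Insulin and glucose pool curves are drawn independently; dependencies
  between the two inputs are not modelled.
* The admissibility shape rule is a surrogate for expert curation; its
  tolerances (5% basal band, 2% wiggle) are package defaults, not
  physiology.
* The GP kernel form and likelihood threshold are package choices isolated
  behind single functions.
* Fitted-parameter uncertainty is not quantified; the optimizer returns
  point estimates only.
* Inference from raw noisy data (as opposed to model-fitting curves) is out
  of scope; no denoising front-end is provided.
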