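# Methods

`emgkin` estimates 15 finger flexion–extension joint angles, continuously
and simultaneously, from 8 channels of forearm surface EMG. The pipeline
has four stages: envelope extraction, an EMG-to-muscle-activation model
that parameterizes the electromechanical delay (EMD), regression from
activations to normalized joint angles, and block cross-validated scoring.
A synthetic-data generator with known ground truth makes every stage
testable end to end.

## Signal model

**Envelope extraction.** Raw EMG (2 kHz) is full-wave rectified, divided
by the per-channel maximum rectified value over all trials (MVC), low-pass
filtered with a zero-phase (forward–backward) 2nd-order Butterworth at
4 Hz, and decimated to 200 Hz to match the kinematics. The forward–backward
pass squares the magnitude response (effective 4th order) and cancels the
phase, so the envelope carries no lag of its own. Filtering a rectified
signal can undershoot slightly below zero; the envelope is clipped to
[0, 1]. Decimation is a pure take-every-10th-sample step: the 4 Hz filter
already guarantees there is no content near the 100 Hz Nyquist of the
output rate.

**Activation dynamics.** Neural activation u(t) follows a discrete
second-order recursion of the envelope e(t):

    u(t) = α e(t − d) − β1 u(t−1) − β2 u(t−2)

with β1 = γ1 + γ2, β2 = γ1·γ2, and α − β1 − β2 = 1. The two pole
parameters satisfy |γ| < 1 (stability) and the α constraint forces unit DC
gain: a sustained envelope level settles at exactly that level. d is the
EMD — the physiological lag, tens of milliseconds, between EMG onset and
joint motion. Muscle activation applies an exponential shaping

    v = (e^{A·u} − 1) / (e^A − 1),    −3 ≤ A ≤ 0,

linear at A = 0, strongly saturating (concave) at A = −3, with exact
endpoints v(0) = 0, v(1) = 1. Below |A| = 1e−8 the linear limit v = u is
substituted.

**Parameter fitting.** (γ1, γ2, d, A) are fitted by minimizing the mean
squared error of reconstructing the normalized joint angles from the
activations. The inner estimator is a closed-form ridge map (λ = 1e−3) fit
on the leading 75 % of the series and scored on the trailing 25 %, with
the first and last 0.5 s excluded (filter start-up). The search is a
seeded multi-start bounded Powell method (8 restarts, ≤ 500 evaluations
each) over γ ∈ (−1, 1) with γ1 ≤ γ2 (removes the label-swap symmetry),
A ∈ [−3, 0] and d ∈ [0, 150 ms] — the upper bound reflecting the
physiological EMD range. d is continuous in the optimizer but rounded to
whole samples (5 ms at 200 Hz) when the recursion is applied, which makes
the cost piecewise-constant along the delay axis; two countermeasures keep
the search out of flat regions: each restart begins from the best of a
coarse delay probe, and the final answer comes from a delay profile — the
cost re-minimized over (γ1, γ2, A) at every whole-sample delay, warm-started
along the grid. The profile step matters because the recursion's poles
near +1 contribute group delay of their own: delay and pole smoothing
trade off along a shallow valley, and only re-optimizing the poles at each
candidate delay separates the two.

## Kinematics

Joint angles are computed from three markers per joint as 180° minus the
interior angle at the middle marker: a straight finger reads 0° and
flexion is positive. This convention is unsigned — three markers cannot
orient hyperextension without an external reference — so marker-derived
angles live in [0°, 180°); the synthetic angle series themselves may carry
signed hyperextension. Measured angles are low-pass filtered at 10 Hz
(zero-phase, 2nd-order Butterworth) to remove capture jitter, then
normalized per DOF to [0, 1] with the training-set minimum and maximum;
test data reuse the training statistics and are not clipped.

## Regression

Inputs (activations, envelopes, or windowed time-domain features) are
standardized to zero mean and unit variance on the training split; test
inputs reuse the training statistics; zero-variance dimensions are dropped
with a warning.

**Neural network.** One multi-output feedforward network (tanh hidden
layer, linear output) maps inputs to all 15 DOFs at once. The hidden size
is selected from a geometric grid {5, 10, 25, 50, 100, 200, 350} by
validation MSE on the trailing 20 % of the training pool; each candidate
trains with Adam (learning rate 5e−3) and early stopping (patience 25,
max 2000 epochs), deterministically for a given seed. The grid spans the
same range a denser scan would, at a fraction of the cost.

**Gaussian processes.** One exact-inference GP per DOF with zero mean,
squared-exponential covariance k(v,v′) = σ_f² exp(−‖v−v′‖²/(2l²)) with a
single isotropic length-scale, and Gaussian noise σ_n. Hyperparameters
minimize the negative log marginal likelihood ½yᵀK⁻¹y + ½ln|K| + (N/2)ln2π
(K = K_f + σ_n²I) by L-BFGS-B in log-space with analytic gradients and 3
seeded restarts, initialized at σ_f = std(y), σ_n = 0.1·std(y), l = median
pairwise input distance. The Cholesky factor is cached for prediction; if
factorization fails, jitter escalates from 1e−10·trace(K)/N by decades up
to 1e−4 before erroring. Training cost is bounded by fixed-interval
subsampling (every k-th row, k = ⌈N/cap⌉); the library default cap is
1500 rows, and the bundled experiments use 250–300 rows, which keeps dense
factorizations to a few seconds without changing the qualitative
comparisons.

**Time-domain baseline.** MAV, WL, WA and VAR per channel over 200 ms
windows stepping 25 ms, computed on raw 2 kHz EMG. "200 ms with 25 ms
overlap" is read as step = 25 ms (the usual convention, 40 Hz frame rate);
the literal step = 175 ms reading remains available through `WindowSpec`.
The WA threshold defaults to twice the median sample-to-sample absolute
difference of a rest segment, or 1 % of the channel max-abs when no rest
segment exists.

## Evaluation

Pearson's R and the RMSE of the 0–1 normalized angles (NRMSE; fraction in
machine-readable output, percent in summaries) are computed per DOF.
Cross-validation folds are contiguous temporal blocks, never shuffled
samples: at 200 Hz the series is heavily autocorrelated and random folds
would leak training information into the test scores. Feature-set
comparisons share fold boundaries, regressor and seed so that per-DOF
differences are paired. Learning curves hold out a fixed trailing test
block and subsample the training pool by fixed intervals.

## Synthetic data

The generator emulates a finger flexion–extension recording session:

* **Drives** — per-channel smooth signals in [0, 1] built from random
  tones below 2 Hz (the upper bound of voluntary periodic finger
  movement), with task modes for individual-finger (block-active),
  simultaneous (shared waveform, pairwise correlation ≥ 0.8) and free
  movements.
* **True envelope** — the activation model's input is by definition the
  rectified, normalized, 4 Hz-filtered EMG, so the generator's ground-truth
  envelope is the zero-phase 4 Hz response of the drive; this is exactly
  what ideal preprocessing of the synthetic raw EMG recovers.
* **Raw EMG** — the drive amplitude-modulates a broadband carrier scaled
  by a per-channel MVC factor. The carrier is constant-modulus: Gaussian
  noise band-passed to 20–450 Hz, repeatedly normalized by its Hilbert
  envelope and re-band-passed. A plain Gaussian carrier would leave ~3 %
  low-frequency ripple in the recovered envelope (the rectified-Gaussian
  fluctuation inside a 4 Hz band is irreducible at this bandwidth); the
  constant-modulus construction keeps all amplitude information in the
  drive and calibrates the recovery to well under 1 % RMS, with the
  rectification-mean compensation measured per realization as
  1/mean|carrier|.
* **Kinematics** — true activations v* = activation(true envelope; γ1 =
  γ2 = −0.9539, d = 45 ms, A = −3, a published operating point of these
  dynamics) are mixed by a row-stochastic 15×8 matrix (each DOF dominated
  by one muscle), rescaled into realistic per-joint ranges of motion, plus
  white angle noise of 1° std — consistent with optical capture residuals
  below 0.5 mm on finger-sized bones. The true EMD therefore genuinely
  separates angle onset from EMG onset.
* **Markers** — optional planar five-marker chains per finger (forward
  kinematics in the flexion–extension plane) whose interior angles
  reproduce the input angles exactly.

What the generator does **not** model: motor-unit recruitment and firing
statistics, electrode crosstalk beyond linear mixing, fatigue, electrode
shift, marker occlusion. Passing tests therefore demonstrate correctness
of the algorithms and identifiability under the stated conditions, not
performance on human recordings.

## Numerical choices and limitations

* Recursion history u(−1) = u(−2) = 0; the first/last 0.5 s are excluded
  from fitting costs.
* The recursion's vectorized path is `scipy.signal.lfilter` with
  numerator [α] and denominator [1, β1, β2] on the zero-padded delayed
  envelope; tests pin it to a naive per-sample loop at 1e−12.
* MVC from data is the max |sample| over trials; an all-zero channel is a
  hard error naming the channel. For synthetic pipelines the generator's
  stored true MVC scale is used: the max of a stochastic carrier
  systematically overestimates the modulation scale, which is faithful to
  real MVC normalization but would rescale calibration checks.
* GP predictive variance includes the noise term σ_n², so far from the
  data it reverts to σ_f² + σ_n².
* The delay is identifiable to one sample (5 ms) under the default
  conditions; with substantially noisier kinematics the delay/pole valley
  flattens and only the total lag is well determined.
* Problem sizes in the bundled experiments (60 s recordings, 3–5 seeds,
  GP caps of 250–300, NN grids of 2 sizes) are chosen to keep each
  experiment in the minutes range on one core; all are configurable.
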