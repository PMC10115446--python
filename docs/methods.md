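# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of the `barsaccade` package. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## The integrate-and-fire saccade-trigger model

During fixation the bar's angular error relative to the fly's heading grows
at the bar speed v. The model posits that the error beyond an integration
**offset** (default 26° from the visual midline) is integrated over time and
a body saccade fires when the integral reaches a constant, the integrated
retinal position error **I_rpe** (default 2.5 °·s). Two closed forms follow
from the triangle geometry (base ISI, height E − offset, area I_rpe):

* `error_from_isi`: E = offset + 2·I_rpe/ISI. With the defaults this gives
  E(0.22 s) → 49°, E(0.27 s) → 45°, E(0.37 s) → 40° (nearest degree).
* `isi_from_speed`: ½·v·ISI² = I_rpe ⇒ ISI = √(2·I_rpe/v), hence
  E(v) = offset + √(2·I_rpe·v).

`estimate_irpe` inverts the law: the mean over saccades of
½·(pre-error − offset)·ISI. Pairs with pre-error below the offset carry no
information about the integral and are excluded with a warning.

### Closed-loop simulator

`simulate_tracking` advances the bar at constant speed with an Euler step of
dt = 5 ms (halving dt changes steady-state ISIs by less than one step; this
is a test in the suite). The fly is stationary between saccades by default
(a configurable smooth gain adds fractional bar-following). The accumulator
adds max(0, |error| − offset)·dt outside a frontal **dead zone** (default
half-width 10°, within which it holds at zero — with the beyond-offset
integrand the dead zone only matters for the alternative `magnitude`
integrand, which is provided for sensitivity analysis). On reaching I_rpe a
saccade fires toward the bar; its amplitude is either the configured
stereotyped value or, by default, |error| − offset, returning the error to
the offset.

Saccades are **instantaneous state updates** in the dynamics; the exported
heading trace redraws each step as a linear ramp over 50 ms so the standard
saccade-detection kinematics apply to simulator output. Executing the turn
over a finite duration inside the dynamics, with the bar still moving, would
leave a residual error of v·Δt after each saccade and pull the steady-state
ISI ≈ 20 % away from the analytic law the model is meant to embody; the
instantaneous update keeps simulator, estimator and closed form mutually
consistent (the suite checks measured ISIs against √(2·I_rpe/v) for
v ∈ [20, 200] °/s within two simulator steps).

### From calcium transients to cell counts

Single-neuron transients are fitted with the two-shape curve
y = γ·x^(α−1)·(1−x)^(β−1) on the window mapped to x ∈ [0, 1] — the shape of
a beta density with a free scale. Fitting is bounded nonlinear least
squares (α, β ∈ [10⁻³, 50]) from a 4×4 multi-start grid over
(α, β) ∈ {0.5, 1, 2, 4}², with γ profiled out linearly at every step; the
lowest-RSS converged start wins. The area under the fit,
I_Ca²⁺ = γ·B(α, β)·(t₁ − t₀) with B the Euler beta function, is
cross-checked against adaptive quadrature to 1e−8 in the suite.
`cells_to_threshold` converts it to the number of sequentially activated
columnar neurons needed to charge a downstream integrator to a threshold
I_thr (default 0.1, in the same arbitrary ΔF/F·s unit as the fitted
integrals): n = ⌈I_thr/I_Ca²⁺⌉, spanning n·Δφ of visual space at the
interommatidial angle Δφ = 4.5°. The unrounded product
(I_thr/I_Ca²⁺)·Δφ is also reported, since it is dimensionally an angular
distance rather than a count.

A deliberate tension is left in place: the pure integrate-to-threshold
scheme integrates over a roughly constant time window and so does not by
itself produce the speed-dependent ISI; the simulator's behavioral
controller (offset + dead zone + stereotyped amplitudes) is the canonical
closed-loop model, and the cell-count arithmetic is a parallel,
physiology-facing read-out.

## Kinematic analyses

Headings are stored wrapped to [0, 360); all displacement arithmetic is on
unwrapped angles, and signed errors are wrapped to (−180, 180].

* **Saccade detection.** The heading is unwrapped, low-pass filtered with a
  zero-phase 2nd-order Butterworth at 25 Hz, and differentiated centrally.
  Samples with |velocity| ≥ 300 °/s are grouped into events (groups closer
  than the 0.1 s refractory merge); onset/offset sit where |velocity| falls
  below 25 % of the event peak. Threshold, cutoff, refractory and fraction
  are configuration values, not assertions about any particular prior
  study's settings. Note a geometric consequence of the 25 % window: for a
  logistic heading step it brackets tanh(arccosh 2) = √3/2 ≈ 86.6 % of the
  full amplitude, so detected amplitudes systematically under-report the
  asymptotic step; the detector tests assert against this analytic fraction.
* **Performance index.** Δheading/Δbar (unwrapped) over a window; invariant
  to whole wraps of either channel.
* **Epochs.** Trials are parsed into 5 s epochs, displacement re-zeroed per
  epoch; trials with counter-clockwise stimuli are reflected (bilateral
  symmetry) so that following the bar is positive-going. The positive-PI
  fraction counts strictly positive PIs.
* **Tracking bouts.** Non-overlapping windows each spanning 180° of bar
  rotation (1.6 s at 112.5 °/s; 15 whole windows in a 25 s trial); a window
  qualifies when the OLS regression of fly on bar displacement reaches
  R² ≥ 0.75, and adjacent qualifying windows merge into one bout. A window
  with a constant channel gets R² = 0.
* **Inter-saccadic gain.** Between saccade offset and next onset, clipped to
  bouts. Besides the unweighted per-interval mean, a **pooled** gain
  (total fly rotation / total bar rotation across intervals) is reported
  and preferred: very short intervals have noisy individual ratios and the
  residual tails of the sigmoidal saccade waveform leak a few degrees into
  adjacent intervals, which biases the unweighted mean upward (recovery of
  a generative smooth gain of 0.3 is within ±0.05 for the pooled estimate).
* **Rigid tether.** The midline crossing is the first zero crossing of the
  signed bar azimuth through the frontal pole; the steering metric is the
  mean ΔWBA over the 200 ms before it, and the wind-up series is the
  cumulative trapezoidal ΔWBA integral normalized per trial to its maximum
  magnitude for cross-trial pooling.

## Tuning classification

For each spatial wavelength λ the temporal frequency of the maximal
response is extracted; a quadratic interpolation of log-amplitude in log-TF
around the discrete argmax refines it (for a log-Gaussian tuning curve the
log-amplitude is exactly quadratic in log TF, so the refined vertex is
exact). Rows whose maximum falls on the boundary of the sampled TF range
are flagged: their true preferred TF is censored by the stimulus grid, and
`classify_tuning` excludes them from the regression by default — with a
preferred speed of 150 °/s and a 0.5–12 Hz grid, the λ = 9° row's preferred
TF (16.7 Hz) lies beyond the grid, and keeping the clamped value would bias
the slope from 1.00 to ≈ 0.84.

The slope of log₁₀(preferred TF) on log₁₀(spatial frequency, cycles/deg) is
1 for perfect speed tuning and 0 for perfect TF tuning. Model comparison
fits the intercept-only (TF-tuned) and intercept+slope (speed-tuned) linear
models, scores them with BIC = n·ln(RSS/n) + p·ln n (Gaussian likelihood,
variance profiled out; the slope is estimated freely rather than fixed at
1), and reports log BF = (BIC_tf − BIC_speed)/2, positive favouring the
speed model. The RSS is floored at 1e−12 so perfect fits stay finite, and
|log BF| is capped at 1e6. At exactly equal RSS the score reduces to the
parameter penalty, log BF = −ln(n)/2 (a test asserts this analytically).

## Synthetic data

The generators define the conditions under which every analysis is tested;
they are deterministic given (config, seed).

* **Stripe patterns.** Balanced ±1 columns, rejection-sampled until no
  circular run exceeds `max_run` (default 6 columns of 3.75° = 22.5° on a
  96-column display); 10,000 rejected draws raise an error. An independent
  brute-force validator re-checks balance and run length in the suite.
* **Bar trajectories.** Unwrapped angle affine in time. The grid is
  `linspace(0, duration, round(duration·rate))` — endpoint inclusive, so a
  25 s trial at 112.5 °/s ends at exactly 2812.5° of displacement with 5000
  samples; the sampling interval (25/4999 s) is within 0.02 % of 5 ms.
* **Calcium transients.** The drive is the full-wave-rectified Gaussian
  receptive-field profile (σ = 4.5°) crossed by the bar, scaled by
  amp₁₈·(18/v)^0.5 — the exponent 0.5 is a package choice that reproduces
  the observed monotone decrease of peak response over 18–180 °/s — and
  convolved with an exponential indicator kernel (τ = 0.6 s) on a 1 kHz
  internal grid before sampling at the 10 Hz frame rate. The trace integral
  matches the closed-form product of drive and kernel areas to 1 %.
* **Tuning matrices.** Amplitude is log-Gaussian (σ = 0.5 log units) in
  pattern speed λ·TF (speed-tuned) or in TF (TF-tuned); additive Gaussian
  noise is clipped at zero.
* **Heading traces.** heading = smooth_gain·bar drift + logistic saccade
  steps (amplitude 30°, 5–95 % rise in 80 ms, directed with the bar) +
  band-limited wobble. Saccade times are a renewal process with
  exponential gaps shifted by a 2×duration refractory, parameterized so the
  mean interval is exactly 1/rate (≈ 1 Hz for control-like flies). The
  wobble is white noise low-passed at ~5 Hz and rescaled to the requested
  SD: white position noise at 200 Hz would put unrealistic power into the
  velocity band the detector thresholds.

What the generators do **not** emulate: saccade-amplitude and velocity
variability and their correlations, slow drift in inter-saccadic gain,
wingbeat-coupled body oscillation, nystagmus-like optomotor saccades during
large-field motion, tracking loss/recapture dynamics, and any dependence of
calcium responses on contrast polarity or adaptation. Passing tests
therefore demonstrate correctness of the computations under the stated
statistical structure, not performance on real recordings.

## Sizes and tolerances

Simulations in tests and the acceptance script are sized for a desk run:
100-seed Monte-Carlo suites for detector fidelity and the stripe validator,
200 seeds for the saccade-count calibration, 20 s simulator runs at three
speeds (36.5, 68.6, 103.3 °/s — speeds whose analytic ISIs match the three
published anchor pairs). Key numeric tolerances: beta-integral closed form
vs quadrature 1e−8; unwrap error on analytic ramps 1e−9; displacement
conservation (saccadic + inter-saccadic = total) 1e−6; simulator ISIs
within 2·dt of the closed form; CSV round trips lossless to 1e−9.

## Known limitations

* The saccade detector's defaults (300 °/s, 25 Hz, 25 %) are reasonable for
  200 Hz magno-tether data but are not fitted to any dataset.
* `rf_center_and_average` keeps the input grid size; receptive fields whose
  centre sits near a grid edge lose the bins shifted out of the window
  (per-bin counts prevent averaging bias, but coverage shrinks).
* The beta-curve fit window must exclude long flat baselines; with α < 1
  the curve diverges at x = 0 and the fit clips x away from the endpoints.
* The closed-loop simulator is deterministic; it reproduces mean behavior
  (ISI, pre-error, I_rpe) but no trial-to-trial variability.
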