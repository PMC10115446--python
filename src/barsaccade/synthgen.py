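"""Synthetic stimuli and recordings with the statistical structure the analyses assume.

The generators emulate the three kinds of recordings the pipeline consumes:

* random bright/dark stripe patterns with balanced contrast and bounded
  run lengths, as shown on a cylindrical LED display;
* constant-speed revolving-bar trajectories;
* single-neuron calcium transients whose amplitude falls with bar speed,
  produced by a small Gaussian receptive field and an exponential
  indicator kernel;
* grating response matrices that are either speed-tuned (amplitude a
  function of wavelength x TF only) or TF-tuned (a function of TF only);
* magno-tether heading traces composed of smooth inter-saccadic drift plus
  impulsive sigmoidal saccades, with ground truth returned for detector
  validation.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .errors import InfeasibleConstraintError, InvalidArgumentError
from .types import (
    BarTrajectory,
    CalciumTrace,
    HeadingTrace,
    ResponseMatrix,
    StimulusEvent,
    StripePattern,
    wrap_360,
)

__all__ = [
    "SynthCalciumConfig",
    "SynthHeadingConfig",
    "GroundTruthSaccade",
    "gen_stripe_pattern",
    "gen_bar_trajectory",
    "gen_calcium_trace",
    "gen_tuning_dataset",
    "gen_heading_trace",
]

# Display geometry of the magno-tether arena: 96 LED columns over 360 deg.
DISPLAY_COLUMNS = 96
PIXEL_WIDTH_DEG = 360.0 / DISPLAY_COLUMNS  # 3.75 deg per column

_STRIPE_RETRY_CAP = 10_000


@dataclass
class SynthCalciumConfig:
    """Parameters of the synthetic calcium-transient generator.

    rf_center_deg : deg
        Azimuth of the receptive-field centre along the sweep axis.
    rf_sigma_deg : deg
        Gaussian receptive-field width (SD).
    amp_at_18 : dF/F
        Drive amplitude for a bar moving at 18 deg/s.
    speed_exponent : dimensionless
        Amplitude falls as (18 / speed) ** speed_exponent; 0.5 by default so
        that peak responses decrease monotonically over 18-180 deg/s.
    kernel_tau_s : s
        Exponential decay constant of the calcium indicator.
    noise_sd : dF/F
        SD of additive Gaussian noise on the sampled trace.
    sample_rate_hz : Hz
        Imaging frame rate (10 Hz by default).
    """

    rf_center_deg: float = 36.0
    rf_sigma_deg: float = 4.5
    amp_at_18: float = 1.0
    speed_exponent: float = 0.5
    kernel_tau_s: float = 0.6
    noise_sd: float = 0.0
    sample_rate_hz: float = 10.0
    sweep_extent_deg: float = 72.0
    pre_s: float = 1.0
    post_s: float = 2.0

    def __post_init__(self):
        if self.rf_sigma_deg <= 0:
            raise InvalidArgumentError("rf_sigma_deg must be positive")
        if self.kernel_tau_s <= 0:
            raise InvalidArgumentError("kernel_tau_s must be positive")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")
        if self.sample_rate_hz <= 0 or self.sweep_extent_deg <= 0:
            raise InvalidArgumentError("sample_rate_hz and sweep_extent_deg must be positive")


@dataclass
class SynthHeadingConfig:
    """Parameters of the synthetic magno-tether heading generator.

    saccade_rate_hz : Hz
        Mean saccade frequency (shifted-exponential inter-saccade times with
        refractory 2 * saccade_dur_s; the mean interval equals 1 / rate).
    saccade_amp_deg : deg
        Saccade amplitude, directed with the bar's motion.
    saccade_dur_s : s
        5%-to-95% rise time of the sigmoidal heading step.
    smooth_gain : dimensionless
        Inter-saccadic gain: fraction of bar drift followed smoothly.
    heading_noise_sd : deg
        SD of band-limited (~5 Hz) heading wobble.
    sample_rate_hz : Hz
        Camera frame rate (200 Hz by default).
    """

    saccade_rate_hz: float = 1.0
    saccade_amp_deg: float = 30.0
    saccade_dur_s: float = 0.08
    smooth_gain: float = 0.3
    heading_noise_sd: float = 0.0
    sample_rate_hz: float = 200.0
    start_heading_deg: float = 0.0

    def __post_init__(self):
        if self.saccade_dur_s <= 0:
            raise InvalidArgumentError("saccade_dur_s must be positive")
        if not (0.0 <= self.smooth_gain <= 1.5):
            raise InvalidArgumentError("smooth_gain must lie in [0, 1.5]")
        if self.saccade_rate_hz < 0:
            raise InvalidArgumentError("saccade_rate_hz must be non-negative")
        if self.heading_noise_sd < 0:
            raise InvalidArgumentError("heading_noise_sd must be non-negative")
        if self.saccade_rate_hz > 0 and 1.0 / self.saccade_rate_hz <= 2.0 * self.saccade_dur_s:
            raise InvalidArgumentError(
                "saccade_rate_hz too high for the 2 x saccade_dur_s refractory period"
            )


@dataclass(frozen=True)
class GroundTruthSaccade:
    """Injected saccade parameters returned alongside a synthetic heading trace."""

    onset_s: float
    offset_s: float
    amplitude_deg: float
    peak_velocity_deg_s: float


def _circular_run_ok(values: np.ndarray, max_run: int) -> bool:
    """True iff no circular run of identical entries exceeds max_run."""
    n = values.size
    if np.all(values == values[0]):
        return n <= max_run
    doubled = np.concatenate([values, values])
    run = 1
    longest = 1
    for i in range(1, 2 * n):
        if doubled[i] == doubled[i - 1]:
            run += 1
            longest = max(longest, min(run, n))
        else:
            run = 1
    return longest <= max_run


def gen_stripe_pattern(
    n_columns: int = DISPLAY_COLUMNS,
    max_run: int = 6,
    seed: int = 0,
    pixel_width_deg: float = PIXEL_WIDTH_DEG,
) -> StripePattern:
    """Draw a balanced random stripe pattern with bounded circular run lengths.

    The display is cylindrical, so run lengths are checked on the circular
    pattern.  Rejection sampling over balanced permutations; raises
    InfeasibleConstraintError after 10,000 rejected draws.
    """
    if n_columns < 2 or n_columns % 2 != 0:
        raise InvalidArgumentError("n_columns must be an even integer >= 2")
    if not (1 <= max_run < n_columns):
        raise InvalidArgumentError("max_run must satisfy 1 <= max_run < n_columns")
    rng = np.random.default_rng(seed)
    base = np.array([1, -1] * (n_columns // 2), dtype=int)
    for _ in range(_STRIPE_RETRY_CAP):
        values = rng.permutation(base)
        if _circular_run_ok(values, max_run):
            return StripePattern(
                values=tuple(int(v) for v in values),
                pixel_width_deg=float(pixel_width_deg),
                max_run=int(max_run),
                seed=int(seed),
            )
    raise InfeasibleConstraintError(
        f"no balanced pattern with circular runs <= {max_run} found "
        f"in {_STRIPE_RETRY_CAP} draws (n_columns={n_columns})"
    )


def gen_bar_trajectory(
    speed_deg_s: float,
    duration_s: float,
    start_angle_deg: float = 0.0,
    direction: int = 1,
    sample_rate_hz: float = 200.0,
) -> BarTrajectory:
    """Constant-speed bar rotation: unwrapped angle affine in time.

    The grid holds ``round(duration * rate)`` samples from 0 to ``duration``
    inclusive, so the final sample sits exactly at ``direction * speed *
    duration`` of unwrapped displacement.
    """
    if speed_deg_s < 0:
        raise InvalidArgumentError("speed must be non-negative")
    if duration_s <= 0 or sample_rate_hz <= 0:
        raise InvalidArgumentError("duration and sample_rate must be positive")
    if direction not in (-1, 1):
        raise InvalidArgumentError("direction must be +1 (CW) or -1 (CCW)")
    n = int(round(duration_s * sample_rate_hz))
    if n < 2:
        raise InvalidArgumentError("duration too short for the sample rate")
    t = np.linspace(0.0, duration_s, n)
    unwrapped = start_angle_deg + direction * speed_deg_s * t
    return BarTrajectory(
        time_s=t,
        angle_deg=wrap_360(unwrapped),
        unwrapped_deg=unwrapped,
        speed_deg_s=float(speed_deg_s),
        direction=int(direction),
        sample_rate_hz=float(sample_rate_hz),
    )


def calcium_drive_amplitude(bar_speed_deg_s: float, config: SynthCalciumConfig) -> float:
    """Peak drive amplitude at a given bar speed: amp_at_18 * (18 / speed) ** exponent."""
    return config.amp_at_18 * (18.0 / bar_speed_deg_s) ** config.speed_exponent


def gen_calcium_trace(
    bar_speed_deg_s: float,
    config: SynthCalciumConfig | None = None,
    seed: int = 0,
) -> CalciumTrace:
    """Synthesize a single-ROI dF/F trace for one bar sweep across the RF.

    A bar sweeps the stimulus window at constant speed; the drive is the
    full-wave-rectified Gaussian receptive-field profile it crosses (the
    response does not depend on contrast polarity or sweep direction), scaled
    by ``amp_at_18 * (18/speed)**speed_exponent``, then convolved with an
    exponential indicator kernel of time constant ``kernel_tau_s``.  The
    convolution runs on a fine internal grid (1 kHz) and is sampled at the
    imaging frame rate, so fast sweeps are not aliased.
    """
    if bar_speed_deg_s <= 0:
        raise InvalidArgumentError("bar_speed must be positive")
    config = config or SynthCalciumConfig()
    rng = np.random.default_rng(seed)

    sweep_s = config.sweep_extent_deg / bar_speed_deg_s
    total_s = config.pre_s + sweep_s + config.post_s

    dt_fine = 1e-3
    t_fine = np.arange(0.0, total_s + dt_fine, dt_fine)
    pos = (t_fine - config.pre_s) * bar_speed_deg_s  # bar azimuth during motion
    in_motion = (t_fine >= config.pre_s) & (t_fine <= config.pre_s + sweep_s)
    amp = calcium_drive_amplitude(bar_speed_deg_s, config)
    drive = np.where(
        in_motion,
        amp * np.exp(-0.5 * ((pos - config.rf_center_deg) / config.rf_sigma_deg) ** 2),
        0.0,
    )
    kernel_t = np.arange(0.0, 8.0 * config.kernel_tau_s, dt_fine)
    kernel = np.exp(-kernel_t / config.kernel_tau_s)
    convolved = np.convolve(drive, kernel)[: t_fine.size] * dt_fine

    n = int(round(total_s * config.sample_rate_hz)) + 1
    t = np.arange(n) / config.sample_rate_hz
    value = np.interp(t, t_fine, convolved)
    if config.noise_sd > 0:
        value = value + rng.normal(0.0, config.noise_sd, size=n)

    events = [
        StimulusEvent("motion", config.pre_s, min(config.pre_s + sweep_s, t[-1])),
    ]
    return CalciumTrace(time_s=t, value=value, events=events, is_dff=True)


def gen_tuning_dataset(
    mode: str,
    wavelengths_deg,
    tfs_hz,
    preferred: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    log_sigma: float = 0.5,
) -> ResponseMatrix:
    """Grating response matrix under a speed-tuned or TF-tuned model.

    ``speed_tuned``: amplitude is a log-Gaussian function of pattern speed
    wavelength x TF (deg/s) centred at ``preferred``.  ``tf_tuned``: a
    log-Gaussian function of TF alone centred at ``preferred`` (Hz).
    Additive Gaussian noise is clipped at zero (responses are non-negative).
    """
    if mode not in ("speed_tuned", "tf_tuned"):
        raise InvalidArgumentError(f"unknown tuning mode {mode!r}")
    lams = np.asarray(wavelengths_deg, dtype=float)
    tfs = np.asarray(tfs_hz, dtype=float)
    if lams.size == 0 or tfs.size == 0 or np.any(lams <= 0) or np.any(tfs <= 0):
        raise InvalidArgumentError("wavelengths and TFs must be non-empty and positive")
    if preferred <= 0:
        raise InvalidArgumentError("preferred must be positive")
    rng = np.random.default_rng(seed)
    lam_grid, tf_grid = np.meshgrid(lams, tfs, indexing="ij")
    x = lam_grid * tf_grid if mode == "speed_tuned" else tf_grid
    amplitude = np.exp(-0.5 * (np.log(x / preferred) / log_sigma) ** 2)
    if noise_sd > 0:
        amplitude = np.clip(amplitude + rng.normal(0.0, noise_sd, amplitude.shape), 0.0, None)
    return ResponseMatrix(wavelengths_deg=lams, tfs_hz=tfs, amplitude=amplitude)


def _saccade_times(rng, rate_hz: float, duration_s: float, refractory_s: float) -> np.ndarray:
    """Saccade onset centres: shifted-exponential gaps with mean 1/rate."""
    if rate_hz <= 0:
        return np.empty(0)
    mean_free = 1.0 / rate_hz - refractory_s  # positive by config invariant
    times = []
    t = rng.exponential(1.0 / rate_hz)  # first event needs no refractory shift
    while t < duration_s:
        times.append(t)
        t += refractory_s + rng.exponential(mean_free)
    return np.asarray(times)


def gen_heading_trace(
    bar: BarTrajectory,
    config: SynthHeadingConfig | None = None,
    seed: int = 0,
) -> tuple[HeadingTrace, list[GroundTruthSaccade]]:
    """Synthesize a magno-tether heading trace tracking a revolving bar.

    heading = smooth_gain * bar drift + sigmoidal saccades directed with the
    bar + band-limited wobble.  Saccade centres follow a renewal process with
    exponential gaps and a refractory period of 2 * saccade_dur_s whose mean
    interval is 1 / saccade_rate_hz.  Ground-truth onsets, amplitudes and
    peak velocities are returned for detector validation.
    """
    config = config or SynthHeadingConfig()
    rng = np.random.default_rng(seed)
    t = bar.time_s
    duration = float(t[-1] - t[0])

    heading = config.start_heading_deg + config.smooth_gain * (
        bar.unwrapped_deg - bar.unwrapped_deg[0]
    )

    dur = config.saccade_dur_s
    k = 2.0 * np.log(19.0) / dur  # 5%-to-95% rise within dur
    centres = _saccade_times(rng, config.saccade_rate_hz, duration - dur, 2.0 * dur)
    centres = centres[centres > dur]
    truth: list[GroundTruthSaccade] = []
    amp = config.saccade_amp_deg * bar.direction
    from scipy.special import expit

    for tc in centres:
        heading = heading + amp * expit(k * (t - tc))
        truth.append(
            GroundTruthSaccade(
                onset_s=float(tc - dur / 2.0),
                offset_s=float(tc + dur / 2.0),
                amplitude_deg=float(amp),
                peak_velocity_deg_s=float(amp * k / 4.0),
            )
        )

    if config.heading_noise_sd > 0:
        white = rng.standard_normal(t.size)
        nyq = bar.sample_rate_hz / 2.0
        b, a = sp_signal.butter(2, min(5.0 / nyq, 0.99), btype="low")
        wobble = sp_signal.filtfilt(b, a, white)
        sd = float(np.std(wobble))
        if sd > 0:
            heading = heading + config.heading_noise_sd * wobble / sd

    trace = HeadingTrace(
        time_s=t,
        heading_deg=wrap_360(heading),
        bar_deg=bar.angle_deg,
        meta={
            "stimulus": "motion_defined_bar",
            "bar_speed_deg_s": bar.speed_deg_s,
            "direction": bar.direction,
            "seed": int(seed),
        },
    )
    return trace, truth
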