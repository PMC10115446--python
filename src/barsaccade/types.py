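"""Core in-memory containers shared by the analysis modules.

Angles are stored in degrees throughout; headings and stimulus positions
are wrapped to [0, 360) and signed angular errors to (-180, 180].  Time is
in seconds on a uniform grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "StimulusEvent",
    "CalciumTrace",
    "HeadingTrace",
    "SteeringTrace",
    "ResponseMatrix",
    "RFMap",
    "DirectionTuning",
    "Saccade",
    "TrackingBout",
    "StripePattern",
    "BarTrajectory",
    "ModelParams",
    "BetaFit",
    "SimResult",
    "wrap_360",
    "wrap_180",
    "infer_sample_rate",
]


def wrap_360(angle_deg):
    """Wrap angles into [0, 360)."""
    return np.asarray(angle_deg, dtype=float) % 360.0


def wrap_180(angle_deg):
    """Wrap signed angular differences into (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped


def infer_sample_rate(time_s: np.ndarray, jitter_tol: float = 0.01) -> float:
    """Return the sample rate in Hz of a uniform time grid.

    Raises InvalidArgumentError if the time axis is non-monotone or its
    sampling intervals deviate from their median by more than ``jitter_tol``
    (relative).
    """
    t = np.asarray(time_s, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise InvalidArgumentError("time axis must be 1-D with at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InvalidArgumentError("time axis must be strictly increasing")
    dt0 = float(np.median(dt))
    if np.max(np.abs(dt - dt0)) > jitter_tol * dt0:
        raise InvalidArgumentError(
            f"non-uniform sampling: interval jitter exceeds {jitter_tol:.0%}"
        )
    return 1.0 / dt0


@dataclass(frozen=True)
class StimulusEvent:
    """A labelled stimulus epoch on a trace, in trace time."""

    label: str
    onset_s: float
    offset_s: float

    def __post_init__(self):
        if self.offset_s < self.onset_s:
            raise InvalidArgumentError("event offset precedes onset")


@dataclass
class CalciumTrace:
    """A single-ROI fluorescence time series sampled at ~10 Hz.

    ``value`` holds raw fluorescence (arbitrary units) or dF/F depending on
    ``is_dff``; ``events`` annotate stimulus epochs.
    """

    time_s: np.ndarray
    value: np.ndarray
    events: list[StimulusEvent] = field(default_factory=list)
    is_dff: bool = False

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.shape != self.value.shape:
            raise InvalidArgumentError("time and value must have equal length")
        self.sample_rate_hz = infer_sample_rate(self.time_s)
        t0, t1 = self.time_s[0], self.time_s[-1]
        for ev in self.events:
            if ev.onset_s < t0 - 1e-9 or ev.offset_s > t1 + 1e-9:
                raise InvalidArgumentError(f"event {ev.label!r} outside trace span")

    def event(self, label: str) -> StimulusEvent:
        for ev in self.events:
            if ev.label == label:
                return ev
        raise InvalidArgumentError(f"no event labelled {label!r}")


@dataclass
class HeadingTrace:
    """Wrapped fly heading and bar (or panorama) position versus time (200 Hz)."""

    time_s: np.ndarray
    heading_deg: np.ndarray
    bar_deg: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.heading_deg = wrap_360(self.heading_deg)
        self.bar_deg = wrap_360(self.bar_deg)
        if not (self.time_s.shape == self.heading_deg.shape == self.bar_deg.shape):
            raise InvalidArgumentError("time, heading and bar channels must align")
        self.sample_rate_hz = infer_sample_rate(self.time_s)


@dataclass
class SteeringTrace:
    """Rigid-tether wing-beat steering signal (dWBA, volts) and bar position (1 kHz)."""

    time_s: np.ndarray
    dwba: np.ndarray
    bar_deg: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dwba = np.asarray(self.dwba, dtype=float)
        self.bar_deg = wrap_360(self.bar_deg)
        if not (self.time_s.shape == self.dwba.shape == self.bar_deg.shape):
            raise InvalidArgumentError("time, dwba and bar channels must align")
        self.sample_rate_hz = infer_sample_rate(self.time_s)


@dataclass
class ResponseMatrix:
    """Peak responses of one neuron to gratings over wavelength x temporal frequency.

    ``amplitude[i, j]`` is the peak dF/F at spatial wavelength
    ``wavelengths_deg[i]`` and temporal frequency ``tfs_hz[j]``.  Spatial
    frequency in cycles per degree is ``1 / wavelength`` and pattern speed is
    ``wavelength * TF`` (deg/s).
    """

    wavelengths_deg: np.ndarray
    tfs_hz: np.ndarray
    amplitude: np.ndarray
    direction: str = "pooled"

    def __post_init__(self):
        self.wavelengths_deg = np.asarray(self.wavelengths_deg, dtype=float)
        self.tfs_hz = np.asarray(self.tfs_hz, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if np.any(np.diff(self.wavelengths_deg) <= 0) or np.any(np.diff(self.tfs_hz) <= 0):
            raise InvalidArgumentError("wavelengths and TFs must be strictly increasing")
        if self.amplitude.shape != (self.wavelengths_deg.size, self.tfs_hz.size):
            raise InvalidArgumentError("amplitude shape must be (n_wavelengths, n_tfs)")
        if np.any(self.amplitude < 0):
            raise InvalidArgumentError("amplitudes must be non-negative")

    @property
    def spatial_frequencies_cpd(self) -> np.ndarray:
        return 1.0 / self.wavelengths_deg


@dataclass
class RFMap:
    """Receptive-field map: peak-response products over azimuth x elevation bins."""

    grid: np.ndarray
    bin_size_deg: tuple[float, float] = (9.0, 9.0)
    normalized: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise InvalidArgumentError("RF grid must be 2-D (azimuth x elevation)")
        if self.normalized:
            finite = self.grid[np.isfinite(self.grid)]
            if finite.size and not math.isclose(float(np.max(finite)), 1.0, abs_tol=1e-9):
                raise InvalidArgumentError("normalized RF map must have max entry 1")

    @property
    def center_bin(self) -> tuple[int, int]:
        """Index of the maximum entry; ties broken toward the lowest index."""
        g = np.where(np.isfinite(self.grid), self.grid, -np.inf)
        return tuple(np.unravel_index(int(np.argmax(g)), g.shape))


@dataclass(frozen=True)
class DirectionTuning:
    """Peak responses per cardinal direction and per-axis direction-selectivity indices."""

    peaks: dict
    dsi_horizontal: float
    dsi_vertical: float


@dataclass(frozen=True)
class Saccade:
    """One detected rapid turn.

    Amplitude and peak velocity are signed (positive = increasing unwrapped
    heading); ``direction`` is 'syn' or 'counter' relative to bar motion and
    ``pre_error_deg`` the signed wrapped bar-minus-heading error at onset,
    positive in the bar's direction of motion.
    """

    onset_s: float
    offset_s: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    direction: str = ""
    pre_error_deg: float = float("nan")

    def __post_init__(self):
        if self.offset_s <= self.onset_s:
            raise InvalidArgumentError("saccade offset must follow onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class TrackingBout:
    """A maximal run of half-revolution windows with regression R^2 >= threshold."""

    start_s: float
    end_s: float
    r_squared: float
    n_windows: int = 1
    window_bar_displacement_deg: float = 180.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class StripePattern:
    """Random bright/dark stripe pattern for a cylindrical display.

    ``values`` holds +1 (bright) / -1 (dark) per display column.  Patterns
    are balanced (equal bright and dark counts) and, treated circularly, have
    no run of identical columns longer than ``max_run``.
    """

    values: tuple
    pixel_width_deg: float
    max_run: int
    seed: int

    @property
    def n_columns(self) -> int:
        return len(self.values)


@dataclass
class BarTrajectory:
    """Constant-speed revolving-bar trajectory on a uniform time grid."""

    time_s: np.ndarray
    angle_deg: np.ndarray       # wrapped to [0, 360)
    unwrapped_deg: np.ndarray
    speed_deg_s: float
    direction: int
    sample_rate_hz: float

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class ModelParams:
    """Constants of the integrate-and-fire saccade-trigger model.

    i_rpe : deg*s
        Integrated retinal position error at which a saccade fires.
    offset_deg : deg
        Azimuth from the visual midline at which error integration starts.
    delta_phi_deg : deg
        Interommatidial angle (one columnar neuron per ommatidial column).
    i_thr : dF/F * s (shared arbitrary unit with the calcium integrals)
        Integrator threshold used to convert calcium integrals to cell counts.
    saccade_amp_deg : deg or None
        Stereotyped saccade amplitude; None lets the simulator return the
        error to ``offset_deg`` at each saccade.
    dead_zone_deg : deg
        Frontal half-width within which no integration takes place and the
        accumulator holds at zero.
    dt_s : s
        Simulator step.
    """

    i_rpe: float = 2.5
    offset_deg: float = 26.0
    delta_phi_deg: float = 4.5
    i_thr: float = 0.1
    saccade_amp_deg: float | None = None
    dead_zone_deg: float = 10.0
    dt_s: float = 0.005

    def __post_init__(self):
        for name in ("i_rpe", "offset_deg", "delta_phi_deg", "i_thr", "dt_s"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.dead_zone_deg < 0:
            raise InvalidArgumentError("dead_zone_deg must be non-negative")
        if self.dead_zone_deg > self.offset_deg:
            raise InvalidArgumentError("dead_zone_deg must not exceed offset_deg")
        if self.saccade_amp_deg is not None and self.saccade_amp_deg <= 0:
            raise InvalidArgumentError("saccade_amp_deg must be positive when given")


@dataclass(frozen=True)
class BetaFit:
    """Least-squares fit of y = gamma * x**(alpha-1) * (1-x)**(beta-1) on x in [0, 1]."""

    alpha: float
    beta: float
    gamma: float
    t0_s: float
    t1_s: float
    rss: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidArgumentError("shape parameters must be positive")
        if self.gamma < 0:
            raise InvalidArgumentError("scale must be non-negative")
        if self.t1_s <= self.t0_s:
            raise InvalidArgumentError("fit window must have positive length")

    def predict(self, time_s: np.ndarray) -> np.ndarray:
        x = (np.asarray(time_s, dtype=float) - self.t0_s) / (self.t1_s - self.t0_s)
        x = np.clip(x, 1e-12, 1.0 - 1e-12)
        return self.gamma * x ** (self.alpha - 1.0) * (1.0 - x) ** (self.beta - 1.0)


@dataclass
class SimResult:
    """Output of the closed-loop tracking simulator."""

    time_s: np.ndarray
    fly_heading_deg: np.ndarray   # wrapped
    bar_deg: np.ndarray           # wrapped
    saccade_onsets_s: np.ndarray
    pre_errors_deg: np.ndarray    # unsigned magnitude at each trigger
    isis_s: np.ndarray            # onset-to-onset; isis_s[0] is NaN (no predecessor)
    params: ModelParams = field(default_factory=ModelParams)

    def to_heading_trace(self) -> "HeadingTrace":
        """View the simulation as a standard heading trace for the kinematics ops."""
        return HeadingTrace(
            time_s=self.time_s,
            heading_deg=self.fly_heading_deg,
            bar_deg=self.bar_deg,
            meta={"source": "saccmodel.simulate_tracking"},
        )
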