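"""Flight kinematics: saccade detection and tracking metrics from magno-tether
heading traces, and steering metrics from rigid-tether dWBA traces.

Headings arrive wrapped to [0, 360); all displacement arithmetic happens on
unwrapped angles.  Saccades are transients in low-pass-filtered angular
velocity: threshold crossings are grouped into events and each event's onset
and offset are placed where velocity falls to 25% of the event peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import InvalidArgumentError, UndefinedPIError
from .types import HeadingTrace, Saccade, SteeringTrace, TrackingBout, wrap_180

__all__ = [
    "Kinematics",
    "angular_kinematics",
    "detect_saccades",
    "performance_index",
    "EpochMetrics",
    "epoch_metrics",
    "tracking_bouts",
    "GainResult",
    "intersaccadic_gain",
    "pre_saccadic_error",
    "RigidTetherMetrics",
    "rigid_tether_metrics",
]


@dataclass
class Kinematics:
    """Unwrapped heading/bar channels and filtered angular velocity."""

    time_s: np.ndarray
    heading_unwrapped_deg: np.ndarray
    velocity_deg_s: np.ndarray
    bar_unwrapped_deg: np.ndarray
    sample_rate_hz: float


def _unwrap_deg(angle_deg: np.ndarray) -> np.ndarray:
    return np.unwrap(np.asarray(angle_deg, dtype=float), period=360.0)


def bar_motion_sign(trace: HeadingTrace) -> int:
    """Sign of the bar's net rotation (+1 CW-positive convention, -1 opposite)."""
    direction = trace.meta.get("direction")
    if direction in (-1, 1):
        return int(direction)
    net = _unwrap_deg(trace.bar_deg)[-1] - _unwrap_deg(trace.bar_deg)[0]
    return 1 if net >= 0 else -1


def angular_kinematics(trace: HeadingTrace, cutoff_hz: float = 25.0) -> Kinematics:
    """Unwrap the heading, low-pass filter it (zero phase) and differentiate.

    The filter is a 2nd-order Butterworth run forward and backward
    (zero-phase); velocity comes from central differences on the filtered
    heading.
    """
    fs = trace.sample_rate_hz
    if trace.time_s[-1] - trace.time_s[0] < 0.5:
        raise InvalidArgumentError("need at least 0.5 s of data")
    heading = _unwrap_deg(trace.heading_deg)
    nyq = fs / 2.0
    if cutoff_hz < nyq:
        b, a = sp_signal.butter(2, cutoff_hz / nyq, btype="low")
        filtered = sp_signal.filtfilt(b, a, heading)
    else:
        filtered = heading
    velocity = np.gradient(filtered, trace.time_s)
    return Kinematics(
        time_s=trace.time_s,
        heading_unwrapped_deg=filtered,
        velocity_deg_s=velocity,
        bar_unwrapped_deg=_unwrap_deg(trace.bar_deg),
        sample_rate_hz=fs,
    )


def detect_saccades(
    trace: HeadingTrace,
    vel_thresh_deg_s: float = 300.0,
    refractory_s: float = 0.1,
    cutoff_hz: float = 25.0,
    onset_fraction: float = 0.25,
) -> list[Saccade]:
    """Detect saccades as supra-threshold transients in filtered angular velocity.

    Samples with |velocity| >= ``vel_thresh_deg_s`` are grouped into events;
    groups closer than ``refractory_s`` merge.  Each event's onset and offset
    sit where |velocity| falls below ``onset_fraction`` of the event's peak
    |velocity|; amplitude is the unwrapped heading change between them.
    Direction is 'syn' when the turn follows the bar's rotation, 'counter'
    otherwise.  Returns an empty list when nothing crosses threshold.
    """
    kin = angular_kinematics(trace, cutoff_hz=cutoff_hz)
    v = kin.velocity_deg_s
    above = np.abs(v) >= vel_thresh_deg_s
    if not np.any(above):
        return []
    idx = np.flatnonzero(above)
    gap = int(round(refractory_s * kin.sample_rate_hz))
    groups: list[tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > gap:
            groups.append((start, prev))
            start = i
        prev = i
    groups.append((start, prev))

    sign_bar = bar_motion_sign(trace)
    n = v.size
    saccades: list[Saccade] = []
    for g0, g1 in groups:
        peak_idx = g0 + int(np.argmax(np.abs(v[g0 : g1 + 1])))
        peak_v = float(v[peak_idx])
        level = onset_fraction * abs(peak_v)
        onset = peak_idx
        while onset > 0 and abs(v[onset - 1]) >= level:
            onset -= 1
        offset = peak_idx
        while offset < n - 1 and abs(v[offset + 1]) >= level:
            offset += 1
        if offset <= onset:
            continue
        amplitude = float(
            kin.heading_unwrapped_deg[offset] - kin.heading_unwrapped_deg[onset]
        )
        err = float(
            wrap_180(kin.bar_unwrapped_deg[onset] - kin.heading_unwrapped_deg[onset])
        )
        saccades.append(
            Saccade(
                onset_s=float(kin.time_s[onset]),
                offset_s=float(kin.time_s[offset]),
                amplitude_deg=amplitude,
                peak_velocity_deg_s=peak_v,
                direction="syn" if np.sign(peak_v) == sign_bar else "counter",
                pre_error_deg=err * sign_bar,
            )
        )
    return saccades


def performance_index(trace: HeadingTrace, window: tuple[float, float] | None = None) -> float:
    """Ratio of the fly's to the bar's unwrapped angular displacement.

    1 = perfect tracking, 0 = stationary, negative = counter-directional.
    """
    heading = _unwrap_deg(trace.heading_deg)
    bar = _unwrap_deg(trace.bar_deg)
    if window is None:
        i0, i1 = 0, trace.time_s.size - 1
    else:
        t0, t1 = window
        i0 = int(np.searchsorted(trace.time_s, t0, side="left"))
        i1 = int(np.searchsorted(trace.time_s, t1, side="right")) - 1
        if i1 <= i0:
            raise InvalidArgumentError("window contains fewer than two samples")
    d_bar = bar[i1] - bar[i0]
    if d_bar == 0:
        raise UndefinedPIError("bar displacement over the window is zero")
    return float((heading[i1] - heading[i0]) / d_bar)


@dataclass
class EpochMetrics:
    """Per-epoch tracking summary of one trial."""

    table: pd.DataFrame
    positive_pi_fraction: float
    epoch_s: float


def epoch_metrics(
    trace: HeadingTrace,
    epoch_s: float = 5.0,
    saccades: list[Saccade] | None = None,
) -> EpochMetrics:
    """Parse a trial into fixed-length epochs and summarize each.

    Per epoch: displacement re-zeroed at the epoch start (CCW trials are
    reflected so that following the bar is positive-going, assuming bilateral
    symmetry), the performance index, the saccade count, and an optional
    label taken from ``trace.meta['epoch_labels']`` (one label per epoch,
    e.g. LED ON/OFF).  The positive-PI fraction uses strictly positive PIs.
    """
    duration = float(trace.time_s[-1] - trace.time_s[0])
    if duration < epoch_s:
        raise InvalidArgumentError("trace shorter than one epoch")
    if saccades is None:
        saccades = detect_saccades(trace)
    heading = _unwrap_deg(trace.heading_deg)
    bar = _unwrap_deg(trace.bar_deg)
    reflect = bar_motion_sign(trace)
    labels = trace.meta.get("epoch_labels")
    t0 = trace.time_s[0]
    n_epochs = int(duration // epoch_s)
    rows = []
    for k in range(n_epochs):
        e0, e1 = t0 + k * epoch_s, t0 + (k + 1) * epoch_s
        i0 = int(np.searchsorted(trace.time_s, e0, side="left"))
        i1 = min(int(np.searchsorted(trace.time_s, e1, side="right")) - 1, heading.size - 1)
        d_bar = bar[i1] - bar[i0]
        d_heading = heading[i1] - heading[i0]
        pi = d_heading / d_bar if d_bar != 0 else np.nan
        n_sacc = sum(1 for s in saccades if e0 <= s.onset_s < e1)
        rows.append(
            {
                "epoch": k,
                "t_start_s": float(e0),
                "t_end_s": float(e1),
                "label": labels[k] if labels is not None and k < len(labels) else "",
                "displacement_deg": float(reflect * d_heading),
                "pi": float(pi) if np.isfinite(pi) else np.nan,
                "n_saccades": int(n_sacc),
            }
        )
    table = pd.DataFrame(rows)
    valid = table["pi"].dropna()
    frac = float((valid > 0).mean()) if len(valid) else float("nan")
    return EpochMetrics(table=table, positive_pi_fraction=frac, epoch_s=epoch_s)


def _window_r_squared(fly: np.ndarray, bar: np.ndarray) -> float:
    """R^2 of the OLS regression of fly displacement on bar displacement."""
    if np.ptp(bar) == 0 or np.ptp(fly) == 0:
        return 0.0
    r = np.corrcoef(bar, fly)[0, 1]
    return float(r * r)


def tracking_bouts(
    trace: HeadingTrace,
    r2_min: float = 0.75,
    window_bar_displacement_deg: float = 180.0,
) -> list[TrackingBout]:
    """Find bouts of bar tracking from half-revolution regression windows.

    The trial is tiled into non-overlapping windows each spanning
    ``window_bar_displacement_deg`` of bar rotation; within each window the
    fly's unwrapped displacement is regressed on the bar's, and windows with
    R^2 >= ``r2_min`` qualify.  Runs of adjacent qualifying windows merge
    into single bouts (r_squared reports the mean over merged windows).
    """
    heading = _unwrap_deg(trace.heading_deg)
    bar = _unwrap_deg(trace.bar_deg)
    progress = np.abs(bar - bar[0])
    total = progress[-1]
    if total < window_bar_displacement_deg:
        warnings.warn("trial shorter than one half-revolution window; no bouts", stacklevel=2)
        return []
    n_windows = int(total // window_bar_displacement_deg)
    edges = np.searchsorted(
        progress, window_bar_displacement_deg * np.arange(n_windows + 1), side="left"
    )
    qualifying = []
    for w in range(n_windows):
        i0, i1 = int(edges[w]), int(edges[w + 1])
        if i1 - i0 < 3:
            continue
        r2 = _window_r_squared(heading[i0 : i1 + 1], bar[i0 : i1 + 1])
        if r2 >= r2_min:
            qualifying.append((w, i0, i1, r2))
    bouts: list[TrackingBout] = []
    run: list[tuple[int, int, int, float]] = []
    for item in qualifying:
        if run and item[0] != run[-1][0] + 1:
            bouts.append(_merge_run(trace, run, window_bar_displacement_deg))
            run = []
        run.append(item)
    if run:
        bouts.append(_merge_run(trace, run, window_bar_displacement_deg))
    return bouts


def _merge_run(trace, run, window_deg) -> TrackingBout:
    i0 = run[0][1]
    i1 = run[-1][2]
    return TrackingBout(
        start_s=float(trace.time_s[i0]),
        end_s=float(trace.time_s[min(i1, trace.time_s.size - 1)]),
        r_squared=float(np.mean([r for *_, r in run])),
        n_windows=len(run),
        window_bar_displacement_deg=float(window_deg),
    )


@dataclass
class GainResult:
    """Inter-saccadic gains within tracking bouts.

    ``mean`` is the unweighted mean of per-interval gains; ``pooled`` is the
    total fly rotation over the total bar rotation across all intervals
    (displacement-weighted), which is robust to very short intervals whose
    individual ratios are noisy.
    """

    per_interval: list = field(default_factory=list)  # (t0, t1, gain)
    mean: float = float("nan")
    pooled: float = float("nan")


def intersaccadic_gain(
    trace: HeadingTrace,
    saccades: list[Saccade],
    bouts: list[TrackingBout],
) -> GainResult:
    """Ratio of fly to bar rotation during inter-saccadic intervals in bouts.

    Intervals run from one saccade's offset to the next saccade's onset,
    clipped to each bout (a bout with no saccades contributes one interval
    spanning the whole bout).  Returns the per-interval gains, their
    unweighted mean, and the displacement-weighted pooled gain.
    """
    heading = _unwrap_deg(trace.heading_deg)
    bar = _unwrap_deg(trace.bar_deg)

    def disp(channel, t0, t1):
        i0 = int(np.searchsorted(trace.time_s, t0, side="left"))
        i1 = min(int(np.searchsorted(trace.time_s, t1, side="right")) - 1, channel.size - 1)
        return channel[i1] - channel[i0], i1 - i0

    result = GainResult()
    total_fly = total_bar = 0.0
    for bout in bouts:
        cuts = [bout.start_s]
        for s in sorted(saccades, key=lambda s: s.onset_s):
            if s.offset_s <= bout.start_s or s.onset_s >= bout.end_s:
                continue
            cuts.extend([max(s.onset_s, bout.start_s), min(s.offset_s, bout.end_s)])
        cuts.append(bout.end_s)
        for t0, t1 in zip(cuts[0::2], cuts[1::2]):
            if t1 <= t0:
                continue
            d_bar, n = disp(bar, t0, t1)
            if n < 2 or d_bar == 0:
                continue
            d_fly, _ = disp(heading, t0, t1)
            result.per_interval.append((float(t0), float(t1), float(d_fly / d_bar)))
            total_fly += d_fly
            total_bar += d_bar
    if result.per_interval:
        result.mean = float(np.mean([g for *_, g in result.per_interval]))
        if total_bar != 0:
            result.pooled = float(total_fly / total_bar)
    return result


def pre_saccadic_error(trace: HeadingTrace, saccades: list[Saccade]) -> np.ndarray:
    """Signed bar-minus-heading error at each saccade onset, wrapped to
    (-180, 180], positive in the bar's direction of motion."""
    heading = _unwrap_deg(trace.heading_deg)
    bar = _unwrap_deg(trace.bar_deg)
    sign_bar = bar_motion_sign(trace)
    errors = np.empty(len(saccades))
    for k, s in enumerate(saccades):
        i = int(np.searchsorted(trace.time_s, s.onset_s, side="left"))
        i = min(i, heading.size - 1)
        errors[k] = wrap_180(bar[i] - heading[i]) * sign_bar
    return errors


@dataclass
class RigidTetherMetrics:
    """Steering summary of one rigid-tether open-loop trial."""

    midline_mean_dwba: float
    midline_crossing_s: float
    windup_time_s: np.ndarray
    windup: np.ndarray          # cumulative dWBA integral, normalized to max |value|
    windup_raw: np.ndarray      # volt-seconds, unnormalized


def rigid_tether_metrics(
    trace: SteeringTrace,
    midline_window_s: float = 0.2,
) -> RigidTetherMetrics:
    """dWBA mean before the bar crosses the visual midline, plus the wind-up
    integral.

    The midline crossing is the first zero crossing of the signed bar
    position (wrapped to +-180, away from the rear pole); the mean dWBA is
    taken over the ``midline_window_s`` preceding it.  The wind-up series is
    the cumulative trapezoidal integral of dWBA (fictive angular
    displacement), normalized per trial to its maximum absolute value.
    """
    signed = wrap_180(trace.bar_deg)
    crossing = None
    for i in range(1, signed.size):
        a, b = signed[i - 1], signed[i]
        if a == 0.0:
            crossing = float(trace.time_s[i - 1])
            break
        if a * b < 0 and abs(a) < 90 and abs(b) < 90:  # through the front, not the rear
            crossing = float(
                trace.time_s[i - 1]
                + (trace.time_s[i] - trace.time_s[i - 1]) * abs(a) / (abs(a) + abs(b))
            )
            break
    if crossing is None:
        raise InvalidArgumentError("bar never crosses the visual midline")
    in_window = (trace.time_s >= crossing - midline_window_s) & (trace.time_s < crossing)
    if not np.any(in_window):
        raise InvalidArgumentError("no samples in the pre-midline window")
    midline_mean = float(np.mean(trace.dwba[in_window]))

    from scipy.integrate import cumulative_trapezoid

    windup_raw = cumulative_trapezoid(trace.dwba, trace.time_s, initial=0.0)
    peak = float(np.max(np.abs(windup_raw)))
    windup = windup_raw / peak if peak > 0 else windup_raw.copy()
    return RigidTetherMetrics(
        midline_mean_dwba=midline_mean,
        midline_crossing_s=crossing,
        windup_time_s=trace.time_s.copy(),
        windup=windup,
        windup_raw=windup_raw,
    )
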