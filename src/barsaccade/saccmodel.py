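"""Integrate-and-fire model of saccade triggering from columnar visual input.

The model holds that bar-tracking saccades fire when the integrated retinal
position error (I_rpe) — the time integral of the bar's angular error beyond
an integration offset — reaches a constant (2.5 deg*s).  ISI and
pre-saccadic error are then inversely related: with the error growing
linearly during fixation, the triangle of base ISI and height
(error - offset) has constant area I_rpe, so E = offset + 2 * I_rpe / ISI.

On the physiology side, single-neuron calcium transients are fitted with a
beta-density-shaped curve; the area under the fit (I_Ca2+) measures how much
signal one columnar neuron contributes, and dividing an integrator threshold
I_thr by I_Ca2+ gives the number of columns (at interommatidial spacing
delta_phi) a moving bar must recruit to fire a saccade.

A closed-loop discrete-time simulator couples the accumulator to a revolving
bar: the fly holds heading (or tracks smoothly at a configurable gain),
accumulates (|error| - offset) outside a frontal dead zone, and fires a
stereotyped saccade toward the bar when the accumulator reaches I_rpe.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, special

from .errors import FitFailureError, InvalidArgumentError
from .types import BetaFit, CalciumTrace, ModelParams, SimResult, wrap_180, wrap_360

__all__ = [
    "fit_beta_curve",
    "response_integral",
    "cells_to_threshold",
    "error_from_isi",
    "isi_from_speed",
    "simulate_tracking",
    "estimate_irpe",
]

_X_EPS = 1e-9
_BETA_STARTS = (0.5, 1.0, 2.0, 4.0)


def _beta_shape(x: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    return x ** (alpha - 1.0) * (1.0 - x) ** (beta - 1.0)


def fit_beta_curve(trace: CalciumTrace, window: tuple[float, float]) -> BetaFit:
    """Least-squares fit of y = gamma * x**(alpha-1) * (1-x)**(beta-1).

    Time in ``window`` = (t0, t1) is mapped to x in [0, 1].  The shape
    parameters are optimized by bounded nonlinear least squares with a
    multi-start grid over (alpha, beta) in {0.5, 1, 2, 4}^2; gamma is
    profiled out linearly at each start.  The best (lowest-RSS) converged
    fit is returned.
    """
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise InvalidArgumentError("window must have positive length")
    mask = (trace.time_s >= t0) & (trace.time_s <= t1)
    if int(np.sum(mask)) < 8:
        raise InvalidArgumentError("need at least 8 samples in the fit window")
    y = trace.value[mask]
    if not np.all(np.isfinite(y)):
        raise InvalidArgumentError("non-finite values in the fit window")
    x = (trace.time_s[mask] - t0) / (t1 - t0)
    x = np.clip(x, _X_EPS, 1.0 - _X_EPS)

    def residuals(theta):
        a, b = theta
        shape = _beta_shape(x, a, b)
        denom = float(shape @ shape)
        g = float(shape @ y) / denom if denom > 0 else 0.0
        g = max(g, 0.0)
        return g * shape - y

    best = None
    for a0 in _BETA_STARTS:
        for b0 in _BETA_STARTS:
            try:
                sol = optimize.least_squares(
                    residuals,
                    x0=[a0, b0],
                    bounds=([1e-3, 1e-3], [50.0, 50.0]),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, float(sol.x[0]), float(sol.x[1]))
    if best is None:
        raise FitFailureError("beta-curve fit failed from every starting point")
    rss, alpha, beta = best
    shape = _beta_shape(x, alpha, beta)
    gamma = max(float(shape @ y) / float(shape @ shape), 0.0)
    return BetaFit(alpha=alpha, beta=beta, gamma=gamma, t0_s=t0, t1_s=t1, rss=rss)


def response_integral(fit: BetaFit) -> float:
    """Area under the fitted transient, I_Ca2+ = gamma * B(alpha, beta) * (t1 - t0).

    B is the Euler beta function; the closed form agrees with adaptive
    quadrature of the fitted curve.
    """
    if fit.alpha <= 0 or fit.beta <= 0:
        raise InvalidArgumentError("integral diverges for non-positive shape parameters")
    return float(fit.gamma * special.beta(fit.alpha, fit.beta) * (fit.t1_s - fit.t0_s))


def cells_to_threshold(i_ca: float, params: ModelParams | None = None):
    """Columnar neurons needed to charge the integrator to threshold.

    ``n_cells = ceil(i_thr / i_ca)`` and the angular span they cover is
    ``n_cells * delta_phi_deg``; ``raw_distance_deg`` additionally reports
    the unrounded product (i_thr / i_ca) * delta_phi.
    """
    params = params or ModelParams()
    if i_ca <= 0:
        raise InvalidArgumentError("i_ca must be positive")
    n = int(np.ceil(params.i_thr / i_ca))
    n = max(n, 1)
    return {
        "n_cells": n,
        "angular_distance_deg": n * params.delta_phi_deg,
        "raw_distance_deg": (params.i_thr / i_ca) * params.delta_phi_deg,
    }


def error_from_isi(isi_s: float, params: ModelParams | None = None) -> float:
    """Pre-saccadic error predicted from the ISI by the inverse-I_rpe law.

    E = offset + 2 * I_rpe / ISI: the triangle with base ISI and height
    (E - offset) has constant area I_rpe.
    """
    params = params or ModelParams()
    if isi_s <= 0:
        raise InvalidArgumentError("isi must be positive")
    return params.offset_deg + 2.0 * params.i_rpe / isi_s


def isi_from_speed(bar_speed_deg_s: float, params: ModelParams | None = None) -> float:
    """Steady-state ISI for a bar revolving at constant speed.

    With the error growing at the bar speed v from the offset,
    (1/2) * v * ISI^2 = I_rpe, so ISI = sqrt(2 * I_rpe / v); equivalently
    error_from_isi(isi_from_speed(v)) = offset + sqrt(2 * I_rpe * v).
    """
    params = params or ModelParams()
    if bar_speed_deg_s <= 0:
        raise InvalidArgumentError("bar speed must be positive")
    return float(np.sqrt(2.0 * params.i_rpe / bar_speed_deg_s))


def simulate_tracking(
    bar_speed_deg_s: float,
    duration_s: float,
    params: ModelParams | None = None,
    smooth_gain: float = 0.0,
    saccade_dur_s: float = 0.05,
    start_error_deg: float = 0.0,
    integrand: str = "beyond_offset",
) -> SimResult:
    """Closed-loop discrete-time tracking simulation.

    Each Euler step (dt = params.dt_s): the bar advances at constant speed;
    the fly advances by ``smooth_gain`` times the bar step (0 by default:
    stationary between saccades); the signed wrapped error bar - fly drives
    the accumulator, which adds ``max(0, |error| - offset) * dt`` (or
    ``|error| * dt`` with ``integrand='magnitude'``) while |error| exceeds
    the frontal dead zone and holds at zero inside it.  When the accumulator
    reaches I_rpe a saccade fires toward the bar — amplitude
    ``params.saccade_amp_deg`` if set, else |error| - offset so the error
    returns to the offset — the accumulator resets, and the pre-saccadic
    |error| and onset-to-onset ISI are recorded.  The state update is
    instantaneous; the exported heading renders the turn as a ramp over
    ``saccade_dur_s`` so the saccade-detection kinematics apply unchanged.
    """
    params = params or ModelParams()
    if bar_speed_deg_s < 0 or duration_s <= 0:
        raise InvalidArgumentError("speed must be >= 0 and duration positive")
    if integrand not in ("beyond_offset", "magnitude"):
        raise InvalidArgumentError("integrand must be 'beyond_offset' or 'magnitude'")
    dt = params.dt_s
    if bar_speed_deg_s * dt > 1.0:
        raise InvalidArgumentError("dt too coarse: the bar moves more than 1 deg per step")
    n = int(round(duration_s / dt)) + 1
    t = np.arange(n) * dt
    bar = bar_speed_deg_s * t
    fly = np.empty(n)
    fly[0] = -start_error_deg

    accumulator = 0.0
    heading = fly[0]
    onsets: list[float] = []
    pre_errors: list[float] = []
    amps_signed: list[float] = []
    ramp_steps = max(int(round(saccade_dur_s / dt)), 1)

    for k in range(1, n):
        heading += smooth_gain * bar_speed_deg_s * dt
        err = float(wrap_180(bar[k] - heading))
        if abs(err) <= params.dead_zone_deg:
            accumulator = 0.0
        else:
            if integrand == "beyond_offset":
                accumulator += max(0.0, abs(err) - params.offset_deg) * dt
            else:
                accumulator += abs(err) * dt
        if accumulator >= params.i_rpe:
            amp = (
                params.saccade_amp_deg
                if params.saccade_amp_deg is not None
                else abs(err) - params.offset_deg
            )
            amp = max(amp, 0.0)
            onsets.append(float(t[k]))
            pre_errors.append(abs(err))
            amps_signed.append(float(np.sign(err) * amp))
            heading += np.sign(err) * amp
            accumulator = 0.0
        fly[k] = heading

    # The dynamics treat each saccade as an instantaneous heading step; for
    # export, spread the step linearly over saccade_dur_s so the detection
    # kinematics see a realistic velocity transient.
    fly_drawn = fly.copy()
    for onset, amp_signed in zip(onsets, amps_signed):
        k0 = int(round(onset / dt))
        k1 = min(k0 + ramp_steps, n - 1)
        span = max(k1 - k0, 1)
        for j in range(k0, k1):
            fly_drawn[j] -= amp_signed * (1.0 - (j - k0 + 1) / span)

    onsets_arr = np.asarray(onsets)
    isis = np.full(onsets_arr.size, np.nan)
    if onsets_arr.size > 1:
        isis[1:] = np.diff(onsets_arr)
    return SimResult(
        time_s=t,
        fly_heading_deg=wrap_360(fly_drawn),
        bar_deg=wrap_360(bar),
        saccade_onsets_s=onsets_arr,
        pre_errors_deg=np.asarray(pre_errors),
        isis_s=isis,
        params=params,
    )


def estimate_irpe(
    saccades,
    params: ModelParams | None = None,
) -> float:
    """Estimate I_rpe from (pre-saccadic error, ISI) pairs.

    Mean over saccades of (1/2) * (pre_error - offset) * ISI, the area of
    the error triangle.  Pairs with error below the offset are excluded with
    a warning; pairs with NaN ISI (first saccade of a run) are skipped.
    """
    params = params or ModelParams()
    pairs = [(float(e), float(i)) for e, i in saccades]
    if not pairs:
        raise InvalidArgumentError("need at least one (pre_error, isi) pair")
    areas = []
    n_excluded = 0
    for err, isi in pairs:
        if not np.isfinite(isi) or isi <= 0:
            continue
        if err < params.offset_deg:
            n_excluded += 1
            continue
        areas.append(0.5 * (err - params.offset_deg) * isi)
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} saccade(s) with pre-error below the offset",
            stacklevel=2,
        )
    if not areas:
        raise InvalidArgumentError("no usable (pre_error, isi) pairs after exclusions")
    return float(np.mean(areas))
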