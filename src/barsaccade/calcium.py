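"""Calcium-imaging analysis: dF/F normalization, peak extraction, receptive-field
maps from orthogonal bar sweeps, and direction tuning.

The receptive field of a small-field columnar neuron is mapped by sweeping a
single-pixel bar through horizontal bins (azimuth) and vertical bins
(elevation); the outer product of the per-bin peak responses gives a rank-1
estimate of the 2-D field.  Maps from several flies are peak-normalized,
re-centred on their maximum bin and averaged.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DegenerateBaselineError, InvalidArgumentError
from .types import CalciumTrace, DirectionTuning, RFMap

__all__ = [
    "dff_trace",
    "peak_response",
    "rf_outer_product",
    "rf_center_and_average",
    "direction_tuning",
]

CARDINAL_DIRECTIONS = ("up", "down", "left", "right")


def dff_trace(
    raw: CalciumTrace,
    baseline_window_s: float = 0.5,
    onset_label: str | None = None,
) -> CalciumTrace:
    """Normalize raw fluorescence to dF/F = (F_t - F0) / F0.

    F0 is the mean fluorescence over the ``baseline_window_s`` seconds
    preceding stimulus onset (the first event, or the one named by
    ``onset_label``).
    """
    if not raw.events:
        raise InvalidArgumentError("trace has no stimulus-onset event")
    event = raw.event(onset_label) if onset_label is not None else raw.events[0]
    onset = event.onset_s
    if onset - baseline_window_s < raw.time_s[0] - 1e-9:
        raise InvalidArgumentError(
            f"fewer than {baseline_window_s} s of data precede stimulus onset"
        )
    in_baseline = (raw.time_s >= onset - baseline_window_s) & (raw.time_s < onset)
    if not np.any(in_baseline):
        raise InvalidArgumentError("baseline window contains no samples")
    f0 = float(np.mean(raw.value[in_baseline]))
    if f0 <= 0:
        raise DegenerateBaselineError(f"baseline fluorescence F0 = {f0} is not positive")
    return CalciumTrace(
        time_s=raw.time_s.copy(),
        value=(raw.value - f0) / f0,
        events=list(raw.events),
        is_dff=True,
    )


def peak_response(trace: CalciumTrace, window: str, lag_s: float = 1.0) -> float:
    """Maximum dF/F within a labelled stimulus window, extended by ``lag_s``
    after offset to capture the indicator's decay."""
    event = trace.event(window)
    mask = (trace.time_s >= event.onset_s) & (trace.time_s <= event.offset_s + lag_s)
    if not np.any(mask):
        raise InvalidArgumentError(f"window {window!r} contains no samples")
    return float(np.max(trace.value[mask]))


def rf_outer_product(h_responses, v_responses) -> RFMap:
    """Outer product of horizontal-bin and vertical-bin peak responses.

    ``grid[i, j] = h[i] * v[j]``, the rank-1 receptive-field estimate from
    orthogonal sweeps (10 azimuth bins x 8 elevation bins of 9 deg each by
    default; any lengths are accepted).
    """
    h = np.asarray(h_responses, dtype=float)
    v = np.asarray(v_responses, dtype=float)
    if h.ndim != 1 or v.ndim != 1 or h.size == 0 or v.size == 0:
        raise InvalidArgumentError("h_responses and v_responses must be non-empty 1-D")
    return RFMap(grid=np.outer(h, v), normalized=False)


def _normalize_map(m: RFMap) -> tuple[np.ndarray, tuple[int, int]]:
    grid = np.asarray(m.grid, dtype=float)
    flat_max = np.nanmax(grid)
    if not np.isfinite(flat_max) or flat_max <= 0:
        raise InvalidArgumentError("RF map has no positive maximum to normalize to")
    n_ties = int(np.sum(grid == flat_max))
    if n_ties > 1:
        warnings.warn(
            f"RF maximum tied across {n_ties} bins; using the lowest (azimuth, elevation) index",
            stacklevel=3,
        )
    center = tuple(np.unravel_index(int(np.nanargmax(grid)), grid.shape))
    return grid / flat_max, center


def rf_center_and_average(maps: list[RFMap]) -> RFMap:
    """Peak-normalize each map, re-centre it on its maximum bin, and average.

    Each map is divided by its maximum (centre bin = 1) and shifted so all
    centres coincide at the middle bin of the common grid; bins shifted
    outside the window are dropped and the average divides by the per-bin
    count of contributing maps (bins never covered are NaN).  The output is
    idempotent under re-application.
    """
    if not maps:
        raise InvalidArgumentError("need at least one RF map")
    shape = maps[0].grid.shape
    if any(m.grid.shape != shape for m in maps):
        raise InvalidArgumentError("all RF maps must share one grid shape")
    target = (shape[0] // 2, shape[1] // 2)
    acc = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)
    for m in maps:
        grid, center = _normalize_map(m)
        di, dj = target[0] - center[0], target[1] - center[1]
        for i in range(shape[0]):
            si = i - di
            if not (0 <= si < shape[0]):
                continue
            for j in range(shape[1]):
                sj = j - dj
                if 0 <= sj < shape[1] and np.isfinite(grid[si, sj]):
                    acc[i, j] += grid[si, sj]
                    counts[i, j] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan)
    return RFMap(grid=mean, bin_size_deg=maps[0].bin_size_deg, normalized=True)


def direction_tuning(peaks_by_direction: dict) -> DirectionTuning:
    """Direction-selectivity indices per axis from the four cardinal peaks.

    dsi = |p1 - p2| / (p1 + p2) with 0/0 defined as 0; 0 means
    omnidirectional, 1 fully selective.
    """
    missing = [d for d in CARDINAL_DIRECTIONS if d not in peaks_by_direction]
    if missing:
        raise InvalidArgumentError(f"missing direction(s): {', '.join(missing)}")
    peaks = {d: float(peaks_by_direction[d]) for d in CARDINAL_DIRECTIONS}
    if any(p < 0 for p in peaks.values()):
        raise InvalidArgumentError("peak responses must be non-negative")

    def dsi(p1: float, p2: float) -> float:
        total = p1 + p2
        return abs(p1 - p2) / total if total > 0 else 0.0

    return DirectionTuning(
        peaks=peaks,
        dsi_horizontal=dsi(peaks["left"], peaks["right"]),
        dsi_vertical=dsi(peaks["up"], peaks["down"]),
    )
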