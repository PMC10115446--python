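"""Speed-tuning versus temporal-frequency-tuning classification of grating
responses.

For each spatial wavelength the temporal frequency of the maximal response
is extracted; regressing log10(TF of max) on log10(spatial frequency, cycles
per degree) gives a slope of 1 for a perfectly speed-tuned neuron (maxima on
a constant-speed line TF = v / wavelength) and 0 for a TF-tuned neuron
(maxima at a fixed TF).  The two hypotheses are compared as nested linear
models via a BIC-difference approximation to the Bayes factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError, UndefinedArgmaxError
from .types import ResponseMatrix

__all__ = [
    "TuningFit",
    "tf_of_max",
    "spatiotemporal_slope",
    "tuning_model_bayes_factor",
    "classify_tuning",
]

RSS_FLOOR = 1e-12
LOG_BF_CAP = 1e6


@dataclass(frozen=True)
class TuningFit:
    """Summary of the speed-vs-TF model comparison for one neuron."""

    tf_of_max_hz: np.ndarray
    slope: float
    intercept: float
    log_bf: float       # (BIC_tf - BIC_speed) / 2; positive favours the speed model
    bic_speed: float
    bic_tf: float

    @property
    def speed_tuned(self) -> bool:
        return self.log_bf > 0


def tf_of_max(
    matrix: ResponseMatrix, refine: bool = True, return_flags: bool = False
):
    """Per-wavelength temporal frequency of the maximal response.

    With ``refine``, a quadratic interpolation of log-amplitude in log-TF
    around the discrete argmax gives a continuous estimate, clamped to the
    sampled TF range; an argmax on the grid boundary is returned as the
    boundary TF.  With ``return_flags`` a boolean array marking such
    boundary (censored) rows is returned alongside — their true preferred TF
    may lie outside the sampled range.  A row of all zeros has no preferred
    TF and raises UndefinedArgmaxError.
    """
    if refine and matrix.tfs_hz.size < 3:
        raise InvalidArgumentError("refinement needs at least 3 TF samples")
    log_tf = np.log10(matrix.tfs_hz)
    out = np.empty(matrix.wavelengths_deg.size)
    boundary = np.zeros(matrix.wavelengths_deg.size, dtype=bool)
    for i, row in enumerate(matrix.amplitude):
        if np.all(row == 0):
            raise UndefinedArgmaxError(
                f"all-zero response row at wavelength {matrix.wavelengths_deg[i]} deg"
            )
        j = int(np.argmax(row))
        if j == 0 or j == row.size - 1:
            boundary[i] = True
        if not refine or j == 0 or j == row.size - 1:
            out[i] = matrix.tfs_hz[j]
            continue
        # quadratic vertex through the 3 points around the discrete argmax,
        # in (log TF, log amplitude); fall back to the grid point when the
        # parabola is degenerate
        x = log_tf[j - 1 : j + 2]
        y = np.log(np.maximum(row[j - 1 : j + 2], 1e-300))
        denom = (y[0] - 2.0 * y[1] + y[2])
        if denom >= 0:
            out[i] = matrix.tfs_hz[j]
            continue
        # uniform-grid vertex formula generalized to possibly uneven spacing
        a, b, c = np.polyfit(x, y, 2)
        vertex = -b / (2.0 * a)
        vertex = min(max(vertex, log_tf[0]), log_tf[-1])
        out[i] = 10.0 ** vertex
    if return_flags:
        return out, boundary
    return out


def spatiotemporal_slope(tf_of_max_hz, wavelengths_deg) -> float:
    """OLS slope of log10(TF of max) on log10(spatial frequency in cpd).

    1 = perfect speed tuning, 0 = perfect TF tuning.
    """
    tf = np.asarray(tf_of_max_hz, dtype=float)
    lam = np.asarray(wavelengths_deg, dtype=float)
    if tf.shape != lam.shape or tf.ndim != 1:
        raise InvalidArgumentError("tf_of_max and wavelengths must be 1-D and aligned")
    if np.unique(lam).size < 2:
        raise InvalidArgumentError("need at least 2 distinct wavelengths")
    if np.any(tf <= 0) or np.any(lam <= 0):
        raise InvalidArgumentError("TFs and wavelengths must be positive")
    x = np.log10(1.0 / lam)  # spatial frequency, cycles per degree
    y = np.log10(tf)
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def tuning_model_bayes_factor(tf_of_max_hz, wavelengths_deg) -> TuningFit:
    """Compare a TF-tuned (intercept-only) and a speed-tuned (slope) linear model.

    Both models are ordinary least squares on y = log10(TF of max) with
    regressor x = log10(SF); BIC_k = n ln(RSS_k / n) + p_k ln n (Gaussian
    likelihood with the variance profiled out), and
    log BF = (BIC_tf - BIC_speed) / 2, positive when the speed model wins.
    The RSS is floored at 1e-12 so perfect fits give a large finite score,
    capped at +-1e6.
    """
    tf = np.asarray(tf_of_max_hz, dtype=float)
    lam = np.asarray(wavelengths_deg, dtype=float)
    n = tf.size
    if n < 3:
        raise InsufficientDataError("model comparison needs at least 3 points")
    if np.any(tf <= 0) or np.any(lam <= 0):
        raise InvalidArgumentError("TFs and wavelengths must be positive")
    x = np.log10(1.0 / lam)
    y = np.log10(tf)

    slope, intercept = np.polyfit(x, y, 1)
    rss_speed = max(float(np.sum((y - (intercept + slope * x)) ** 2)), RSS_FLOOR)
    rss_tf = max(float(np.sum((y - np.mean(y)) ** 2)), RSS_FLOOR)

    bic_speed = n * np.log(rss_speed / n) + 2.0 * np.log(n)
    bic_tf = n * np.log(rss_tf / n) + 1.0 * np.log(n)
    log_bf = float(np.clip((bic_tf - bic_speed) / 2.0, -LOG_BF_CAP, LOG_BF_CAP))

    return TuningFit(
        tf_of_max_hz=tf,
        slope=float(slope),
        intercept=float(intercept),
        log_bf=log_bf,
        bic_speed=float(bic_speed),
        bic_tf=float(bic_tf),
    )


def classify_tuning(
    matrix: ResponseMatrix, refine: bool = True, censor_boundary: bool = True
) -> TuningFit:
    """Extract preferred TFs from a response matrix and run the model comparison.

    With ``censor_boundary`` (default), wavelengths whose response maximum
    falls on the edge of the sampled TF range are excluded from the
    regression: for those rows the preferred TF is censored by the stimulus
    grid, and the clamped value would bias the slope toward zero.
    """
    tf, flags = tf_of_max(matrix, refine=refine, return_flags=True)
    lam = matrix.wavelengths_deg
    if censor_boundary and np.any(flags):
        keep = ~flags
        if int(np.sum(keep)) < 3:
            raise InsufficientDataError(
                "fewer than 3 wavelengths with an interior response maximum"
            )
        tf, lam = tf[keep], lam[keep]
    return tuning_model_bayes_factor(tf, lam)
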