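"""Trimming, linear detrending, and amplitude/period estimation.

Oscillating TTC-reduction series ride on a growth-related trend. Following
standard practice for such series, the points up to and including the
first local maximum and from the last local maximum onward are removed (so
only the central, linear-trend section remains), a least-squares line is
subtracted, and the residuals are summarized by their amplitude (half the
peak-to-trough range) and dominant period (lag of the first significant
positive autocorrelation peak).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

log = logging.getLogger(__name__)


@dataclass
class RhythmResult:
    """Detrending and rhythm summary of one series."""

    trimmed_range: tuple[int, int]  # [start, stop) indices kept from the input
    slope: float
    intercept: float
    x: np.ndarray
    residuals: np.ndarray
    amplitude: float | None = None
    period_h: float | None = None

    def summary(self) -> dict:
        return {
            "trimmed_start": self.trimmed_range[0],
            "trimmed_stop": self.trimmed_range[1],
            "n": len(self.residuals),
            "slope": self.slope,
            "intercept": self.intercept,
            "amplitude": self.amplitude,
            "period_h": self.period_h,
        }


def find_series_peaks(values: np.ndarray, prominence_frac: float = 0.25) -> np.ndarray:
    """Local maxima with prominence >= prominence_frac x detrended SD.

    The prominence floor is taken relative to the SD of the linearly
    detrended series so that a sloping baseline does not mask (or fake)
    peaks.
    """
    values = np.asarray(values, dtype=np.float64)
    detrended = signal.detrend(values, type="linear")
    floor = prominence_frac * detrended.std()
    peaks, _ = signal.find_peaks(values, prominence=floor if floor > 0 else None)
    return peaks


def trim_peaks(
    x, values, prominence_frac: float = 0.25
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Drop everything up to/including the first peak and from the last peak on.

    Returns (x_trimmed, values_trimmed, (start, stop)) with half-open index
    range into the input. If fewer than two peaks are found the series is
    returned unchanged with a logged warning.
    """
    x = np.asarray(x, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if len(values) < 5:
        raise ValueError(f"series of length {len(values)} is too short to trim (need >= 5)")
    peaks = find_series_peaks(values, prominence_frac)
    if len(peaks) < 2:
        log.warning("fewer than 2 peaks found; series returned untrimmed")
        return x, values, (0, len(values))
    start, stop = peaks[0] + 1, peaks[-1]
    return x[start:stop], values[start:stop], (int(start), int(stop))


def linear_detrend(x, values, trimmed_range: tuple[int, int] | None = None) -> RhythmResult:
    """Ordinary least-squares line fit; residuals = values - fitted."""
    x = np.asarray(x, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if len(x) != len(values):
        raise ValueError("x and values must have equal length")
    if len(values) < 3:
        raise ValueError("detrending needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("all x values identical; cannot fit a trend line")
    fit = stats.linregress(x, values)
    residuals = values - (fit.slope * x + fit.intercept)
    return RhythmResult(
        trimmed_range=trimmed_range if trimmed_range is not None else (0, len(values)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        x=x,
        residuals=residuals,
    )


def estimate_amplitude(residuals) -> float:
    """Half the peak-to-trough range of the detrended series."""
    residuals = np.asarray(residuals, dtype=np.float64)
    if len(residuals) < 3:
        raise ValueError("amplitude needs at least 3 points")
    return float(np.ptp(residuals) / 2.0)


def autocorrelation(residuals: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags 0..max_lag."""
    r = np.asarray(residuals, dtype=np.float64)
    r = r - r.mean()
    denom = float(r @ r)
    if denom == 0:
        return np.zeros(max_lag + 1)
    full = np.correlate(r, r, mode="full")[len(r) - 1 :]
    return full[: max_lag + 1] / denom


def estimate_period(residuals, dt_h: float) -> float | None:
    """Dominant period: lag of the first significant positive ACF peak.

    A peak qualifies if the autocorrelation there exceeds the white-noise
    band 2/sqrt(N). Returns the period in hours, or None if no peak
    qualifies (e.g. white noise or a series shorter than two cycles of any
    candidate period).
    """
    residuals = np.asarray(residuals, dtype=np.float64)
    n = len(residuals)
    if n < 8:
        log.info("series of %d points too short for period estimation", n)
        return None
    max_lag = n // 2
    acf = autocorrelation(residuals, max_lag)
    band = 2.0 / np.sqrt(n)
    peaks, _ = signal.find_peaks(acf[1:])
    peaks = peaks + 1
    significant = peaks[acf[peaks] > band]
    if len(significant) == 0:
        return None
    return float(significant[0] * dt_h)


def analyze_series(x, values, dt_h: float | None = None,
                   prominence_frac: float = 0.25) -> RhythmResult:
    """Trim -> detrend -> amplitude + period, the standard rhythm workflow."""
    x_t, v_t, rng = trim_peaks(x, values, prominence_frac)
    result = linear_detrend(x_t, v_t, trimmed_range=rng)
    result.amplitude = estimate_amplitude(result.residuals)
    if dt_h is None:
        dt_h = float(np.median(np.diff(x_t)))
    result.period_h = estimate_period(result.residuals, dt_h)
    return result


def compare_amplitudes(group_a, group_b) -> tuple[float, float, str]:
    """Two-sided unpaired Welch t-test on two groups of amplitudes.

    Returns (t statistic, p-value, direction), where direction reports
    which group has the larger mean ("a>b", "b>a", or "equal").
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 amplitudes")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    diff = a.mean() - b.mean()
    direction = "a>b" if diff > 0 else ("b>a" if diff < 0 else "equal")
    return float(t), float(p), direction
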