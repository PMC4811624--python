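"""GAW normalization, fundamental-frequency estimation, band-pass filtering.

The analysis runs on two signal variants: the unfiltered normalized GAW
(GAW_o) and a band-pass filtered variant (GAW_f) restricted to a band of
0.7-1.3 times the fundamental frequency f0.  The low-pass side smooths
segmentation artifacts so cycle maxima are located more accurately; the
high-pass side removes the DC offset so the signal, like the analytic onset
envelope, converges to zero for t -> -inf.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DegenerateSignalError, EstimationError, InputError
from .signal import GAWSignal

__all__ = [
    "first_syllable_samples",
    "normalize_gaw",
    "estimate_f0",
    "bandpass_gaw",
    "bandpass_sos",
]

#: physiological f0 search range, Hz
F0_MIN = 50.0
F0_MAX = 500.0


def first_syllable_samples(gaw: GAWSignal, syllable_fraction: float = 0.4) -> int:
    """Number of samples in the first-syllable window.

    The first syllable of the analyzed word is taken as the first
    ``syllable_fraction`` (default 40%) of the total signal duration.
    """
    if not 0 < syllable_fraction <= 1:
        raise ConfigError(f"syllable_fraction must be in (0, 1], got {syllable_fraction}")
    return max(1, int(round(syllable_fraction * gaw.n)))


def normalize_gaw(gaw: GAWSignal, syllable_fraction: float = 0.4) -> GAWSignal:
    """Normalize to the maximum area within the first syllable.

    After normalization the maximum value inside the first-syllable window
    equals 1; values from later syllables may exceed 1.  Scale-invariant:
    ``normalize(c * x) == normalize(x)`` for any c > 0.
    """
    if gaw.filtered:
        raise InputError("normalize_gaw expects the raw (unfiltered) GAW")
    n_win = first_syllable_samples(gaw, syllable_fraction)
    peak = float(gaw.values[:n_win].max())
    if peak <= 0:
        raise DegenerateSignalError("first-syllable window contains no positive area")
    return gaw.replace(values=gaw.values / peak, normalized=True)


def estimate_f0(gaw: GAWSignal, window_ms: float = 180.0,
                fmin: float = F0_MIN, fmax: float = F0_MAX) -> float:
    """Estimate the fundamental frequency from the start of the GAW.

    Autocorrelation of the mean-removed first ``window_ms`` of the signal;
    the lag search is restricted to periods between 1/fmax and 1/fmin, and
    the best autocorrelation peak is refined by parabolic interpolation.

    Returns f0 in Hz.  A warning is issued if the estimate falls on the edge
    of the physiological search range.
    """
    if window_ms <= 0:
        raise ConfigError("window_ms must be positive")
    n_win = min(gaw.n, int(round(window_ms * gaw.fps / 1000.0)))
    x = gaw.values[:n_win] - gaw.values[:n_win].mean()
    if not np.any(np.abs(x) > 1e-12 * max(1.0, np.abs(gaw.values[:n_win]).max())):
        raise EstimationError("signal is constant in the f0 window; no oscillation")

    lag_min = max(1, int(np.floor(gaw.fps / fmax)))
    lag_max = int(np.ceil(gaw.fps / fmin))
    if lag_max >= n_win // 2:
        lag_max = n_win // 2 - 1
    if lag_max <= lag_min:
        raise EstimationError(
            f"f0 window of {n_win} samples is too short for periods down to {fmin} Hz"
        )

    ac = sps.correlate(x, x, mode="full")[x.size - 1:]
    ac = ac / ac[0]
    # genuine periodicity shows as a local autocorrelation maximum at the
    # period; a window shorter than ~2 cycles has none in the search range
    cand, _ = sps.find_peaks(ac[: lag_max + 2])
    cand = cand[(cand >= lag_min) & (cand <= lag_max) & (ac[cand] > 0)]
    if cand.size == 0:
        raise EstimationError(
            "no periodicity peak in the f0 window (fewer than two cycles?)"
        )
    lag = int(cand[np.argmax(ac[cand])])

    # parabolic interpolation around the discrete autocorrelation maximum
    if lag_min < lag < lag_max:
        y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        lag_refined = lag + float(np.clip(delta, -0.5, 0.5))
    else:
        lag_refined = float(lag)

    f0 = gaw.fps / lag_refined
    # the refined window must still contain at least ~2 full cycles
    if n_win < 2 * lag_refined:
        raise EstimationError("f0 window shorter than two oscillation cycles")
    if not fmin < f0 < fmax:
        warnings.warn(f"f0 estimate {f0:.1f} Hz at the edge of [{fmin}, {fmax}] Hz",
                      stacklevel=2)
    return float(f0)


def bandpass_sos(f0: float, fps: float, low_factor: float = 0.7,
                 high_factor: float = 1.3, order: int = 4) -> np.ndarray:
    """Design the Butterworth band-pass (second-order sections).

    ``order`` is the overall band-pass order (default 4, i.e. a 2nd-order
    low-pass prototype transformed to a band-pass).
    """
    if order < 2 or order % 2:
        raise ConfigError(f"band-pass order must be an even integer >= 2, got {order}")
    if f0 <= 0:
        raise ConfigError("f0 must be positive")
    low, high = low_factor * f0, high_factor * f0
    if high >= fps / 2:
        raise ConfigError(
            f"upper band edge {high:.1f} Hz reaches the Nyquist frequency {fps / 2:.1f} Hz"
        )
    return sps.butter(order // 2, [low, high], btype="bandpass", fs=fps, output="sos")


def bandpass_gaw(gaw: GAWSignal, f0: float | None = None, low_factor: float = 0.7,
                 high_factor: float = 1.3, order: int = 4) -> GAWSignal:
    """Produce the filtered variant GAW_f.

    Zero-phase (forward-backward) filtering is used so that peak times, which
    the VOT measurement ultimately rests on, are not displaced by group
    delay.  The output has zero mean by construction and may be negative.
    """
    f0 = gaw.f0 if f0 is None else f0
    if f0 is None:
        raise ConfigError("f0 is required to design the band-pass (estimate it first)")
    sos = bandpass_sos(f0, gaw.fps, low_factor, high_factor, order)
    y = sps.sosfiltfilt(sos, gaw.values)
    return GAWSignal(y, gaw.fps, normalized=gaw.normalized, filtered=True, f0=float(f0))
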