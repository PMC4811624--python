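"""Cycle peaks, first vocal-fold contact, saturation amplitude, fit-point selection.

The envelope fits operate on the per-cycle maxima of the GAW.  The
saturation amplitude r_sat — the mean oscillation amplitude of sustained
phonation — is estimated as the maximum of a central moving average (cma,
kernel of five peaks) of cycle-peak amplitudes within the first syllable.
Peaks not preceded by glottal closure (the folds oscillate without touching
at the very start of onset) are excluded from the cma.  The last peak inside
the maximizing cma window bounds the fit domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateSignalError, InputError, InsufficientDataError
from .signal import GAWSignal

__all__ = [
    "Peak",
    "CMAResult",
    "SaturationInfo",
    "detect_cycle_peaks",
    "detect_first_contact",
    "central_moving_average",
    "saturation_amplitude",
    "select_fit_peaks",
]

#: default normalized-area threshold below which the glottis counts as closed
CLOSURE_EPSILON = 0.005


@dataclass(frozen=True)
class Peak:
    """A per-cycle maximum of the GAW."""

    index: int               # sample index
    time_ms: float
    amplitude: float
    preceded_by_closure: bool


@dataclass
class CMAResult:
    """Central moving average of eligible peak amplitudes.

    ``values[i]`` is the mean over ``kernel`` consecutive eligible peaks
    centered on ``center_peaks[i]``; ``window_last_peaks[i]`` is the last
    peak of that window.
    """

    values: np.ndarray
    center_peaks: list[Peak]
    window_last_peaks: list[Peak]
    eligible_peaks: list[Peak]
    kernel: int


@dataclass
class SaturationInfo:
    """Saturation amplitude r_sat = cma_max and the resulting fit bound."""

    r_sat: float
    cma: CMAResult
    last_fit_peak: Peak
    r0: float | None = field(default=None)

    @property
    def cma_max(self) -> float:
        return self.r_sat


def detect_cycle_peaks(gaw: GAWSignal, closure_epsilon: float = CLOSURE_EPSILON,
                       closure_reference: GAWSignal | None = None) -> list[Peak]:
    """Detect one peak per oscillation cycle.

    Unfiltered signals: candidate maxima at least ~0.6 periods apart are
    taken as cycle peaks, with cycles delimited by the minima between
    consecutive peaks.  Filtered signals: cycles are delimited by
    negative-to-positive zero crossings and the maximum of each segment is
    the cycle peak.  Ties at flat maxima resolve to the earliest sample.

    ``preceded_by_closure`` marks peaks whose preceding cycle reached the
    glottis-closed state (area <= closure_epsilon).  For filtered signals,
    closure cannot be read off the zero-mean waveform, so it is judged on
    ``closure_reference`` (the paired unfiltered signal) over the same
    sample ranges; without a reference, all filtered peaks are marked
    eligible.
    """
    if gaw.f0 is None:
        raise ConfigError("f0 must be set on the signal before peak detection")
    x = gaw.values
    period = gaw.fps / gaw.f0

    if gaw.filtered:
        up = np.nonzero((x[:-1] < 0) & (x[1:] >= 0))[0] + 1
        if up.size < 2:
            raise DegenerateSignalError("no oscillation cycles found in filtered GAW")
        peak_idx = []
        for a, b in zip(up[:-1], up[1:]):
            peak_idx.append(a + int(np.argmax(x[a:b])))
        ref = closure_reference.values if closure_reference is not None else None
        peaks = []
        prev = peak_idx[0]
        for k, i in enumerate(peak_idx):
            if ref is None:
                closed = True
            else:
                lo = 0 if k == 0 else prev
                closed = bool(np.min(ref[lo:i + 1]) <= closure_epsilon) if i > lo else False
            peaks.append(Peak(int(i), i / gaw.fps * 1000.0, float(x[i]), closed))
            prev = i
        return peaks

    from scipy.signal import find_peaks

    distance = max(1, int(round(0.6 * period)))
    idx, props = find_peaks(x, distance=distance, height=closure_epsilon, plateau_size=1)
    idx = props["left_edges"]  # flat maxima resolve to the earliest sample
    if idx.size == 0:
        raise DegenerateSignalError("no oscillation cycles found in GAW")
    peaks = []
    prev = 0
    for k, i in enumerate(idx):
        # cycle delimited below by the minimum since the previous peak
        lo = prev if k > 0 else 0
        closed = bool(np.min(x[lo:i + 1]) <= closure_epsilon) if i > lo else False
        peaks.append(Peak(int(i), i / gaw.fps * 1000.0, float(x[i]), closed))
        prev = i
    return peaks


def detect_first_contact(gaw: GAWSignal, closure_epsilon: float = CLOSURE_EPSILON) -> float | None:
    """Time (ms) of the first vocal-fold contact, or None if none occurs.

    First contact is the first sample with area <= closure_epsilon that is
    followed by a reopening (a later sample above the threshold).  At the
    very beginning of onset the folds oscillate without touching, so absence
    of closure is a valid outcome, not an error.
    """
    if gaw.filtered:
        raise InputError("first contact is defined on the unfiltered GAW")
    below = np.nonzero(gaw.values <= closure_epsilon)[0]
    if below.size == 0:
        return None
    above_after = gaw.values > closure_epsilon
    # cumulative "any reopening at or after this index", scanned from the end
    reopen = np.flip(np.logical_or.accumulate(np.flip(above_after)))
    for i in below:
        if i + 1 < gaw.n and reopen[i + 1]:
            return float(i / gaw.fps * 1000.0)
    return None


def central_moving_average(peaks: list[Peak], kernel: int = 5) -> CMAResult:
    """Centered moving average of eligible peak amplitudes.

    Peaks without a preceding glottal closure are excluded before
    averaging.  The cma is defined only where the full kernel fits, so the
    first value is centered on eligible peak number ceil(kernel/2).
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ConfigError(f"cma kernel must be an odd integer >= 1, got {kernel}")
    eligible = [p for p in peaks if p.preceded_by_closure]
    if len(eligible) < kernel:
        raise InsufficientDataError(
            f"need at least {kernel} closure-preceded peaks for the cma, "
            f"got {len(eligible)}"
        )
    amps = np.array([p.amplitude for p in eligible])
    values = np.convolve(amps, np.full(kernel, 1.0 / kernel), mode="valid")
    half = kernel // 2
    centers = eligible[half:len(eligible) - half]
    lasts = eligible[kernel - 1:]
    return CMAResult(values, centers, lasts, eligible, kernel)


def saturation_amplitude(cma: CMAResult, total_duration_ms: float,
                         syllable_fraction: float = 0.4) -> SaturationInfo:
    """Saturation amplitude r_sat = max cma within the first syllable.

    Only cma values whose center peak lies in the first ``syllable_fraction``
    of the signal are considered.  The last of the five peaks in the
    maximizing window becomes the last peak to which envelopes are fitted.
    """
    if not 0 < syllable_fraction <= 1:
        raise ConfigError(f"syllable_fraction must be in (0, 1], got {syllable_fraction}")
    limit_ms = syllable_fraction * total_duration_ms
    in_window = [i for i, p in enumerate(cma.center_peaks) if p.time_ms < limit_ms]
    if not in_window:
        raise InsufficientDataError("no cma value inside the first-syllable window")
    best = max(in_window, key=lambda i: cma.values[i])
    return SaturationInfo(
        r_sat=float(cma.values[best]),
        cma=cma,
        last_fit_peak=cma.window_last_peaks[best],
    )


def select_fit_peaks(peaks: list[Peak], variant: str,
                     first_contact_ms: float | None,
                     last_fit_peak: Peak) -> list[Peak]:
    """Select the peaks the envelope is fitted to.

    Unfiltered GAW: only peaks after the first vocal-fold contact, up to the
    last peak of the maximizing cma window.  Filtered GAW: all peaks up to
    that bound, including those before first contact.  At least 3 peaks are
    required for a meaningful fit.
    """
    if variant not in ("filtered", "unfiltered"):
        raise ConfigError(f"variant must be 'filtered' or 'unfiltered', got {variant!r}")
    if not peaks:
        raise InsufficientDataError("empty peak series")
    upto = [p for p in peaks if p.time_ms <= last_fit_peak.time_ms]
    if variant == "unfiltered":
        if first_contact_ms is None:
            raise InsufficientDataError(
                "no vocal-fold contact: no fit peaks on the unfiltered GAW"
            )
        selected = [p for p in upto if p.time_ms > first_contact_ms]
    else:
        selected = upto
    if len(selected) < 3:
        raise InsufficientDataError(
            f"only {len(selected)} fit peaks selected; need at least 3"
        )
    return selected
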