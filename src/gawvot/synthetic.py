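"""Synthetic glottal area waveforms and frame stacks with known ground truth.

The generator emulates the structure the analysis assumes: a nonnegative
area oscillation at f0 whose cycle-peak envelope follows the Hopf onset law
M(t), with the first cycles lacking glottal closure (the folds oscillate
without touching, so the area never reaches zero) and later cycles closing
fully.  Optional per-cycle amplitude jitter, additive sample noise, slow
baseline drift and a second syllable exercise the robustness of each
pipeline stage.  Every signal ships with its ground truth (true f0, growth
rate, crossing-convention VOT_67, first-contact sample) so recovery can be
asserted end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .envelope import _eval_m_raw
from .frames import FrameStack
from .signal import GAWSignal
from .vot import VOT67_CROSSING_FACTOR

__all__ = ["SyntheticSpec", "GroundTruth", "generate_gaw", "generate_frames"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic onset GAW.

    Defaults describe a typical sustained female-range phonation onset
    recorded at 8000 fps: f0 = 200 Hz, growth rate a = 25 1/s (VOT_67 about
    40 ms), first-cycle amplitude 0.1 of the saturation amplitude, two
    open (non-closing) cycles before first vocal-fold contact, and 2% per-
    cycle peak-amplitude jitter.  ``closure_exponent`` sharpens the closed
    phase (>1 lengthens closure); ``open_margin`` / ``closed_margin`` are
    the oscillation offsets that make early cycles miss closure and later
    cycles reach it.
    """

    f0: float = 200.0
    a_true: float = 25.0
    r0_true: float = 0.1
    r_sat_true: float = 1.0
    fps: float = 8000.0
    n_open_cycles: int = 2
    duration_ms: float = 600.0
    closure_exponent: float = 1.0
    noise_sd: float = 0.02          # per-cycle peak-amplitude jitter
    sample_noise_sd: float = 0.0    # additive white noise on samples
    drift_amp: float = 0.0          # slow additive baseline modulation
    drift_hz: float = 2.0
    second_syllable: bool = False
    pause_ms: float = 120.0
    second_amp_scale: float = 1.25
    area_scale: float = 1.0         # multiply to emulate raw pixel areas
    open_margin: float = -1.2
    closed_margin: float = -0.2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.r0_true < self.r_sat_true:
            raise ConfigError("need 0 < r0_true < r_sat_true")
        if not 50 <= self.f0 <= 500:
            raise ConfigError("f0 must lie in the physiological range [50, 500] Hz")
        if self.fps <= 2.6 * self.f0:
            raise ConfigError("fps too low to resolve the band around f0")
        if self.a_true <= 0 or self.duration_ms <= 0 or self.area_scale <= 0:
            raise ConfigError("a_true, duration_ms and area_scale must be positive")
        if not self.open_margin < -1 < self.closed_margin < 1:
            raise ConfigError("need open_margin < -1 (no closure) and |closed_margin| < 1")
        if self.noise_sd < 0 or self.sample_noise_sd < 0 or self.drift_amp < 0:
            raise ConfigError("noise amplitudes must be nonnegative")


@dataclass
class GroundTruth:
    """What the generator actually produced."""

    f0: float
    a: float
    r0: float
    r_sat: float
    vot67_crossing_ms: float     # 1000 * 0.99766 / a
    vot67_reciprocal_ms: float   # 1000 / a
    first_contact_index: int | None
    first_contact_ms: float | None
    n_cycles: int
    onset_duration_ms: float
    second_syllable_start_ms: float | None = field(default=None)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "f0", "a", "r0", "r_sat", "vot67_crossing_ms", "vot67_reciprocal_ms",
            "first_contact_index", "first_contact_ms", "n_cycles",
            "onset_duration_ms", "second_syllable_start_ms")}


def _burst(spec: SyntheticSpec, t: np.ndarray, rng: np.random.Generator,
           amp_scale: float = 1.0) -> np.ndarray:
    """One phonation burst: rectified oscillation under the M envelope.

    r(t) = E(t) * max(0, (sin(2 pi f0 t) - c(t)) / (1 - c(t)))**q  where the
    offset c per cycle is ``open_margin`` (< -1, minima stay positive: no
    contact) for the first ``n_open_cycles`` and ``closed_margin`` after
    (minima clip at zero: full closure).  Peak values track E(t).
    """
    env = _eval_m_raw(t * 1000.0, spec.a_true, spec.r0_true, spec.r_sat_true)
    cyc = np.floor(spec.f0 * t).astype(int)
    n_cycles = int(cyc.max()) + 1
    c = np.where(cyc < spec.n_open_cycles, spec.open_margin, spec.closed_margin)
    shape = np.maximum(0.0, (np.sin(2 * np.pi * spec.f0 * t) - c) / (1.0 - c))
    if spec.closure_exponent != 1.0:
        shape = shape ** spec.closure_exponent
    jitter = np.maximum(0.0, 1.0 + spec.noise_sd * rng.standard_normal(n_cycles))
    return amp_scale * env * shape * jitter[cyc], n_cycles


def generate_gaw(spec: SyntheticSpec,
                 rng: np.random.Generator | None = None) -> tuple[GAWSignal, GroundTruth]:
    """Generate a synthetic GAW and its ground truth.

    Deterministic given ``spec.seed`` (or an explicitly passed generator).
    The true VOT_67 follows the crossing convention,
    1000 * 0.99766 / a ms; the reciprocal convention 1000/a is stored
    alongside.  The first-contact sample is read off the clean rectified
    waveform before noise floors are added, which per-cycle jitter and
    rectification leave intact.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = int(round(spec.duration_ms * spec.fps / 1000.0))
    t = np.arange(n) / spec.fps

    if spec.second_syllable:
        n1 = int(round(0.4 * n))
        n_pause = int(round(spec.pause_ms * spec.fps / 1000.0))
        n2 = n - n1 - n_pause
        if n2 <= 0:
            raise ConfigError("duration too short for a second syllable")
        burst1, n_cycles = _burst(spec, t[:n1], rng)
        burst2, _ = _burst(spec, t[:n2], rng, amp_scale=spec.second_amp_scale)
        values = np.concatenate([burst1, np.zeros(n_pause), burst2])
        second_start_ms = (n1 + n_pause) / spec.fps * 1000.0
        onset_ms = n1 / spec.fps * 1000.0
    else:
        values, n_cycles = _burst(spec, t, rng)
        second_start_ms = None
        onset_ms = spec.duration_ms

    # first contact on the clean burst: first zero sample followed by reopening
    first_idx: int | None = None
    zero = values[: int(round(onset_ms * spec.fps / 1000.0))] <= 0.0
    if zero.any():
        cand = int(np.argmax(zero))
        if np.any(values[cand + 1:] > 0):
            first_idx = cand

    if spec.drift_amp > 0:
        values = values + spec.drift_amp * 0.5 * (1.0 + np.sin(2 * np.pi * spec.drift_hz * t))
    if spec.sample_noise_sd > 0:
        values = values + spec.sample_noise_sd * rng.standard_normal(n)
    values = np.maximum(values, 0.0) * spec.area_scale

    truth = GroundTruth(
        f0=spec.f0, a=spec.a_true, r0=spec.r0_true, r_sat=spec.r_sat_true,
        vot67_crossing_ms=1000.0 * VOT67_CROSSING_FACTOR / spec.a_true,
        vot67_reciprocal_ms=1000.0 / spec.a_true,
        first_contact_index=first_idx,
        first_contact_ms=None if first_idx is None else first_idx / spec.fps * 1000.0,
        n_cycles=n_cycles,
        onset_duration_ms=onset_ms,
        second_syllable_start_ms=second_start_ms,
    )
    return GAWSignal(values, spec.fps, f0=None), truth


def generate_frames(spec: SyntheticSpec, size: int = 128, flicker_depth: float = 0.15,
                    grid_amp: float = 10.0, background: float = 200.0,
                    glottis_level: float = 30.0,
                    rng: np.random.Generator | None = None
                    ) -> tuple[FrameStack, GAWSignal, GroundTruth]:
    """Render the GAW as a stack of endoscopy-like grayscale frames.

    A dark vertical ellipse (the glottis) on bright tissue; the ellipse area
    tracks the GAW.  Multiplicative 50 Hz brightness flicker emulates the
    light source, an additive high-frequency grid emulates fiber-optic
    interference patterns.  Returns the stack together with the generating
    GAW and its ground truth.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    gaw, truth = generate_gaw(spec, rng=rng)
    r = gaw.values / max(gaw.values.max(), 1e-12)
    n = gaw.n
    t = np.arange(n) / spec.fps

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    max_area_px = 0.10 * size * size       # fully open glottis covers 10%
    aspect = 3.0                           # vertical semi-axis : horizontal
    grid = grid_amp * np.sin(2 * np.pi * xx / 6.0) * np.sin(2 * np.pi * yy / 6.0)
    flick = 1.0 + flicker_depth * np.sin(2 * np.pi * 50.0 * t)

    frames = np.empty((n, size, size), dtype=np.uint8)
    for i in range(n):
        frame = np.full((size, size), background) + grid
        area = r[i] * max_area_px
        if area > 0:
            b = np.sqrt(area / (np.pi * aspect))   # horizontal semi-axis
            a_ax = aspect * b
            inside = ((xx - cx) / b) ** 2 + ((yy - cy) / a_ax) ** 2 <= 1.0
            frame[inside] = glottis_level
        frame = frame * flick[i]
        frames[i] = np.clip(np.floor(frame + 0.5), 0, 255).astype(np.uint8)
    return FrameStack(frames, spec.fps), gaw, truth
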