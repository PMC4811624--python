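"""The glottal area waveform (GAW) container.

A GAW is the segmented glottal opening area sampled once per video frame:
maxima correspond to the open glottis, (near-)zeros to glottal closure.
Raw areas are in pixel units; after :func:`gawvot.preprocess.normalize_gaw`
they are dimensionless with the first-syllable maximum at 1.  The band-pass
filtered variant oscillates around zero and may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError

__all__ = ["GAWSignal"]


@dataclass
class GAWSignal:
    """Sampled glottal area over time.

    Parameters
    ----------
    values : array-like of float
        Area per sample (pixel^2 if raw, dimensionless if normalized).
    fps : float
        Sampling rate in Hz (the camera frame rate, typically 8000).
    normalized : bool
        Whether the signal was normalized to the first-syllable maximum.
    filtered : bool
        Whether the signal is the band-pass filtered variant GAW_f
        (filtered signals may be negative).
    f0 : float, optional
        Fundamental frequency in Hz once estimated.
    """

    values: np.ndarray
    fps: float
    normalized: bool = False
    filtered: bool = False
    f0: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise InputError("GAW values must be a nonempty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise InputError("GAW values must be finite")
        if not self.fps > 0:
            raise InputError(f"fps must be positive, got {self.fps}")
        if not self.filtered and np.any(self.values < 0):
            raise InputError("raw/normalized glottal areas must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration_ms(self) -> float:
        """Total signal duration in ms (n samples at fps)."""
        return self.n / self.fps * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(self.n) / self.fps * 1000.0

    def replace(self, **kwargs) -> "GAWSignal":
        return replace(self, **kwargs)
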