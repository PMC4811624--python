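"""Voice onset time from a fitted envelope.

Two VOT definitions from the literature are supported, both measured as the
time the fitted envelope needs to traverse an amplitude interval relative to
the saturation amplitude r_sat:

* VOT_67: from 32.2% to 67.8% of r_sat,
* VOT_90: from 5% to 90% of r_sat.

For the Hopf envelope M(t) the growth-rate parameter ``a`` is (to within
0.3%) the reciprocal of VOT_67, so M-family fits report VOT_67 directly as
1000/a ms and never VOT_90.  Polynomial fits locate threshold crossings
numerically; a fit that never crosses a threshold inside its trusted domain
simply yields a non-computable result — non-computability is the atom the
corpus-level reliability statistic counts, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ParameterError
from .envelope import MEnvelope, PolynomialEnvelope

__all__ = [
    "VOTDefinition",
    "VOT67",
    "VOT90",
    "VOT67_CROSSING_FACTOR",
    "VOTResult",
    "vot_from_crossings",
    "vot67_from_M",
]


@dataclass(frozen=True)
class VOTDefinition:
    """An onset interval as fractions of the saturation amplitude."""

    name: str
    lower_fraction: float
    upper_fraction: float

    def __post_init__(self):
        if not 0 < self.lower_fraction < self.upper_fraction < 1:
            raise ConfigError(
                f"need 0 < lower < upper < 1, got ({self.lower_fraction}, {self.upper_fraction})"
            )


VOT67 = VOTDefinition("VOT67", 0.322, 0.678)
VOT90 = VOTDefinition("VOT90", 0.05, 0.90)

#: exact crossing interval of M(t) between 32.2% and 67.8% of r_sat, in
#: units of 1/a:  (1/2) * ln((1 - c1^2) c2^2 / (c1^2 (1 - c2^2))) ~ 0.99766.
#: Its closeness to 1 is what makes a the reciprocal of VOT_67.
VOT67_CROSSING_FACTOR = 0.5 * math.log(
    (1.0 - VOT67.lower_fraction ** 2) * VOT67.upper_fraction ** 2
    / (VOT67.lower_fraction ** 2 * (1.0 - VOT67.upper_fraction ** 2))
)


@dataclass
class VOTResult:
    """Threshold-crossing times and the resulting VOT."""

    definition: VOTDefinition
    t_lower_ms: float | None
    t_upper_ms: float | None
    vot_ms: float | None
    computable: bool
    method: str  # 'crossing' or 'reciprocal'

    def to_dict(self) -> dict:
        return {
            "definition": self.definition.name,
            "t_lower_ms": self.t_lower_ms,
            "t_upper_ms": self.t_upper_ms,
            "vot_ms": self.vot_ms,
            "computable": self.computable,
            "method": self.method,
        }


def _not_computable(definition, method="crossing"):
    return VOTResult(definition, None, None, None, False, method)


def _bisect_crossing(f, lo, hi, thr, tol_ms):
    """Refine an upward crossing bracketed by [lo, hi] to tol_ms."""
    flo = f(lo)
    while hi - lo > tol_ms:
        mid = 0.5 * (lo + hi)
        if f(mid) < thr:
            lo = mid
        else:
            hi = mid
    return hi


def _first_upward_crossing(f, grid, thr, tol_ms, start_index=0):
    """First time on the grid where f rises through thr from below."""
    y = f(grid)
    for i in range(max(start_index, 1), grid.size):
        if y[i - 1] < thr <= y[i]:
            return _bisect_crossing(f, grid[i - 1], grid[i], thr, tol_ms), i
    return None, None


def vot_from_crossings(fit, r_sat: float, definition: VOTDefinition,
                       search_domain: tuple[float, float] | None = None,
                       tol_ms: float = 1e-4) -> VOTResult:
    """Locate the VOT interval on a fitted envelope by threshold crossing.

    ``r_sat`` is the measured saturation amplitude the thresholds refer to.
    The lower threshold must be crossed from below (a fit sitting above it
    over the whole domain, the failure mode the supporting point exists to
    prevent, is non-computable); the upper threshold is then the first later
    upward crossing.

    The default search domain is [supporting-point time, last fit peak] for
    polynomials.  The M envelope is defined analytically on all of t and
    decays to 0 for t -> -inf, so its domain is extended to the left until
    the envelope drops below the lower threshold.
    """
    if r_sat <= 0:
        raise ParameterError("r_sat must be positive")
    thr_lo = definition.lower_fraction * r_sat
    thr_hi = definition.upper_fraction * r_sat

    if search_domain is not None:
        lo, hi = map(float, search_domain)
    elif isinstance(fit, PolynomialEnvelope):
        lo = fit.supporting_point_[0] if fit.supporting_point_ is not None \
            else fit.t_first_peak_ms_
        hi = fit.t_last_peak_ms_
    elif isinstance(fit, MEnvelope):
        # extend left until M < thr_lo (M is monotone, M -> 0 at -inf)
        span = 1000.0 / fit.a_
        lo = fit.t_origin_ms_
        hi = fit.t_origin_ms_ + 20.0 * span
        while fit.predict([lo])[0] >= thr_lo and span < 1e7:
            lo -= span
            span *= 2.0
    else:
        raise ConfigError("cannot infer a search domain for this fit; pass search_domain")
    if not hi > lo:
        return _not_computable(definition)

    f = lambda t: np.asarray(fit.predict(np.atleast_1d(t)))
    n = int(min(20001, max(1001, (hi - lo) / 0.01)))
    grid = np.linspace(lo, hi, n)
    t_lower, i = _first_upward_crossing(f, grid, thr_lo, tol_ms)
    if t_lower is None:
        return _not_computable(definition)
    t_upper, _ = _first_upward_crossing(f, grid, thr_hi, tol_ms, start_index=i)
    if t_upper is None or t_upper <= t_lower:
        return _not_computable(definition)
    return VOTResult(definition, float(t_lower), float(t_upper),
                     float(t_upper - t_lower), True, "crossing")


def vot67_from_M(fit_or_a) -> VOTResult:
    """VOT_67 of an M-family fit via the reciprocal rule: VOT = 1000/a ms."""
    a = fit_or_a.a_ if isinstance(fit_or_a, MEnvelope) else float(fit_or_a)
    if a <= 0:
        raise ParameterError(f"growth rate a must be positive, got {a}")
    return VOTResult(VOT67, None, None, 1000.0 / a, True, "reciprocal")
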