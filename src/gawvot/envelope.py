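"""Analytic envelope models of phonation onset and their least-squares fits.

Two model families approximate the growth of cycle-peak amplitudes during
voice onset:

* the Hopf-bifurcation envelope

      M(t) = r0 * [(1 - xi) * exp(-2 a t) + xi]^(-1/2),   xi = (r0 / r_sat)^2

  which rises from M(-inf) = 0 through M(0) = r0 to M(+inf) = r_sat.  The
  growth rate ``a`` (1/s) is, to within 0.3%, the reciprocal of the
  32.2-67.8% onset time.  Three variants differ in which parameters are
  optimized: M_a (a only; r0 and r_sat fixed to their measured values),
  M_as (a and r_sat), M_asr (a, r_sat and r0);

* plain polynomials P2/P3/P4 of order 2-4 over time in ms, with an optional
  zero-amplitude "supporting point" one oscillation cycle before the first
  fit peak that anchors the polynomial near zero at early times.

Both are exposed as scikit-learn style estimators: ``fit(X, y)`` takes peak
times in ms and normalized amplitudes, fitted attributes carry a trailing
underscore, and ``predict`` evaluates the envelope at arbitrary times.
Goodness of fit is the RMSE between the envelope and the peak amplitudes
(the supporting point never contributes to the RMSE).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConfigError, FitError, InputError, InsufficientDataError, ParameterError
from .peaks import Peak

__all__ = [
    "A_BOUNDS",
    "RSAT_BOUNDS",
    "R0_BOUNDS",
    "eval_M",
    "MEnvelope",
    "PolynomialEnvelope",
    "fit_M",
    "fit_polynomial",
    "rmse",
]

#: physically reasonable optimization boundaries
A_BOUNDS = (1.0, 1000.0)     # 1/s
RSAT_BOUNDS = (0.0, 2.0)     # normalized
R0_BOUNDS = (0.0, 1.0)       # normalized

M_VARIANTS = ("a", "as", "asr")


def _eval_m_raw(t_ms, a, r0, r_sat):
    """M(t) without parameter validation; t in ms, a in 1/s."""
    t = np.asarray(t_ms, dtype=float) / 1000.0
    xi = (r0 / r_sat) ** 2
    with np.errstate(over="ignore"):
        denom = (1.0 - xi) * np.exp(-2.0 * a * t) + xi
    return r0 / np.sqrt(denom)


def eval_M(t_ms, a: float, r0: float, r_sat: float):
    """Evaluate the Hopf-bifurcation envelope at time ``t_ms`` (ms).

    Requires a > 0 and 0 < r0 < r_sat; then M is strictly increasing with
    M(0) = r0 and supremum r_sat.
    """
    if a <= 0:
        raise ParameterError(f"growth rate a must be positive, got {a}")
    if not 0 < r0 < r_sat:
        raise ParameterError(
            f"need 0 < r0 < r_sat for a growing envelope, got r0={r0}, r_sat={r_sat}"
        )
    out = _eval_m_raw(t_ms, a, r0, r_sat)
    return float(out) if np.isscalar(t_ms) else out


def _as_times_amps(X, y=None):
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise InputError("X must be 1-D peak times in ms (or a single column)")
    if y is None:
        return t
    a = np.asarray(y, dtype=float)
    if a.shape != t.shape:
        raise InputError("X and y must have matching lengths")
    return t, a


class MEnvelope(BaseEstimator, RegressorMixin):
    """Bounded nonlinear least-squares fit of the Hopf onset envelope.

    Parameters
    ----------
    variant : {'a', 'as', 'asr'}
        Which parameters are free: 'a' optimizes the growth rate only,
        'as' additionally the saturation amplitude, 'asr' additionally the
        first-cycle amplitude r0.
    r0, r_sat : float or None
        Measured values (first-cycle amplitude; cma-based saturation
        amplitude).  Required for the parameters the variant keeps fixed
        and used as initial values otherwise.
    a_starts : tuple of float
        Multi-start initial growth rates in 1/s.

    Fitted attributes: ``a_``, ``r0_``, ``rsat_``, ``rmse_``,
    ``converged_``, ``t_origin_ms_`` (time of the first fit peak; the model
    clock t = 0 sits there so that M(0) = r0).
    """

    family_prefix = "M"

    def __init__(self, variant: str = "asr", r0: float | None = None,
                 r_sat: float | None = None,
                 a_bounds: tuple = A_BOUNDS, rsat_bounds: tuple = RSAT_BOUNDS,
                 r0_bounds: tuple = R0_BOUNDS,
                 a_starts: tuple = (10.0, 50.0, 200.0)):
        self.variant = variant
        self.r0 = r0
        self.r_sat = r_sat
        self.a_bounds = a_bounds
        self.rsat_bounds = rsat_bounds
        self.r0_bounds = r0_bounds
        self.a_starts = a_starts

    @property
    def family(self) -> str:
        return f"M_{self.variant}"

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y):
        if self.variant not in M_VARIANTS:
            raise ConfigError(f"variant must be one of {M_VARIANTS}, got {self.variant!r}")
        t, amps = _as_times_amps(X, y)
        if t.size < 3:
            raise InsufficientDataError("need at least 3 peaks to fit the M envelope")
        if np.any(np.diff(t) <= 0):
            raise InputError("peak times must be strictly increasing")
        if self.r0 is None or self.r_sat is None:
            raise ParameterError("measured r0 and r_sat are required (fixed values / inits)")
        r0_meas = float(np.clip(self.r0, *self.r0_bounds))
        rsat_meas = float(np.clip(self.r_sat, *self.rsat_bounds))
        if not 0 < r0_meas < rsat_meas:
            raise ParameterError(
                f"measured r0={r0_meas} must lie in (0, r_sat={rsat_meas})"
            )
        t0 = float(t[0])
        tloc = t - t0

        def resid(theta):
            a, r0, rsat = theta
            return _eval_m_raw(tloc, a, r0, rsat) - amps

        bounds = {"a": self.a_bounds, "r0": self.r0_bounds, "rsat": self.rsat_bounds}

        def solve(free, start):
            """Bounded LS over the free components, others fixed at start."""
            names = [n for n in ("a", "r0", "rsat") if n in free]
            lb = np.array([bounds[n][0] for n in names])
            ub = np.array([bounds[n][1] for n in names])
            x0 = np.clip(np.array([start[n] for n in names]), lb + 1e-12, ub - 1e-12)

            def r(x):
                p = dict(start)
                p.update(zip(names, x))
                # keep r0 < rsat strictly inside the evaluable region
                r0v = max(min(p["r0"], p["rsat"] - 1e-9), 1e-12)
                return resid((p["a"], r0v, p["rsat"]))

            sol = least_squares(r, x0, bounds=(lb, ub), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            p = dict(start)
            p.update(zip(names, sol.x))
            return p, float(np.sqrt(np.mean(r(sol.x) ** 2))), sol.status > 0

        def best_of(free, starts, incumbent=None):
            out = incumbent
            for s in starts:
                cand = solve(free, s)
                if out is None or cand[1] < out[1]:
                    out = cand
            return out

        base = {"a": 0.0, "r0": r0_meas, "rsat": rsat_meas}
        cold = [{**base, "a": a0} for a0 in self.a_starts]
        # Each richer variant is warm-started from the previous solution and
        # keeps it unless improved, so rmse(M_asr) <= rmse(M_as) <= rmse(M_a)
        # holds structurally (nested feasible sets).
        best = best_of(("a",), cold)
        if self.variant in ("as", "asr"):
            best = best_of(("a", "rsat"), [dict(best[0])] + cold, incumbent=best)
        if self.variant == "asr":
            best = best_of(("a", "r0", "rsat"), [dict(best[0])] + cold, incumbent=best)

        p, err, ok = best
        self.a_ = float(p["a"])
        self.r0_ = float(min(p["r0"], p["rsat"] - 1e-9))
        self.rsat_ = float(p["rsat"])
        self.rmse_ = float(np.sqrt(np.mean(
            (_eval_m_raw(tloc, self.a_, self.r0_, self.rsat_) - amps) ** 2)))
        self.converged_ = bool(ok)
        self.t_origin_ms_ = t0
        self.n_peaks_ = int(t.size)
        return self

    def predict(self, X):
        t = _as_times_amps(X)
        self._check_fitted()
        return _eval_m_raw(np.asarray(t, dtype=float) - self.t_origin_ms_,
                           self.a_, self.r0_, self.rsat_)

    def _check_fitted(self):
        if not hasattr(self, "a_"):
            raise FitError("MEnvelope is not fitted")

    @classmethod
    def from_params(cls, a: float, r0: float, r_sat: float,
                    t_origin_ms: float = 0.0) -> "MEnvelope":
        """Construct an already-parameterized envelope (no fitting)."""
        if a <= 0 or not 0 < r0 < r_sat:
            raise ParameterError("need a > 0 and 0 < r0 < r_sat")
        m = cls(variant="asr", r0=r0, r_sat=r_sat)
        m.a_, m.r0_, m.rsat_ = float(a), float(r0), float(r_sat)
        m.rmse_, m.converged_, m.t_origin_ms_, m.n_peaks_ = 0.0, True, float(t_origin_ms), 0
        return m

    def crossing_time_ms(self, level: float) -> float | None:
        """Closed-form time (absolute ms) where M reaches ``level``.

        Returns None when the level is outside (0, sup M) and never reached.
        Solves (1 - xi) exp(-2 a t) + xi = (r0 / level)^2 for t.
        """
        self._check_fitted()
        if not 0 < level < self.rsat_:
            return None
        xi = (self.r0_ / self.rsat_) ** 2
        arg = ((self.r0_ / level) ** 2 - xi) / (1.0 - xi)
        if arg <= 0:
            return None
        t_s = -np.log(arg) / (2.0 * self.a_)
        return float(t_s * 1000.0 + self.t_origin_ms_)

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "family": self.family,
            "params": {"a": self.a_, "r0": self.r0_, "r_sat": self.rsat_},
            "t_origin_ms": self.t_origin_ms_,
            "rmse": self.rmse_,
            "converged": self.converged_,
            "n_peaks": self.n_peaks_,
        }


class PolynomialEnvelope(BaseEstimator, RegressorMixin):
    """Least-squares polynomial envelope with an optional supporting point.

    Parameters
    ----------
    order : {2, 3, 4}
        Polynomial order (P2, P3, P4).
    cycle_period_ms : float or None
        Oscillation period; the supporting point (amplitude 0) is placed one
        period before the first fit peak.  Required when
        ``supporting_point=True``.
    supporting_point : bool
        Whether to add the zero-amplitude anchor.  Without it, polynomials
        fitted to saturating data tend to rise toward early times and never
        cross the lower VOT threshold from below.

    Coefficients are solved on times rescaled to [-1, 1] for conditioning
    and reported in the original ms basis (``coef_``, a0 first).
    Underdetermined systems take the minimum-norm least-squares solution.
    Fitted attributes: ``coef_``, ``rmse_``, ``converged_``,
    ``supporting_point_`` ((t_ms, 0.0) or None), ``t_first_peak_ms_``,
    ``t_last_peak_ms_``.
    """

    def __init__(self, order: int = 4, cycle_period_ms: float | None = None,
                 supporting_point: bool = True):
        self.order = order
        self.cycle_period_ms = cycle_period_ms
        self.supporting_point = supporting_point

    @property
    def family(self) -> str:
        return f"P{self.order}"

    def fit(self, X, y):
        if self.order not in (2, 3, 4):
            raise ConfigError(f"polynomial order must be 2, 3 or 4, got {self.order}")
        t, amps = _as_times_amps(X, y)
        if self.supporting_point:
            if self.cycle_period_ms is None or self.cycle_period_ms <= 0:
                raise ConfigError("supporting_point=True requires a positive cycle_period_ms")
            ts = float(t[0]) - float(self.cycle_period_ms)
            td = np.concatenate([[ts], t])
            ad = np.concatenate([[0.0], amps])
            self.supporting_point_ = (ts, 0.0)
        else:
            td, ad = t, amps
            self.supporting_point_ = None
        if td.size < self.order + 1 and td.size < 3:
            raise InsufficientDataError(
                f"need at least 3 data points for a P{self.order} fit, got {td.size}"
            )
        if np.unique(td).size < td.size:
            raise FitError("coincident peak times: rank-deficient polynomial design")

        lo, hi = float(td.min()), float(td.max())
        u = 2.0 * (td - lo) / (hi - lo) - 1.0
        V = np.vander(u, self.order + 1, increasing=True)
        coef_u, _, rank, _ = np.linalg.lstsq(V, ad, rcond=None)
        self._poly = Polynomial(coef_u, domain=[lo, hi], window=[-1.0, 1.0])
        conv = self._poly.convert()
        coef = np.zeros(self.order + 1)
        coef[: conv.coef.size] = conv.coef
        self.coef_ = coef
        self.rmse_ = float(np.sqrt(np.mean((self._poly(t) - amps) ** 2)))
        # residual over the full least-squares data set (peaks + supporting
        # point); this is the quantity the order-nesting inequality holds for
        self.rmse_with_support_ = float(np.sqrt(np.mean((self._poly(td) - ad) ** 2)))
        self.converged_ = True
        self.rank_ = int(rank)
        self.t_first_peak_ms_ = float(t[0])
        self.t_last_peak_ms_ = float(t[-1])
        self.n_peaks_ = int(t.size)
        return self

    def predict(self, X):
        t = _as_times_amps(X)
        if not hasattr(self, "coef_"):
            raise FitError("PolynomialEnvelope is not fitted")
        return self._poly(np.asarray(t, dtype=float))

    def to_dict(self) -> dict:
        if not hasattr(self, "coef_"):
            raise FitError("PolynomialEnvelope is not fitted")
        return {
            "family": self.family,
            "params": {f"a{i}": float(c) for i, c in enumerate(self.coef_)},
            "supporting_point": self.supporting_point_,
            "rmse": self.rmse_,
            "converged": self.converged_,
            "n_peaks": self.n_peaks_,
        }


# -- thin functional wrappers over the estimators -------------------------

def _peaks_to_xy(peaks: list[Peak]):
    t = np.array([p.time_ms for p in peaks])
    a = np.array([p.amplitude for p in peaks])
    return t, a


def fit_M(peaks: list[Peak], variant: str, measured_r0: float,
          measured_r_sat: float, **kwargs) -> MEnvelope:
    """Fit an M-family envelope to a peak series."""
    t, a = _peaks_to_xy(peaks)
    return MEnvelope(variant=variant, r0=measured_r0, r_sat=measured_r_sat,
                     **kwargs).fit(t, a)


def fit_polynomial(peaks: list[Peak], order: int, cycle_period_ms: float,
                   supporting_point: bool = True) -> PolynomialEnvelope:
    """Fit a P2/P3/P4 envelope (with supporting point) to a peak series."""
    t, a = _peaks_to_xy(peaks)
    return PolynomialEnvelope(order=order, cycle_period_ms=cycle_period_ms,
                              supporting_point=supporting_point).fit(t, a)


def rmse(fit, peaks: list[Peak]) -> float:
    """Root-mean-square error of a fitted envelope over contributing peaks.

    The supporting point, when present, is excluded: only genuine cycle
    peaks enter the error.
    """
    if not peaks:
        raise InputError("empty peak series")
    t, a = _peaks_to_xy(peaks)
    return float(np.sqrt(np.mean((np.asarray(fit.predict(t)) - a) ** 2)))
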