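"""End-to-end per-recording analysis: raw GAW -> envelope fits -> VOT report.

Stages: normalization to the first-syllable maximum, f0 estimation over the
first 180 ms, band-pass filtering (GAW_f), per-variant cycle-peak detection,
first-contact detection, saturation amplitude via the kernel-5 central
moving average, fit-peak selection, the six envelope fits, and VOT under the
requested definitions.  Stage failures are recorded per family/variant in
the report rather than aborting the recording; the corpus layer counts them
as non-computable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import peaks as pk
from . import preprocess as pp
from .envelope import MEnvelope, PolynomialEnvelope, fit_M, fit_polynomial
from .errors import ConfigError, GawvotError
from .signal import GAWSignal
from .vot import VOT67, VOT90, VOTDefinition, vot67_from_M, vot_from_crossings

logger = logging.getLogger("gawvot")

__all__ = ["PipelineConfig", "FamilyResult", "RecordingReport", "analyze_gaw",
           "ALL_FAMILIES", "M_FAMILIES", "P_FAMILIES"]

M_FAMILIES = ("M_a", "M_as", "M_asr")
P_FAMILIES = ("P2", "P3", "P4")
ALL_FAMILIES = M_FAMILIES + P_FAMILIES
_DEFINITIONS = {"VOT67": VOT67, "VOT90": VOT90}


@dataclass
class PipelineConfig:
    """All tunables of the analysis, defaulting to the study conditions."""

    syllable_fraction: float = 0.4
    f0_window_ms: float = 180.0
    filter_order: int = 4
    band_low_factor: float = 0.7
    band_high_factor: float = 1.3
    closure_epsilon: float = pk.CLOSURE_EPSILON
    cma_kernel: int = 5
    families: tuple = ALL_FAMILIES
    variants: tuple = ("GAW_o", "GAW_f")
    definitions: tuple = ("VOT67", "VOT90")
    supporting_point: bool = True

    def __post_init__(self):
        for fam in self.families:
            if fam not in ALL_FAMILIES:
                raise ConfigError(f"unknown fit family {fam!r}")
        for v in self.variants:
            if v not in ("GAW_o", "GAW_f"):
                raise ConfigError(f"unknown signal variant {v!r}")
        for d in self.definitions:
            if d not in _DEFINITIONS:
                raise ConfigError(f"unknown VOT definition {d!r}")

    def definition(self, name: str) -> VOTDefinition:
        return _DEFINITIONS[name]

    def to_dict(self) -> dict:
        return asdict(self)


def check_family_definition(family: str, definition: str) -> None:
    """Reject M-family VOT_90: only VOT_67 is defined for M fits (a = 1/VOT_67)."""
    if family in M_FAMILIES and definition == "VOT90":
        raise ConfigError(
            "VOT_90 is not computed for M-family fits; the growth rate a is the "
            "reciprocal of VOT_67, so only VOT_67 is defined"
        )


@dataclass
class FamilyResult:
    """Fit + VOT outcomes for one (family, variant) cell."""

    family: str
    variant: str
    fit: MEnvelope | PolynomialEnvelope | None
    rmse: float | None
    converged: bool
    vot: dict = field(default_factory=dict)   # definition name -> VOTResult
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "variant": self.variant,
            "fit": None if self.fit is None else self.fit.to_dict(),
            "rmse": self.rmse,
            "converged": self.converged,
            "vot": {k: v.to_dict() for k, v in self.vot.items()},
            "error": self.error,
        }


@dataclass
class RecordingReport:
    """Everything the pipeline derived from one recording."""

    f0: float | None
    first_contact_ms: float | None
    r_sat: dict            # variant -> measured saturation amplitude
    r0: dict               # variant -> measured first-cycle amplitude
    results: list          # list[FamilyResult]
    errors: list = field(default_factory=list)

    def result(self, family: str, variant: str) -> FamilyResult | None:
        for r in self.results:
            if r.family == family and r.variant == variant:
                return r
        return None

    def to_dict(self) -> dict:
        return {
            "f0": self.f0,
            "first_contact_ms": self.first_contact_ms,
            "r_sat": self.r_sat,
            "r0": self.r0,
            "results": [r.to_dict() for r in self.results],
            "errors": self.errors,
        }


def _fit_and_vot(family: str, variant: str, sel: list, r0: float, r_sat: float,
                 cycle_period_ms: float, config: PipelineConfig) -> FamilyResult:
    if family in M_FAMILIES:
        fit = fit_M(sel, family.split("_")[1], r0, r_sat)
    else:
        fit = fit_polynomial(sel, int(family[1]), cycle_period_ms,
                             supporting_point=config.supporting_point)
    res = FamilyResult(family, variant, fit, fit.rmse_, fit.converged_)
    for dname in config.definitions:
        if family in M_FAMILIES:
            if dname == "VOT90":
                continue  # not defined for M fits
            res.vot[dname] = vot67_from_M(fit)
        else:
            res.vot[dname] = vot_from_crossings(fit, r_sat, config.definition(dname))
    return res


def analyze_gaw(gaw: GAWSignal, config: PipelineConfig | None = None) -> RecordingReport:
    """Run the full analysis on one raw GAW recording."""
    config = config or PipelineConfig()

    norm = pp.normalize_gaw(gaw, config.syllable_fraction) if not gaw.normalized else gaw
    f0 = pp.estimate_f0(norm, config.f0_window_ms)
    norm = norm.replace(f0=f0)
    cycle_period_ms = 1000.0 / f0

    report = RecordingReport(f0=f0, first_contact_ms=None, r_sat={}, r0={}, results=[])

    peaks_o = pk.detect_cycle_peaks(norm, config.closure_epsilon)
    first_contact = pk.detect_first_contact(norm, config.closure_epsilon)
    report.first_contact_ms = first_contact

    signals = {"GAW_o": (norm, peaks_o)}
    if "GAW_f" in config.variants:
        filt = pp.bandpass_gaw(norm, f0, config.band_low_factor,
                               config.band_high_factor, config.filter_order)
        peaks_f = pk.detect_cycle_peaks(filt, config.closure_epsilon,
                                        closure_reference=norm)
        signals["GAW_f"] = (filt, peaks_f)

    for variant in config.variants:
        sig, peaks = signals[variant]
        kind = "unfiltered" if variant == "GAW_o" else "filtered"
        try:
            cma = pk.central_moving_average(peaks, config.cma_kernel)
            sat = pk.saturation_amplitude(cma, sig.duration_ms, config.syllable_fraction)
            sel = pk.select_fit_peaks(peaks, kind, first_contact, sat.last_fit_peak)
        except GawvotError as exc:
            msg = f"{variant}: {exc}"
            logger.warning(msg)
            report.errors.append(msg)
            for family in config.families:
                report.results.append(FamilyResult(family, variant, None, None,
                                                   False, error=str(exc)))
            continue

        r0_meas = sel[0].amplitude
        report.r_sat[variant] = sat.r_sat
        report.r0[variant] = r0_meas
        logger.info("%s: r_sat=%.4f r0=%.4f, %d fit peaks (%.1f-%.1f ms)",
                    variant, sat.r_sat, r0_meas, len(sel),
                    sel[0].time_ms, sel[-1].time_ms)

        for family in config.families:
            try:
                report.results.append(_fit_and_vot(
                    family, variant, sel, r0_meas, sat.r_sat, cycle_period_ms, config))
            except GawvotError as exc:
                logger.warning("%s/%s failed: %s", family, variant, exc)
                report.results.append(FamilyResult(family, variant, None, None,
                                                   False, error=str(exc)))
    return report
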