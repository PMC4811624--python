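"""Corpus-level evaluation: reliability, consistency, accuracy.

For every combination of fit family, signal variant (GAW_o / GAW_f) and VOT
definition, the corpus table reports

* reliability — the percentage of recordings for which the VOT is
  computable (the fit actually traverses the defined amplitude interval),
* consistency — mean and standard deviation of the VOT over the computable
  recordings,
* accuracy — mean and standard deviation of the fit RMSE over the
  recordings for which VOT_67 was computable for that family/variant.

M-family rows exist for VOT_67 only (the growth rate a is its reciprocal;
VOT_90 is not defined for M fits).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import M_FAMILIES, PipelineConfig, RecordingReport, analyze_gaw
from .signal import GAWSignal

__all__ = ["evaluate_corpus", "format_corpus_table"]


def _sd(x: np.ndarray) -> float:
    # sample standard deviation (n-1); 0 for a single value
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def evaluate_corpus(recordings, config: PipelineConfig | None = None,
                    group: str = "all") -> pd.DataFrame:
    """Evaluate a list of recordings (GAWSignal or precomputed reports).

    Recording-level failures never abort the corpus: a recording whose
    pipeline raises is counted as non-computable for every cell.  Returns a
    tidy DataFrame with one row per (variant, family, definition).
    """
    config = config or PipelineConfig()
    reports: list[RecordingReport | None] = []
    for rec in recordings:
        if isinstance(rec, RecordingReport):
            reports.append(rec)
            continue
        try:
            reports.append(analyze_gaw(rec, config))
        except Exception:  # degenerate recording: counts as non-computable
            reports.append(None)
    n = len(reports)
    if n == 0:
        raise ValueError("empty corpus")

    rows = []
    for variant in config.variants:
        for family in config.families:
            # VOT_67 computability gates the RMSE statistics (accuracy is
            # only meaningful where the onset was actually measurable)
            rmse67 = []
            for rep in reports:
                if rep is None:
                    continue
                res = rep.result(family, variant)
                if res is not None and res.rmse is not None:
                    v67 = res.vot.get("VOT67")
                    if v67 is not None and v67.computable:
                        rmse67.append(res.rmse)
            rmse67 = np.asarray(rmse67, dtype=float)

            for dname in config.definitions:
                if family in M_FAMILIES and dname == "VOT90":
                    continue
                vots = []
                n_computable = 0
                for rep in reports:
                    if rep is None:
                        continue
                    res = rep.result(family, variant)
                    if res is None or not res.converged:
                        continue
                    vr = res.vot.get(dname)
                    if vr is not None and vr.computable:
                        n_computable += 1
                        vots.append(vr.vot_ms)
                vots = np.asarray(vots, dtype=float)
                rows.append({
                    "group": group,
                    "variant": variant,
                    "family": family,
                    "definition": dname,
                    "reliability_pct": 100.0 * n_computable / n,
                    "mean_vot_ms": float(vots.mean()) if vots.size else np.nan,
                    "sd_vot_ms": _sd(vots) if vots.size else np.nan,
                    "mean_rmse": float(rmse67.mean()) if rmse67.size else np.nan,
                    "sd_rmse": _sd(rmse67) if rmse67.size else np.nan,
                    "n": n,
                })
    return pd.DataFrame(rows)


def format_corpus_table(table: pd.DataFrame) -> pd.DataFrame:
    """Round to reporting precision: reliability and VOT to integers, RMSE to 2 dp."""
    out = table.copy()
    out["reliability_pct"] = out["reliability_pct"].round(0).astype(int)
    for col in ("mean_vot_ms", "sd_vot_ms"):
        out[col] = out[col].round(0)
    for col in ("mean_rmse", "sd_rmse"):
        out[col] = out[col].round(2)
    return out
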