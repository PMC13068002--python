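"""Calcium-flux trace quantification and classification.

Fluo-4 traces from the 30-minute high-frequency assay (one sample every
~10 s) are normalized to F/F0 with F0 the median of the first five frames,
then searched for transients (rise-and-return peaks above the baseline
noise).  Traces fall into three classes: ``responder`` (at least one
physiological transient), ``non_responder`` (flat baseline), and
``death_signature`` — a sustained high plateau with no return to baseline,
the hallmark of an effector compromised shortly after loading, which is
excluded from responder-fraction statistics.

Classification is invariant to uniform intensity scaling because the gain is
removed by normalization.  A mild linear detrend of the baseline segments
compensates photobleaching before peak detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "CalciumTrace",
    "Transient",
    "TraceClassification",
    "normalize_trace",
    "detect_transients",
    "classify_trace",
    "summarize_responses",
    "classify_frame",
]

BASELINE_FRAMES = 5


@dataclass
class CalciumTrace:
    trap: int
    cell: int
    time_s: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray | None = None
    f0: float | None = None
    valid: bool = True
    invalid_reason: str | None = None


@dataclass(frozen=True)
class Transient:
    onset_s: float
    peak_s: float
    amplitude: float  # F/F0 above baseline
    duration_s: float  # width at half prominence


@dataclass
class TraceClassification:
    label: str  # responder | non_responder | death_signature | unclassified
    features: dict = field(default_factory=dict)
    transients: list = field(default_factory=list)


def normalize_trace(
    trace: CalciumTrace | None = None,
    *,
    time_s: np.ndarray | None = None,
    raw: np.ndarray | None = None,
    trap: int = 0,
    cell: int = 0,
) -> CalciumTrace:
    """F/F0 normalization with F0 = median of the first five frames."""
    if trace is None:
        trace = CalciumTrace(trap=trap, cell=cell, time_s=np.asarray(time_s, float), raw=np.asarray(raw, float))
    raw_arr = np.asarray(trace.raw, dtype=float)
    if len(raw_arr) < 6:
        raise ValueError("need at least 6 frames to normalize")
    f0 = float(np.median(raw_arr[:BASELINE_FRAMES]))
    if f0 <= 0:
        trace.valid = False
        trace.invalid_reason = "non-positive F0 after background subtraction"
        trace.f0 = f0
        return trace
    trace.f0 = f0
    trace.normalized = raw_arr / f0
    return trace


def _baseline_stats(norm: np.ndarray, time_s: np.ndarray) -> tuple[np.ndarray, float]:
    """Detrended trace and robust baseline sd.

    The baseline segments (samples within 1 robust sd of the median) are fit
    with a line whose slope — bleaching drift — is removed; the trace is
    re-anchored at baseline 1.0.
    """
    med = np.median(norm)
    mad_sd = 1.4826 * np.median(np.abs(norm - med)) or 1e-6
    base_sel = np.abs(norm - med) <= max(2 * mad_sd, 0.05)
    if base_sel.sum() >= max(10, len(norm) // 10):
        slope, intercept = np.polyfit(time_s[base_sel], norm[base_sel], 1)
        detrended = norm - (slope * time_s + intercept) + 1.0
    else:
        detrended = norm - med + 1.0
    base = detrended[np.abs(detrended - 1.0) <= max(2 * mad_sd, 0.05)]
    sd = float(np.std(base)) if len(base) > 5 else float(mad_sd)
    return detrended, max(sd, 1e-4)


def detect_transients(
    trace: CalciumTrace,
    min_prominence: float = 0.2,
    sd_multiplier: float = 2.0,
) -> list[Transient]:
    """Rise-and-return peaks above the baseline noise.

    A peak must exceed the baseline by max(``min_prominence`` F/F0 units,
    ``sd_multiplier`` times the baseline sd) with genuine prominence on both
    sides, so a sustained step without return yields no transients (that is a
    plateau, not a peak).
    """
    if trace.normalized is None:
        raise ValueError("normalize the trace first")
    if not trace.valid:
        return []
    detrended, sd = _baseline_stats(trace.normalized, trace.time_s)
    threshold = max(min_prominence, sd_multiplier * sd)
    dt = float(np.median(np.diff(trace.time_s)))
    peaks, props = signal.find_peaks(
        detrended, prominence=threshold, height=1.0 + threshold
    )
    if len(peaks) == 0:
        return []
    widths, _, _, _ = signal.peak_widths(detrended, peaks, rel_height=0.5)
    _, _, onset_ips, _ = signal.peak_widths(detrended, peaks, rel_height=0.95)
    transients = []
    for i, p in enumerate(peaks):
        onset_idx = min(int(np.floor(onset_ips[i])), int(p))
        transients.append(
            Transient(
                onset_s=float(trace.time_s[onset_idx]),
                peak_s=float(trace.time_s[p]),
                amplitude=float(detrended[p] - 1.0),
                duration_s=float(widths[i] * dt),
            )
        )
    return transients


def classify_trace(
    trace: CalciumTrace,
    plateau_multiple: float = 2.0,
    plateau_fraction: float = 0.5,
    min_prominence: float = 0.2,
    sd_multiplier: float = 2.0,
) -> TraceClassification:
    """Three-way trace taxonomy.

    ``death_signature``: at least ``plateau_fraction`` of the window sits at
    or above ``plateau_multiple`` times baseline and the trace never returns
    to baseline by the end.  ``responder``: at least one detected transient.
    Otherwise ``non_responder``.  Invalid traces come back ``unclassified``
    with the reason in the features.
    """
    if trace.normalized is None:
        trace = normalize_trace(trace)
    if not trace.valid:
        return TraceClassification(
            label="unclassified", features={"reason": trace.invalid_reason}
        )
    norm = trace.normalized
    above = norm >= plateau_multiple
    frac_above = float(above.mean())
    tail = norm[-BASELINE_FRAMES:]
    no_return = bool(np.mean(tail) >= plateau_multiple)
    transients = detect_transients(trace, min_prominence, sd_multiplier)

    features = {
        "baseline_f0": trace.f0,
        "plateau_fraction": frac_above,
        "no_return": no_return,
        "peak_amplitude": max((t.amplitude for t in transients), default=float(norm.max() - 1.0)),
        "peak_time_s": (
            max(transients, key=lambda t: t.amplitude).peak_s
            if transients
            else float(trace.time_s[int(np.argmax(norm))])
        ),
        "peak_duration_s": max((t.duration_s for t in transients), default=0.0),
        "n_transients": len(transients),
    }
    if frac_above >= plateau_fraction and no_return:
        label = "death_signature"
    elif transients:
        label = "responder"
    else:
        label = "non_responder"
    return TraceClassification(label=label, features=features, transients=transients)


def classify_frame(
    traces: pd.DataFrame,
    condition: str | None = None,
    **classify_kwargs,
) -> pd.DataFrame:
    """Classify every (trap, cell) trace in a long-form frame.

    ``traces`` needs columns (trap, cell, time_s, intensity); returns one row
    per trace with the label and headline features.
    """
    normalized: list[CalciumTrace] = []
    for (trap, cell), grp in traces.groupby(["trap", "cell"]):
        grp = grp.sort_values("time_s")
        normalized.append(
            normalize_trace(
                time_s=grp.time_s.to_numpy(),
                raw=grp.intensity.to_numpy(),
                trap=int(trap),
                cell=int(cell),
            )
        )
    # population-level baseline: a trace already elevated before its own
    # baseline window (a cell compromised before imaging) has an inflated F0
    # that hides its plateau; re-anchor such traces to the cohort baseline
    valid_f0 = [t.f0 for t in normalized if t.valid]
    pop_f0 = float(np.median(valid_f0)) if len(valid_f0) >= 8 else None
    rows = []
    for tr in normalized:
        if pop_f0 is not None and tr.valid and tr.f0 > 1.5 * pop_f0:
            tr.normalized = tr.raw / pop_f0
        cls = classify_trace(tr, **classify_kwargs)
        trap, cell = tr.trap, tr.cell
        row = {"trap": int(trap), "cell": int(cell), "label": cls.label}
        if condition is not None:
            row["condition"] = condition
        row.update(
            {
                k: cls.features.get(k)
                for k in ("peak_amplitude", "peak_time_s", "peak_duration_s", "plateau_fraction", "n_transients")
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_responses(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-condition response table.

    Death-signature traces are excluded from the responder-fraction
    denominator (compromised effectors are not informative about engagement).
    The discordance rate is the fraction of traps that contain both a
    responder and a non-responder effector.
    """
    if classified.empty:
        raise ValueError("no classified traces")
    frame = classified.copy()
    if "condition" not in frame.columns:
        frame["condition"] = "all"
    rows = []
    for condition, grp in frame.groupby("condition"):
        n = len(grp)
        counts = grp.label.value_counts()
        healthy = grp.loc[grp.label != "death_signature"]
        responder_fraction = (
            float((healthy.label == "responder").mean()) if len(healthy) else np.nan
        )
        by_trap = grp.groupby("trap").label.agg(set)
        discordant = by_trap.map(
            lambda s: "responder" in s and "non_responder" in s
        )
        peaks = grp.loc[grp.label == "responder", "peak_time_s"]
        rows.append(
            {
                "condition": condition,
                "n_traces": n,
                "fraction_responder": counts.get("responder", 0) / n,
                "fraction_non_responder": counts.get("non_responder", 0) / n,
                "fraction_death_signature": counts.get("death_signature", 0) / n,
                "responder_fraction_of_healthy": responder_fraction,
                "peak_time_mean_s": peaks.mean() if len(peaks) else np.nan,
                "peak_time_sd_s": peaks.std(ddof=0) if len(peaks) else np.nan,
                "discordance_rate": float(discordant.mean()) if len(discordant) else 0.0,
            }
        )
    return pd.DataFrame(rows)
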