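"""Per-beat energy metrics.

Cycle segmentation from the ECG, the continuous aortic power curve, the
per-cycle power integral, PV-loop stroke work, conductance volume-gain
calibration, and the derived cardiac-output / mean-pressure / power
summaries.  All energies are in Joules, powers in Watts; channel inputs
are in clinical units and converted internally.

Conventions fixed here: cycles are half-open R-to-R sample intervals;
integrals use the trapezoidal rule including the sample at the closing R
(so a constant integrand over a 1 s span integrates to exactly 1 s worth);
stroke work is the absolute shoelace area of the sampled (V, P) polygon,
which makes it invariant to the traversal direction and the starting
point within the cycle.  The power curve is NOT floored at zero: any
small negative diastolic flow is integrated as-is.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import CalibrationError, SegmentationError
from .signal_io import BEAT_COLUMNS, WaveformRecord, to_si

#: Minimum distance between detected R peaks (seconds).
REFRACTORY_S = 0.200


@dataclasses.dataclass(frozen=True)
class CycleSpan:
    """Half-open sample interval [start, end) covering one cardiac cycle."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def duration(self, fs: float) -> float:
        return len(self) / fs


@dataclasses.dataclass(frozen=True)
class AlphaFactor:
    """Conductance volume gain estimated once per animal from baseline."""

    alpha: float
    n_cycles_used: int
    source_condition: str = "baseline"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise CalibrationError(f"alpha must be > 0, got {self.alpha}")


IDENTITY_ALPHA = AlphaFactor(alpha=1.0, n_cycles_used=0, source_condition="none")


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect R spikes in the (synthetic) ECG channel.

    Peaks must exceed 40% of the signal range above baseline (median) and
    respect a 200 ms refractory period.  Returns strictly increasing
    sample indices.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < fs:
        raise SegmentationError("ECG shorter than 1 s; cannot segment")
    baseline = np.median(ecg)
    amp = np.max(ecg) - baseline
    if amp <= 0:
        raise SegmentationError("flat ECG: no peaks found")
    height = baseline + 0.4 * amp
    distance = max(1, int(round(REFRACTORY_S * fs)))
    peaks, _ = find_peaks(ecg, height=height, distance=distance)
    if len(peaks) == 0:
        raise SegmentationError("no R peaks found")
    return peaks.astype(int)


def segment_cycles(record: WaveformRecord, r_peaks: Sequence[int]) -> list[CycleSpan]:
    """One half-open span per consecutive R-peak pair.

    The partial cycles before the first and after the last peak are
    discarded.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 2:
        raise SegmentationError(f"need >= 2 R peaks to segment, got {len(r_peaks)}")
    if np.any(np.diff(r_peaks) <= 0):
        raise SegmentationError("R peaks must be strictly increasing")
    if r_peaks[0] < 0 or r_peaks[-1] > record.n_samples:
        raise SegmentationError("R peaks outside record")
    return [CycleSpan(int(a), int(b)) for a, b in zip(r_peaks[:-1], r_peaks[1:])]


def power_curve(p_ao: np.ndarray, q_ao: np.ndarray) -> np.ndarray:
    """Instantaneous hydraulic power (W) from aortic pressure and flow.

    ``PWR[i] = p_ao[i] [Pa] * q_ao[i] [m^3/s]`` with inputs in mmHg and
    L/min.
    """
    p_ao = np.asarray(p_ao, dtype=float)
    q_ao = np.asarray(q_ao, dtype=float)
    if p_ao.shape != q_ao.shape:
        raise ValueError(f"shape mismatch: p_ao {p_ao.shape} vs q_ao {q_ao.shape}")
    return to_si(p_ao, "mmHg") * to_si(q_ao, "L/min")


def _span_slice(series: np.ndarray, span: CycleSpan, closed: bool) -> np.ndarray:
    # include the closing sample when available so the trapezoid covers
    # the full span duration
    if span.end > len(series):
        raise ValueError(f"span [{span.start}, {span.end}) exceeds series length {len(series)}")
    stop = min(span.end + 1, len(series)) if closed else span.end
    return series[span.start : stop]


def pwr_integral(pwr: np.ndarray, span: CycleSpan, fs: float) -> float:
    """Trapezoidal time integral (J) of the power curve over one cycle."""
    pwr = np.asarray(pwr, dtype=float)
    seg = _span_slice(pwr, span, closed=True)
    if len(seg) < 2:
        raise ValueError("span too short to integrate")
    return float(np.trapezoid(seg, dx=1.0 / fs))


def stroke_work(p_lv: np.ndarray, v_lv: np.ndarray, span: CycleSpan) -> float:
    """PV-loop area (J): absolute shoelace area of the (V, P) polygon."""
    p = to_si(np.asarray(p_lv, dtype=float)[span.start : span.end], "mmHg")
    v = to_si(np.asarray(v_lv, dtype=float)[span.start : span.end], "mL")
    if len(p) < 3:
        raise ValueError(f"degenerate span (<3 points): [{span.start}, {span.end})")
    return float(0.5 * abs(np.dot(v, np.roll(p, -1)) - np.dot(np.roll(v, -1), p)))


def stroke_volume_from_flow(q_ao: np.ndarray, span: CycleSpan, fs: float) -> float:
    """Stroke volume (mL) as the time integral of aortic flow over a cycle."""
    q_mls = np.asarray(q_ao, dtype=float) / 0.06  # L/min -> mL/s
    seg = _span_slice(q_mls, span, closed=True)
    return float(np.trapezoid(seg, dx=1.0 / fs))


def stroke_volume_from_conductance(v_lv: np.ndarray, span: CycleSpan) -> float:
    """Stroke volume (mL) from the volume channel: max minus min over the
    cycle.  Offset-invariant but scales with the conductance gain."""
    seg = np.asarray(v_lv, dtype=float)[span.start : span.end]
    return float(np.max(seg) - np.min(seg))


def alpha_calibration(
    baseline_cycles: Sequence[tuple[float, float]],
    source_condition: str = "baseline",
) -> AlphaFactor:
    """Estimate the conductance gain from paired baseline stroke volumes.

    ``alpha = mean(SV_conductance) / mean(SV_flowprobe)``; the calibrated
    volume channel is ``v_raw / alpha``.  Computed once per animal, from
    baseline measurements only.
    """
    if len(baseline_cycles) == 0:
        raise CalibrationError("need at least one baseline cycle for calibration")
    sv_cond = np.array([c for c, _ in baseline_cycles], dtype=float)
    sv_flow = np.array([f for _, f in baseline_cycles], dtype=float)
    if np.any(sv_cond <= 0) or np.any(sv_flow <= 0):
        raise CalibrationError("nonpositive stroke volume in calibration cycles")
    return AlphaFactor(
        alpha=float(np.mean(sv_cond) / np.mean(sv_flow)),
        n_cycles_used=len(baseline_cycles),
        source_condition=source_condition,
    )


def apply_alpha(record: WaveformRecord, alpha: AlphaFactor) -> WaveformRecord:
    """Record with the volume channel divided by the calibrated gain."""
    return record.replace(v_lv=record.v_lv / alpha.alpha)


def beat_summary(
    record: WaveformRecord,
    spans: Sequence[CycleSpan],
    alpha: AlphaFactor = IDENTITY_ALPHA,
) -> pd.DataFrame:
    """One beat-table row per cycle span.

    Stroke work uses the alpha-calibrated volume channel; the power
    integral never touches volume.  CO is per-beat stroke volume times
    that beat's heart rate; CPO is mean aortic pressure times CO, in
    Watts.
    """
    if len(spans) == 0:
        raise ValueError("no cycle spans given")
    meta = record.meta
    v_cal = record.v_lv / alpha.alpha
    pwr = power_curve(record.p_ao, record.q_ao)
    rows = []
    for k, span in enumerate(spans):
        duration = span.duration(record.fs)
        sv = stroke_volume_from_flow(record.q_ao, span, record.fs)
        hr = 60.0 / duration
        co = sv * hr / 1000.0  # mL/beat * beats/min -> L/min
        map_mmhg = float(np.mean(record.p_ao[span.start : span.end]))
        rows.append(
            {
                "animal_id": meta.get("animal_id", ""),
                "condition": meta.get("condition", ""),
                "measurement_index": meta.get("measurement_index", 0),
                "cycle_index": k,
                "sw_J": stroke_work(record.p_lv, v_cal, span),
                "pwr_integral_J": pwr_integral(pwr, span, record.fs),
                "sv_mL": sv,
                "co_Lmin": co,
                "map_mmHg": map_mmhg,
                "cpo_W": to_si(map_mmhg, "mmHg") * to_si(co, "L/min"),
            }
        )
    return pd.DataFrame(rows, columns=BEAT_COLUMNS)


def oscillatory_fraction(record: WaveformRecord, spans: Sequence[CycleSpan]) -> float:
    """Fraction of total hydraulic power that is oscillatory.

    ``f = 1 - steady_power / total_power`` where steady power is mean
    pressure times mean flow and total power is the cycle-averaged power
    integral, both over the given spans.  Tiny negative values are
    clipped to 0.
    """
    if len(spans) == 0:
        raise ValueError("no cycle spans given")
    lo, hi = spans[0].start, spans[-1].end
    p_si = to_si(record.p_ao[lo:hi], "mmHg")
    q_si = to_si(record.q_ao[lo:hi], "L/min")
    steady = float(np.mean(p_si)) * float(np.mean(q_si))
    pwr = power_curve(record.p_ao, record.q_ao)
    totals = [pwr_integral(pwr, s, record.fs) / s.duration(record.fs) for s in spans]
    total = float(np.mean(totals))
    if total <= 0:
        raise ValueError("zero or negative total power; oscillatory fraction undefined")
    return max(0.0, 1.0 - steady / total)


def segment_record(record: WaveformRecord) -> list[CycleSpan]:
    """Convenience: R-peak detection followed by cycle segmentation."""
    return segment_cycles(record, detect_r_peaks(record.ecg, record.fs))
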