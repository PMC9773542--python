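"""Calcium-transient kinetics from GCaMP fluorescence traces.

For each detected transient the module derives the four variable families
used to phenotype organoid electrophysiology:

1. calcium transient duration (CTD, s) — onset to end, with onset/end at a
   configurable fraction (default 10 %) of the peak amplitude above the
   rolling baseline;
2. peak intensity (a.u.) — trace minus baseline at the peak;
3. depolarization duration and speed — onset-to-peak time and mean rate of
   fluorescence rise (amplitude / upstroke duration);
4. repolarization 30/60/90 (s) — time from the peak until the signal has
   decayed by 30/60/90 % of the amplitude, linearly interpolated between
   samples (APD30/60/90-style).

Per-recording means of these metrics (the ``*_M`` summary variables) and the
mean beat-to-beat duration are reported by :func:`summarize_transients`.
The measurement window defaults to the first 30 s of a recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter
from scipy.signal import find_peaks

from .io import CalciumTrace

__all__ = [
    "TransientConfig",
    "TransientEvent",
    "TransientSummary",
    "estimate_baseline",
    "detect_transients",
    "transient_metrics",
    "summarize_transients",
    "analyze_trace",
]


@dataclass(frozen=True)
class TransientConfig:
    """Knobs of baseline estimation, peak detection and per-event metrics."""

    smooth_window: int = 3            # centred moving average, samples
    baseline_window_s: float = 10.0   # rolling window; >= 5x a typical transient
    baseline_percentile: float = 10.0
    min_prominence_frac: float = 0.2  # of the max baseline-subtracted amplitude
    min_interval_s: float = 0.2
    onset_frac: float = 0.1           # amplitude fraction defining transient onset
    end_frac: float = 0.1             # amplitude fraction defining transient end
    window_s: Optional[float] = 30.0  # analysis window from t=0; None = full trace


@dataclass(frozen=True)
class TransientEvent:
    """Kinetics of one calcium transient (NaN where truncated/undefined)."""

    onset_time: float
    peak_time: float
    end_time: float
    peak_intensity: float             # a.u. above baseline
    depolarization_duration: float    # s
    depolarization_speed: float       # a.u./s (amplitude / upstroke duration)
    ctd: float                        # s, end - onset
    repol30: float
    repol60: float
    repol90: float
    beat_to_beat: float = float("nan")  # s to next peak; NaN for the last event


_METRIC_FIELDS = ("peak_intensity", "depolarization_duration", "depolarization_speed",
                  "ctd", "repol30", "repol60", "repol90", "beat_to_beat")


@dataclass(frozen=True)
class TransientSummary:
    """Per-recording means (the ``*_M`` variables) over valid transients."""

    n_transients: int
    peak_intensity_m: float
    depolarization_duration_m: float
    depolarization_speed_m: float
    ctd_m: float
    repol30_m: float
    repol60_m: float
    repol90_m: float
    beat_to_beat_m: float


def estimate_baseline(trace: CalciumTrace, *, window_s: float = 10.0,
                      percentile: float = 10.0) -> np.ndarray:
    """Rolling low-percentile baseline, edge-padded.

    A window longer than the trace falls back to the global percentile with
    a warning.
    """
    f = trace.fluorescence
    if len(trace) < 2:
        return np.full_like(f, np.percentile(f, percentile))
    dt = trace.frame_interval
    size = int(round(window_s / dt))
    if size >= f.size:
        warnings.warn("baseline window exceeds trace duration; using global percentile")
        return np.full_like(f, np.percentile(f, percentile))
    size = max(size, 1)
    return percentile_filter(f, percentile, size=size, mode="nearest")


def detect_transients(trace: CalciumTrace, baseline: np.ndarray,
                      config: TransientConfig = TransientConfig()) -> np.ndarray:
    """Peak indices of baseline-subtracted transients.

    Peaks are local maxima of (trace - baseline) with prominence at least
    ``min_prominence_frac`` of the maximum amplitude, spaced at least
    ``min_interval_s`` apart. An empty result is valid.
    """
    rel = trace.fluorescence - np.asarray(baseline, dtype=float)
    amp_max = float(rel.max(initial=0.0))
    if amp_max <= 0 or np.ptp(rel) == 0:
        return np.array([], dtype=int)
    dt = trace.frame_interval
    distance = max(1, int(round(config.min_interval_s / dt)))
    peaks, _ = find_peaks(rel, prominence=config.min_prominence_frac * amp_max,
                          distance=distance)
    return peaks


def _cross_time(t: np.ndarray, rel: np.ndarray, i: int, j: int, level: float) -> float:
    """Linearly interpolated time where rel crosses ``level`` between samples i, j."""
    if rel[j] == rel[i]:
        return float(t[j])
    frac = (level - rel[i]) / (rel[j] - rel[i])
    return float(t[i] + frac * (t[j] - t[i]))


def transient_metrics(trace: CalciumTrace, baseline: np.ndarray, peak_idx: int,
                      config: TransientConfig = TransientConfig(),
                      *, next_peak_idx: Optional[int] = None) -> TransientEvent:
    """Kinetic metrics of the transient peaking at sample ``peak_idx``.

    Onset is the last pre-peak crossing of ``onset_frac * amplitude`` above
    baseline; end is the first post-peak decay to ``end_frac * amplitude``.
    Repolarization-x is the interpolated time from the peak until the signal
    has decayed by x % of the amplitude. Decays truncated by the trace end
    (or masked by the following transient) are NaN.
    """
    t = trace.time
    rel = trace.fluorescence - np.asarray(baseline, dtype=float)
    amp = float(rel[peak_idx])
    if amp <= 0:
        raise ValueError("peak amplitude must be positive")
    stop = next_peak_idx if next_peak_idx is not None else rel.size

    # onset: walk back to the last crossing of onset_frac * amp
    onset_level = config.onset_frac * amp
    onset_time = float(t[0])
    for i in range(peak_idx - 1, -1, -1):
        if rel[i] <= onset_level:
            onset_time = _cross_time(t, rel, i, i + 1, onset_level)
            break

    def decay_time(level: float) -> float:
        for j in range(peak_idx + 1, stop):
            if rel[j] <= level:
                return _cross_time(t, rel, j - 1, j, level)
        return float("nan")

    end_time = decay_time(config.end_frac * amp)
    peak_time = float(t[peak_idx])
    repol = {x: decay_time((1 - x / 100.0) * amp) for x in (30, 60, 90)}
    depol = peak_time - onset_time
    return TransientEvent(
        onset_time=onset_time,
        peak_time=peak_time,
        end_time=end_time,
        peak_intensity=amp,
        depolarization_duration=depol,
        depolarization_speed=amp / depol if depol > 0 else float("nan"),
        ctd=end_time - onset_time,
        repol30=repol[30] - peak_time if np.isfinite(repol[30]) else float("nan"),
        repol60=repol[60] - peak_time if np.isfinite(repol[60]) else float("nan"),
        repol90=repol[90] - peak_time if np.isfinite(repol[90]) else float("nan"),
    )


def summarize_transients(events: Sequence[TransientEvent]) -> TransientSummary:
    """Means of each metric over valid (non-NaN) events.

    Zero events yields an all-NaN summary with ``n_transients = 0``.
    """
    if not events:
        return TransientSummary(0, *([float("nan")] * 8))

    def mean_of(name: str) -> float:
        vals = np.asarray([getattr(e, name) for e in events], dtype=float)
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    return TransientSummary(
        n_transients=len(events),
        peak_intensity_m=mean_of("peak_intensity"),
        depolarization_duration_m=mean_of("depolarization_duration"),
        depolarization_speed_m=mean_of("depolarization_speed"),
        ctd_m=mean_of("ctd"),
        repol30_m=mean_of("repol30"),
        repol60_m=mean_of("repol60"),
        repol90_m=mean_of("repol90"),
        beat_to_beat_m=mean_of("beat_to_beat"),
    )


def analyze_trace(trace: CalciumTrace, config: TransientConfig = TransientConfig()):
    """Full per-recording analysis: (events, summary).

    Restricts to the configured analysis window (default the first 30 s).
    Baseline estimation and peak detection run on a lightly smoothed copy
    (suppressing spurious noise peaks); the per-event metrics are measured on
    the raw trace, whose steep crossings are less biased by smoothing.
    ``beat_to_beat`` is the time to the next detected peak.
    """
    if config.window_s is not None and trace.time[-1] > config.window_s:
        sel = trace.time <= config.window_s
        trace = CalciumTrace(trace.time[sel], trace.fluorescence[sel])
    if config.smooth_window > 1:
        w = config.smooth_window
        padded = np.pad(trace.fluorescence, w // 2, mode="edge")
        sm = np.convolve(padded, np.ones(w) / w, mode="valid")[: len(trace)]
        smoothed = CalciumTrace(trace.time, sm)
    else:
        smoothed = trace
    baseline = estimate_baseline(smoothed, window_s=config.baseline_window_s,
                                 percentile=config.baseline_percentile)
    peaks = detect_transients(smoothed, baseline, config)
    events: List[TransientEvent] = []
    for j, p in enumerate(peaks):
        nxt = int(peaks[j + 1]) if j + 1 < len(peaks) else None
        ev = transient_metrics(trace, baseline, int(p), config, next_peak_idx=nxt)
        b2b = float(trace.time[nxt] - trace.time[p]) if nxt is not None else float("nan")
        events.append(TransientEvent(**{**ev.__dict__, "beat_to_beat": b2b}))
    return events, summarize_transients(events)


def events_to_frame(events: Sequence[TransientEvent]) -> pd.DataFrame:
    """Per-event table (peak_s, amplitude_au, depol_s, ... b2b_s)."""
    return pd.DataFrame([{
        "peak_s": e.peak_time,
        "amplitude_au": e.peak_intensity,
        "depol_s": e.depolarization_duration,
        "depol_speed_au_per_s": e.depolarization_speed,
        "ctd_s": e.ctd,
        "repol30_s": e.repol30,
        "repol60_s": e.repol60,
        "repol90_s": e.repol90,
        "b2b_s": e.beat_to_beat,
    } for e in events])
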