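"""Contraction phenotypes from area/wall-thickness time series.

Beat events are located on the (smoothed) outer-area trace as the extrema
bracketed by sign changes of the first-order difference: peak systole is a
local *minimum* of projected area (the organoid contracts), and each systole
is paired with the preceding area maximum (maximal relaxation, diastole).
Interval statistics are invariant to the minima-vs-maxima choice for a
periodic trace; the convention is recorded in the outputs.

Derived phenotypes:

* contraction rate — mean of the systole-to-systole intervals, also as
  beats/min (60 / interval mean);
* rhythm variability — sample standard deviation of the intervals;
* fractional shortening (FS) — per beat, the percentage change of wall
  thickness between the paired diastole and systole,
  ``FS = 100 * (T_sys - T_dia) / T_dia`` (positive when the wall thickens at
  systole); a chamber-diameter convention is available via config;
* week-over-week wall thickness normalized to each organoid's week 0.

Undefined metrics are explicit NaN, never silent zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .segment import AreaTrace

__all__ = [
    "BeatDetectionConfig",
    "BeatSeries",
    "ContractionSummary",
    "detect_beats",
    "beat_statistics",
    "fractional_shortening",
    "weekly_normalize",
    "summarize_contraction",
]

_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class BeatDetectionConfig:
    """Beat-detector knobs (stamped into every output).

    ``min_prominence_frac`` is relative to the trace's max-min range;
    ``min_interval_s`` suppresses double-counting within one contraction.
    ``fs_convention`` selects ``"wall_thickness"`` (default; positive FS =
    systolic thickening) or ``"chamber_diameter"`` (echocardiography-style
    shortening of the inner equivalent diameter).
    """

    smooth_window: int = 3
    min_prominence_frac: float = 0.2
    min_interval_s: float = 0.2
    fs_convention: str = "wall_thickness"


@dataclass(frozen=True)
class BeatSeries:
    """Detected contraction events of one recording.

    ``systole_times`` are the moments of maximal contraction (area minima);
    ``diastole_times[k]`` is the preceding area maximum paired with systole
    ``k``; ``intervals`` are successive systole-to-systole differences.
    """

    systole_times: np.ndarray
    diastole_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.systole_times, dtype=float)
        d = np.asarray(self.diastole_times, dtype=float)
        if s.size != d.size:
            raise ValueError("each systole needs exactly one paired diastole")
        if s.size and (np.any(np.diff(s) <= 0) or np.any(d >= s)):
            raise ValueError("times must increase and diastoles precede systoles")
        object.__setattr__(self, "systole_times", s)
        object.__setattr__(self, "diastole_times", d)
        object.__setattr__(self, "intervals", np.asarray(self.intervals, dtype=float))

    @property
    def n_beats(self) -> int:
        return int(self.systole_times.size)


@dataclass(frozen=True)
class ContractionSummary:
    """Per-recording contraction phenotype (NaN where undefined)."""

    n_beats: int
    interval_mean: float          # s
    interval_sd: float            # s, sample SD (n-1)
    contraction_frequency: float  # beats/min = 60 / interval_mean
    fs_per_beat: np.ndarray       # %
    fs_mean: float                # %
    diastolic_thickness: float    # px, mean over beats
    systolic_thickness: float     # px, mean over beats
    config: BeatDetectionConfig = field(default_factory=BeatDetectionConfig)


def _check_uniform(time: np.ndarray) -> float:
    dt = np.diff(time)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError("need a strictly increasing time grid")
    if np.ptp(dt) > _GRID_RTOL * dt[0]:
        raise ValueError("beat detection requires a uniform time grid")
    return float(dt[0])


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    pad = window // 2
    padded = np.pad(values.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: values.size]


def detect_beats(time: np.ndarray, values: np.ndarray,
                 config: BeatDetectionConfig = BeatDetectionConfig()) -> BeatSeries:
    """Detect contraction events on an area-vs-time trace.

    The trace is smoothed by a centred moving average; candidate systoles are
    the negative-to-positive zero crossings of the first-order difference
    (area minima) with prominence at least ``min_prominence_frac`` of the
    trace range and spacing at least ``min_interval_s``. A constant trace
    yields an empty series.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if time.size != values.size or time.size < 3:
        raise ValueError("need >= 3 samples of matching length")
    dt = _check_uniform(time)

    sm = _smooth(values, config.smooth_window)
    vrange = float(np.ptp(sm))
    if vrange == 0:
        return BeatSeries(np.array([]), np.array([]), np.array([]))
    distance = max(1, int(round(config.min_interval_s / dt)))
    minima, _ = find_peaks(-sm, prominence=config.min_prominence_frac * vrange,
                           distance=distance)
    if minima.size == 0:
        return BeatSeries(np.array([]), np.array([]), np.array([]))

    diastole_idx = np.empty(minima.size, dtype=int)
    prev = 0
    for j, m in enumerate(minima):
        seg = sm[prev:m]
        diastole_idx[j] = prev + int(np.argmax(seg)) if seg.size else max(m - 1, 0)
        prev = m
    systole_times = time[minima]
    return BeatSeries(systole_times, time[diastole_idx], np.diff(systole_times))


def beat_statistics(beats: BeatSeries) -> Tuple[float, float, float]:
    """(interval mean s, sample SD s, contraction frequency beats/min).

    With fewer than two systoles the metrics are undefined and returned as
    NaN; SD additionally needs at least two intervals.
    """
    iv = beats.intervals
    if iv.size < 1:
        return float("nan"), float("nan"), float("nan")
    mean = float(iv.mean())
    sd = float(iv.std(ddof=1)) if iv.size > 1 else float("nan")
    return mean, sd, 60.0 / mean


def fractional_shortening(
    time: np.ndarray,
    thickness: np.ndarray,
    beats: BeatSeries,
    *,
    inner_area: Optional[np.ndarray] = None,
    convention: str = "wall_thickness",
) -> Tuple[np.ndarray, float]:
    """Per-beat and mean fractional shortening (%).

    Default convention: percentage change of wall thickness between the
    paired diastole and systole, positive when the wall thickens during
    contraction. With ``convention="chamber_diameter"`` (requires
    ``inner_area``), FS is instead the relative reduction of the chamber's
    equivalent diameter, as in echocardiography. Beats with non-positive
    diastolic reference are excluded with a warning.
    """
    if beats.n_beats == 0:
        return np.array([]), float("nan")
    time = np.asarray(time, dtype=float)
    if convention == "chamber_diameter":
        if inner_area is None:
            raise ValueError("chamber_diameter convention requires inner_area")
        ref = 2.0 * np.sqrt(np.asarray(inner_area, dtype=float) / np.pi)
        dia = np.interp(beats.diastole_times, time, ref)
        sys_ = np.interp(beats.systole_times, time, ref)
        fs = 100.0 * (dia - sys_) / dia
        denom = dia
    elif convention == "wall_thickness":
        th = np.asarray(thickness, dtype=float)
        t_dia = np.interp(beats.diastole_times, time, th)
        t_sys = np.interp(beats.systole_times, time, th)
        with np.errstate(invalid="ignore", divide="ignore"):
            fs = 100.0 * (t_sys - t_dia) / t_dia
        denom = t_dia
    else:
        raise ValueError(f"unknown FS convention: {convention!r}")
    bad = ~(denom > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} beat(s) excluded from FS: non-positive "
                      "diastolic reference")
        fs = fs[~bad]
    mean = float(fs.mean()) if fs.size else float("nan")
    return fs, mean


def summarize_contraction(trace: AreaTrace,
                          config: BeatDetectionConfig = BeatDetectionConfig()) -> ContractionSummary:
    """Beat detection + statistics + FS for one segmented recording."""
    beats = detect_beats(trace.time, trace.outer_area, config)
    mean, sd, freq = beat_statistics(beats)
    fs, fs_mean = fractional_shortening(
        trace.time, trace.wall_thickness, beats,
        inner_area=trace.inner_area, convention=config.fs_convention)
    if beats.n_beats:
        t_dia = float(np.interp(beats.diastole_times, trace.time, trace.wall_thickness).mean())
        t_sys = float(np.interp(beats.systole_times, trace.time, trace.wall_thickness).mean())
    else:
        t_dia = t_sys = float("nan")
    return ContractionSummary(
        n_beats=beats.n_beats, interval_mean=mean, interval_sd=sd,
        contraction_frequency=freq, fs_per_beat=fs, fs_mean=fs_mean,
        diastolic_thickness=t_dia, systolic_thickness=t_sys, config=config,
    )


def weekly_normalize(metrics: pd.DataFrame, *, value: str = "wall_thickness",
                     week0_label=None) -> pd.DataFrame:
    """Fold change of a per-organoid metric relative to its week-0 value.

    ``metrics`` needs columns ``organoid``, ``week`` and ``value``. Week 0 is
    the smallest week label unless ``week0_label`` is given. Organoids
    lacking a week-0 record are excluded with a warning. Adds a
    ``{value}_fold`` column; week-0 rows get fold change 1.
    """
    required = {"organoid", "week", value}
    if not required <= set(metrics.columns):
        raise ValueError(f"metrics must have columns {sorted(required)}")
    week0 = week0_label if week0_label is not None else metrics["week"].min()
    base = metrics.loc[metrics["week"] == week0].set_index("organoid")[value]
    missing = sorted(set(metrics["organoid"]) - set(base.index))
    if missing:
        warnings.warn(f"excluded organoids without week-{week0} record: {missing}")
    out = metrics[metrics["organoid"].isin(base.index)].copy()
    out[f"{value}_fold"] = out[value] / out["organoid"].map(base).to_numpy()
    return out
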