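"""Synthetic beating-organoid videos, calcium traces and toy count matrices.

Every generator returns its inputs' consequences as explicit ground truth so
the segmentation, kinetics and QC stages can be validated against known
answers. The organoid is rendered as a concentric annulus — a bright chamber
core surrounded by a darker wall on a dark background — because the analytic
areas (pi*R^2) give exact oracles for the segmentation stage. Real chambered
organoids are irregular; an optional low-order harmonic boundary perturbation
is available for robustness experiments.

Geometry and waveform
---------------------
The inner (chamber) radius pulses between its diastolic value ``R_inner_dia``
and a systolic value ``R_inner_dia * (1 - pulsation_fraction)``. Within each
beat cycle the radius falls along a half-cosine over ``contraction_rise_
fraction`` of the cycle (contraction) and recovers along a half-cosine over
the remainder (relaxation), so contraction is faster than relaxation, as in
real cardiac motion. A fraction ``outer_coupling`` of the inner-radius
excursion is transmitted to the outer radius, so at peak systole the wall is
*thicker* by ``(1 - outer_coupling) * pulsation_fraction * R_inner_dia``.
Beat-to-beat intervals are drawn from a normal distribution truncated below
at ``0.2 * mean`` to prevent non-physical cycle overlap.

Calcium transients follow the standard two-exponential kinetic
``(1 - exp(-t/tau_up)) * exp(-t/tau_down)``, scaled to a programmed peak
amplitude, superimposed on a baseline with optional linear drift and
Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy import sparse

from .io import CalciumTrace, FrameStack

__all__ = [
    "OrganoidSimParams",
    "CalciumSimParams",
    "EffectMultipliers",
    "CohortSpec",
    "OrganoidGroundTruth",
    "CalciumGroundTruth",
    "make_annulus_image",
    "make_organoid_video",
    "make_calcium_trace",
    "make_cohort",
    "make_calcium_cohort",
    "make_count_matrix",
    "transient_shape",
    "transient_truth_times",
]

_SEED_STRIDE = 1_000_003  # fixed increment expanding one cohort seed into sub-seeds
_MOD = 2**31

#: the 13 protein-coding human mitochondrial genes, used to name mito features
MITO_GENE_NAMES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrganoidSimParams:
    """Programmable geometry, waveform and imaging noise of one organoid.

    Defaults describe a ~1 Hz spontaneously beating chambered organoid imaged
    for 30 s at 10 frames per second (~300 frames per recording).
    """

    image_size: int = 192
    center: Optional[Tuple[float, float]] = None  # (row, col); default: image centre
    R_outer_dia: float = 70.0          # diastolic outer equivalent radius, px
    R_inner_dia: float = 35.0          # diastolic inner-chamber radius, px
    pulsation_fraction: float = 0.15   # fractional inner-radius reduction at systole
    outer_coupling: float = 0.5        # share of inner excursion seen by outer radius
    beat_interval_mean: float = 1.0    # s
    beat_interval_sd: float = 0.05     # s
    contraction_rise_fraction: float = 0.35  # fraction of cycle spent contracting
    duration: float = 30.0             # s
    frame_interval: float = 0.1        # s
    wall_intensity: float = 120.0
    chamber_intensity: float = 200.0
    background_intensity: float = 40.0
    noise_sd: float = 4.0              # grayscale units
    boundary_harmonic_amp: float = 0.0  # px; low-order harmonic perturbation (robustness)
    boundary_harmonic_order: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.R_inner_dia < self.R_outer_dia):
            raise ValueError("require 0 <= R_inner_dia < R_outer_dia")
        if self.R_outer_dia <= 0:
            raise ValueError("radii must be positive")
        if not (0 <= self.pulsation_fraction < 1):
            raise ValueError("pulsation_fraction must lie in [0, 1)")
        if not (0 <= self.outer_coupling <= 1):
            raise ValueError("outer_coupling must lie in [0, 1]")
        if not (0 < self.contraction_rise_fraction < 1):
            raise ValueError("contraction_rise_fraction must lie in (0, 1)")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")
        if self.beat_interval_sd < 0 or self.beat_interval_mean <= 0:
            raise ValueError("beat interval mean must be > 0 and sd >= 0")
        if not (self.chamber_intensity > self.wall_intensity > self.background_intensity):
            raise ValueError("require chamber > wall > background intensity")


@dataclass(frozen=True)
class CalciumSimParams:
    """Programmable GCaMP transient train.

    Defaults emulate a 1 min recording at 50 Hz of a ~1 Hz spontaneous
    rhythm with a fast upstroke (tau_up) and slower decay (tau_down).
    """

    baseline: float = 100.0       # a.u.
    amplitude: float = 80.0       # a.u. above baseline at the transient peak
    tau_up: float = 0.08          # s
    tau_down: float = 0.25        # s
    beat_interval_mean: float = 1.0
    beat_interval_sd: float = 0.05
    duration: float = 60.0
    frame_interval: float = 0.02
    drift_slope: float = 0.0      # a.u./s baseline drift
    noise_sd: float = 2.0         # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0 < self.tau_up < self.tau_down):
            raise ValueError("require 0 < tau_up < tau_down")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")
        if self.beat_interval_sd < 0 or self.beat_interval_mean <= 0:
            raise ValueError("beat interval mean must be > 0 and sd >= 0")


@dataclass(frozen=True)
class OrganoidGroundTruth:
    """Programmed truth accompanying one synthetic video."""

    beat_times: np.ndarray            # systole times, s
    cycle_onsets: np.ndarray          # diastolic cycle-start times, s
    r_inner_dia: float
    r_inner_sys: float
    r_outer_dia: float
    r_outer_sys: float
    fractional_shortening: float      # % thickening of the wall at systole
    interval_mean: float              # of realized systole-to-systole intervals, s
    interval_sd: float                # sample SD (n-1), s
    n_beats: int

    @property
    def wall_thickness_dia(self) -> float:
        return self.r_outer_dia - self.r_inner_dia

    @property
    def wall_thickness_sys(self) -> float:
        return self.r_outer_sys - self.r_inner_sys


@dataclass(frozen=True)
class CalciumGroundTruth:
    """Programmed truth accompanying one synthetic calcium trace."""

    peak_times: np.ndarray
    onset_times: np.ndarray           # transient start times (waveform t=0), s
    amplitude: float
    transient_duration: float         # onset->end at the 10% crossings, s
    depolarization_duration: float    # 10%-crossing to peak, s
    repol30: float
    repol60: float
    repol90: float
    interval_mean: float
    interval_sd: float
    n_transients: int


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def make_annulus_image(
    R_outer: float,
    R_inner: float,
    *,
    image_size: int = 192,
    center: Optional[Tuple[float, float]] = None,
    wall_intensity: float = 120.0,
    chamber_intensity: float = 200.0,
    background_intensity: float = 40.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    boundary_harmonic_amp: float = 0.0,
    boundary_harmonic_order: int = 3,
) -> Tuple[np.ndarray, Dict[str, float]]:
    """Render one annulus frame and return it with the analytic areas.

    Pixels within ``R_inner`` of the centre take the chamber intensity,
    pixels between the radii the wall intensity, the rest the background;
    optional iid Gaussian pixel noise is added on top. The returned dict
    carries the analytic areas ``pi*R^2`` (px^2) of the rendered geometry.
    """
    if not (0 <= R_inner < R_outer):
        raise ValueError("require 0 <= R_inner < R_outer")
    if center is None:
        center = ((image_size - 1) / 2.0, (image_size - 1) / 2.0)
    if R_outer + abs(boundary_harmonic_amp) >= image_size / 2:
        raise ValueError("outer radius exceeds the field of view")
    rows = np.arange(image_size)[:, None] - center[0]
    cols = np.arange(image_size)[None, :] - center[1]
    r = np.hypot(rows, cols)
    if boundary_harmonic_amp:
        theta = np.arctan2(rows, cols)
        r_out = R_outer + boundary_harmonic_amp * np.cos(boundary_harmonic_order * theta)
    else:
        r_out = R_outer
    img = np.full((image_size, image_size), background_intensity, dtype=np.float32)
    img[r <= r_out] = wall_intensity
    img[r <= R_inner] = chamber_intensity
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape).astype(np.float32)
    areas = {
        "outer_area": float(np.pi * R_outer**2),
        "inner_area": float(np.pi * R_inner**2),
    }
    return img, areas


def _draw_beat_onsets(rng: np.random.Generator, mean: float, sd: float, duration: float) -> np.ndarray:
    """Cycle onset times: cumulative truncated-normal intervals covering [0, duration]."""
    onsets = [0.0]
    floor = 0.2 * mean
    while onsets[-1] <= duration:
        iv = rng.normal(mean, sd) if sd > 0 else mean
        while iv < floor:
            iv = rng.normal(mean, sd)
        onsets.append(onsets[-1] + iv)
    return np.asarray(onsets)


def _pulse_profile(times: np.ndarray, onsets: np.ndarray, rise_fraction: float) -> np.ndarray:
    """Waveform in [0, 1]: 0 at diastole, 1 at peak systole, per cycle.

    Half-cosine fall over ``rise_fraction`` of the cycle, half-cosine
    recovery over the remainder. Times outside all cycles sit at diastole.
    """
    w = np.zeros_like(times, dtype=float)
    if len(onsets) < 2:
        return w
    k = np.searchsorted(onsets, times, side="right") - 1
    valid = (k >= 0) & (k < len(onsets) - 1)
    kv = k[valid]
    cycle_len = onsets[kv + 1] - onsets[kv]
    phase = (times[valid] - onsets[kv]) / cycle_len
    contracting = phase < rise_fraction
    wv = np.empty(phase.shape)
    wv[contracting] = 0.5 * (1 - np.cos(np.pi * phase[contracting] / rise_fraction))
    rel = (phase[~contracting] - rise_fraction) / (1 - rise_fraction)
    wv[~contracting] = 0.5 * (1 + np.cos(np.pi * rel))
    w[valid] = wv
    return w


def make_organoid_video(params: OrganoidSimParams) -> Tuple[FrameStack, OrganoidGroundTruth]:
    """Render a pulsating-annulus video with its programmed ground truth.

    Deterministic under a fixed seed. Ground-truth beat times are the peak
    systoles (inner/outer area minima, wall-thickness maxima); the truth
    fractional shortening follows the wall-thickness definition
    ``100 * (T_sys - T_dia) / T_dia`` exactly.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_frames = int(np.floor(p.duration / p.frame_interval + 1e-9))
    times = np.arange(n_frames) * p.frame_interval

    onsets = _draw_beat_onsets(rng, p.beat_interval_mean, p.beat_interval_sd, p.duration)
    # only complete cycles are animated (the organoid rests at diastole after
    # the last one), so every programmed systole is observable in the frames;
    # systole of cycle k sits rise_fraction of the way through the cycle
    onsets = onsets[:-1]
    beat_times = onsets[:-1] + p.contraction_rise_fraction * np.diff(onsets)
    if beat_times.size == 0:
        warnings.warn("duration too short for one beat; zero-beat ground truth")

    if p.pulsation_fraction > 0:
        w = _pulse_profile(times, onsets, p.contraction_rise_fraction)
    else:
        w = np.zeros_like(times)
    dR = p.pulsation_fraction * p.R_inner_dia
    r_inner = p.R_inner_dia - dR * w
    r_outer = p.R_outer_dia - p.outer_coupling * dR * w

    frames = np.empty((n_frames, p.image_size, p.image_size), dtype=np.float32)
    for k in range(n_frames):
        frames[k], _ = make_annulus_image(
            r_outer[k], r_inner[k],
            image_size=p.image_size, center=p.center,
            wall_intensity=p.wall_intensity, chamber_intensity=p.chamber_intensity,
            background_intensity=p.background_intensity,
            noise_sd=p.noise_sd, rng=rng,
            boundary_harmonic_amp=p.boundary_harmonic_amp,
            boundary_harmonic_order=p.boundary_harmonic_order,
        )

    r_inner_sys = p.R_inner_dia - dR
    r_outer_sys = p.R_outer_dia - p.outer_coupling * dR
    t_dia = p.R_outer_dia - p.R_inner_dia
    t_sys = r_outer_sys - r_inner_sys
    fs = 100.0 * (t_sys - t_dia) / t_dia
    intervals = np.diff(beat_times)
    truth = OrganoidGroundTruth(
        beat_times=beat_times,
        cycle_onsets=onsets,
        r_inner_dia=p.R_inner_dia,
        r_inner_sys=r_inner_sys,
        r_outer_dia=p.R_outer_dia,
        r_outer_sys=r_outer_sys,
        fractional_shortening=fs,
        interval_mean=float(intervals.mean()) if intervals.size else float("nan"),
        interval_sd=float(intervals.std(ddof=1)) if intervals.size > 1 else float("nan"),
        n_beats=int(beat_times.size),
    )
    stack = FrameStack(frames, p.frame_interval, origin=f"synthetic(seed={p.seed})")
    return stack, truth


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

def transient_shape(t: np.ndarray, tau_up: float, tau_down: float) -> np.ndarray:
    """Unnormalized transient kinetic ``(1 - exp(-t/tau_up)) * exp(-t/tau_down)`` for t >= 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (1.0 - np.exp(-t[pos] / tau_up)) * np.exp(-t[pos] / tau_down)
    return out


def transient_truth_times(
    tau_up: float, tau_down: float, *, onset_frac: float = 0.1, end_frac: float = 0.1
) -> Dict[str, float]:
    """Closed-form/root-found kinetics of the noiseless transient waveform.

    Returns peak time (from waveform start), onset/end crossing times at the
    given amplitude fractions, the resulting transient duration and
    depolarization duration, and the repolarization 30/60/90 times (time from
    peak until the waveform has decayed by 30/60/90 % of its peak amplitude).
    """
    tp = tau_up * np.log1p(tau_down / tau_up)
    gmax = float(transient_shape(np.array([tp]), tau_up, tau_down)[0])

    def g(t):  # normalized to peak 1
        return float(transient_shape(np.array([t]), tau_up, tau_down)[0]) / gmax

    t_end_search = tp + 60.0 * tau_down
    onset = brentq(lambda t: g(t) - onset_frac, 0.0, tp, xtol=1e-12) if onset_frac > 0 else 0.0
    end = brentq(lambda t: g(t) - end_frac, tp, t_end_search, xtol=1e-12) if end_frac > 0 else float("inf")
    repol = {
        x: brentq(lambda t: g(t) - (1 - x / 100.0), tp, t_end_search, xtol=1e-12) - tp
        for x in (30, 60, 90)
    }
    return {
        "peak_time": tp,
        "onset_time": onset,
        "end_time": end,
        "transient_duration": end - onset,
        "depolarization_duration": tp - onset,
        "repol30": repol[30],
        "repol60": repol[60],
        "repol90": repol[90],
    }


def make_calcium_trace(params: CalciumSimParams) -> Tuple[CalciumTrace, CalciumGroundTruth]:
    """Synthesize a GCaMP-style transient train with programmed ground truth."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(np.floor(p.duration / p.frame_interval + 1e-9))
    t = np.arange(n) * p.frame_interval

    kin = transient_truth_times(p.tau_up, p.tau_down)
    tp = kin["peak_time"]
    gmax = float(transient_shape(np.array([tp]), p.tau_up, p.tau_down)[0])

    if p.amplitude > 0:
        onsets = _draw_beat_onsets(rng, p.beat_interval_mean, p.beat_interval_sd, p.duration)
        # first transient starts one interval in, so its rise is fully sampled
        onsets = onsets[1:]
        onsets = onsets[onsets + tp < p.duration]
    else:
        onsets = np.array([])

    f = np.full(n, p.baseline, dtype=float) + p.drift_slope * t
    for o in onsets:
        f += p.amplitude * transient_shape(t - o, p.tau_up, p.tau_down) / gmax
    if p.noise_sd > 0:
        f = f + rng.normal(0.0, p.noise_sd, n)

    peaks = onsets + tp
    intervals = np.diff(peaks)
    truth = CalciumGroundTruth(
        peak_times=peaks,
        onset_times=onsets,
        amplitude=p.amplitude,
        transient_duration=kin["transient_duration"],
        depolarization_duration=kin["depolarization_duration"],
        repol30=kin["repol30"],
        repol60=kin["repol60"],
        repol90=kin["repol90"],
        interval_mean=float(intervals.mean()) if intervals.size else float("nan"),
        interval_sd=float(intervals.std(ddof=1)) if intervals.size > 1 else float("nan"),
        n_transients=int(peaks.size),
    )
    return CalciumTrace(t, f), truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectMultipliers:
    """Per-week multiplicative effects applied to a base organoid."""

    wall_thickness: float = 1.0   # scales diastolic wall thickness (inner radius shrinks)
    beat_rate: float = 1.0        # scales beats/min (divides the interval mean)
    interval_sd: float = 1.0      # scales rhythm variability
    pulsation: float = 1.0        # scales pulsation_fraction


@dataclass(frozen=True)
class CohortSpec:
    """A labelled multi-week cohort design with programmed effects.

    ``groups`` maps group label -> {week label -> EffectMultipliers}; week
    labels must be identically ordered across groups (e.g. 0..3 emulating a
    3-week treatment time course).
    """

    groups: Mapping[str, Mapping[int, EffectMultipliers]]
    n_per_group: int = 4
    base_params: OrganoidSimParams = field(default_factory=OrganoidSimParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        week_sets = [tuple(weeks.keys()) for weeks in self.groups.values()]
        if any(ws != week_sets[0] for ws in week_sets):
            raise ValueError("all groups must share the same ordered week labels")
        if any(list(ws) != sorted(ws) for ws in week_sets):
            raise ValueError("week labels must be ordered")


def _apply_multipliers(base: OrganoidSimParams, eff: EffectMultipliers, seed: int) -> OrganoidSimParams:
    thickness = (base.R_outer_dia - base.R_inner_dia) * eff.wall_thickness
    r_inner = base.R_outer_dia - thickness
    if r_inner < 0:
        raise ValueError("wall-thickness multiplier exceeds the outer radius")
    return replace(
        base,
        R_inner_dia=r_inner,
        beat_interval_mean=base.beat_interval_mean / eff.beat_rate,
        beat_interval_sd=base.beat_interval_sd * eff.interval_sd,
        pulsation_fraction=min(base.pulsation_fraction * eff.pulsation, 0.95),
        seed=seed,
    )


def _sub_seed(seed: int, k: int) -> int:
    return (seed + k * _SEED_STRIDE) % _MOD


def make_cohort(spec: CohortSpec):
    """Simulate a full video cohort; returns (records, manifest DataFrame).

    Each record is a dict with keys ``group, week, organoid, params, stack,
    truth``. Each organoid keeps the same sub-seed across weeks, so a
    week-over-week change reflects only the programmed effect multipliers.
    """
    records: List[dict] = []
    rows = []
    k = 0
    for group, weeks in spec.groups.items():
        for i in range(spec.n_per_group):
            organoid = f"{group}-{i:02d}"
            org_seed = _sub_seed(spec.seed, k)
            k += 1
            for week, eff in weeks.items():
                params = _apply_multipliers(spec.base_params, eff, org_seed)
                stack, truth = make_organoid_video(params)
                records.append(dict(group=group, week=week, organoid=organoid,
                                    params=params, stack=stack, truth=truth))
                rows.append(dict(
                    group=group, week=week, organoid=organoid, seed=org_seed,
                    true_wall_thickness_dia_px=truth.wall_thickness_dia,
                    true_fs_percent=truth.fractional_shortening,
                    true_interval_mean_s=truth.interval_mean,
                    true_interval_sd_s=truth.interval_sd,
                    true_n_beats=truth.n_beats,
                ))
    return records, pd.DataFrame(rows)


def make_calcium_cohort(
    groups: Mapping[str, float],
    *,
    n_per_group: int = 10,
    base_params: CalciumSimParams = CalciumSimParams(),
    seed: int = 0,
):
    """Simulate calcium-trace groups with a programmed beat-rate multiplier each.

    ``groups`` maps label -> beat-rate multiplier (>1 means faster rhythm,
    i.e. shorter beat-to-beat duration). Returns (records, manifest).
    """
    if not groups:
        raise ValueError("cohort needs at least one group")
    records: List[dict] = []
    rows = []
    k = 0
    for group, rate_mult in groups.items():
        for i in range(n_per_group):
            params = replace(
                base_params,
                beat_interval_mean=base_params.beat_interval_mean / rate_mult,
                seed=_sub_seed(seed, k),
            )
            k += 1
            trace, truth = make_calcium_trace(params)
            records.append(dict(group=group, organoid=f"{group}-{i:02d}",
                                params=params, trace=trace, truth=truth))
            rows.append(dict(group=group, organoid=f"{group}-{i:02d}",
                             true_interval_mean_s=truth.interval_mean,
                             true_n_transients=truth.n_transients))
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toy count matrices
# ---------------------------------------------------------------------------

def make_count_matrix(
    n_cells: int,
    n_genes: int,
    *,
    features_per_cell=3000,
    mito_fraction=0.0,
    mean_counts_per_feature: int = 3,
    seed: int = 0,
):
    """Build a sparse genes x cells count matrix with programmed QC truth.

    ``features_per_cell`` and ``mito_fraction`` may be scalars or per-cell
    arrays; each cell detects exactly its programmed number of features and
    carries (to count rounding) its programmed mitochondrial read fraction.
    Mitochondrial genes are named with the human "MT-" prefix. Returns
    ``(CellMatrix, truth)`` where truth is a per-cell DataFrame of realized
    feature counts and mito fractions.
    """
    from .scqc import CellMatrix  # local import to avoid a module cycle

    if n_cells < 1 or n_genes < 1:
        raise ValueError("n_cells and n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    feats = np.broadcast_to(np.asarray(features_per_cell, dtype=int), (n_cells,)).copy()
    mito = np.broadcast_to(np.asarray(mito_fraction, dtype=float), (n_cells,)).copy()
    if np.any(feats < 1) or np.any(feats > n_genes):
        raise ValueError("features_per_cell must lie in [1, n_genes]")
    if np.any((mito < 0) | (mito >= 1)):
        raise ValueError("mito_fraction must lie in [0, 1)")

    n_mito = min(len(MITO_GENE_NAMES), max(1, n_genes // 20))
    gene_ids = list(MITO_GENE_NAMES[:n_mito]) + [f"GENE{j:05d}" for j in range(n_genes - n_mito)]
    barcodes = [f"CELL{j:05d}-1" for j in range(n_cells)]

    rows, cols, data = [], [], []
    realized_mito = np.zeros(n_cells)
    for c in range(n_cells):
        total = int(feats[c]) * mean_counts_per_feature
        m_counts = int(round(mito[c] * total))
        n_mito_feats = 0
        if m_counts > 0:
            n_mito_feats = min(n_mito, max(1, min(int(feats[c]) - 1, m_counts)))
            per = np.full(n_mito_feats, m_counts // n_mito_feats)
            per[: m_counts % n_mito_feats] += 1
            for g, cnt in zip(rng.permutation(n_mito)[:n_mito_feats], per):
                rows.append(int(g)); cols.append(c); data.append(int(cnt))
        n_plain = int(feats[c]) - n_mito_feats
        if n_plain > n_genes - n_mito:
            raise ValueError("features_per_cell exceeds the non-mitochondrial gene pool")
        plain_total = total - m_counts
        per = np.full(n_plain, plain_total // n_plain)
        per[: plain_total % n_plain] += 1
        if np.any(per < 1):  # guard: every detected feature needs >= 1 count
            raise ValueError("mean_counts_per_feature too low for requested mito fraction")
        genes = rng.permutation(n_genes - n_mito)[:n_plain] + n_mito
        for g, cnt in zip(genes, per):
            rows.append(int(g)); cols.append(c); data.append(int(cnt))
        realized_mito[c] = m_counts / total if total else 0.0

    counts = sparse.coo_matrix((data, (rows, cols)), shape=(n_genes, n_cells)).tocsr()
    truth = pd.DataFrame({
        "barcode": barcodes,
        "n_features": feats,
        "mito_fraction": realized_mito,
    })
    return CellMatrix(counts=counts, gene_ids=gene_ids, barcodes=barcodes), truth
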