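"""Framewise displacement and motion-rate summaries from realignment traces.

Framewise displacement (FD) for the transition between consecutive fMRI
volumes is the sum of the absolute first differences of the six
rigid-body parameters, with the three rotations first converted to arc
length on a sphere of radius 50 mm (so a head-sized rotation is expressed
in millimetres).  Volumes at the very start of a run show inflated
apparent displacement, so the first five are excluded before summarising.

The per-scan summary statistic is a *rate* in mm/min: the mean
displacement per transition divided by the repetition time, times 60.
Normalising by time makes scans with different TRs (e.g. rest at
1.970 s vs movie at 2.470 s) directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .io import RealignmentTrace

DEFAULT_SPHERE_RADIUS_MM = 50.0
DEFAULT_DROP_INITIAL = 5


@dataclass
class MotionSummary:
    fd_series: np.ndarray  # per-transition displacement, mm
    mean_rate_mm_per_min: float
    frames_dropped: int
    sphere_radius_mm: float = DEFAULT_SPHERE_RADIUS_MM


@dataclass
class TimecourseSummary:
    """Group-mean motion time-course with a 95% confidence band."""

    time_s: np.ndarray
    group_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    group_label: str = ""


def angular_to_mm(angle: float, unit: str,
                  radius_mm: float = DEFAULT_SPHERE_RADIUS_MM) -> float:
    """Arc length of a rotation on a sphere surface: radius x angle (rad).

    Sign is preserved; ``unit`` selects how ``angle`` is expressed.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius must be positive, got {radius_mm}")
    if unit == "radians":
        rad = angle
    elif unit == "degrees":
        rad = math.radians(angle)
    else:
        raise ValueError(f"unit must be 'radians' or 'degrees', got {unit!r}")
    return radius_mm * rad


def framewise_displacement(trace: RealignmentTrace,
                           radius_mm: float = DEFAULT_SPHERE_RADIUS_MM) -> np.ndarray:
    """Per-transition displacement series, length T - 1.

    For each consecutive frame pair, sums |delta| over the six parameters
    with rotation columns (4-6) converted to mm on the sphere surface.
    """
    params = trace.params.copy()
    scale = radius_mm if trace.angle_unit == "radians" else radius_mm * math.pi / 180.0
    params[:, 3:] *= scale
    return np.abs(np.diff(params, axis=0)).sum(axis=1)


def mean_motion_rate(trace: RealignmentTrace,
                     drop_initial: int = DEFAULT_DROP_INITIAL,
                     radius_mm: float = DEFAULT_SPHERE_RADIUS_MM) -> MotionSummary:
    """Motion rate in mm/min after excluding the initial frames.

    Displacement is computed only between frames ``drop_initial..T-1``;
    the transition crossing the drop boundary is discarded so excluded
    frames contribute nothing.
    """
    if drop_initial < 0:
        raise ValueError("drop_initial must be >= 0")
    if trace.n_frames - drop_initial < 2:
        raise ValueError(
            f"{trace.n_frames} frames leave fewer than 2 after dropping {drop_initial}"
        )
    kept = RealignmentTrace(params=trace.params[drop_initial:],
                            angle_unit=trace.angle_unit,
                            tr_seconds=trace.tr_seconds, label=trace.label)
    fd = framewise_displacement(kept, radius_mm=radius_mm)
    rate = float(fd.mean() / trace.tr_seconds * 60.0)
    return MotionSummary(fd_series=fd, mean_rate_mm_per_min=rate,
                         frames_dropped=drop_initial, sphere_radius_mm=radius_mm)


def group_timecourse(traces: list[RealignmentTrace],
                     drop_initial: int = DEFAULT_DROP_INITIAL,
                     radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
                     ci: str = "normal",
                     group_label: str = "") -> TimecourseSummary:
    """Across-subject mean displacement per transition with a 95% CI band.

    All traces must share length and TR.  ``ci="normal"`` uses
    mean +/- 1.96 SE; ``ci="t"`` uses Student-t quantiles (matters only
    for small groups).  Timestamps are the arrival frame's acquisition
    time, ``(frame index) x TR``, on the full-trace clock so events keep
    their real latencies after the initial frames are dropped.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    T, tr = traces[0].n_frames, traces[0].tr_seconds
    for t in traces[1:]:
        if t.n_frames != T or t.tr_seconds != tr:
            raise ValueError("traces must share length and repetition time")
    if T - drop_initial < 2:
        raise ValueError("too few frames after dropping the initial block")
    series = np.stack([
        framewise_displacement(
            RealignmentTrace(params=t.params[drop_initial:], angle_unit=t.angle_unit,
                             tr_seconds=tr, label=t.label),
            radius_mm=radius_mm)
        for t in traces
    ])
    n = series.shape[0]
    mean = series.mean(axis=0)
    se = series.std(axis=0, ddof=1) / math.sqrt(n)
    if ci == "normal":
        q = 1.959963984540054
    elif ci == "t":
        q = float(sp_stats.t.ppf(0.975, n - 1))
    else:
        raise ValueError(f"ci must be 'normal' or 't', got {ci!r}")
    time_s = (np.arange(drop_initial + 1, T)) * tr
    return TimecourseSummary(time_s=time_s, group_mean=mean,
                             ci_low=mean - q * se, ci_high=mean + q * se,
                             group_label=group_label)
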