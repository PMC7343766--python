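"""Slow-phase (fixation) classification by adaptive velocity threshold.

Gaze speed is estimated per sample from the displacements to the
neighboring samples. A velocity threshold is then derived by iterative
outlier trimming — repeatedly discarding speeds above mean + 2.5 SD until
the surviving set is stable (or 200 iterations) — and set at mean + 3 SD
of the survivors. In the windowed mode this is done inside an 8-s moving
window; each sample's final threshold is the average of the thresholds of
every window it belonged to, so the threshold tracks slow changes in
overall gaze velocity (walking, turning). Samples strictly below the
threshold are potential fixation samples; maximal runs lasting at least
80 ms become fixations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import GazeRecording

FIXATION_COLUMNS = (
    "onset_s",
    "offset_s",
    "duration_ms",
    "mean_azimuth_deg",
    "mean_elevation_deg",
)


@dataclass(frozen=True)
class ClassifierParams:
    """Tunables of the adaptive velocity-threshold classifier.

    ``sd_ddof=1`` selects the sample (n−1) standard deviation throughout.
    """

    window_s: float = 8.0
    trim_k: float = 2.5
    threshold_k: float = 3.0
    max_iterations: int = 200
    min_fixation_ms: float = 80.0
    mode: str = "windowed"
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.trim_k <= 0 or self.threshold_k <= 0:
            raise ValueError("trim_k and threshold_k must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.min_fixation_ms < 0:
            raise ValueError("min_fixation_ms must be nonnegative")
        if self.mode not in ("windowed", "global"):
            raise ValueError("mode must be 'windowed' or 'global'")


@dataclass
class VelocitySignal:
    """Per-sample gaze speed (deg/s) with the position signal it came from."""

    t_s: np.ndarray
    speed_deg_s: np.ndarray
    az_deg: np.ndarray
    el_deg: np.ndarray

    @property
    def nominal_dt_s(self) -> float:
        return float(np.median(np.diff(self.t_s)))


@dataclass
class ThresholdSignal:
    """Per-sample velocity threshold (deg/s) and bookkeeping."""

    threshold_deg_s: np.ndarray
    mode: str
    n_windows: int
    n_windows_skipped: int


def compute_velocity(
    recording: GazeRecording, eye_mode: str = "mean", great_circle: bool = False
) -> VelocitySignal:
    """Estimate gaze speed per sample.

    For each sample the displacement to the previous and to the next
    sample is divided by the respective time difference; the two speeds
    are averaged. Boundary samples, and samples with one missing
    neighbor, use the single available one-sided speed; with both
    neighbors missing (or the sample itself missing) the speed is NaN.

    Displacement is Euclidean in (azimuth, elevation) degrees (small-angle
    approximation); ``great_circle=True`` uses the spherical angle instead.
    """
    t = recording.t_s
    if len(t) < 3:
        raise ValueError("need at least 3 samples to estimate velocity")
    az, el = recording.position(eye_mode)
    if great_circle:
        az_r, el_r = np.radians(az), np.radians(el)
        cos_d = np.sin(el_r[:-1]) * np.sin(el_r[1:]) + np.cos(el_r[:-1]) * np.cos(
            el_r[1:]
        ) * np.cos(az_r[1:] - az_r[:-1])
        disp = np.degrees(np.arccos(np.clip(cos_d, -1.0, 1.0)))
    else:
        disp = np.hypot(np.diff(az), np.diff(el))
    seg_speed = disp / np.diff(t)  # speed of segment (i-1, i), NaN if either end missing
    back = np.concatenate([[np.nan], seg_speed])
    fwd = np.concatenate([seg_speed, [np.nan]])
    both = np.column_stack([back, fwd])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        speed = np.nanmean(both, axis=1)
    return VelocitySignal(t, speed, az, el)


def iterative_window_threshold(
    velocities: np.ndarray, params: ClassifierParams | None = None
) -> float:
    """Adaptive velocity threshold of one window of speeds.

    Speeds above mean + ``trim_k``·SD are removed iteratively until the
    surviving set no longer changes (or ``max_iterations`` is reached);
    the threshold is mean + ``threshold_k``·SD of the survivors. Returns
    NaN when fewer than two values survive (window is skipped).
    """
    params = params or ClassifierParams()
    x = np.asarray(velocities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    m = s = 0.0
    for _ in range(params.max_iterations):
        m = x.mean()
        s = x.std(ddof=params.sd_ddof)
        keep = x <= m + params.trim_k * s
        if keep.all():
            break
        x = x[keep]
        if x.size < 2:
            return float("nan")
    else:
        m = x.mean()
        s = x.std(ddof=params.sd_ddof)
    return float(m + params.threshold_k * s)


def adaptive_threshold_signal(
    velocity: VelocitySignal, params: ClassifierParams | None = None
) -> ThresholdSignal:
    """Per-sample velocity threshold in windowed or global mode.

    Windowed mode slides a ``window_s`` window one sample at a time and
    assigns each sample the average of the thresholds of all windows that
    contained it. A recording shorter than one window degrades to global
    mode with a warning. Skipped (degenerate) windows are excluded from
    the averages.
    """
    params = params or ClassifierParams()
    v = velocity.speed_deg_s
    n = len(v)
    if n < 2:
        raise ValueError("recording must be longer than one sample")
    w = int(round(params.window_s / velocity.nominal_dt_s))
    mode = params.mode
    if mode == "windowed" and w >= n:
        warnings.warn(
            "recording shorter than the threshold window; using global mode"
        )
        mode = "global"
    if mode == "global":
        thr = iterative_window_threshold(v, params)
        skipped = int(np.isnan(thr))
        return ThresholdSignal(np.full(n, thr), "global", 1, skipped)

    n_win = n - w + 1
    thr_w = np.empty(n_win)
    for s in range(n_win):
        thr_w[s] = iterative_window_threshold(v[s : s + w], params)
    valid = np.isfinite(thr_w)
    skipped = int((~valid).sum())
    # sample i is covered by windows s in [i-w+1, i] clipped to [0, n_win-1]
    csum = np.concatenate([[0.0], np.cumsum(np.where(valid, thr_w, 0.0))])
    ccnt = np.concatenate([[0], np.cumsum(valid.astype(int))])
    i = np.arange(n)
    lo = np.clip(i - w + 1, 0, n_win - 1)
    hi = np.clip(i, 0, n_win - 1)
    sums = csum[hi + 1] - csum[lo]
    cnts = ccnt[hi + 1] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        thr = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return ThresholdSignal(thr, "windowed", n_win, skipped)


def classify_fixations(
    velocity: VelocitySignal,
    thresholds: ThresholdSignal,
    params: ClassifierParams | None = None,
) -> pd.DataFrame:
    """Fixations as maximal runs of below-threshold samples ≥ 80 ms.

    "Below" is strict, so a degenerate zero-variance window (threshold
    equal to every speed) yields no potential fixation samples — a
    warning is emitted when that occurs. A run of n samples lasts
    n × (nominal sample interval); runs shorter than ``min_fixation_ms``
    are discarded. Missing speeds terminate runs. Intervals are half-open:
    ``offset_s = onset_s + n·dt``.
    """
    params = params or ClassifierParams()
    v = velocity.speed_deg_s
    thr = thresholds.threshold_deg_s
    if len(v) != len(thr):
        raise ValueError("velocity and threshold signals must be aligned")
    defined = np.isfinite(v) & np.isfinite(thr)
    pot = defined & (v < thr)
    if np.any(defined & (v == thr)):
        warnings.warn(
            "speeds exactly at threshold (zero-variance window?) are not fixation samples"
        )
    dt = velocity.nominal_dt_s
    edges = np.diff(np.concatenate([[0], pot.astype(np.int8), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    rows = []
    for i0, i1 in zip(starts, ends):
        n_run = i1 - i0
        dur_ms = n_run * dt * 1000.0
        if dur_ms < params.min_fixation_ms - 1e-9:
            continue
        rows.append(
            (
                velocity.t_s[i0],
                velocity.t_s[i0] + n_run * dt,
                dur_ms,
                float(np.nanmean(velocity.az_deg[i0:i1])),
                float(np.nanmean(velocity.el_deg[i0:i1])),
            )
        )
    return pd.DataFrame(rows, columns=list(FIXATION_COLUMNS))


def detect_fixations(
    recording: GazeRecording,
    params: ClassifierParams | None = None,
    eye_mode: str = "mean",
) -> tuple[pd.DataFrame, ThresholdSignal, VelocitySignal]:
    """Convenience: velocity → adaptive threshold → fixations."""
    params = params or ClassifierParams()
    vel = compute_velocity(recording, eye_mode)
    thr = adaptive_threshold_signal(vel, params)
    fixations = classify_fixations(vel, thr, params)
    return fixations, thr, vel
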