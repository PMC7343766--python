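"""Eye-tracking data-quality metrics and validation-marker geometry.

Precision (variable error) is summarized as the median over a 300-ms
moving window of the RMS of successive-sample differences, computed per
signal (left/right eye, azimuth/elevation component). Taking the median
over window positions excludes the high velocities of fast phases from
the measure. Data loss is the percentage of samples without a gaze
coordinate for an eye.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import GazeRecording


@dataclass(frozen=True)
class QualityParams:
    rms_window_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.rms_window_ms <= 0:
            raise ValueError("rms_window_ms must be positive")


def median_rms_s2s(
    values: np.ndarray, sampling_rate_hz: float, params: QualityParams | None = None
) -> float:
    """Median windowed RMS sample-to-sample deviation of one signal.

    The window advances one sample at a time; within each window the RMS
    is taken over differences of adjacent valid sample pairs. Windows with
    fewer than two valid pairs are skipped. Returns NaN when no window
    qualifies (e.g. an all-missing signal).
    """
    params = params or QualityParams()
    x = np.asarray(values, dtype=float)
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    w = max(2, int(round(params.rms_window_ms / 1000.0 * sampling_rate_hz)))
    n = len(x)
    if n < 2:
        return float("nan")
    d = np.diff(x)
    valid = np.isfinite(d)
    d2 = np.where(valid, d, 0.0) ** 2
    if n - 1 <= w - 1:
        # single (short) window
        if valid.sum() < 2:
            return float("nan")
        return float(np.sqrt(d2[valid].sum() / valid.sum()))
    # sliding sums over windows of w samples = w-1 difference slots
    kernel = w - 1
    csum = np.concatenate([[0.0], np.cumsum(d2)])
    ccnt = np.concatenate([[0], np.cumsum(valid.astype(int))])
    sums = csum[kernel:] - csum[:-kernel]
    cnts = ccnt[kernel:] - ccnt[:-kernel]
    ok = cnts >= 2
    if not ok.any():
        return float("nan")
    rms = np.sqrt(sums[ok] / cnts[ok])
    return float(np.median(rms))


def data_loss_pct(recording: GazeRecording, eye: str) -> float:
    """Percentage of samples for which the eye lacks a gaze coordinate.

    A sample counts as lost if either the azimuth or the elevation
    component is missing (a coordinate is a pair).
    """
    az, el = recording.eye(eye)
    lost = ~(np.isfinite(az) & np.isfinite(el))
    return 100.0 * lost.sum() / len(az)


def angular_subtense_deg(size_cm: float, distance_cm: float) -> float:
    """Full visual angle subtended by an object of given size at a distance."""
    if distance_cm <= 0:
        raise ValueError("distance_cm must be positive")
    if size_cm < 0:
        raise ValueError("size_cm must be nonnegative")
    return float(np.degrees(2.0 * np.arctan(size_cm / (2.0 * distance_cm))))


def cyclopean_distance_cm(
    horizontal_cm: float, eye_height_cm: float, target_height_cm: float
) -> float:
    """Euclidean distance from the cyclopean eye to a wall target."""
    if horizontal_cm < 0:
        raise ValueError("horizontal_cm must be nonnegative")
    return float(np.hypot(horizontal_cm, eye_height_cm - target_height_cm))


def quality_report(
    recording: GazeRecording, params: QualityParams | None = None
) -> pd.DataFrame:
    """Per-signal precision and per-eye data loss, one row per signal.

    Mirrors the standard per-component data-quality table: rows are
    (left|right) × (azimuth|elevation), columns ``rms_deg`` and
    ``data_loss_pct``.
    """
    params = params or QualityParams()
    fs = recording.sampling_rate_hz
    rows = []
    for eye in ("left", "right"):
        az, el = recording.eye(eye)
        loss = data_loss_pct(recording, eye)
        for comp, sig in (("azimuth", az), ("elevation", el)):
            rms = median_rms_s2s(sig, fs, params)
            if np.isnan(rms):
                warnings.warn(f"{eye} {comp}: no window with enough valid samples")
            rows.append((eye, comp, rms, loss))
    return pd.DataFrame(rows, columns=["eye", "component", "rms_deg", "data_loss_pct"])
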