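"""Container for binocular gaze-direction recordings.

A recording is a regularly sampled (nominally 50 Hz) table of gaze
directions for the left and right eye in Fick coordinates (azimuth,
elevation, degrees) relative to the scene-camera center, plus a button
voltage channel used for manual responses. Missing gaze samples (blinks,
tracking failures) are NaN.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical column order of the on-disk TSV format and in-memory table.
GAZE_COLUMNS = ("t_s", "az_l_deg", "el_l_deg", "az_r_deg", "el_r_deg", "button_v")

_EYE_COLUMNS = {
    "left": ("az_l_deg", "el_l_deg"),
    "right": ("az_r_deg", "el_r_deg"),
}


@dataclass
class GazeRecording:
    """Timestamped binocular azimuth/elevation signal with a button channel.

    Parameters
    ----------
    data:
        DataFrame with exactly the columns in :data:`GAZE_COLUMNS`.
        ``t_s`` must be strictly increasing; azimuth must lie in
        [-180, 180] and elevation in [-90, 90] where not NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = tuple(self.data.columns)
        missing = [c for c in GAZE_COLUMNS if c not in cols]
        unknown = [c for c in cols if c not in GAZE_COLUMNS]
        if missing or unknown:
            raise ValueError(
                f"gaze table columns must be {list(GAZE_COLUMNS)}; "
                f"missing={missing}, unknown={unknown}"
            )
        self.data = self.data.loc[:, list(GAZE_COLUMNS)].reset_index(drop=True)
        t = self.data["t_s"].to_numpy(float)
        if len(t) == 0:
            raise ValueError("empty recording")
        if np.any(~np.isfinite(t)):
            raise ValueError("timestamps must be finite")
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"timestamps must be strictly increasing; first violation at row {bad[0] + 1}"
            )
        for az_c, el_c in _EYE_COLUMNS.values():
            az = self.data[az_c].to_numpy(float)
            el = self.data[el_c].to_numpy(float)
            if np.any(np.abs(az[np.isfinite(az)]) > 180):
                raise ValueError(f"{az_c} outside [-180, 180]")
            if np.any(np.abs(el[np.isfinite(el)]) > 90):
                raise ValueError(f"{el_c} outside [-90, 90]")

    # -- basic geometry of the sample grid ---------------------------------
    @property
    def t_s(self) -> np.ndarray:
        return self.data["t_s"].to_numpy(float)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def nominal_dt_s(self) -> float:
        """Median inter-sample interval (the nominal 1/rate spacing)."""
        t = self.t_s
        if len(t) < 2:
            return float("nan")
        return float(np.median(np.diff(t)))

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / self.nominal_dt_s

    @property
    def duration_s(self) -> float:
        t = self.t_s
        return float(t[-1] - t[0]) + self.nominal_dt_s

    # -- signal access ------------------------------------------------------
    def eye(self, eye: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (azimuth, elevation) arrays in degrees for one eye."""
        try:
            az_c, el_c = _EYE_COLUMNS[eye]
        except KeyError:
            raise ValueError(f"eye must be 'left' or 'right', got {eye!r}") from None
        return self.data[az_c].to_numpy(float), self.data[el_c].to_numpy(float)

    def position(self, eye_mode: str = "mean") -> tuple[np.ndarray, np.ndarray]:
        """Combined gaze position used for classification.

        ``eye_mode='mean'`` averages the eyes where both are valid and
        falls back to the single valid eye; 'left'/'right' select one eye.
        """
        if eye_mode in _EYE_COLUMNS:
            return self.eye(eye_mode)
        if eye_mode != "mean":
            raise ValueError(f"eye_mode must be 'left', 'right' or 'mean', got {eye_mode!r}")
        az_l, el_l = self.eye("left")
        az_r, el_r = self.eye("right")
        # a gaze coordinate is a pair: an eye with either component missing
        # contributes nothing for that sample
        valid_l = np.isfinite(az_l) & np.isfinite(el_l)
        valid_r = np.isfinite(az_r) & np.isfinite(el_r)
        az_l = np.where(valid_l, az_l, np.nan)
        el_l = np.where(valid_l, el_l, np.nan)
        az_r = np.where(valid_r, az_r, np.nan)
        el_r = np.where(valid_r, el_r, np.nan)
        with np.errstate(invalid="ignore"):
            az = np.where(valid_l & valid_r, 0.5 * (az_l + az_r), np.where(valid_l, az_l, az_r))
            el = np.where(valid_l & valid_r, 0.5 * (el_l + el_r), np.where(valid_l, el_l, el_r))
        return az, el

    @property
    def button_v(self) -> np.ndarray:
        return self.data["button_v"].to_numpy(float)
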