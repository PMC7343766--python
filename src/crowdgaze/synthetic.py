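"""Synthetic gaze recordings for the two-round crowd-navigation scenario.

The generator emulates a wearable eye tracker worn while walking two
rounds through hallways with three oncoming groups of walkers (sizes 6,
12 and 20, each encountered twice per round). It produces a 50-Hz
binocular azimuth/elevation signal built from alternating fixations
(constant position plus slow drift and Gaussian noise) and saccade-like
fast phases (linear position ramps), blink-like data-loss bursts, a
button channel with scripted presses in the dual-task round, and the
ground truth every downstream stage is tested against: fixation epochs
with true AOI labels, the event timeline, and press times.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aoi import AOI_LABELS
from .recording import GAZE_COLUMNS, GazeRecording
from .timeline import ENCOUNTER_COLUMNS, ROUND_COLUMNS, EventTimeline

#: Per-round AOI sampling probabilities outside group encounters. Round 2
#: (dual task: assessing eye contact) shifts probability mass from bodies
#: to heads; all other categories are unchanged.
AOI_PROBS_BY_ROUND = {
    1: {
        "walls": 0.34,
        "non_aoi": 0.20,
        "body_walker": 0.15,
        "head_walker": 0.13,
        "group_distance": 0.08,
        "objects": 0.06,
        "body_obstructor": 0.02,
        "head_obstructor": 0.02,
    },
    2: {
        "walls": 0.34,
        "non_aoi": 0.20,
        "body_walker": 0.07,
        "head_walker": 0.21,
        "group_distance": 0.08,
        "objects": 0.06,
        "body_obstructor": 0.02,
        "head_obstructor": 0.02,
    },
}

#: AOI probabilities while walking inside a group (between the first and
#: last group member leaving the scene video): heads/bodies dominate.
IN_GROUP_AOI_PROBS_BY_ROUND = {
    1: {
        "head_walker": 0.30,
        "body_walker": 0.34,
        "walls": 0.10,
        "non_aoi": 0.10,
        "group_distance": 0.05,
        "objects": 0.05,
        "body_obstructor": 0.03,
        "head_obstructor": 0.03,
    },
    2: {
        "head_walker": 0.44,
        "body_walker": 0.20,
        "walls": 0.10,
        "non_aoi": 0.10,
        "group_distance": 0.05,
        "objects": 0.05,
        "body_obstructor": 0.03,
        "head_obstructor": 0.03,
    },
}

# gaze-direction box the simulated eyes stay within (deg, Fick)
_AZ_BOX = (-35.0, 35.0)
_EL_BOX = (-30.0, 8.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """Study-design parameters of the two-round/three-group scenario."""

    n_rounds: int = 2
    group_sizes: tuple[int, ...] = (6, 12, 20)
    encounters_per_group: int = 4  # across the whole experiment
    round_duration_s: float | None = None  # None: drawn uniformly in [95, 125]
    watcher_fraction: float = 0.30
    obstructor_fraction: float = 0.175
    sampling_rate_hz: float = 50.0
    lead_in_s: float = 5.0
    inter_round_gap_s: float = 20.0
    fixation_duration_range_ms: tuple[float, float] = (160.0, 800.0)
    button_presses_range: tuple[int, int] = (24, 46)

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if any(g < 2 for g in self.group_sizes):
            raise ValueError("all group sizes must be >= 2")
        if self.round_duration_s is not None and self.round_duration_s <= 0:
            raise ValueError("round_duration_s must be positive")
        for name in ("watcher_fraction", "obstructor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.encounters_per_group % self.n_rounds != 0:
            raise ValueError("encounters_per_group must be divisible by n_rounds")
        lo, hi = self.fixation_duration_range_ms
        if not 0 < lo <= hi:
            raise ValueError("fixation_duration_range_ms must be positive and ordered")


@dataclass(frozen=True)
class NoiseModel:
    """Oculomotor and device noise injected into the true gaze signal.

    Defaults emulate the wearable-tracker regime of the study design:
    sample-to-sample RMS around 0.7° (noise SD 0.5° ≈ 0.7/√2) and per-eye
    data loss near 8.5%.
    """

    fixation_noise_sd: float = 0.5  # deg, iid per sample/eye/component
    drift_rate: float = 0.5  # deg/s slow drift within a fixation
    saccade_amplitude_range: tuple[float, float] = (2.0, 20.0)  # deg
    saccade_duration_ms: float = 40.0
    loss_fraction: float = 0.085  # per eye
    loss_burst_ms: float = 200.0  # blink-like contiguous gaps

    def __post_init__(self) -> None:
        for name in ("fixation_noise_sd", "drift_rate", "saccade_duration_ms", "loss_burst_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.saccade_amplitude_range
        if lo < 0 or hi < lo:
            raise ValueError("saccade_amplitude_range must be nonnegative and ordered")
        if not 0.0 <= self.loss_fraction < 1.0:
            raise ValueError("loss_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Scripted truth for one simulated recording.

    ``true_fixations`` has columns ``onset_s, offset_s, aoi`` (half-open
    intervals on the sample grid, strictly increasing, non-overlapping);
    the complement of the fixation epochs consists of fast phases.
    """

    true_fixations: pd.DataFrame
    true_timeline: EventTimeline
    true_button_presses: np.ndarray

    def __post_init__(self) -> None:
        f = self.true_fixations.reset_index(drop=True)
        on = f["onset_s"].to_numpy(float)
        off = f["offset_s"].to_numpy(float)
        if np.any(off <= on):
            raise ValueError("fixation offsets must exceed onsets")
        if np.any(on[1:] < off[:-1]):
            raise ValueError("fixations must be non-overlapping and increasing")
        bad = set(f["aoi"]) - set(AOI_LABELS)
        if bad:
            raise ValueError(f"unknown AOI labels in ground truth: {sorted(bad)}")
        self.true_fixations = f
        self.true_button_presses = np.asarray(self.true_button_presses, dtype=float)


# ---------------------------------------------------------------------------
# schedule and signal construction
# ---------------------------------------------------------------------------

def _fixation_schedule(
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    duration_range_ms: tuple[float, float],
    saccade_len: int,
) -> list[tuple[int, int]]:
    """Alternating fixation/fast-phase tiling of the sample grid.

    Returns half-open fixation sample intervals; fixation lengths are
    drawn log-uniformly within the configured range so short fixations
    are common, as in natural viewing.
    """
    lo = max(2, int(round(duration_range_ms[0] / 1000.0 * fs)))
    hi = max(lo, int(round(duration_range_ms[1] / 1000.0 * fs)))
    out: list[tuple[int, int]] = []
    i = 0
    while i < n_samples:
        length = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        j = min(i + max(lo, length), n_samples)
        if j - i >= lo:
            out.append((i, j))
        i = j + saccade_len
    return out


def _fixation_positions(
    n_fix: int, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Sequence of fixation center positions inside the gaze box."""
    pos = np.empty((n_fix, 2))
    pos[0] = (0.0, -9.0)  # slightly downward, as when walking
    for k in range(1, n_fix):
        amp = rng.uniform(*noise.saccade_amplitude_range)
        # redraw the direction until the landing point stays inside the box,
        # so the drawn amplitude is always honored (the box diagonal exceeds
        # any default amplitude, so an inward direction always exists)
        for _ in range(1000):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            cand = pos[k - 1] + amp * np.array([np.cos(ang), np.sin(ang)])
            if _AZ_BOX[0] <= cand[0] <= _AZ_BOX[1] and _EL_BOX[0] <= cand[1] <= _EL_BOX[1]:
                break
        else:
            cand = np.clip(cand, (_AZ_BOX[0], _EL_BOX[0]), (_AZ_BOX[1], _EL_BOX[1]))
        pos[k] = cand
    return pos


def _true_signal(
    t: np.ndarray,
    fixations: list[tuple[int, int]],
    centers: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear true azimuth/elevation: drifting fixations joined
    by linear fast-phase ramps."""
    dt = t[1] - t[0] if len(t) > 1 else 0.02
    knot_t, knot_az, knot_el = [], [], []
    for (i, j), c in zip(fixations, centers):
        dur = (j - i) * dt
        ang = rng.uniform(0.0, 2.0 * np.pi)
        drift = noise.drift_rate * np.array([np.cos(ang), np.sin(ang)])
        start = c
        end = c + drift * dur
        knot_t += [i * dt, j * dt - dt]  # last sample of the fixation
        knot_az += [start[0], end[0]]
        knot_el += [start[1], end[1]]
    az = np.interp(t, knot_t, knot_az)
    el = np.interp(t, knot_t, knot_el)
    return az, el


def _inject_loss(
    az: np.ndarray, el: np.ndarray, noise: NoiseModel, fs: float, rng: np.random.Generator
) -> None:
    """NaN out blink-like bursts covering ≈ loss_fraction of samples (in place)."""
    n = len(az)
    n_loss = int(round(noise.loss_fraction * n))
    if n_loss == 0:
        return
    burst = max(1, int(round(noise.loss_burst_ms / 1000.0 * fs)))
    burst = min(burst, n_loss)
    n_slots = n // burst
    n_full, rem = divmod(n_loss, burst)
    take = n_full + (1 if rem else 0)
    slots = rng.choice(n_slots, size=min(take, n_slots), replace=False)
    for idx, s in enumerate(slots):
        length = burst if idx < n_full else rem
        az[s * burst : s * burst + length] = np.nan
        el[s * burst : s * burst + length] = np.nan


def _build_timeline(
    scenario: ScenarioSpec, round_bounds: list[tuple[float, float]], rng: np.random.Generator
) -> EventTimeline:
    per_round = scenario.encounters_per_group // scenario.n_rounds
    rounds = pd.DataFrame(
        [(r + 1, b[0], b[1]) for r, b in enumerate(round_bounds)], columns=list(ROUND_COLUMNS)
    )
    rows = []
    obstructor_out: list[float] = []
    enc_id = 0
    for r, (start, end) in enumerate(round_bounds):
        order = [g for _ in range(per_round) for g in range(len(scenario.group_sizes))]
        n_enc = len(order)
        slot = (end - start) / n_enc
        for k, g in enumerate(order):
            size = scenario.group_sizes[g]
            in_view = start + k * slot + rng.uniform(0.0, 1.0)
            first_out = in_view + rng.uniform(4.0, 6.0)
            pass_dur = min(0.4 * size + rng.uniform(0.0, 1.0), slot - (first_out - in_view) - 1.5)
            last_out = first_out + max(pass_dur, 1.0)
            rows.append((r + 1, g, enc_id, in_view, first_out, last_out))
            n_obs = int(round(scenario.obstructor_fraction * size))
            if n_obs:
                obstructor_out.extend(np.sort(rng.uniform(in_view, last_out, size=n_obs)))
            enc_id += 1
    encounters = pd.DataFrame(rows, columns=list(ENCOUNTER_COLUMNS))
    return EventTimeline(rounds, encounters, np.asarray(obstructor_out))


def _assign_aois(
    fix_onsets: np.ndarray, timeline: EventTimeline, rng: np.random.Generator
) -> list[str]:
    """Draw a true AOI per fixation from round- and encounter-dependent tables."""
    labels = []
    enc = timeline.encounters
    for onset in fix_onsets:
        round_idx = None
        for _, row in timeline.rounds.iterrows():
            if row["start_s"] <= onset < row["end_s"]:
                round_idx = int(row["round"])
                break
        table_round = min(round_idx, 2) if round_idx else 1
        probs = AOI_PROBS_BY_ROUND[table_round]
        if round_idx is not None:
            within = enc[
                (enc["round"] == round_idx)
                & (enc["first_out_s"] <= onset)
                & (onset < enc["last_out_s"])
            ]
            if not within.empty:
                probs = IN_GROUP_AOI_PROBS_BY_ROUND[table_round]
        names = list(probs)
        labels.append(str(rng.choice(names, p=[probs[k] for k in names])))
    return labels


def simulate_recording(
    scenario: ScenarioSpec | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[GazeRecording, GroundTruth]:
    """Simulate one observer's full recording plus its ground truth.

    The same ``(scenario, noise, seed)`` triple always yields identical
    output. Fixation epochs lie on the sample grid; each fast phase is a
    linear ramp of ``saccade_duration_ms`` connecting successive fixation
    positions, so any velocity threshold below the ramp speed and above
    the noise floor separates the two phases.
    """
    scenario = scenario or ScenarioSpec()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    fs = scenario.sampling_rate_hz
    dt = 1.0 / fs

    round_bounds = []
    cursor = scenario.lead_in_s
    for _ in range(scenario.n_rounds):
        dur = (
            scenario.round_duration_s
            if scenario.round_duration_s is not None
            else rng.uniform(95.0, 125.0)
        )
        round_bounds.append((cursor, cursor + dur))
        cursor += dur + scenario.inter_round_gap_s
    total_s = cursor
    n = int(round(total_s * fs))
    t = np.arange(n) * dt

    saccade_len = max(1, int(round(noise.saccade_duration_ms / 1000.0 * fs)))
    schedule = _fixation_schedule(n, fs, rng, scenario.fixation_duration_range_ms, saccade_len)
    centers = _fixation_positions(len(schedule), noise, rng)
    az_true, el_true = _true_signal(t, schedule, centers, noise, rng)

    timeline = _build_timeline(scenario, round_bounds, rng)
    fix_onsets = np.array([i * dt for i, _ in schedule])
    aois = _assign_aois(fix_onsets, timeline, rng)
    true_fixations = pd.DataFrame(
        {
            "onset_s": fix_onsets,
            "offset_s": np.array([j * dt for _, j in schedule]),
            "aoi": aois,
        }
    )

    # button presses in dual-task rounds (round 2 onwards)
    presses: list[float] = []
    for r, (start, end) in enumerate(round_bounds):
        if r == 0:
            continue
        lo, hi = scenario.button_presses_range
        k = int(rng.integers(lo, hi + 1))
        bin_w = (end - start) / k
        presses.extend(start + (b + rng.uniform(0.0, 0.8)) * bin_w for b in range(k))
    presses_arr = np.asarray(presses)
    button = np.zeros(n)
    pulse = max(1, int(round(0.2 * fs)))
    for p in presses_arr:
        i = int(round(p * fs))
        button[i : i + pulse] = 3.3

    data = {"t_s": t, "button_v": button}
    for eye in ("l", "r"):
        az = az_true + rng.normal(0.0, noise.fixation_noise_sd, n)
        el = el_true + rng.normal(0.0, noise.fixation_noise_sd, n)
        np.clip(az, *_AZ_BOX_WIDE, out=az)
        np.clip(el, *_EL_BOX_WIDE, out=el)
        _inject_loss(az, el, noise, fs, rng)
        data[f"az_{eye}_deg"] = az
        data[f"el_{eye}_deg"] = el

    recording = GazeRecording(pd.DataFrame(data, columns=list(GAZE_COLUMNS)))
    truth = GroundTruth(true_fixations, timeline, presses_arr)
    return recording, truth


# clipping box for the noisy signal (stays well inside Fick validity)
_AZ_BOX_WIDE = (-60.0, 60.0)
_EL_BOX_WIDE = (-45.0, 45.0)


def sample_phase_labels(recording: GazeRecording, truth: GroundTruth) -> np.ndarray:
    """Per-sample phase: ``'loss'`` (either eye missing), else ``'fixation'``
    inside a true fixation epoch, else ``'fast_phase'``."""
    t = recording.t_s
    labels = np.full(len(t), "fast_phase", dtype=object)
    for _, row in truth.true_fixations.iterrows():
        labels[(t >= row["onset_s"]) & (t < row["offset_s"])] = "fixation"
    az_l, el_l = recording.eye("left")
    az_r, el_r = recording.eye("right")
    lost = ~(np.isfinite(az_l) & np.isfinite(el_l) & np.isfinite(az_r) & np.isfinite(el_r))
    labels[lost] = "loss"
    return labels


def match_fixation_events(
    true_fixations: pd.DataFrame,
    classified: pd.DataFrame,
    dt_s: float,
    tol_samples: int = 1,
) -> dict[str, float]:
    """Score a classification against ground truth, boundary by boundary.

    A true onset (offset) counts as recovered when some classified onset
    (offset) lies within ``tol_samples`` of it on the sample grid.
    Returns onset, offset and pooled recovery rates.
    """
    t_on = np.round(true_fixations["onset_s"].to_numpy(float) / dt_s).astype(int)
    t_off = np.round(true_fixations["offset_s"].to_numpy(float) / dt_s).astype(int)
    c_on = np.round(classified["onset_s"].to_numpy(float) / dt_s).astype(int)
    c_off = np.round(classified["offset_s"].to_numpy(float) / dt_s).astype(int)
    if len(t_on) == 0:
        raise ValueError("no true fixations to match")
    if len(c_on) == 0:
        return {"onset_recovery": 0.0, "offset_recovery": 0.0, "overall_recovery": 0.0}
    on_hit = np.array([np.min(np.abs(c_on - a)) <= tol_samples for a in t_on])
    off_hit = np.array([np.min(np.abs(c_off - b)) <= tol_samples for b in t_off])
    return {
        "onset_recovery": float(on_hit.mean()),
        "offset_recovery": float(off_hit.mean()),
        "overall_recovery": float((on_hit.sum() + off_hit.sum()) / (len(t_on) + len(t_off))),
    }


# ---------------------------------------------------------------------------
# coder and timeline simulation
# ---------------------------------------------------------------------------

def identity_confusion() -> pd.DataFrame:
    """Coders reproduce the true label exactly."""
    eye = np.eye(len(AOI_LABELS))
    return pd.DataFrame(eye, index=list(AOI_LABELS), columns=list(AOI_LABELS))


def uniform_confusion() -> pd.DataFrame:
    """Coders guess uniformly, independent of the true label."""
    k = len(AOI_LABELS)
    return pd.DataFrame(
        np.full((k, k), 1.0 / k), index=list(AOI_LABELS), columns=list(AOI_LABELS)
    )


def obstructor_walker_confusion(p_swap: float = 0.4) -> pd.DataFrame:
    """Disagreement concentrated between obstructor and walker categories.

    With probability ``p_swap`` a head_obstructor is coded head_walker and
    vice versa (same for bodies); all other labels are coded faithfully.
    """
    conf = identity_confusion()
    for a, b in (("head_obstructor", "head_walker"), ("body_obstructor", "body_walker")):
        for x, y in ((a, b), (b, a)):
            conf.loc[x, x] = 1.0 - p_swap
            conf.loc[x, y] = p_swap
    return conf


def simulate_codings(
    truth: GroundTruth,
    confusion: pd.DataFrame,
    n_coders: int = 3,
    seed: int = 0,
) -> list[pd.Series]:
    """Draw per-coder AOI codings from a label confusion matrix.

    ``confusion`` rows index the true label, columns the assigned label;
    each row must sum to 1. Returns one coding per coder: a Series mapping
    fixation id (the row index of ``truth.true_fixations``) to a label.
    """
    confusion = confusion.loc[list(AOI_LABELS), list(AOI_LABELS)]
    sums = confusion.to_numpy().sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("confusion matrix rows must each sum to 1")
    rng = np.random.default_rng(seed)
    true_labels = truth.true_fixations["aoi"].to_numpy()
    label_arr = np.array(AOI_LABELS, dtype=object)
    row_idx = {lab: i for i, lab in enumerate(AOI_LABELS)}
    probs = confusion.to_numpy()
    codings = []
    for c in range(n_coders):
        drawn = np.empty(len(true_labels), dtype=object)
        for lab in np.unique(true_labels):
            mask = true_labels == lab
            picks = rng.choice(len(AOI_LABELS), size=int(mask.sum()), p=probs[row_idx[lab]])
            drawn[mask] = label_arr[picks]
        codings.append(
            pd.Series(drawn, index=truth.true_fixations.index, name=f"coder{c + 1}")
        )
    return codings


def simulate_timelines(
    truth: GroundTruth, jitter_sd_s: float = 0.2, seed: int = 0
) -> tuple[EventTimeline, EventTimeline]:
    """Two independent coders' timelines: truth plus Gaussian jitter.

    Event ordering within a round or encounter is preserved: a draw that
    breaks it is rejected and redrawn (with a warning); negative times are
    clipped at 0 (with a warning).
    """
    if jitter_sd_s < 0:
        raise ValueError("jitter_sd_s must be nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(2):
        rounds = truth.true_timeline.rounds.copy()
        enc = truth.true_timeline.encounters.copy()
        for _attempt in range(1000):
            cand = rounds.copy()
            cand["start_s"] = rounds["start_s"] + rng.normal(0, jitter_sd_s, len(rounds))
            cand["end_s"] = rounds["end_s"] + rng.normal(0, jitter_sd_s, len(rounds))
            if np.all(cand["start_s"] < cand["end_s"]):
                rounds = cand
                break
            warnings.warn("jittered round boundaries out of order; redrawing")
        for _attempt in range(1000):
            cand = enc.copy()
            for col in ("in_view_s", "first_out_s", "last_out_s"):
                cand[col] = enc[col] + rng.normal(0, jitter_sd_s, len(enc))
            ok = (cand["in_view_s"] <= cand["first_out_s"]) & (
                cand["first_out_s"] <= cand["last_out_s"]
            )
            if ok.all():
                enc = cand
                break
            warnings.warn("jittered encounter events out of order; redrawing")
        for frame, cols in ((rounds, ("start_s", "end_s")),
                            (enc, ("in_view_s", "first_out_s", "last_out_s"))):
            for col in cols:
                neg = frame[col] < 0
                if neg.any():
                    warnings.warn(f"clipped {int(neg.sum())} negative {col} values at 0")
                    frame.loc[neg, col] = 0.0
        obst = np.maximum(
            truth.true_timeline.obstructor_out_s
            + rng.normal(0, jitter_sd_s, len(truth.true_timeline.obstructor_out_s)),
            0.0,
        )
        out.append(EventTimeline(rounds, enc, obst))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# stress scenario for classifier comparison
# ---------------------------------------------------------------------------

def simulate_two_regime_recording(
    seed: int = 0,
    half_duration_s: float = 60.0,
    fs: float = 50.0,
) -> tuple[GazeRecording, GroundTruth]:
    """Nonstationary recording: quiet first half, noisy second half.

    The first half has low noise (0.05°) and small saccades (2.5°); the
    second half has high noise (0.6°) and large saccades (15°). A single
    whole-recording velocity threshold, inflated by the noisy half, misses
    the small fast phases of the quiet half, whereas the windowed
    threshold adapts — the motivating failure mode for the windowed
    classifier.
    """
    quiet = NoiseModel(
        fixation_noise_sd=0.05, drift_rate=0.2, saccade_amplitude_range=(2.5, 2.5),
        saccade_duration_ms=40.0, loss_fraction=0.0,
    )
    loud = NoiseModel(
        fixation_noise_sd=0.6, drift_rate=0.2, saccade_amplitude_range=(15.0, 15.0),
        saccade_duration_ms=40.0, loss_fraction=0.0,
    )
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs
    n_half = int(round(half_duration_s * fs))
    parts = []
    truth_rows = []
    for h, nm in enumerate((quiet, loud)):
        n = n_half
        t = np.arange(n) * dt
        schedule = _fixation_schedule(n, fs, rng, (200.0, 700.0), 2)
        centers = _fixation_positions(len(schedule), nm, rng)
        az_true, el_true = _true_signal(t, schedule, centers, nm, rng)
        offset = h * n_half * dt
        for i, j in schedule:
            truth_rows.append((offset + i * dt, offset + j * dt))
        part = {}
        for eye in ("l", "r"):
            part[f"az_{eye}_deg"] = az_true + rng.normal(0, nm.fixation_noise_sd, n)
            part[f"el_{eye}_deg"] = el_true + rng.normal(0, nm.fixation_noise_sd, n)
        parts.append(part)
    n_total = 2 * n_half
    t_all = np.arange(n_total) * dt
    data = {"t_s": t_all, "button_v": np.zeros(n_total)}
    for key in ("az_l_deg", "el_l_deg", "az_r_deg", "el_r_deg"):
        data[key] = np.concatenate([parts[0][key], parts[1][key]])
    recording = GazeRecording(pd.DataFrame(data, columns=list(GAZE_COLUMNS)))
    fix = pd.DataFrame(truth_rows, columns=["onset_s", "offset_s"])
    fix["aoi"] = "non_aoi"
    rounds = pd.DataFrame({"round": [1], "start_s": [0.0], "end_s": [n_total * dt]})
    enc = pd.DataFrame(columns=list(ENCOUNTER_COLUMNS))
    truth = GroundTruth(fix, EventTimeline(rounds, enc), np.empty(0))
    return recording, truth
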