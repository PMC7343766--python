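"""Readers and writers for the on-disk formats, button detection, config.

Formats
-------
gaze TSV
    columns ``t_s, az_l_deg, el_l_deg, az_r_deg, el_r_deg, button_v``;
    missing gaze samples are empty fields.
fixations CSV
    ``fixation_id, onset_s, offset_s, duration_ms, mean_azimuth_deg,
    mean_elevation_deg``.
codings CSV
    ``fixation_id, onset_s, offset_s, label, coder_id`` (long format,
    several coders per file).
timeline CSV
    long format ``coder_id, event_type, round, group, encounter, time_s``
    with event types round_start/round_end/group_in_view/
    first_person_out/last_person_out/obstructor_out.
truth JSON, config YAML/JSON
    plain nested mappings.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fixation import FIXATION_COLUMNS, ClassifierParams
from .quality import QualityParams
from .recording import GAZE_COLUMNS, GazeRecording
from .synthetic import GroundTruth, NoiseModel, ScenarioSpec
from .timeline import ENCOUNTER_COLUMNS, ROUND_COLUMNS, EventTimeline

TIMELINE_EVENT_TYPES = (
    "round_start",
    "round_end",
    "group_in_view",
    "first_person_out",
    "last_person_out",
    "obstructor_out",
)


# ---------------------------------------------------------------------------
# gaze TSV
# ---------------------------------------------------------------------------

def write_gaze_tsv(recording: GazeRecording, path: str | Path) -> None:
    recording.data.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.6f")


def read_gaze_tsv(path: str | Path) -> GazeRecording:
    """Read a gaze TSV, enforcing the column schema and monotone timestamps."""
    df = pd.read_csv(path, sep="\t")
    unknown = [c for c in df.columns if c not in GAZE_COLUMNS]
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if unknown or missing:
        raise ValueError(
            f"{path}: bad gaze TSV header; unknown columns {unknown}, missing {missing}"
        )
    for c in df.columns:
        df[c] = pd.to_numeric(df[c], errors="raise")
    try:
        return GazeRecording(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# fixations CSV
# ---------------------------------------------------------------------------

def write_fixations_csv(fixations: pd.DataFrame, path: str | Path) -> None:
    out = fixations.reset_index(drop=True)
    out.insert(0, "fixation_id", out.index)
    out.to_csv(path, index=False)


def read_fixations_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = ("fixation_id",) + FIXATION_COLUMNS
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fixations CSV missing columns {missing}")
    return df.set_index("fixation_id")[list(FIXATION_COLUMNS)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# codings CSV
# ---------------------------------------------------------------------------

def write_codings_csv(
    codings: list[pd.Series], fixations: pd.DataFrame, path: str | Path
) -> None:
    rows = []
    for coding in codings:
        for fid, label in coding.items():
            rows.append(
                (
                    fid,
                    fixations.loc[fid, "onset_s"],
                    fixations.loc[fid, "offset_s"],
                    label,
                    coding.name,
                )
            )
    pd.DataFrame(
        rows, columns=["fixation_id", "onset_s", "offset_s", "label", "coder_id"]
    ).to_csv(path, index=False)


def read_codings_csv(path: str | Path) -> list[pd.Series]:
    df = pd.read_csv(path)
    need = ["fixation_id", "label", "coder_id"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: codings CSV missing columns {missing}")
    out = []
    for coder, sub in df.groupby("coder_id", sort=True):
        s = sub.sort_values("fixation_id").set_index("fixation_id")["label"]
        s.name = str(coder)
        s.index.name = None
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# timeline CSV
# ---------------------------------------------------------------------------

def write_timelines_csv(timelines: dict[str, EventTimeline], path: str | Path) -> None:
    rows = []
    for coder, tl in timelines.items():
        for _, r in tl.rounds.iterrows():
            rows.append((coder, "round_start", int(r["round"]), "", "", r["start_s"]))
            rows.append((coder, "round_end", int(r["round"]), "", "", r["end_s"]))
        for _, e in tl.encounters.iterrows():
            for ev, col in (
                ("group_in_view", "in_view_s"),
                ("first_person_out", "first_out_s"),
                ("last_person_out", "last_out_s"),
            ):
                rows.append(
                    (coder, ev, int(e["round"]), int(e["group"]), int(e["encounter"]), e[col])
                )
        for tt in tl.obstructor_out_s:
            rows.append((coder, "obstructor_out", "", "", "", tt))
    pd.DataFrame(
        rows, columns=["coder_id", "event_type", "round", "group", "encounter", "time_s"]
    ).to_csv(path, index=False)


def read_timelines_csv(path: str | Path) -> dict[str, EventTimeline]:
    df = pd.read_csv(path)
    need = ["coder_id", "event_type", "round", "group", "encounter", "time_s"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: timeline CSV missing columns {missing}")
    bad = set(df["event_type"]) - set(TIMELINE_EVENT_TYPES)
    if bad:
        raise ValueError(f"{path}: unknown event types {sorted(bad)}")
    out = {}
    for coder, sub in df.groupby("coder_id", sort=True):
        rs = sub[sub["event_type"] == "round_start"].set_index("round")["time_s"]
        re_ = sub[sub["event_type"] == "round_end"].set_index("round")["time_s"]
        rounds = pd.DataFrame(
            {
                "round": rs.index.astype(int),
                "start_s": rs.to_numpy(float),
                "end_s": re_.reindex(rs.index).to_numpy(float),
            },
            columns=list(ROUND_COLUMNS),
        )
        enc_rows = {}
        for _, r in sub[sub["event_type"].isin(
            ("group_in_view", "first_person_out", "last_person_out")
        )].iterrows():
            key = int(r["encounter"])
            rec = enc_rows.setdefault(
                key,
                {
                    "round": int(r["round"]),
                    "group": int(r["group"]),
                    "encounter": key,
                    "in_view_s": np.nan,
                    "first_out_s": np.nan,
                    "last_out_s": np.nan,
                },
            )
            col = {
                "group_in_view": "in_view_s",
                "first_person_out": "first_out_s",
                "last_person_out": "last_out_s",
            }[r["event_type"]]
            rec[col] = float(r["time_s"])
        encounters = pd.DataFrame(
            [enc_rows[k] for k in sorted(enc_rows)] or None,
            columns=list(ENCOUNTER_COLUMNS),
        )
        obst = sub[sub["event_type"] == "obstructor_out"]["time_s"].to_numpy(float)
        out[str(coder)] = EventTimeline(rounds, encounters, obst)
    return out


# ---------------------------------------------------------------------------
# ground-truth JSON
# ---------------------------------------------------------------------------

def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "true_fixations": truth.true_fixations.to_dict(orient="list"),
        "true_timeline": {
            "rounds": truth.true_timeline.rounds.to_dict(orient="list"),
            "encounters": truth.true_timeline.encounters.to_dict(orient="list"),
            "obstructor_out_s": truth.true_timeline.obstructor_out_s.tolist(),
        },
        "true_button_presses": truth.true_button_presses.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    tl = payload["true_timeline"]
    timeline = EventTimeline(
        pd.DataFrame(tl["rounds"], columns=list(ROUND_COLUMNS)),
        pd.DataFrame(tl["encounters"], columns=list(ENCOUNTER_COLUMNS)),
        np.asarray(tl["obstructor_out_s"], dtype=float),
    )
    return GroundTruth(
        pd.DataFrame(payload["true_fixations"]),
        timeline,
        np.asarray(payload["true_button_presses"], dtype=float),
    )


# ---------------------------------------------------------------------------
# button presses
# ---------------------------------------------------------------------------

def detect_button_presses(recording: GazeRecording, high_v: float = 3.3) -> np.ndarray:
    """Press times: rising edges of the button channel through high_v/2."""
    v = recording.button_v
    thresh = high_v / 2.0
    above = v >= thresh
    rising = above & ~np.concatenate([[False], above[:-1]])
    return recording.t_s[rising]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    quality: QualityParams = field(default_factory=QualityParams)
    eye_mode: str = "mean"
    tiebreak_coder: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        # JSON round-trip turns tuples into lists for clean YAML/JSON output
        return json.loads(json.dumps(asdict(self)))


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: (tuple(v) if k in keys and isinstance(v, list) else v) for k, v in d.items()}


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON (by extension)."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    raw = raw or {}
    kwargs = {}
    if "scenario" in raw:
        kwargs["scenario"] = ScenarioSpec(
            **_tupled(raw["scenario"], ("group_sizes", "fixation_duration_range_ms", "button_presses_range"))
        )
    if "noise" in raw:
        kwargs["noise"] = NoiseModel(**_tupled(raw["noise"], ("saccade_amplitude_range",)))
    if "classifier" in raw:
        kwargs["classifier"] = ClassifierParams(**raw["classifier"])
    if "quality" in raw:
        kwargs["quality"] = QualityParams(**raw["quality"])
    for key in ("eye_mode", "tiebreak_coder", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
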