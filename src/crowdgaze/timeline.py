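"""Event timelines from scene-video coding.

A video coder marks, per round, the round start/end (door visible /
experimenter starts talking) and, per group encounter, when the group
comes into view, when its first person leaves the scene video and when
its last person leaves, plus obstructor-exit events.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROUND_COLUMNS = ("round", "start_s", "end_s")
ENCOUNTER_COLUMNS = (
    "round",
    "group",
    "encounter",
    "in_view_s",
    "first_out_s",
    "last_out_s",
)


class IncompleteEncounterError(ValueError):
    """An encounter is missing one of its coded events."""


@dataclass
class EventTimeline:
    """Round boundaries and group-visibility events for one video coder.

    ``rounds`` has columns ``round, start_s, end_s`` (1-based round index);
    ``encounters`` has columns ``round, group, encounter, in_view_s,
    first_out_s, last_out_s`` where ``encounter`` indexes encounters over
    the whole experiment (0-based) and ``group`` is the group's size class
    index (0-based). NaN marks an event the coder could not code.
    """

    rounds: pd.DataFrame
    encounters: pd.DataFrame
    obstructor_out_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.rounds = self.rounds.loc[:, list(ROUND_COLUMNS)].reset_index(drop=True)
        self.encounters = self.encounters.loc[:, list(ENCOUNTER_COLUMNS)].reset_index(drop=True)
        self.obstructor_out_s = np.asarray(self.obstructor_out_s, dtype=float)
        r = self.rounds
        if np.any(r["start_s"].to_numpy() >= r["end_s"].to_numpy()):
            raise ValueError("every round must have start_s < end_s")
        e = self.encounters
        iv = e["in_view_s"].to_numpy(float)
        fo = e["first_out_s"].to_numpy(float)
        lo = e["last_out_s"].to_numpy(float)
        ok = ~(np.isnan(iv) | np.isnan(fo) | np.isnan(lo))
        if np.any(iv[ok] > fo[ok]) or np.any(fo[ok] > lo[ok]):
            raise ValueError("encounter events must satisfy in_view <= first_out <= last_out")

    def round_bounds(self, round_index: int) -> tuple[float, float]:
        """Coded (start_s, end_s) of a 1-based round index."""
        row = self.rounds[self.rounds["round"] == round_index]
        if row.empty:
            raise KeyError(f"round {round_index} not coded")
        return float(row["start_s"].iloc[0]), float(row["end_s"].iloc[0])

    def encounter_row(self, encounter: int) -> pd.Series:
        row = self.encounters[self.encounters["encounter"] == encounter]
        if row.empty:
            raise KeyError(f"encounter {encounter} not coded")
        return row.iloc[0]

    def shifted(self, offset_s: float) -> "EventTimeline":
        """Timeline with all event times shifted by a constant offset."""
        rounds = self.rounds.copy()
        rounds[["start_s", "end_s"]] += offset_s
        enc = self.encounters.copy()
        enc[["in_view_s", "first_out_s", "last_out_s"]] += offset_s
        return EventTimeline(rounds, enc, self.obstructor_out_s + offset_s)
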