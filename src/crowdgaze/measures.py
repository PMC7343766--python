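"""AOI-based and task-performance measures of crowd-navigation gaze.

Per observer × round × AOI the pipeline reports the number of fixations,
the median fixation duration and the total fixation duration, restricted
to fixations lying fully inside the round window agreed by both video
coders. On top of these come the relative people-viewing bounds, the
group-size normalization, the absolute-agreement ICC for round
durations, between-round difference tables, and fixation-direction
statistics.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .aoi import AOI_LABELS, PEOPLE_LABELS
from .recording import GazeRecording
from .timeline import EventTimeline, IncompleteEncounterError

MEASURE_COLUMNS = ("aoi", "n_fixations", "median_duration_ms", "total_duration_s")


def analysis_window(
    timelines: tuple[EventTimeline, EventTimeline], round_index: int
) -> tuple[float, float]:
    """Window inside which both coders agree the round was running.

    The latest coded start and the earliest coded end — the only interval
    for which a fixation can begin after and end before both coders'
    round boundaries.
    """
    a, b = timelines
    sa, ea = a.round_bounds(round_index)
    sb, eb = b.round_bounds(round_index)
    start, end = max(sa, sb), min(ea, eb)
    if start >= end:
        raise ValueError(
            f"round {round_index}: coders' windows do not overlap ({start} >= {end})"
        )
    return start, end


def qualifying_fixations(
    fixations: pd.DataFrame, window: tuple[float, float]
) -> pd.DataFrame:
    """Fixations that begin after the window start and end before its end."""
    start, end = window
    mask = (fixations["onset_s"] > start) & (fixations["offset_s"] < end)
    return fixations[mask]


def round_duration(fixations: pd.DataFrame, window: tuple[float, float]) -> float:
    """Time from the first to the last fixation fully inside the window.

    Defined as last qualifying offset − first qualifying onset; NaN (with
    a warning) when no fixation qualifies.
    """
    q = qualifying_fixations(fixations, window)
    if q.empty:
        warnings.warn("no fixation lies fully within the analysis window")
        return float("nan")
    return float(q["offset_s"].max() - q["onset_s"].min())


def aoi_summary(
    fixations: pd.DataFrame,
    consensus: pd.Series,
    window: tuple[float, float],
) -> pd.DataFrame:
    """Per-AOI fixation count, median duration and total duration.

    ``consensus`` must label every fixation (same index as ``fixations``).
    Every AOI is reported; empty AOIs have count 0, total 0 and a missing
    median. The median of an even number of durations is the midpoint of
    the two central values.
    """
    if not consensus.index.equals(fixations.index):
        raise ValueError("consensus coding must cover all fixations")
    q = fixations.assign(aoi=consensus)
    q = qualifying_fixations(q, window)
    grouped = q.groupby("aoi")["duration_ms"]
    count = grouped.size().reindex(AOI_LABELS, fill_value=0)
    med = grouped.median().reindex(AOI_LABELS)
    total = (grouped.sum().reindex(AOI_LABELS, fill_value=0.0)) / 1000.0
    return pd.DataFrame(
        {
            "aoi": list(AOI_LABELS),
            "n_fixations": count.to_numpy(int),
            "median_duration_ms": med.to_numpy(float),
            "total_duration_s": total.to_numpy(float),
        }
    )


def fixation_time_proportion(fixations: pd.DataFrame, total_time_s: float) -> float:
    """Proportion of a time span covered by fixations (vs fast phases/loss)."""
    if total_time_s <= 0:
        raise ValueError("total_time_s must be positive")
    return float(fixations["duration_ms"].sum() / 1000.0 / total_time_s)


def people_relative_duration_bounds(
    table: pd.DataFrame, in_view_s: float, fixation_proportion: float
) -> tuple[float, float]:
    """Lower/upper bounds on the relative time people were looked at.

    ``people_total`` sums the total fixation duration over the group,
    body and head AOIs. The lower bound divides by the total time people
    were in view; the upper bound divides by the estimated maximum time
    people could have been looked at — the in-view time scaled by the
    proportion of the recording that contained fixations at all (e.g.
    50 s in view × 0.8 → a 40-s denominator).
    """
    if in_view_s <= 0:
        raise ValueError("in_view_s must be positive")
    if not 0.0 < fixation_proportion <= 1.0:
        raise ValueError("fixation_proportion must lie in (0, 1]")
    sub = table[table["aoi"].isin(PEOPLE_LABELS)]
    people_total = float(sub["total_duration_s"].sum())
    upper_denom = fixation_proportion * in_view_s
    if people_total > upper_denom + 1e-9:
        warnings.warn(
            "total people-fixation time exceeds the estimated maximum lookable time; "
            "inputs are inconsistent"
        )
    return people_total / in_view_s, people_total / upper_denom


def relative_fixations_eq1(n: int, group_size: int, encounters: int = 4) -> float:
    """Fixations within a group per (passable person × encounter).

    n / ((g − 1) × encounters): the divisor excludes the first person of
    the group, who is already out of view once the observer is 'in' the
    group, and averages over the encounters of that group.
    """
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    if n < 0 or encounters < 1:
        raise ValueError("n must be >= 0 and encounters >= 1")
    return n / ((group_size - 1) * encounters)


def in_group_window(timeline: EventTimeline, encounter: int) -> tuple[float, float]:
    """Walking-in-a-group interval: first person out → last person out."""
    row = timeline.encounter_row(encounter)
    first, last = float(row["first_out_s"]), float(row["last_out_s"])
    if np.isnan(first) or np.isnan(last):
        raise IncompleteEncounterError(
            f"encounter {encounter} is missing a first/last-person-out event"
        )
    return first, last


def group_in_view_window(timeline: EventTimeline, encounter: int) -> tuple[float, float]:
    """Visibility interval for the people-viewing bounds: group comes into
    view → last person out. Distinct from :func:`in_group_window`."""
    row = timeline.encounter_row(encounter)
    in_view, last = float(row["in_view_s"]), float(row["last_out_s"])
    if np.isnan(in_view) or np.isnan(last):
        raise IncompleteEncounterError(
            f"encounter {encounter} is missing an in-view/last-person-out event"
        )
    return in_view, last


def icc_a1(ratings: np.ndarray) -> float:
    """Two-way, absolute-agreement, single-measure intraclass correlation.

    ``ratings`` is an n-targets × k-raters matrix with no missing cells.
    Uses the two-way ANOVA decomposition:

        ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E))

    with MS_R the between-target, MS_C the between-rater and MS_E the
    residual mean squares. Zero total variance is defined as 1 (warning).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n x k matrix with n, k >= 2")
    if np.any(~np.isfinite(x)):
        raise ValueError("ratings must have no missing cells")
    n, k = x.shape
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0.0:
        warnings.warn("zero total variance; ICC defined as 1")
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float(
        (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err))
    )


def round_differences(tables: pd.DataFrame) -> pd.DataFrame:
    """Round-2 minus round-1 differences per observer × AOI.

    ``tables`` stacks per-round AOI summaries with columns ``observer,
    round, aoi, n_fixations, median_duration_ms, total_duration_s``.
    Positive values mean an increase in round 2 (the dual-task round).
    Observers missing either round are excluded with a warning.
    """
    required = {"observer", "round"} | set(MEASURE_COLUMNS)
    if not required.issubset(tables.columns):
        raise ValueError(f"tables must have columns {sorted(required)}")
    r1 = tables[tables["round"] == 1].set_index(["observer", "aoi"])
    r2 = tables[tables["round"] == 2].set_index(["observer", "aoi"])
    obs1, obs2 = set(r1.index.get_level_values(0)), set(r2.index.get_level_values(0))
    common = obs1 & obs2
    dropped = (obs1 | obs2) - common
    if dropped:
        warnings.warn(f"observers missing a round were excluded: {sorted(dropped)}")
    idx = pd.MultiIndex.from_product(
        [sorted(common), list(AOI_LABELS)], names=["observer", "aoi"]
    )
    cols = ["n_fixations", "median_duration_ms", "total_duration_s"]
    diff = r2.reindex(idx)[cols] - r1.reindex(idx)[cols]
    return diff.rename(
        columns={
            "n_fixations": "d_n_fixations",
            "median_duration_ms": "d_median_duration_ms",
            "total_duration_s": "d_total_duration_s",
        }
    ).reset_index()


def fixation_direction_stats(
    recording: GazeRecording,
    fixations: pd.DataFrame,
    az_range: tuple[float, float] = (-45.0, 45.0),
    el_range: tuple[float, float] = (-40.0, 40.0),
    bin_deg: float = 1.0,
) -> dict:
    """Pooled gaze-direction statistics over fixation samples, per eye.

    Pools every sample inside a fixation interval and reports, per eye,
    the mean and SD of azimuth and elevation plus a 2-D histogram whose
    counts sum to the number of pooled valid samples for that eye.
    """
    if fixations.empty:
        raise ValueError("need at least one fixation")
    t = recording.t_s
    in_fix = np.zeros(len(t), dtype=bool)
    for on, off in fixations[["onset_s", "offset_s"]].itertuples(index=False):
        in_fix |= (t >= on) & (t < off)
    az_edges = np.arange(az_range[0], az_range[1] + bin_deg, bin_deg)
    el_edges = np.arange(el_range[0], el_range[1] + bin_deg, bin_deg)
    out = {}
    for eye in ("left", "right"):
        az, el = recording.eye(eye)
        valid = in_fix & np.isfinite(az) & np.isfinite(el)
        # clip into the outer bins so the histogram conserves every sample
        az_c = np.clip(az[valid], az_edges[0], az_edges[-1] - 1e-9)
        el_c = np.clip(el[valid], el_edges[0], el_edges[-1] - 1e-9)
        hist, _, _ = np.histogram2d(az_c, el_c, bins=[az_edges, el_edges])
        out[eye] = {
            "mean_azimuth_deg": float(az[valid].mean()) if valid.any() else float("nan"),
            "sd_azimuth_deg": float(az[valid].std(ddof=1)) if valid.sum() > 1 else float("nan"),
            "mean_elevation_deg": float(el[valid].mean()) if valid.any() else float("nan"),
            "sd_elevation_deg": float(el[valid].std(ddof=1)) if valid.sum() > 1 else float("nan"),
            "n_samples": int(valid.sum()),
            "histogram": hist,
            "az_edges": az_edges,
            "el_edges": el_edges,
        }
    return out
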