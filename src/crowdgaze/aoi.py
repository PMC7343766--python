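"""Area-of-interest codings, inter-rater agreement, and consensus.

Each fixation is manually assigned one of seven AOIs (objects on the
ground, walls, a group at a distance, walker bodies/heads, obstructor
bodies/heads) or the non-AOI fallback (floors, corridor ends). A coding
is a Series mapping fixation id to label, one per coder.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: Closed label vocabulary; ``non_aoi`` is the fallback.
AOI_LABELS = (
    "objects",
    "walls",
    "group_distance",
    "body_walker",
    "head_walker",
    "body_obstructor",
    "head_obstructor",
    "non_aoi",
)

#: The three AOIs that together constitute "people" for the relative
#: total-fixation-duration bounds.
PEOPLE_LABELS = ("group_distance", "body_walker", "head_walker")

_OBSTRUCTOR_MERGE = {"head_obstructor": "head_walker", "body_obstructor": "body_walker"}


def _check_aligned(a: pd.Series, b: pd.Series) -> None:
    if len(a) != len(b) or not a.index.equals(b.index):
        raise ValueError("codings must cover the same fixation set")


def validate_coding(coding: pd.Series) -> None:
    bad = set(coding) - set(AOI_LABELS)
    if bad:
        raise ValueError(f"unknown AOI labels: {sorted(bad)}")


def cohens_kappa(a: pd.Series, b: pd.Series) -> float:
    """Unweighted Cohen's kappa between two codings of the same fixations.

    Chance agreement comes from the coders' marginal label frequencies.
    When both coders are constant and identical (chance agreement 1) the
    statistic is defined as 1 with a warning.
    """
    _check_aligned(a, b)
    if len(a) == 0:
        raise ValueError("empty codings")
    av, bv = a.to_numpy(object), b.to_numpy(object)
    p_obs = float(np.mean(av == bv))
    labels = sorted(set(av) | set(bv))
    fa = pd.Series(av).value_counts(normalize=True)
    fb = pd.Series(bv).value_counts(normalize=True)
    p_chance = float(sum(fa.get(lab, 0.0) * fb.get(lab, 0.0) for lab in labels))
    if p_chance >= 1.0 - 1e-12:
        warnings.warn("both coders constant and identical; kappa defined as 1")
        return 1.0
    return (p_obs - p_chance) / (1.0 - p_chance)


def merge_obstructor_labels(coding: pd.Series) -> pd.Series:
    """Collapse obstructor categories into the matching walker categories.

    head_obstructor → head_walker and body_obstructor → body_walker;
    everything else is unchanged. Idempotent.
    """
    return coding.replace(_OBSTRUCTOR_MERGE)


def consensus_coding(
    codings: list[pd.Series], tiebreak_coder: int
) -> tuple[pd.Series, float]:
    """Majority label per fixation across exactly three coders.

    If at least two coders agree, that label is used; when all three
    disagree the ``tiebreak_coder``'s label (0-based index into
    ``codings``) is used. Returns the consensus coding and the fraction
    of fixations that needed the tie break.
    """
    if len(codings) != 3:
        raise ValueError("consensus requires exactly 3 codings")
    if not 0 <= tiebreak_coder < 3:
        raise ValueError("tiebreak_coder must index one of the 3 codings")
    a, b, c = codings
    _check_aligned(a, b)
    _check_aligned(a, c)
    av, bv, cv = (s.to_numpy(object) for s in codings)
    out = np.where(av == bv, av, np.where(av == cv, av, np.where(bv == cv, bv, None)))
    ties = pd.isna(out)
    out[ties] = codings[tiebreak_coder].to_numpy(object)[ties]
    rate = float(ties.mean())
    return pd.Series(out, index=a.index, name="consensus"), rate


def pairwise_kappa_table(codings: list[pd.Series], merged: bool = False) -> pd.DataFrame:
    """Cohen's kappa for every coder pair, optionally after the
    obstructor→walker merge."""
    if merged:
        codings = [merge_obstructor_labels(c) for c in codings]
    rows = []
    for i in range(len(codings)):
        for j in range(i + 1, len(codings)):
            rows.append(
                (
                    codings[i].name or f"coder{i + 1}",
                    codings[j].name or f"coder{j + 1}",
                    cohens_kappa(codings[i], codings[j]),
                )
            )
    return pd.DataFrame(rows, columns=["coder_a", "coder_b", "kappa"])
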