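"""Frame-level merging of gaze directions and speech annotations.

The merged representation is one row per 33.3 ms video frame (30 Hz),
carrying the active speech attribute and both participants' gaze
directions — the format all ratio/frequency statistics and the windowed
model inputs are computed from.

Ratio statistics are computed in exact rational arithmetic on frame
counts: for a speech label S, each maximal occurrence of S contributes
one ratio per maximal same-direction gaze run, the run's frame count over
the occurrence's gaze-labeled frame count.  Within an occurrence free of
missing frames, the aversion and face-gaze run ratios sum to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .gaze_preprocess import AVERSION, FACE_GAZE, FRAME_MS, MISSING
from .speech_annotation import DialogueActUnit, SpeechSegment, unit_interval
from .vocab import COMMUNICATIVE_FUNCTIONS, SPEECH_TAGS

#: Canonical participant ids; the frame table holds one gaze column each.
PARTICIPANTS = ("interviewer", "interviewee")

NO_TAG = ""


class MergeError(ValueError):
    pass


def _segment_attr_at(
    mids: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Index of the covering segment per frame midpoint, -1 when none.

    A midpoint exactly on a boundary belongs to the later segment (the one
    starting there).
    """
    idx = np.searchsorted(starts, mids, side="right") - 1
    idx[idx < 0] = -1
    covered = (idx >= 0) & (mids < ends[np.clip(idx, 0, None)])
    return np.where(covered, idx, -1)


def build_frame_table(
    directions: dict[str, list[str]],
    segments: list[SpeechSegment],
    n_frames: int | None = None,
    frame_ms: float = FRAME_MS,
    beep_ms: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Merge per-frame gaze directions and speech segments into one table.

    ``directions`` maps participant id to a frame-indexed direction list
    (all on the common, synchronized clock with frame 0 starting at 0 ms).
    Each frame takes the sender and tag of the segment covering its
    midpoint; midpoints on a boundary go to the later segment.  Frames
    covered by no segment carry an empty tag.

    ``beep_ms`` optionally carries each recording's beep time on the
    common clock; differing beep times mean the inputs were never
    synchronized and raise :class:`MergeError`.
    """
    if beep_ms is not None and len(set(round(v, 6) for v in beep_ms.values())) > 1:
        raise MergeError(
            f"recordings are not synchronized: beep times {beep_ms} differ"
        )
    if n_frames is None:
        n_frames = max(len(v) for v in directions.values())
    mids = (np.arange(n_frames) + 0.5) * frame_ms

    segs = sorted(segments, key=lambda s: s.start_ms)
    if segs:
        starts = np.array([s.start_ms for s in segs])
        ends = np.array([s.end_ms for s in segs])
        idx = _segment_attr_at(mids, starts, ends)
        senders = [segs[i].sender if i >= 0 else NO_TAG for i in idx]
        tags = [segs[i].tag if i >= 0 else NO_TAG for i in idx]
    else:
        senders = [NO_TAG] * n_frames
        tags = [NO_TAG] * n_frames

    table = {
        "frame_index": np.arange(n_frames),
        "t_ms": mids - frame_ms / 2.0,
        "sender": senders,
        "tag": tags,
    }
    for pid, dirs in directions.items():
        col = list(dirs[:n_frames]) + [MISSING] * max(0, n_frames - len(dirs))
        table[f"gaze_{pid}"] = col
    return pd.DataFrame(table)


def build_frame_table_units(
    directions: dict[str, list[str]],
    units: list[DialogueActUnit],
    n_frames: int | None = None,
    frame_ms: float = FRAME_MS,
) -> pd.DataFrame:
    """Frame table for the dialogue-act scheme.

    Each frame carries the attribute bundle of the dialogue act whose
    (word-interval-concatenated) span covers its midpoint: communicative
    function, dimension, qualifiers, first rhetorical relation and its
    argument number, and the relative offsets (in units, 0 = none) of the
    functional and feedback dependence references.
    """
    if n_frames is None:
        n_frames = max(len(v) for v in directions.values())
    mids = (np.arange(n_frames) + 0.5) * frame_ms

    ordered = sorted(units, key=lambda u: unit_interval(u)[0])
    pos = {u.unit_id: k for k, u in enumerate(ordered)}

    def dep_offset(u: DialogueActUnit, refs: tuple[str, ...]) -> int:
        # relative offset in units back to the referenced act, capped at 20
        if not refs:
            return 0
        off = max(1, pos[u.unit_id] - pos.get(refs[0], pos[u.unit_id] - 1))
        return min(off, 20)

    if ordered:
        starts = np.array([unit_interval(u)[0] for u in ordered])
        ends = np.array([unit_interval(u)[1] for u in ordered])
        idx = _segment_attr_at(mids, starts, ends)
    else:
        idx = np.full(n_frames, -1)

    def attr(getter, default=""):
        return [getter(ordered[i]) if i >= 0 else default for i in idx]

    table = {
        "frame_index": np.arange(n_frames),
        "t_ms": mids - frame_ms / 2.0,
        "sender": attr(lambda u: u.sender),
        "communicative_function": attr(lambda u: u.communicative_function),
        "dimension": attr(lambda u: u.dimension),
        "certainty": attr(lambda u: u.certainty),
        "sentiment": attr(lambda u: u.sentiment),
        "rhetorical_relation": attr(
            lambda u: u.rhetorical_relations[0][0] if u.rhetorical_relations else ""
        ),
        "rr_argument": attr(
            lambda u: u.rhetorical_relations[0][1] if u.rhetorical_relations else 0,
            default=0,
        ),
        "functional_dep_offset": attr(
            lambda u: dep_offset(u, u.functional_dependences), default=0
        ),
        "feedback_dep_offset": attr(
            lambda u: dep_offset(u, u.feedback_dependences), default=0
        ),
    }
    for pid, dirs in directions.items():
        col = list(dirs[:n_frames]) + [MISSING] * max(0, n_frames - len(dirs))
        table[f"gaze_{pid}"] = col
    return pd.DataFrame(table)


# --- ratio statistics -----------------------------------------------------


@dataclass(frozen=True)
class RatioSet:
    """Per-run gaze-direction ratios during occurrences of one label.

    ``elements`` holds (occurrence id, run id, ratio) triples; ratios are
    exact fractions of frame counts.
    """

    label: str
    direction: str
    elements: list[tuple[int, int, Fraction]]

    @property
    def ratios(self) -> list[Fraction]:
        return [r for _, _, r in self.elements]


def _occurrence_slices(values: np.ndarray, label: str) -> list[slice]:
    """Maximal runs of ``label`` in a frame-indexed attribute column."""
    out = []
    n = len(values)
    i = 0
    while i < n:
        if values[i] == label:
            j = i
            while j < n and values[j] == label:
                j += 1
            out.append(slice(i, j))
            i = j
        else:
            i += 1
    return out


def _check_label(label: str, attr: str) -> None:
    known = SPEECH_TAGS if attr == "tag" else COMMUNICATIVE_FUNCTIONS
    if attr in ("tag", "communicative_function") and label not in known:
        raise ValueError(f"unknown {attr} label {label!r}")


def gaze_ratio_set(
    frames: pd.DataFrame,
    label: str,
    direction: str,
    participant: str,
    attr: str = "tag",
) -> RatioSet:
    """Run-wise gaze ratios during occurrences of a speech label.

    Occurrences of ``label`` are maximal frame runs with that value in
    column ``attr``.  Within each occurrence, missing-gaze frames are
    excluded; every maximal run of ``direction`` contributes its frame
    count over the occurrence's gaze-labeled frame count.
    """
    if direction not in (FACE_GAZE, AVERSION):
        raise ValueError(f"direction must be face_gaze or aversion, got {direction!r}")
    _check_label(label, attr)
    gaze = frames[f"gaze_{participant}"].to_numpy()
    labels = frames[attr].to_numpy()
    elements: list[tuple[int, int, Fraction]] = []
    for occ_id, sl in enumerate(_occurrence_slices(labels, label)):
        seq = [g for g in gaze[sl] if g != MISSING]
        denom = len(seq)
        if denom == 0:
            continue
        run_id = 0
        i = 0
        while i < denom:
            if seq[i] == direction:
                j = i
                while j < denom and seq[j] == direction:
                    j += 1
                elements.append((occ_id, run_id, Fraction(j - i, denom)))
                run_id += 1
                i = j
            else:
                i += 1
    return RatioSet(label=label, direction=direction, elements=elements)


@dataclass(frozen=True)
class FrequencyProportions:
    """Per-occurrence gaze run counts and their proportions."""

    label: str
    occurrences: list[dict]  # occurrence_id, fg_runs, a_runs, fg_prop, a_prop


def gaze_frequency_proportions(
    frames: pd.DataFrame,
    label: str,
    participant: str,
    attr: str = "tag",
) -> FrequencyProportions:
    """Run-count proportions of each direction within label occurrences.

    A run is a maximal same-direction gaze stretch (missing frames
    excluded); proportions are run counts over the occurrence's total runs.
    """
    _check_label(label, attr)
    gaze = frames[f"gaze_{participant}"].to_numpy()
    labels = frames[attr].to_numpy()
    occs = []
    for occ_id, sl in enumerate(_occurrence_slices(labels, label)):
        seq = [g for g in gaze[sl] if g != MISSING]
        runs = {FACE_GAZE: 0, AVERSION: 0}
        prev = None
        for g in seq:
            if g != prev:
                runs[g] += 1
            prev = g
        total = runs[FACE_GAZE] + runs[AVERSION]
        if total == 0:
            continue
        occs.append(
            {
                "occurrence_id": occ_id,
                "fg_runs": runs[FACE_GAZE],
                "a_runs": runs[AVERSION],
                "fg_prop": Fraction(runs[FACE_GAZE], total),
                "a_prop": Fraction(runs[AVERSION], total),
            }
        )
    return FrequencyProportions(label=label, occurrences=occs)


def mutual_face_gaze(
    frames: pd.DataFrame,
    participants: tuple[str, str] = PARTICIPANTS,
    frame_ms: float = FRAME_MS,
) -> tuple[float, float]:
    """Mutual face gaze: session fraction and mean episode duration (ms).

    The fraction is frames where both participants show face gaze over
    frames where both directions are non-missing; episodes are maximal
    mutual-face-gaze frame runs (duration = frame count x frame length).
    Returns (0.0, 0.0) when no frame is jointly observed.
    """
    a = frames[f"gaze_{participants[0]}"].to_numpy()
    b = frames[f"gaze_{participants[1]}"].to_numpy()
    both_obs = (a != MISSING) & (b != MISSING)
    mutual = (a == FACE_GAZE) & (b == FACE_GAZE)
    n_obs = int(both_obs.sum())
    if n_obs == 0:
        return 0.0, 0.0
    fraction = float(mutual.sum() / n_obs)
    episodes = _occurrence_slices(mutual, True)
    mean_ms = (
        float(np.mean([(sl.stop - sl.start) * frame_ms for sl in episodes]))
        if episodes
        else 0.0
    )
    return fraction, mean_ms
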