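"""Synthetic dyadic interview sessions.

Generates the full input surface of the analysis pipeline — raw 30 Hz gaze
samples, face tracks, speech segment annotations, and a beep marker per
recording — with known ground truth, so every downstream stage is testable
without recorded data.

The behavioural model:

* Each participant's gaze alternates between *face gaze* (on the partner's
  face) and *aversion* (one of the eight outer AOI cells), a two-state
  semi-Markov process with gamma-distributed state durations.  Default
  mean durations are role-dependent: interviewers hold face gaze longer
  (648.9 ms vs 585.8 ms) and avert for shorter spells (258.2 ms vs
  313.2 ms) than interviewees.
* Speech is a turn-alternating tag chain over the 14-label speech tag set,
  with role-specific transition weights and gamma tag durations; micro
  pauses are capped at 200 ms.
* Gaze couples to speech through a log-odds shift of the aversion hazard
  while a biased tag is active (:func:`couple_gaze_to_speech`); coupling
  strength 0 leaves the gaze process untouched.
* Tracking losses are injected as invalid-sample runs; the two recordings
  run on independent clocks anchored by a shared beep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gaze_preprocess import AVERSION, FACE_GAZE, FRAME_MS, FaceObservation
from .speech_annotation import SpeechSegment, SyncOffset
from .vocab import MICRO_PAUSE_MAX_MS, SPEECH_TAGS, SpeechTag

INTERVIEWER = "interviewer"
INTERVIEWEE = "interviewee"

#: Scene-camera image size, px.
SCENE_SIZE: tuple[float, float] = (640.0, 480.0)
#: The partner's face box in the scene camera, (left, top, right, bottom) px.
FACE_BOX: tuple[float, float, float, float] = (260.0, 160.0, 380.0, 320.0)
#: Positional jitter radius within a gaze state, px.  Kept well below the
#: fixation dispersion threshold so each state maps to exactly one fixation.
JITTER_PX: float = 10.0


class VocabularyError(ValueError):
    """A tag outside the 14-label speech tag set."""


def _check_tags(tags) -> None:
    for tag in tags:
        if tag not in SPEECH_TAGS:
            raise VocabularyError(f"unknown speech tag {tag!r}")


# --- role parameters ------------------------------------------------------

_T = SpeechTag  # local alias for table literals

_INTERVIEWER_TRANSITIONS: dict[str, dict[str, float]] = {
    _T.GREETING.value: {_T.READ_QUESTION.value: 1.0},
    _T.READ_QUESTION.value: {
        _T.ASKING_A_QUESTION.value: 2.0,
        _T.MICRO_PAUSE.value: 1.0,
    },
    _T.MICRO_PAUSE.value: {
        _T.ASKING_A_QUESTION.value: 1.0,
        _T.READ_QUESTION.value: 1.0,
    },
    _T.ASKING_A_QUESTION.value: {
        _T.SIGNALING_END_OF_SPEECH.value: 2.0,
        _T.SPEECH_PAUSE.value: 1.0,
    },
    _T.SIGNALING_END_OF_SPEECH.value: {
        _T.QUESTIONNAIRE_FILLING.value: 1.0,
        _T.SPEECH_PAUSE.value: 1.0,
    },
    _T.SPEECH_PAUSE.value: {
        _T.READ_QUESTION.value: 1.0,
        _T.CONFIRMATION.value: 1.0,
    },
    _T.CONFIRMATION.value: {
        _T.QUESTIONNAIRE_FILLING.value: 1.0,
        _T.SPEECH.value: 1.0,
    },
    _T.SPEECH.value: {
        _T.SPEECH_PAUSE.value: 1.0,
        _T.SIGNALING_END_OF_SPEECH.value: 1.0,
    },
    _T.QUESTIONNAIRE_FILLING.value: {
        _T.READ_QUESTION.value: 2.0,
        _T.REPETITION_OF_THE_QUESTION.value: 0.5,
    },
    _T.REPETITION_OF_THE_QUESTION.value: {_T.SIGNALING_END_OF_SPEECH.value: 1.0},
}

_INTERVIEWEE_TRANSITIONS: dict[str, dict[str, float]] = {
    _T.GREETING.value: {_T.PRE_SPEECH.value: 1.0},
    _T.PRE_SPEECH.value: {_T.SPEECH.value: 2.0, _T.THINKING.value: 1.0},
    _T.SPEECH.value: {
        _T.THINKING.value: 2.0,
        _T.SPEECH_PAUSE.value: 2.0,
        _T.MICRO_PAUSE.value: 2.0,
        _T.SIGNALING_END_OF_SPEECH.value: 1.0,
        _T.SPEECH_WHILE_LAUGHING.value: 0.3,
        _T.LAUGH.value: 0.2,
    },
    _T.THINKING.value: {_T.SPEECH.value: 3.0, _T.SPEECH_PAUSE.value: 1.0},
    _T.SPEECH_PAUSE.value: {_T.SPEECH.value: 2.0, _T.THINKING.value: 1.0},
    _T.MICRO_PAUSE.value: {_T.SPEECH.value: 3.0, _T.THINKING.value: 1.0},
    _T.SIGNALING_END_OF_SPEECH.value: {_T.SPEECH_PAUSE.value: 1.0},
    _T.LAUGH.value: {_T.SPEECH.value: 1.0},
    _T.SPEECH_WHILE_LAUGHING.value: {_T.SPEECH.value: 1.0},
    _T.CONFIRMATION.value: {_T.SPEECH.value: 1.0},
}

#: Per-tag (mean duration ms, gamma shape) shared across roles.
_TAG_DURATIONS: dict[str, tuple[float, float]] = {
    _T.SPEECH.value: (2500.0, 4.0),
    _T.ASKING_A_QUESTION.value: (1500.0, 4.0),
    _T.CONFIRMATION.value: (400.0, 4.0),
    _T.PRE_SPEECH.value: (300.0, 4.0),
    _T.SPEECH_PAUSE.value: (600.0, 4.0),
    _T.MICRO_PAUSE.value: (120.0, 4.0),
    _T.SIGNALING_END_OF_SPEECH.value: (400.0, 4.0),
    _T.THINKING.value: (800.0, 4.0),
    _T.READ_QUESTION.value: (3000.0, 4.0),
    _T.REPETITION_OF_THE_QUESTION.value: (1200.0, 4.0),
    _T.LAUGH.value: (700.0, 4.0),
    _T.SPEECH_WHILE_LAUGHING.value: (900.0, 4.0),
    _T.GREETING.value: (600.0, 4.0),
    _T.QUESTIONNAIRE_FILLING.value: (4000.0, 4.0),
}


@dataclass(frozen=True)
class RoleParams:
    """Behavioural parameters of one conversational role.

    ``duration_shape`` is the gamma shape of the gaze state duration
    distribution; the default keeps nearly all states above the 100 ms
    fixation detectability floor while leaving visible dispersion.
    """

    role: str
    gender: str = "F"
    mean_face_gaze_ms: float = 600.0
    mean_aversion_ms: float = 300.0
    duration_shape: float = 6.0
    tag_transition_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    tag_duration_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in (INTERVIEWER, INTERVIEWEE):
            raise ValueError(f"unknown role {self.role!r}")
        if self.gender not in ("F", "M"):
            raise ValueError(f"gender must be 'F' or 'M', got {self.gender!r}")
        if self.mean_face_gaze_ms <= 0 or self.mean_aversion_ms <= 0:
            raise ValueError("gaze state duration means must be positive")
        if self.duration_shape <= 0:
            raise ValueError("duration_shape must be positive")
        _check_tags(self.tag_transition_weights)
        for src, row in self.tag_transition_weights.items():
            _check_tags(row)
            if not any(w > 0 for w in row.values()):
                raise ValueError(f"transition weights from {src!r} are all zero")
        _check_tags(self.tag_duration_params)
        mp = self.tag_duration_params.get(_T.MICRO_PAUSE.value)
        if mp is not None and mp[0] > MICRO_PAUSE_MAX_MS:
            raise ValueError(
                f"Micro Pause mean must be <= {MICRO_PAUSE_MAX_MS:g} ms"
            )


def default_role_params(role: str, gender: str = "F") -> RoleParams:
    """Shipped defaults: the study's role-specific mean gaze durations."""
    if role == INTERVIEWER:
        return RoleParams(
            role=role,
            gender=gender,
            mean_face_gaze_ms=648.9,
            mean_aversion_ms=258.2,
            tag_transition_weights=_INTERVIEWER_TRANSITIONS,
            tag_duration_params=_TAG_DURATIONS,
        )
    if role == INTERVIEWEE:
        return RoleParams(
            role=role,
            gender=gender,
            mean_face_gaze_ms=585.8,
            mean_aversion_ms=313.2,
            tag_transition_weights=_INTERVIEWEE_TRANSITIONS,
            tag_duration_params=_TAG_DURATIONS,
        )
    raise ValueError(f"unknown role {role!r}")


@dataclass(frozen=True)
class CouplingSpec:
    """Gaze-speech coupling: log-odds shift of the aversion hazard per tag.

    While a tag with bias ``b`` is active and the coupling strength is
    ``s``, aversion durations are scaled by ``exp(s * b)`` and face-gaze
    durations by ``exp(-s * b)``: positive bias raises aversion occupancy.
    ``strength`` 0 leaves the gaze process exactly unchanged.
    """

    strength: float = 0.0
    tag_aversion_bias: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must be in [0, 1]")
        _check_tags(self.tag_aversion_bias)


def default_coupling(role: str, strength: float = 1.0) -> CouplingSpec:
    """Shipped coupling: aversion elevated during thinking/pauses for
    interviewees, and during on-screen tasks (reading questions, filling
    the questionnaire) for interviewers, who otherwise watch the speaker."""
    if role == INTERVIEWER:
        bias = {
            _T.READ_QUESTION.value: 1.5,
            _T.QUESTIONNAIRE_FILLING.value: 1.5,
            _T.REPETITION_OF_THE_QUESTION.value: 1.0,
            _T.SPEECH.value: -1.5,
            _T.THINKING.value: -1.5,
        }
    elif role == INTERVIEWEE:
        bias = {
            _T.THINKING.value: 1.2,
            _T.SPEECH.value: 0.8,
            _T.SPEECH_PAUSE.value: 0.8,
            _T.MICRO_PAUSE.value: 0.6,
            _T.READ_QUESTION.value: -0.8,
        }
    else:
        raise ValueError(f"unknown role {role!r}")
    return CouplingSpec(strength=strength, tag_aversion_bias=bias)


# --- gaze state paths -----------------------------------------------------


@dataclass(frozen=True)
class GazeState:
    """One face-gaze or aversion spell with its spatial anchor."""

    direction: str  # face_gaze | aversion
    start_ms: float
    end_ms: float
    anchor: tuple[float, float]


def _cell_anchors(
    face_box: tuple[float, float, float, float] = FACE_BOX,
    scene: tuple[float, float] = SCENE_SIZE,
) -> list[tuple[float, float]]:
    """Centres of the eight outer AOI cells (a-d, f-i), row-major."""
    l, t, r, b = face_box
    w, h = scene
    xs = (l / 2.0, (l + r) / 2.0, (r + w) / 2.0)
    ys = (t / 2.0, (t + b) / 2.0, (b + h) / 2.0)
    return [
        (xs[col], ys[row])
        for row in range(3)
        for col in range(3)
        if not (row == 1 and col == 1)
    ]


_FACE_CENTER = ((FACE_BOX[0] + FACE_BOX[2]) / 2.0, (FACE_BOX[1] + FACE_BOX[3]) / 2.0)


def _gamma_duration(rng: np.random.Generator, mean: float, shape: float) -> float:
    return float(rng.gamma(shape, mean / shape))


def _draw_anchor(rng: np.random.Generator, direction: str) -> tuple[float, float]:
    if direction == FACE_GAZE:
        return _FACE_CENTER
    cells = _cell_anchors()
    return cells[int(rng.integers(len(cells)))]


def generate_gaze_stream(
    params: RoleParams,
    duration_ms: float,
    seed: int | np.random.Generator,
) -> tuple[list[GazeState], pd.DataFrame]:
    """Alternating face-gaze/aversion path plus the raw 30 Hz samples.

    State durations are gamma with the role's means and shape.  Samples
    are placed at the state's anchor — the face centre for face gaze, a
    uniformly chosen outer-cell centre for aversion — plus uniform jitter
    within a disc of radius :data:`JITTER_PX`.
    """
    if duration_ms < 0:
        raise ValueError("duration_ms must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    path: list[GazeState] = []
    t = 0.0
    direction = FACE_GAZE if rng.random() < 0.5 else AVERSION
    while t < duration_ms:
        mean = (
            params.mean_face_gaze_ms if direction == FACE_GAZE else params.mean_aversion_ms
        )
        d = _gamma_duration(rng, mean, params.duration_shape)
        end = min(t + d, duration_ms)
        path.append(GazeState(direction, t, end, _draw_anchor(rng, direction)))
        t = end
        direction = AVERSION if direction == FACE_GAZE else FACE_GAZE
    samples = samples_from_path(path, duration_ms, rng)
    return path, samples


def samples_from_path(
    path: list[GazeState],
    duration_ms: float,
    seed: int | np.random.Generator,
    jitter_px: float = JITTER_PX,
) -> pd.DataFrame:
    """Raw gaze samples on the nominal 30 Hz grid for a given state path."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(math.ceil(duration_ms / FRAME_MS)) if duration_ms > 0 else 0
    t = np.arange(n) * FRAME_MS
    t = t[t < duration_ms]
    n = len(t)
    x = np.empty(n)
    y = np.empty(n)
    starts = np.array([s.start_ms for s in path]) if path else np.array([0.0])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, max(len(path) - 1, 0))
    # uniform jitter in a disc
    r = jitter_px * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    for k in range(n):
        ax, ay = path[idx[k]].anchor
        x[k] = ax + r[k] * np.cos(theta[k])
        y[k] = ay + r[k] * np.sin(theta[k])
    return pd.DataFrame(
        {"t_ms": t, "x_px": x, "y_px": y, "valid": np.ones(n, dtype=bool)}
    )


def path_direction_at(path: list[GazeState], t_ms: float) -> str:
    """Ground-truth direction at a time point (states are [start, end))."""
    for s in path:
        if s.start_ms <= t_ms < s.end_ms:
            return s.direction
    return "missing"


# --- speech ---------------------------------------------------------------


def _draw_tag_duration(
    rng: np.random.Generator, params: RoleParams, tag: str
) -> float:
    mean, shape = params.tag_duration_params.get(tag, (500.0, 4.0))
    d = _gamma_duration(rng, mean, shape)
    if tag == _T.MICRO_PAUSE.value:
        while d > MICRO_PAUSE_MAX_MS:  # micro pauses are <= 200 ms by definition
            d = _gamma_duration(rng, mean, shape)
    return max(d, 10.0)


def generate_speech_tags(
    params: RoleParams,
    duration_ms: float,
    seed: int | np.random.Generator,
    sender: str | None = None,
    start_ms: float = 0.0,
) -> list[SpeechSegment]:
    """Contiguous speech tag segments tiling ``[start_ms, start_ms + duration_ms)``.

    Tags follow the role's transition-weight chain; durations are gamma
    with per-tag means, micro pauses capped at 200 ms.
    """
    if duration_ms < 0:
        raise ValueError("duration_ms must be >= 0")
    if not params.tag_transition_weights:
        raise VocabularyError("role has no tag transition weights")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sender = sender or params.role
    tags = list(params.tag_transition_weights)
    tag = tags[0]
    out: list[SpeechSegment] = []
    t = start_ms
    end_total = start_ms + duration_ms
    while t < end_total:
        d = _draw_tag_duration(rng, params, tag)
        seg_end = min(t + d, end_total)
        if seg_end > t:
            out.append(SpeechSegment(sender=sender, tag=tag, start_ms=t, end_ms=seg_end))
        t = seg_end
        row = params.tag_transition_weights.get(tag)
        if not row:
            tag = tags[0]
            continue
        choices = list(row)
        w = np.array([row[c] for c in choices], dtype=float)
        tag = choices[int(rng.choice(len(choices), p=w / w.sum()))]
    return out


def generate_dialogue(
    interviewer: RoleParams,
    interviewee: RoleParams,
    duration_ms: float,
    seed: int | np.random.Generator,
    mean_turn_ms: dict[str, float] | None = None,
) -> list[SpeechSegment]:
    """A joint turn-alternating segment stream for the pair.

    The interviewer opens (greeting, reading a question); turns alternate
    with role-specific mean lengths — interviewee turns are longer, since
    answering dominates a mock job interview.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mean_turn_ms = mean_turn_ms or {INTERVIEWER: 7000.0, INTERVIEWEE: 14000.0}
    out: list[SpeechSegment] = []
    t = 0.0
    role_params = {INTERVIEWER: interviewer, INTERVIEWEE: interviewee}
    role = INTERVIEWER
    while t < duration_ms:
        turn = _gamma_duration(rng, mean_turn_ms[role], 2.0)
        turn = min(turn, duration_ms - t)
        out.extend(
            generate_speech_tags(role_params[role], turn, rng, sender=role, start_ms=t)
        )
        t += turn
        role = INTERVIEWEE if role == INTERVIEWER else INTERVIEWER
    return out


# --- coupling -------------------------------------------------------------


def _tag_bias_track(
    segments: list[SpeechSegment], coupling: CouplingSpec
) -> tuple[np.ndarray, np.ndarray]:
    """(start times, bias values) of the piecewise-constant bias signal."""
    segs = sorted(segments, key=lambda s: s.start_ms)
    starts = np.array([s.start_ms for s in segs])
    biases = np.array(
        [coupling.tag_aversion_bias.get(s.tag, 0.0) for s in segs], dtype=float
    )
    return starts, biases


def couple_gaze_to_speech(
    gaze_path: list[GazeState],
    segments: list[SpeechSegment],
    coupling: CouplingSpec,
    seed: int | np.random.Generator,
    params: RoleParams | None = None,
) -> list[GazeState]:
    """Regenerate a gaze path whose state durations track the speech tags.

    With strength 0 the input path is returned unchanged.  Otherwise a new
    alternating path is drawn in which, at each state entry, the mean
    aversion duration is scaled by ``exp(strength * bias)`` and the mean
    face-gaze duration by ``exp(-strength * bias)``, where ``bias`` is the
    active tag's aversion bias (0 for unbiased tags).

    ``params`` supplies the baseline means and gamma shape; when omitted
    they are recovered from the input path by the method of moments.
    """
    if coupling.strength == 0.0:
        return gaze_path
    if not gaze_path:
        return gaze_path
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if params is not None:
        mean_fg, mean_av = params.mean_face_gaze_ms, params.mean_aversion_ms
        shape = params.duration_shape
    else:
        durs = {FACE_GAZE: [], AVERSION: []}
        for s in gaze_path:
            durs[s.direction].append(s.end_ms - s.start_ms)
        mean_fg = float(np.mean(durs[FACE_GAZE])) if durs[FACE_GAZE] else 600.0
        mean_av = float(np.mean(durs[AVERSION])) if durs[AVERSION] else 300.0
        alldur = np.array(durs[FACE_GAZE] + durs[AVERSION])
        m, v = alldur.mean(), alldur.var()
        shape = float(np.clip(m * m / v, 1.0, 50.0)) if v > 0 else 6.0

    duration_ms = gaze_path[-1].end_ms
    start_ms = gaze_path[0].start_ms
    starts, biases = _tag_bias_track(segments, coupling)

    def bias_at(t: float) -> float:
        if len(starts) == 0:
            return 0.0
        i = int(np.searchsorted(starts, t, side="right")) - 1
        return float(biases[i]) if i >= 0 else 0.0

    s = coupling.strength
    out: list[GazeState] = []
    t = start_ms
    direction = gaze_path[0].direction
    while t < duration_ms:
        b = bias_at(t)
        if direction == AVERSION:
            mean = mean_av * math.exp(s * b)
        else:
            mean = mean_fg * math.exp(-s * b)
        d = _gamma_duration(rng, mean, shape)
        end = min(t + d, duration_ms)
        out.append(GazeState(direction, t, end, _draw_anchor(rng, direction)))
        t = end
        direction = AVERSION if direction == FACE_GAZE else FACE_GAZE
    return out


# --- gaps -----------------------------------------------------------------


def inject_gaps(
    samples: pd.DataFrame,
    gap_rate: float,
    gap_length_dist=None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Clear validity flags over Poisson-started tracking-loss runs.

    ``gap_rate`` is the expected number of gaps per second; gap lengths
    (ms) are drawn from ``gap_length_dist(rng)``.  The default emulates
    sub-blink single-sample dropouts (uniform on [5, 30] ms), which the
    75 ms interpolation rule repairs completely; blink-scale or occlusion
    losses are modelled by passing a longer-tailed distribution.  The
    first and last samples always stay valid so every gap is interior.
    """
    df = samples.reset_index(drop=True).copy()
    if gap_rate < 0:
        raise ValueError("gap_rate must be >= 0")
    if gap_rate == 0 or len(df) < 3:
        return df
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if gap_length_dist is None:
        gap_length_dist = lambda r: r.uniform(5.0, 30.0)  # noqa: E731
    t = df["t_ms"].to_numpy(dtype=float)
    valid = df["valid"].to_numpy(dtype=bool).copy()
    total_s = (t[-1] - t[0]) / 1000.0
    n_gaps = rng.poisson(gap_rate * total_s)
    for _ in range(n_gaps):
        g0 = rng.uniform(t[0], t[-1])
        g1 = g0 + float(gap_length_dist(rng))
        valid[(t >= g0) & (t < g1)] = False
    valid[0] = True
    valid[-1] = True
    df["valid"] = valid
    return df


# --- sessions -------------------------------------------------------------


@dataclass(frozen=True)
class SessionConfig:
    """Knobs of one synthetic pair recording."""

    session_id: str = "S01"
    duration_ms: float = 580_000.0  # the study's mean session length scale
    seed: int = 0
    offset_ms: float = 500.0  # recording B clock minus recording A clock
    base_a_ms: float = 500.0  # beep time on recording A's clock
    interviewer: RoleParams | None = None
    interviewee: RoleParams | None = None
    coupling_interviewer: CouplingSpec | None = None
    coupling_interviewee: CouplingSpec | None = None
    coupling_strength: float = 1.0
    gap_rate: float = 0.1  # gaps per second
    gap_length_dist: object = None
    interviewer_gender: str = "F"
    interviewee_gender: str = "F"


@dataclass(frozen=True)
class ParticipantRecording:
    """One participant's raw files, timestamps on that recording's clock."""

    role: str
    gender: str
    samples: pd.DataFrame
    faces: dict[int, FaceObservation]
    segments: list[SpeechSegment]
    beep_ms: float


@dataclass(frozen=True)
class GroundTruth:
    role_params: dict[str, RoleParams]
    coupling: dict[str, CouplingSpec]
    segments: list[SpeechSegment]  # global clock (0 = beep)
    state_paths: dict[str, list[GazeState]]  # global clock
    frame_directions: dict[str, list[str]]
    n_frames: int
    offset_ms: float


@dataclass(frozen=True)
class SyntheticSession:
    session_id: str
    duration_ms: float
    participants: dict[str, ParticipantRecording]
    ground_truth: GroundTruth

    @property
    def beep_a_ms(self) -> float:
        return self.participants[INTERVIEWER].beep_ms

    @property
    def beep_b_ms(self) -> float:
        return self.participants[INTERVIEWEE].beep_ms


def generate_session(config: SessionConfig) -> SyntheticSession:
    """Generate one synchronized pair recording with full ground truth.

    Global time 0 is the beep; recording A (interviewer) runs
    ``base_a_ms`` ahead of global time and recording B a further
    ``offset_ms`` ahead, so ``beep_b - beep_a = offset_ms`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    iwer = config.interviewer or default_role_params(
        INTERVIEWER, config.interviewer_gender
    )
    iwee = config.interviewee or default_role_params(
        INTERVIEWEE, config.interviewee_gender
    )
    coupling = {
        INTERVIEWER: config.coupling_interviewer
        or default_coupling(INTERVIEWER, config.coupling_strength),
        INTERVIEWEE: config.coupling_interviewee
        or default_coupling(INTERVIEWEE, config.coupling_strength),
    }
    segments = generate_dialogue(iwer, iwee, config.duration_ms, rng)

    params = {INTERVIEWER: iwer, INTERVIEWEE: iwee}
    bases = {
        INTERVIEWER: config.base_a_ms,
        INTERVIEWEE: config.base_a_ms + config.offset_ms,
    }
    n_frames = int(math.ceil(config.duration_ms / FRAME_MS))
    participants: dict[str, ParticipantRecording] = {}
    paths: dict[str, list[GazeState]] = {}
    frame_dirs: dict[str, list[str]] = {}
    for pid in (INTERVIEWER, INTERVIEWEE):
        path, _ = generate_gaze_stream(params[pid], config.duration_ms, rng)
        path = couple_gaze_to_speech(
            path, segments, coupling[pid], rng, params=params[pid]
        )
        paths[pid] = path
        frame_dirs[pid] = [
            path_direction_at(path, (k + 0.5) * FRAME_MS) for k in range(n_frames)
        ]
        samples = samples_from_path(path, config.duration_ms, rng)
        samples = inject_gaps(
            samples, config.gap_rate, config.gap_length_dist, rng
        )
        samples["t_ms"] = samples["t_ms"] + bases[pid]
        faces = {
            int(math.floor(t / FRAME_MS)): FaceObservation(
                frame_index=int(math.floor(t / FRAME_MS)), face_box=FACE_BOX
            )
            for t in samples["t_ms"]
        }
        local_segments = [
            replace(s, start_ms=s.start_ms + bases[pid], end_ms=s.end_ms + bases[pid])
            for s in segments
        ]
        participants[pid] = ParticipantRecording(
            role=pid,
            gender=params[pid].gender,
            samples=samples,
            faces=faces,
            segments=local_segments,
            beep_ms=bases[pid],
        )

    return SyntheticSession(
        session_id=config.session_id,
        duration_ms=config.duration_ms,
        participants=participants,
        ground_truth=GroundTruth(
            role_params=params,
            coupling=coupling,
            segments=segments,
            state_paths=paths,
            frame_directions=frame_dirs,
            n_frames=n_frames,
            offset_ms=config.offset_ms,
        ),
    )


def write_session(session: SyntheticSession, outdir) -> None:
    """Write the standard input files of one session as delimited text.

    Per participant: ``gaze_<id>.tsv`` (t_ms, x_px, y_px, valid),
    ``faces_<id>.tsv`` (frame_index, left, top, right, bottom),
    ``segments_<id>.tsv``; plus ``meta.txt`` with roles, genders, beep
    times and the session id as plain key-value lines.
    """
    from pathlib import Path

    from .speech_annotation import write_segments

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_lines = [f"session_id\t{session.session_id}", f"duration_ms\t{session.duration_ms:g}"]
    for pid, rec in session.participants.items():
        df = rec.samples.copy()
        df["valid"] = df["valid"].astype(int)
        df.to_csv(outdir / f"gaze_{pid}.tsv", sep="\t", index=False)
        rows = [
            (idx, *obs.face_box) for idx, obs in sorted(rec.faces.items())
        ]
        pd.DataFrame(
            rows, columns=["frame_index", "left", "top", "right", "bottom"]
        ).to_csv(outdir / f"faces_{pid}.tsv", sep="\t", index=False)
        write_segments(rec.segments, outdir / f"segments_{pid}.tsv")
        meta_lines += [
            f"role_{pid}\t{rec.role}",
            f"gender_{pid}\t{rec.gender}",
            f"beep_ms_{pid}\t{rec.beep_ms:g}",
        ]
    (outdir / "meta.txt").write_text("\n".join(meta_lines) + "\n")


def session_offset(session: SyntheticSession) -> SyncOffset:
    """The pair's clock offset as recovered from the beep markers."""
    return SyncOffset(offset_ms=session.beep_b_ms - session.beep_a_ms)
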