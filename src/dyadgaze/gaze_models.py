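"""Windowed one-hot encoding and the 1D CNN gaze-direction models.

The models predict one participant's gaze direction (face gaze vs
aversion, default target: the interviewer) at a frame from the speech and
gaze features of the 9 preceding frames (one frame = 33.3 ms; the window
roughly spans a mean aversion, ~300 ms; the stride of 3 frames spans the
100 ms minimum fixation).

Two feature profiles are shipped:

* ``speechtag20`` — 20 channels: the 14 speech tags, sender (2), sender
  gender (2), an is-same-person flag, and the partner's gaze direction.
* ``dialogueact137`` — 137 channels over the ISO 24617-2 attribute
  bundle: communicative function (56), dimension (9), qualifiers,
  rhetorical relation (18) and argument number, dependence offsets, plus
  the four shared channels above.  The profile is the single source of
  truth for the decomposition; the encoder asserts the total.

Two architectures mirror the VGG and ResNet block patterns in 1D:
``gazeVGG`` (plain convolution blocks) and ``gazeResNet`` (residual
connections across blocks, 1x1 projection where channel counts change).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .gaze_preprocess import AVERSION, FACE_GAZE, MISSING
from .vocab import (
    CERTAINTY_VALUES,
    COMMUNICATIVE_FUNCTIONS,
    DIMENSIONS,
    RHETORICAL_RELATIONS,
    SENTIMENT_VALUES,
    SPEECH_TAGS,
)

#: Class codes of the binary target.
LABEL_FACE_GAZE = 0
LABEL_AVERSION = 1


@dataclass(frozen=True)
class ChannelGroup:
    """One one-hot group: a frame column and its category vocabulary."""

    name: str
    column: str
    categories: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class FeatureConfig:
    scheme: str
    groups: tuple[ChannelGroup, ...]

    @property
    def total_channels(self) -> int:
        return sum(g.size for g in self.groups)


_SHARED_GROUPS = (
    ChannelGroup("sender", "sender", ("interviewer", "interviewee")),
    ChannelGroup("sender_gender", "sender_gender", ("F", "M")),
    ChannelGroup("is_same_person", "is_same_person", ("1",)),
    ChannelGroup("partner_gaze", "partner_gaze_fg", ("1",)),
)

SPEECHTAG20 = FeatureConfig(
    scheme="speechtag",
    groups=(ChannelGroup("speech_tag", "tag", SPEECH_TAGS),) + _SHARED_GROUPS,
)

DIALOGUEACT137 = FeatureConfig(
    scheme="dialogueact",
    groups=_SHARED_GROUPS
    + (
        ChannelGroup(
            "communicative_function", "communicative_function", COMMUNICATIVE_FUNCTIONS
        ),
        ChannelGroup("dimension", "dimension", DIMENSIONS),
        ChannelGroup("certainty", "certainty", CERTAINTY_VALUES[1:]),
        ChannelGroup("sentiment", "sentiment", SENTIMENT_VALUES[1:]),
        ChannelGroup(
            "functional_dependence",
            "functional_dep_offset",
            tuple(str(i) for i in range(1, 21)),
        ),
        ChannelGroup(
            "feedback_dependence",
            "feedback_dep_offset",
            tuple(str(i) for i in range(1, 21)),
        ),
        ChannelGroup("rhetorical_relation", "rhetorical_relation", RHETORICAL_RELATIONS),
        ChannelGroup("rr_argument", "rr_argument", ("1", "2")),
    ),
)
assert SPEECHTAG20.total_channels == 20
assert DIALOGUEACT137.total_channels == 137

PROFILES = {"speechtag20": SPEECHTAG20, "dialogueact137": DIALOGUEACT137}


def add_model_columns(
    frames: pd.DataFrame,
    genders: dict[str, str],
    predicted: str = "interviewer",
) -> pd.DataFrame:
    """Add the shared model channels to a frame table.

    ``sender_gender`` is the gender of the frame's speech sender;
    ``is_same_person`` flags frames whose sender is the predicted
    participant; ``partner_gaze_fg`` flags face gaze of the *other*
    participant (the non-predicted one).
    """
    out = frames.copy()
    out["sender_gender"] = [genders.get(s, "") for s in out["sender"]]
    out["is_same_person"] = ["1" if s == predicted else "0" for s in out["sender"]]
    partner = next(
        c[len("gaze_") :]
        for c in out.columns
        if c.startswith("gaze_") and c != f"gaze_{predicted}"
    )
    out["partner_gaze_fg"] = [
        "1" if g == FACE_GAZE else "0" for g in out[f"gaze_{partner}"]
    ]
    return out


def encode_features(frames: pd.DataFrame, config: FeatureConfig) -> np.ndarray:
    """One-hot encode a frame table to a (frames x channels) binary matrix.

    Each categorical attribute occupies its group's channels; an empty /
    absent value leaves the group all-zero.  A non-empty value outside the
    group's vocabulary raises, naming the value and the group.
    """
    n = len(frames)
    out = np.zeros((n, config.total_channels))
    offset = 0
    for group in config.groups:
        index = {c: i for i, c in enumerate(group.categories)}
        col = frames[group.column].astype(str).to_numpy()
        for row, value in enumerate(col):
            if value in ("", "0", "nan"):
                continue
            i = index.get(value)
            if i is None:
                raise ValueError(
                    f"value {value!r} not in the vocabulary of group "
                    f"{group.name!r} ({config.scheme})"
                )
            out[row, offset + i] = 1.0
        offset += group.size
    return out


def frame_labels(frames: pd.DataFrame, predicted: str = "interviewer") -> np.ndarray:
    """Per-frame binary target: 1 = aversion, 0 = face gaze, -1 = missing."""
    gaze = frames[f"gaze_{predicted}"].to_numpy()
    out = np.full(len(gaze), -1, dtype=int)
    out[gaze == FACE_GAZE] = LABEL_FACE_GAZE
    out[gaze == AVERSION] = LABEL_AVERSION
    return out


# --- windowing ------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    window: int = 9
    stride: int = 3

    def __post_init__(self) -> None:
        if self.window < 1 or self.stride < 1:
            raise ValueError("window and stride must be >= 1")


@dataclass(frozen=True)
class WindowSample:
    features: np.ndarray  # (window, channels) in {0, 1}
    label: int
    session_id: str
    end_frame: int
    fold_id: int | None = None


class EmptyDatasetError(ValueError):
    pass


def window_count(n_frames: int, spec: WindowSpec) -> int:
    if n_frames < spec.window:
        return 0
    return (n_frames - spec.window) // spec.stride + 1


def flatten_dim(spec: WindowSpec, config: FeatureConfig) -> int:
    """Flattened input dimensionality: window x channels (9 x 20 = 180)."""
    return spec.window * config.total_channels


def make_windows(
    matrix: np.ndarray,
    labels: np.ndarray,
    spec: WindowSpec,
    session_id: str = "S",
) -> list[WindowSample]:
    """Slide a window over one session's frame matrix.

    Sample ``i`` covers frames ``[i*stride, i*stride + window)``; its
    label is the predicted participant's direction at the last covered
    frame.  Windows whose label frame is missing (label < 0) are dropped.
    """
    out = []
    for i in range(window_count(len(matrix), spec)):
        lo = i * spec.stride
        hi = lo + spec.window
        label = int(labels[hi - 1])
        if label < 0:
            continue
        out.append(
            WindowSample(
                features=matrix[lo:hi],
                label=label,
                session_id=session_id,
                end_frame=hi - 1,
            )
        )
    return out


def make_windows_multi(
    sessions: list[tuple[str, np.ndarray, np.ndarray]],
    spec: WindowSpec,
) -> list[WindowSample]:
    """Window several sessions; windows never cross session boundaries."""
    out = []
    for sid, matrix, labels in sessions:
        out.extend(make_windows(matrix, labels, spec, session_id=sid))
    if not out:
        raise EmptyDatasetError(
            "no windows: every session is shorter than the window"
        )
    return out


def stack_windows(samples: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.features for s in samples])
    y = np.array([s.label for s in samples], dtype=float)
    return x, y


# --- architectures --------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    architecture: str = "gazeResNet"
    first_block_filters: int = 32
    epochs: int = 100
    batch_size: int = 64
    dropout: float = 0.2
    l2: float = 0.001
    learning_rate: float = 1e-3
    seed: int = 0


def _check_filters(filters: int) -> None:
    if filters not in (16, 32):
        warnings.warn(
            f"first-block filter count {filters} is outside the tuned grid "
            "{16, 32}",
            stacklevel=3,
        )


def build_gazevgg(
    input_shape: tuple[int, int],
    filters: int = 32,
    dropout: float = 0.2,
    seed: int = 0,
) -> nn.Model:
    """VGG-style 1D CNN: two plain blocks of two convolutions each.

    Kernel size 3, channel doubling in the second block, max pooling of 2
    and dropout after each block, a 64-unit dense layer, sigmoid output.
    L2 weight-and-bias regularization applies to all conv/dense layers
    (enforced by the optimizer's decay term).
    """
    _check_filters(filters)
    window, channels = input_shape
    rng = np.random.default_rng(seed)
    f = filters
    layers: list[nn.Layer] = [
        nn.Conv1D(channels, f, 3, rng=rng), nn.BatchNorm(f), nn.ReLU(),
        nn.Conv1D(f, f, 3, rng=rng), nn.BatchNorm(f), nn.ReLU(),
        nn.MaxPool1D(2), nn.Dropout(dropout),
        nn.Conv1D(f, 2 * f, 3, rng=rng), nn.BatchNorm(2 * f), nn.ReLU(),
        nn.Conv1D(2 * f, 2 * f, 3, rng=rng), nn.BatchNorm(2 * f), nn.ReLU(),
        nn.MaxPool1D(2), nn.Dropout(dropout),
        nn.Flatten(),
    ]
    flat = (window // 2 // 2) * 2 * f
    layers += [
        nn.Dense(flat, 64, rng=rng), nn.ReLU(), nn.Dropout(dropout),
        nn.Dense(64, 1, rng=rng), nn.Sigmoid(),
    ]
    return nn.Model(layers, name="gazeVGG")


def build_gazeresnet(
    input_shape: tuple[int, int],
    filters: int = 32,
    dropout: float = 0.2,
    seed: int = 0,
) -> nn.Model:
    """ResNet-style 1D CNN: two residual units bridged by a convolution.

    Each residual unit wraps two kernel-3 convolutions with batchnorm and
    adds the unit input back before the final ReLU; the between-block
    convolution doubles the channel count, and the second unit keeps an
    identity shortcut (a 1x1 projection would be inserted automatically if
    its channel counts differed).
    """
    _check_filters(filters)
    window, channels = input_shape
    rng = np.random.default_rng(seed)
    f = filters

    def res_unit(ch_in: int, ch_out: int) -> nn.Residual:
        body: list[nn.Layer] = [
            nn.Conv1D(ch_in, ch_out, 3, rng=rng), nn.BatchNorm(ch_out), nn.ReLU(),
            nn.Conv1D(ch_out, ch_out, 3, rng=rng), nn.BatchNorm(ch_out),
        ]
        return nn.Residual(body, ch_in, ch_out, rng=rng)

    layers: list[nn.Layer] = [
        nn.Conv1D(channels, f, 3, rng=rng), nn.BatchNorm(f), nn.ReLU(),
        res_unit(f, f),
        nn.MaxPool1D(2), nn.Dropout(dropout),
        nn.Conv1D(f, 2 * f, 3, rng=rng), nn.BatchNorm(2 * f), nn.ReLU(),
        res_unit(2 * f, 2 * f),
        nn.MaxPool1D(2), nn.Dropout(dropout),
        nn.Flatten(),
    ]
    flat = (window // 2 // 2) * 2 * f
    layers += [
        nn.Dense(flat, 64, rng=rng), nn.ReLU(), nn.Dropout(dropout),
        nn.Dense(64, 1, rng=rng), nn.Sigmoid(),
    ]
    return nn.Model(layers, name="gazeResNet")


def build_model(config: TrainConfig, input_shape: tuple[int, int]) -> nn.Model:
    builder = {
        "gazeVGG": build_gazevgg,
        "gazeResNet": build_gazeresnet,
    }.get(config.architecture)
    if builder is None:
        raise ValueError(f"unknown architecture {config.architecture!r}")
    return builder(
        input_shape, filters=config.first_block_filters,
        dropout=config.dropout, seed=config.seed,
    )


# --- training -------------------------------------------------------------


def train(
    model: nn.Model,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    verbose: bool = False,
) -> dict[str, list[float]]:
    """Minimize binary cross-entropy with Adam; returns per-epoch history.

    Deterministic under ``config.seed`` (shuffling and dropout masks both
    draw from one seeded generator).  History keys: ``loss``, ``accuracy``
    and, when a validation set is given, ``val_loss``, ``val_accuracy``.
    """
    rng = np.random.default_rng(config.seed)
    model.seed_dropout(rng)
    opt = nn.Adam(model.params(), lr=config.learning_rate, l2=config.l2)
    n = len(x)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if x_val is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward_logits(xb, train=True).ravel()
            p = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
            losses.append(nn.binary_cross_entropy(p, yb))
            correct += int(((p >= 0.5) == (yb >= 0.5)).sum())
            model.zero_grad()
            model.backward_from_logits(((p - yb) / len(yb)).reshape(-1, 1))
            opt.step()
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
        if x_val is not None:
            pv = model.predict_proba(x_val)
            history["val_loss"].append(nn.binary_cross_entropy(pv, y_val))
            history["val_accuracy"].append(
                float(np.mean((pv >= 0.5) == (y_val >= 0.5)))
            )
        if verbose:
            msg = f"epoch {epoch + 1}/{config.epochs} loss {history['loss'][-1]:.4f}"
            if x_val is not None:
                msg += f" val_acc {history['val_accuracy'][-1]:.3f}"
            print(msg)
    return history


def accuracy(model: nn.Model, x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(model.predict(x) == np.asarray(y, dtype=int)))


# --- validation splits ----------------------------------------------------


def backtest_splits(sessions: list, n: int) -> list[tuple[list, list]]:
    """Expanding-window time-series splits over ordered session blocks.

    The sessions are cut into ``n + 1`` contiguous blocks; split ``k``
    (1-based) trains on the first ``k`` blocks and validates on block
    ``k + 1``, so the train:validation block ratio of split ``k`` is
    ``k`` (5 for the fifth split, 1 for the first).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(sessions) < n + 1:
        raise ValueError(f"need at least {n + 1} sessions for {n} splits")
    blocks = [list(b) for b in np.array_split(np.asarray(sessions, dtype=object), n + 1)]
    out = []
    for k in range(1, n + 1):
        train_set = [s for b in blocks[:k] for s in b]
        out.append((train_set, blocks[k]))
    return out


def session_shuffled_cv(sessions: list, k: int = 5, seed: int = 0) -> list[list]:
    """Session-level k-fold assignment with a seeded session shuffle.

    The session order is permuted (temporal order *within* each session is
    untouched — folds partition whole sessions) and cut into ``k``
    validation folds: disjoint, jointly exhaustive.
    """
    if not 1 <= k <= len(sessions):
        raise ValueError("k must be between 1 and the number of sessions")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sessions))
    return [
        [sessions[i] for i in fold] for fold in np.array_split(perm, k)
    ]


def cv_train_sets(folds: list[list]) -> list[tuple[list, list]]:
    """(train sessions, validation sessions) pairs from validation folds."""
    out = []
    for i, val in enumerate(folds):
        train_set = [s for j, f in enumerate(folds) if j != i for s in f]
        out.append((train_set, val))
    return out
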