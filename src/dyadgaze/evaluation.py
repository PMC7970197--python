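"""Metrics and descriptive statistics.

Conventions: the binary gaze-direction target codes face gaze as 0 and
aversion as 1; aversion is the positive class of precision/recall/F
(being the rarer, behaviourally marked direction), configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gaze_preprocess import AVERSION, FACE_GAZE, FRAME_MS, Fixation
from .multimodal_merge import mutual_face_gaze


@dataclass(frozen=True)
class ConfusionPercent:
    """2x2 row-percentage confusion matrix, rows = actual class.

    Row order (face gaze, aversion); each non-empty row sums to 100.
    """

    matrix: np.ndarray
    counts: np.ndarray


def confusion_percent(actual, predicted) -> ConfusionPercent:
    """Row-normalized percentage confusion matrix from label sequences."""
    a = np.asarray(actual, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    counts = np.zeros((2, 2), dtype=int)
    for i in range(2):
        for j in range(2):
            counts[i, j] = int(np.sum((a == i) & (p == j)))
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    return ConfusionPercent(matrix=matrix, counts=counts)


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f_score: float
    degenerate: bool  # a zero denominator was reported as 0, not dropped


def precision_recall_f(actual, predicted, positive: int = 1) -> PRF:
    """Precision, recall and F for the positive class (default: aversion).

    F is the harmonic mean of precision and recall.  Zero-denominator
    cases (no predicted positives / no actual positives / P = R = 0) are
    reported as 0 with ``degenerate`` set, never silently dropped.
    """
    a = np.asarray(actual, dtype=int)
    p = np.asarray(predicted, dtype=int)
    tp = int(np.sum((a == positive) & (p == positive)))
    fp = int(np.sum((a != positive) & (p == positive)))
    fn = int(np.sum((a == positive) & (p != positive)))
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    f_score, d = f_harmonic(precision, recall)
    return PRF(precision, recall, f_score, degenerate or d)


def f_harmonic(precision: float, recall: float) -> tuple[float, bool]:
    """Harmonic mean of precision and recall; (0, True) when both are 0."""
    if precision + recall == 0:
        return 0.0, True
    return 2.0 * precision * recall / (precision + recall), False


@dataclass(frozen=True)
class RoleDescriptives:
    face_gaze_per_min: float
    aversion_per_min: float
    mean_face_gaze_ms: float
    mean_aversion_ms: float
    n_face_gaze: int
    n_aversion: int


@dataclass(frozen=True)
class DescriptiveSummary:
    per_role: dict[str, RoleDescriptives]
    mutual_fraction: float
    mutual_mean_ms: float
    session_minutes: float


def _role_stats(fixations: list[Fixation], minutes: float) -> RoleDescriptives:
    fg = [f for f in fixations if f.direction == FACE_GAZE]
    av = [f for f in fixations if f.direction == AVERSION]
    mean = lambda fs: float(np.mean([f.duration_ms for f in fs])) if fs else 0.0  # noqa: E731
    return RoleDescriptives(
        face_gaze_per_min=len(fg) / minutes,
        aversion_per_min=len(av) / minutes,
        mean_face_gaze_ms=mean(fg),
        mean_aversion_ms=mean(av),
        n_face_gaze=len(fg),
        n_aversion=len(av),
    )


def descriptives(
    fixations_by_role: dict[str, list[Fixation]],
    frames,
    duration_ms: float,
) -> DescriptiveSummary:
    """Per-role gaze event rates and durations, plus mutual face gaze.

    Frequencies are fixation counts of each direction normalized by the
    session length in minutes; durations are averaged over fixations
    (``end - start``); the mutual-gaze statistics come from the merged
    frame table.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    minutes = duration_ms / 60_000.0
    per_role = {
        role: _role_stats(fixations, minutes)
        for role, fixations in fixations_by_role.items()
    }
    fraction, mean_ms = mutual_face_gaze(frames)
    return DescriptiveSummary(
        per_role=per_role,
        mutual_fraction=fraction,
        mutual_mean_ms=mean_ms,
        session_minutes=minutes,
    )


@dataclass(frozen=True)
class FoldReport:
    mean: float
    sd: float  # sample standard deviation (ddof = 1)
    folds: list[float] = field(default_factory=list)


def fold_report(fold_accuracies) -> FoldReport:
    """Mean and sample standard deviation of per-fold accuracies."""
    folds = [float(v) for v in fold_accuracies]
    if not folds:
        raise ValueError("no fold accuracies given")
    sd = float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0
    return FoldReport(mean=float(np.mean(folds)), sd=sd, folds=folds)


def estimate_state_duration_ms(
    fixations: list[Fixation],
    direction: str,
    min_duration_ms: float = 100.0,
) -> float:
    """Estimate the mean underlying gaze-state duration from fixations.

    Two corrections on top of the raw fixation spans:

    * end-correction — a span runs from the first to the last 33.3 ms
      sample of a state, underestimating its duration by one sampling
      interval on average, which is added back;
    * truncation correction — states shorter than the minimum fixation
      duration are undetectable, left-censoring the sample.  The
      corrected durations are fitted as a gamma left-truncated at
      ``min_duration_ms`` plus half a frame (the effective detectability
      floor under random sampling phase) by maximum likelihood, and the
      untruncated mean of the fit is returned.

    Falls back to the corrected sample mean when the fit fails or the
    sample is too small to constrain it.
    """
    from scipy import optimize, stats

    durations = np.array(
        [f.duration_ms + FRAME_MS for f in fixations if f.direction == direction]
    )
    if len(durations) == 0:
        return float("nan")
    naive = float(durations.mean())
    if len(durations) < 30:
        return naive
    floor = min_duration_ms + FRAME_MS / 2.0

    def nll(p):
        k, theta = np.exp(p)
        return -(
            stats.gamma.logpdf(durations, k, scale=theta).sum()
            - len(durations) * stats.gamma.logsf(floor, k, scale=theta)
        )

    m, v = durations.mean(), durations.var()
    if v <= 0:
        return naive
    p0 = np.log([max(m * m / v, 1.1), v / m])
    res = optimize.minimize(nll, p0, method="Nelder-Mead")
    if not res.success:
        return naive
    k, theta = np.exp(res.x)
    return float(k * theta)
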