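"""End-to-end orchestration: session -> frame table -> windows -> models.

Each step is a thin composition of the stage modules; the same functions
back the command-line interface and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gaze_preprocess import (
    FRAME_MS,
    CoverageReport,
    Fixation,
    coverage_report,
    detect_fixations,
    frames_to_direction,
    interpolate_gaps,
    label_aoi_track,
)
from .multimodal_merge import build_frame_table
from .speech_annotation import apply_offset, synchronize_pair
from .synthetic_data import SyntheticSession


@dataclass
class PreprocessedRecording:
    fixations: list[Fixation]
    frame_directions: list[str]
    coverage: CoverageReport
    labeled_samples: pd.DataFrame  # global clock


def preprocess_recording(
    samples: pd.DataFrame,
    faces,
    beep_ms: float,
    n_frames: int,
    max_gap_ms: float = 75.0,
    dispersion_px: float = 60.0,
    min_duration_ms: float = 100.0,
    error_margin_px: float = 0.0,
) -> PreprocessedRecording:
    """Interpolate, AOI-label, detect fixations, resample to frames.

    AOI labeling runs on the recording's own clock (face observations are
    indexed by local video frame); timestamps are then shifted so the beep
    marks global time 0, and fixations/frames are computed on that common
    clock.
    """
    local = interpolate_gaps(samples, max_gap_ms=max_gap_ms)
    local = label_aoi_track(local, faces, error_margin_px=error_margin_px)
    aligned = local.copy()
    aligned["t_ms"] = aligned["t_ms"] - beep_ms
    fixations = detect_fixations(
        aligned, dispersion_px=dispersion_px, min_duration_ms=min_duration_ms
    )
    directions = frames_to_direction(fixations, n_frames)
    coverage = coverage_report(list(aligned["aoi"]))
    return PreprocessedRecording(
        fixations=fixations,
        frame_directions=directions,
        coverage=coverage,
        labeled_samples=aligned,
    )


def preprocess_session(
    session: SyntheticSession, **kwargs
) -> dict[str, PreprocessedRecording]:
    """Preprocess both recordings of a pair onto the common beep clock."""
    n_frames = session.ground_truth.n_frames
    return {
        pid: preprocess_recording(
            rec.samples, rec.faces, rec.beep_ms, n_frames, **kwargs
        )
        for pid, rec in session.participants.items()
    }


def session_frame_table(
    session: SyntheticSession,
    preprocessed: dict[str, PreprocessedRecording] | None = None,
    use_ground_truth_gaze: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """The merged speech-tag frame table of one session (global clock).

    Speech segments are taken from recording A, synchronized via the beep
    offset; gaze directions come from the preprocessing chain unless
    ``use_ground_truth_gaze`` asks for the generator's truth.
    """
    gt = session.ground_truth
    if use_ground_truth_gaze:
        directions = gt.frame_directions
    else:
        preprocessed = preprocessed or preprocess_session(session, **kwargs)
        directions = {p: r.frame_directions for p, r in preprocessed.items()}
    rec_a = session.participants["interviewer"]
    offset = synchronize_pair(0.0, rec_a.beep_ms)
    segments = apply_offset(rec_a.segments, offset)
    return build_frame_table(directions, segments, n_frames=gt.n_frames)
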