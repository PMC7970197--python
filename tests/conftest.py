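import numpy as np
import pandas as pd
import pytest

from dyadgaze.gaze_preprocess import AVERSION, FACE_GAZE, FRAME_MS
from dyadgaze.multimodal_merge import build_frame_table
from dyadgaze.speech_annotation import SpeechSegment


def make_samples(t, x, y, valid=None):
    """Gaze sample table from parallel sequences."""
    t = np.asarray(t, dtype=float)
    valid = np.ones(len(t), dtype=bool) if valid is None else np.asarray(valid, bool)
    return pd.DataFrame(
        {"t_ms": t, "x_px": np.asarray(x, float), "y_px": np.asarray(y, float),
         "valid": valid}
    )


@pytest.fixture
def table3_frames():
    """The 95-frame toy session of the worked ratio example.

    Frames (1-based) 1-9 and 46-95 carry speech label S1 ('Thinking'),
    26-45 carry S2 ('Speech'), 10-25 an unrelated filler label.  The
    interviewer's gaze runs: A x6, FG x3 | filler | FG x10, A x10 |
    A x25, FG x11, A x14.
    """
    dirs = (
        [AVERSION] * 6 + [FACE_GAZE] * 3          # frames 1-9 (S1 occ 1)
        + [FACE_GAZE] * 16                        # frames 10-25 (filler)
        + [FACE_GAZE] * 10 + [AVERSION] * 10      # frames 26-45 (S2 occ 1)
        + [AVERSION] * 25 + [FACE_GAZE] * 11 + [AVERSION] * 14  # 46-95 (S1 occ 2)
    )
    assert len(dirs) == 95
    f = FRAME_MS
    segments = [
        SpeechSegment("interviewer", "Thinking", 0 * f, 9 * f),
        SpeechSegment("interviewer", "Speech Pause", 9 * f, 25 * f),
        SpeechSegment("interviewee", "Speech", 25 * f, 45 * f),
        SpeechSegment("interviewer", "Thinking", 45 * f, 95 * f),
    ]
    return build_frame_table(
        {"interviewer": dirs, "interviewee": [FACE_GAZE] * 95}, segments, n_frames=95
    )
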