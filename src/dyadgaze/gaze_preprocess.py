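"""Raw gaze to per-frame gaze-direction labels.

The stages mirror a standard dual mobile eye-tracking workflow:

1. :func:`interpolate_gaps` — linear interpolation over short tracking
   losses (blinks), bounded by a maximum gap span (default 75 ms, shorter
   than a normal blink).
2. :func:`label_aoi` — area-of-interest labeling against the interlocutor's
   face: label ``e`` (face gaze) inside the face region, one of the eight
   outer cells ``a``–``d``, ``f``–``i`` of a 3x3 grid centred on the face
   box otherwise (gaze aversion).
3. :func:`detect_fixations` — dispersion-threshold (I-DT) fixation
   detection with a minimum duration (default 100 ms).
4. :func:`frames_to_direction` — resampling fixations onto the 30 Hz frame
   grid (one frame per 33.3 ms).
5. :func:`coverage_report` — per-recording label coverage and the <70%
   exclusion rule for a pair of recordings.

Gaze sample tables are pandas DataFrames with columns
``t_ms, x_px, y_px, valid`` sorted by ``t_ms``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Nominal frame spacing at 30 Hz, in milliseconds.
FRAME_MS: float = 1000.0 / 30.0

FACE_GAZE = "face_gaze"
AVERSION = "aversion"
MISSING = "missing"

#: AOI letters of the 3x3 grid, row-major; ``e`` is the face cell.
AOI_LETTERS = ("a", "b", "c", "d", "e", "f", "g", "h", "i")
AVERSION_LETTERS = frozenset("abcdfghi")

GAZE_COLUMNS = ("t_ms", "x_px", "y_px", "valid")


class OrderingError(ValueError):
    """Raised when sample timestamps are not strictly increasing."""


@dataclass(frozen=True)
class FaceObservation:
    """The interlocutor's face in one video frame.

    ``landmarks`` is a (68, 2) array of 2D facial landmark pixel
    coordinates when the face tracker produced them; ``face_box`` is the
    (left, top, right, bottom) bounding box, derived from the landmarks
    when they are present.
    """

    frame_index: int
    landmarks: np.ndarray | None = None
    face_box: tuple[float, float, float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.landmarks is not None:
            lm = np.asarray(self.landmarks, dtype=float)
            if lm.shape != (68, 2):
                raise ValueError(f"landmarks must be (68, 2), got {lm.shape}")
            object.__setattr__(self, "landmarks", lm)
            if self.face_box is None:
                box = (lm[:, 0].min(), lm[:, 1].min(), lm[:, 0].max(), lm[:, 1].max())
                object.__setattr__(self, "face_box", box)
        if self.face_box is not None:
            l, t, r, b = self.face_box
            if not (r > l and b > t):
                raise ValueError(f"face box must have positive area: {self.face_box}")

    @property
    def present(self) -> bool:
        return self.face_box is not None


@dataclass(frozen=True)
class Fixation:
    """A dispersion-grouped gaze event."""

    start_ms: float
    end_ms: float
    centroid: tuple[float, float]
    direction: str  # face_gaze | aversion

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def _check_sorted(t: np.ndarray) -> None:
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise OrderingError("sample timestamps must be strictly increasing")


def interpolate_gaps(
    samples: pd.DataFrame,
    max_gap_ms: float = 75.0,
    nominal_dt_ms: float = FRAME_MS,
) -> pd.DataFrame:
    """Fill short invalid runs by linear interpolation between neighbours.

    A gap is a maximal run of invalid samples bounded by valid samples on
    both sides.  Its span is the missing time at the nominal sampling
    rate: the distance between the bounding valid samples minus one
    nominal sampling interval (a single lost 30 Hz sample spans 33.3 ms).
    Gaps whose span is at most ``max_gap_ms`` — shorter than a normal
    blink — are filled: each inner sample gets the position linearly
    interpolated in time between the two valid neighbours (the
    interpolation weight is the ratio of the sample's temporal offset to
    the bounding distance).  Longer gaps, and runs touching the start or
    end of the recording, are left untouched.

    Valid samples are never modified; the operation is idempotent.
    """
    df = samples.reset_index(drop=True).copy()
    t = df["t_ms"].to_numpy(dtype=float)
    _check_sorted(t)
    valid = df["valid"].to_numpy(dtype=bool)
    if valid.all() or not valid.any():
        return df

    x = df["x_px"].to_numpy(dtype=float).copy()
    y = df["y_px"].to_numpy(dtype=float).copy()
    new_valid = valid.copy()

    valid_idx = np.flatnonzero(valid)
    # walk maximal invalid runs between consecutive valid samples
    for left, right in zip(valid_idx[:-1], valid_idx[1:]):
        if right - left < 2:
            continue
        span = t[right] - t[left] - nominal_dt_ms
        if span > max_gap_ms:
            continue
        inner = np.arange(left + 1, right)
        w = (t[inner] - t[left]) / (t[right] - t[left])
        x[inner] = x[left] + w * (x[right] - x[left])
        y[inner] = y[left] + w * (y[right] - y[left])
        new_valid[inner] = True

    df["x_px"] = x
    df["y_px"] = y
    df["valid"] = new_valid
    return df


def _point_in_hull(point: np.ndarray, hull_points: np.ndarray, margin: float) -> bool:
    """Point-in-convex-hull test with an outward dilation margin."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(hull_points)
    # hull.equations: outward normals, normalized; point inside iff all
    # signed distances <= margin
    dist = hull.equations[:, :2] @ point + hull.equations[:, 2]
    return bool(np.all(dist <= margin))


def label_aoi(
    x_px: float,
    y_px: float,
    face: FaceObservation | None,
    error_margin_px: float = 0.0,
    frame_size: tuple[float, float] | None = None,
    valid: bool = True,
) -> str:
    """Assign an AOI letter to one valid gaze point.

    Returns ``e`` when the point falls within the face region — the convex
    hull of the 68 landmarks when available, else the face box — dilated by
    ``error_margin_px`` (the device's angular error expressed in pixels).
    Otherwise the point is mapped to one of the eight outer cells of a 3x3
    grid whose centre cell is the face box, row-major ``a b c / d e f /
    g h i``, with the outer cells extended to the frame edges.  Returns
    ``missing`` when no face was observed.
    """
    if not valid:
        raise ValueError("label_aoi requires a valid gaze sample")
    if face is None or not face.present:
        return MISSING

    point = np.array([x_px, y_px], dtype=float)
    l, t, r, b = face.face_box
    if face.landmarks is not None:
        in_face = _point_in_hull(point, face.landmarks, error_margin_px)
    else:
        in_face = (
            l - error_margin_px <= x_px <= r + error_margin_px
            and t - error_margin_px <= y_px <= b + error_margin_px
        )
    if in_face:
        return "e"
    # outer 3x3 cell, relative to the (undilated) face box
    col = 0 if x_px < l else (2 if x_px > r else 1)
    row = 0 if y_px < t else (2 if y_px > b else 1)
    letter = AOI_LETTERS[row * 3 + col]
    if letter == "e":
        # inside the box corner region but outside the landmark hull:
        # assign the outer cell the point is nearest to by box-edge distance
        d = {  # distance to each edge
            "b": y_px - t,
            "h": b - y_px,
            "d": x_px - l,
            "f": r - x_px,
        }
        letter = min(d, key=d.get)
    return letter


def label_aoi_track(
    samples: pd.DataFrame,
    faces: dict[int, FaceObservation] | list[FaceObservation],
    error_margin_px: float = 0.0,
    frame_ms: float = FRAME_MS,
) -> pd.DataFrame:
    """AOI-label every sample against the face track.

    Each sample is matched to the face observation of the video frame its
    timestamp falls in (``frame_index = floor(t_ms / frame_ms)``).  Invalid
    samples and samples without a face observation get ``missing``.

    Returns the sample table with an added ``aoi`` column.
    """
    if not isinstance(faces, dict):
        faces = {f.frame_index: f for f in faces}
    df = samples.reset_index(drop=True).copy()
    labels = []
    for t, x, y, valid in zip(df["t_ms"], df["x_px"], df["y_px"], df["valid"]):
        if not valid:
            labels.append(MISSING)
            continue
        face = faces.get(int(np.floor(t / frame_ms)))
        labels.append(label_aoi(x, y, face, error_margin_px))
    df["aoi"] = labels
    return df


def apply_manual_overrides(labels: pd.Series, overrides: dict[int, str]) -> pd.Series:
    """Apply a manual AOI override table (frame index -> letter).

    Overrides take precedence over automatic labels, including ``missing``
    ones; everything not named in the table is unchanged.
    """
    out = labels.copy()
    for idx, letter in overrides.items():
        if letter not in AOI_LETTERS and letter != MISSING:
            raise ValueError(f"unknown AOI label {letter!r}")
        out.loc[idx] = letter
    return out


def detect_fixations(
    labeled_samples: pd.DataFrame,
    dispersion_px: float = 60.0,
    min_duration_ms: float = 100.0,
    tie_direction: str = AVERSION,
) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    Scans left to right over the valid, AOI-labeled samples: from the
    current start index the window is extended as far as its bounding-box
    dispersion (width + height) stays within ``dispersion_px``.  If the
    maximal window spans at least ``min_duration_ms`` it becomes a
    fixation and the scan resumes after it; otherwise the start advances
    by one sample.  Invalid or missing-label samples break windows.

    A fixation's direction is ``face_gaze`` when the majority of its
    samples carry AOI letter ``e``, ``aversion`` otherwise; an exact tie
    goes to ``tie_direction``.
    """
    if dispersion_px <= 0 or min_duration_ms <= 0:
        raise ValueError("dispersion_px and min_duration_ms must be positive")
    df = labeled_samples.reset_index(drop=True)
    t_all = df["t_ms"].to_numpy(dtype=float)
    _check_sorted(t_all)
    usable = df["valid"].to_numpy(dtype=bool) & (df["aoi"].to_numpy() != MISSING)

    fixations: list[Fixation] = []
    # split into maximal usable runs; windows never cross a break
    run_bounds = _runs(usable)
    for lo, hi in run_bounds:
        t = t_all[lo:hi]
        x = df["x_px"].to_numpy(dtype=float)[lo:hi]
        y = df["y_px"].to_numpy(dtype=float)[lo:hi]
        is_e = (df["aoi"].to_numpy()[lo:hi] == "e").astype(int)
        n = hi - lo
        i = 0
        while i < n:
            xmin = xmax = x[i]
            ymin = ymax = y[i]
            j = i
            while j + 1 < n:
                nxmin = min(xmin, x[j + 1])
                nxmax = max(xmax, x[j + 1])
                nymin = min(ymin, y[j + 1])
                nymax = max(ymax, y[j + 1])
                if (nxmax - nxmin) + (nymax - nymin) > dispersion_px:
                    break
                xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
                j += 1
            if t[j] - t[i] >= min_duration_ms:
                e_count = int(is_e[i : j + 1].sum())
                non_e = (j - i + 1) - e_count
                if e_count > non_e:
                    direction = FACE_GAZE
                elif e_count < non_e:
                    direction = AVERSION
                else:
                    direction = tie_direction
                fixations.append(
                    Fixation(
                        start_ms=float(t[i]),
                        end_ms=float(t[j]),
                        centroid=(float(x[i : j + 1].mean()), float(y[i : j + 1].mean())),
                        direction=direction,
                    )
                )
                i = j + 1
            else:
                i += 1
    return fixations


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [lo, hi) bounds of maximal True runs."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def frames_to_direction(
    fixations: list[Fixation],
    n_frames: int,
    frame_ms: float = FRAME_MS,
) -> list[str]:
    """Resample fixations onto the frame grid.

    Frame ``k`` covers ``[k * frame_ms, (k+1) * frame_ms)``; it takes the
    direction of the fixation covering its midpoint, or ``missing`` when no
    fixation does.  Fixation intervals are treated as closed.
    """
    out = [MISSING] * n_frames
    if not fixations:
        return out
    starts = np.array([f.start_ms for f in fixations])
    ends = np.array([f.end_ms for f in fixations])
    mids = (np.arange(n_frames) + 0.5) * frame_ms
    # fixations are time-ordered and non-overlapping
    idx = np.searchsorted(starts, mids, side="right") - 1
    for k, i in enumerate(idx):
        if i >= 0 and mids[k] <= ends[i]:
            out[k] = fixations[i].direction
    return out


@dataclass(frozen=True)
class CoverageReport:
    coverage: float
    excluded: bool


def coverage_report(frame_labels: list[str], threshold: float = 0.70) -> CoverageReport:
    """Fraction of frames with a (non-missing) label, and the exclusion flag."""
    n = len(frame_labels)
    if n == 0:
        return CoverageReport(coverage=0.0, excluded=True)
    covered = sum(1 for v in frame_labels if v != MISSING)
    cov = covered / n
    return CoverageReport(coverage=cov, excluded=cov < threshold)


def pair_excluded(
    labels_a: list[str], labels_b: list[str], threshold: float = 0.70
) -> bool:
    """A pair is excluded when either recording's coverage is below threshold."""
    return (
        coverage_report(labels_a, threshold).excluded
        or coverage_report(labels_b, threshold).excluded
    )
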