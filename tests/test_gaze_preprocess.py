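"""Gap interpolation, AOI labeling, I-DT fixation detection, coverage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadgaze.gaze_preprocess import (
    AOI_LETTERS,
    AVERSION,
    FACE_GAZE,
    FRAME_MS,
    MISSING,
    FaceObservation,
    OrderingError,
    apply_manual_overrides,
    coverage_report,
    detect_fixations,
    frames_to_direction,
    interpolate_gaps,
    label_aoi,
    label_aoi_track,
    pair_excluded,
)

from conftest import make_samples

BOX = (100.0, 100.0, 200.0, 200.0)
FACE = FaceObservation(frame_index=0, face_box=BOX)


class TestInterpolateGaps:
    def test_midpoint_fill(self):
        s = make_samples([0, 50, 100], [0, 99, 10], [0, 99, 10], [True, False, True])
        out = interpolate_gaps(s)
        assert out.loc[1, "valid"]
        assert out.loc[1, "x_px"] == pytest.approx(5.0)
        assert out.loc[1, "y_px"] == pytest.approx(5.0)

    def test_long_gap_untouched(self):
        # three lost samples: 100 ms of missing data at 30 Hz, above 75 ms
        t = [0, 33.3, 66.7, 100, 133.3]
        valid = [True, False, False, False, True]
        s = make_samples(t, [0, 9, 9, 9, 10], [0, 9, 9, 9, 10], valid)
        out = interpolate_gaps(s, max_gap_ms=75)
        assert list(out["valid"]) == valid
        # positions of unfilled samples unchanged
        assert out.loc[1, "x_px"] == 9

    def test_quarter_point_weight_matches_linear_oracle(self):
        # sample at 1/4 of the gap: the time-ratio scaling factor must equal
        # an independently computed two-point linear interpolation
        s = make_samples([0, 25, 100], [2, 0, 10], [4, 0, 20], [True, False, True])
        out = interpolate_gaps(s)
        expect_x = np.interp(25, [0, 100], [2, 10])
        expect_y = np.interp(25, [0, 100], [4, 20])
        assert out.loc[1, "x_px"] == pytest.approx(expect_x)
        assert out.loc[1, "y_px"] == pytest.approx(expect_y)

    def test_boundary_gaps_untouched(self):
        s = make_samples([0, 33, 66], [1, 2, 3], [1, 2, 3], [False, True, False])
        out = interpolate_gaps(s)
        assert list(out["valid"]) == [False, True, False]

    def test_unsorted_raises(self):
        s = make_samples([0, 50, 40], [0, 0, 0], [0, 0, 0])
        with pytest.raises(OrderingError):
            interpolate_gaps(s)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.booleans(), min_size=3, max_size=40))
    def test_valid_samples_never_modified_and_idempotent(self, validity):
        n = len(validity)
        rng = np.random.default_rng(7)
        s = make_samples(
            np.arange(n) * FRAME_MS, rng.normal(size=n), rng.normal(size=n), validity
        )
        out = interpolate_gaps(s)
        keep = s["valid"].to_numpy()
        assert np.array_equal(out.loc[keep, "x_px"], s.loc[keep, "x_px"])
        assert np.array_equal(out.loc[keep, "y_px"], s.loc[keep, "y_px"])
        # validity can only grow
        assert np.all(out["valid"].to_numpy() | ~keep | keep)
        assert not np.any(keep & ~out["valid"].to_numpy())
        again = interpolate_gaps(out)
        pd.testing.assert_frame_equal(again, out)


def _grid_cell_oracle(x, y, box):
    """Brute-force 3x3 cell lookup with outer cells to the frame edges."""
    l, t, r, b = box
    col = 0 if x < l else (2 if x > r else 1)
    row = 0 if y < t else (2 if y > b else 1)
    return "abcdefghi"[row * 3 + col]


class TestLabelAoi:
    def test_face_centroid_is_e(self):
        assert label_aoi(150, 150, FACE) == "e"

    def test_above_left_is_a(self):
        assert label_aoi(50, 50, FACE) == "a"

    def test_absent_face_missing(self):
        assert label_aoi(150, 150, None) == MISSING

    def test_invalid_sample_raises(self):
        with pytest.raises(ValueError):
            label_aoi(150, 150, FACE, valid=False)

    @pytest.mark.parametrize("x,y", [(50, 150), (250, 50), (150, 250), (250, 250),
                                     (150, 50), (50, 250), (250, 150), (1, 1)])
    def test_outer_cells_match_grid_oracle(self, x, y):
        assert label_aoi(x, y, FACE) == _grid_cell_oracle(x, y, BOX)

    def test_partition_every_point_gets_one_of_nine(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x, y = rng.uniform(0, 300, size=2)
            assert label_aoi(x, y, FACE) in AOI_LETTERS

    def test_landmark_hull_used_when_present(self):
        # landmarks trace a diamond inscribed in the box: its corners are
        # inside the box but outside the hull -> not face gaze
        theta = np.linspace(0, 2 * np.pi, 68, endpoint=False)
        lm = np.c_[150 + 50 * np.cos(theta), 150 + 50 * np.sin(theta)]
        face = FaceObservation(frame_index=0, landmarks=lm)
        assert label_aoi(150, 150, face) == "e"
        assert label_aoi(104, 104, face) != "e"

    def test_error_margin_dilates_face(self):
        assert label_aoi(210, 150, FACE) == "f"
        assert label_aoi(210, 150, FACE, error_margin_px=15) == "e"


class TestManualOverrides:
    def test_empty_is_identity(self):
        labels = pd.Series(["e", "a", MISSING])
        pd.testing.assert_series_equal(apply_manual_overrides(labels, {}), labels)

    def test_single_override(self):
        labels = pd.Series(["e"] * 12)
        out = apply_manual_overrides(labels, {10: "b"})
        assert out[10] == "b"
        assert (out.drop(10) == "e").all()

    def test_missing_frame_becomes_labeled(self):
        labels = pd.Series([MISSING, "e"])
        out = apply_manual_overrides(labels, {0: "i"})
        assert out[0] == "i"


def _idt_oracle(t, x, y, is_e, dispersion, min_dur):
    """Exhaustive I-DT: max window per start found by full recomputation."""
    fixations = []
    n = len(t)
    i = 0
    while i < n:
        best = None
        for j in range(i, n):
            xs, ys = x[i : j + 1], y[i : j + 1]
            if (max(xs) - min(xs)) + (max(ys) - min(ys)) > dispersion:
                break
            best = j
        if best is not None and t[best] - t[i] >= min_dur:
            e = sum(is_e[i : best + 1])
            direction = FACE_GAZE if e > (best - i + 1 - e) else AVERSION
            fixations.append(
                (t[i], t[best], float(np.mean(x[i : best + 1])),
                 float(np.mean(y[i : best + 1])), direction)
            )
            i = best + 1
        else:
            i += 1
    return fixations


def _labeled(t, x, y, aoi):
    df = make_samples(t, x, y)
    df["aoi"] = aoi
    return df


class TestDetectFixations:
    def test_two_samples_below_min_duration(self):
        df = _labeled([0, 66], [5, 5], [5, 5], ["e", "e"])
        assert detect_fixations(df) == []

    def test_ten_stationary_samples_one_fixation(self):
        t = np.arange(10) * FRAME_MS
        df = _labeled(t, [7] * 10, [9] * 10, ["e"] * 10)
        fix = detect_fixations(df)
        assert len(fix) == 1
        assert fix[0].centroid == (7.0, 9.0)
        assert fix[0].direction == FACE_GAZE
        assert fix[0].duration_ms == pytest.approx(9 * FRAME_MS)

    def test_direction_tie_goes_to_aversion(self):
        t = np.arange(4) * FRAME_MS
        df = _labeled(t, [0] * 4, [0] * 4, ["e", "e", "a", "a"])
        (fix,) = detect_fixations(df, min_duration_ms=99)
        assert fix.direction == AVERSION

    def test_nonpositive_thresholds_raise(self):
        df = _labeled([0], [0], [0], ["e"])
        with pytest.raises(ValueError):
            detect_fixations(df, dispersion_px=0)
        with pytest.raises(ValueError):
            detect_fixations(df, min_duration_ms=-1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_walk_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        t = np.arange(n) * FRAME_MS
        x = np.cumsum(rng.normal(0, 15, n))
        y = np.cumsum(rng.normal(0, 15, n))
        aoi = rng.choice(["e", "a"], size=n)
        df = _labeled(t, x, y, aoi)
        got = detect_fixations(df, dispersion_px=60, min_duration_ms=100)
        expected = _idt_oracle(t, x, y, aoi == "e", 60, 100)
        assert len(got) == len(expected)
        for f, (s, e, cx, cy, d) in zip(got, expected):
            assert f.start_ms == pytest.approx(s)
            assert f.end_ms == pytest.approx(e)
            assert f.centroid[0] == pytest.approx(cx)
            assert f.centroid[1] == pytest.approx(cy)
            assert f.direction == d

    def test_invalid_samples_break_windows(self):
        t = np.arange(10) * FRAME_MS
        df = make_samples(t, [0] * 10, [0] * 10,
                          [True] * 5 + [False] + [True] * 4)
        df["aoi"] = ["e"] * 5 + [MISSING] + ["e"] * 4
        fix = detect_fixations(df)
        assert len(fix) == 2


class TestFramesToDirection:
    def test_single_fixation_constant(self):
        from dyadgaze.gaze_preprocess import Fixation

        fix = [Fixation(0.0, 400.0, (0, 0), FACE_GAZE)]
        assert frames_to_direction(fix, 12) == [FACE_GAZE] * 12

    def test_gap_between_fixations_is_missing(self):
        from dyadgaze.gaze_preprocess import Fixation

        fix = [
            Fixation(0.0, 100.0, (0, 0), FACE_GAZE),
            Fixation(300.0, 400.0, (0, 0), AVERSION),
        ]
        out = frames_to_direction(fix, 12)
        mids = (np.arange(12) + 0.5) * FRAME_MS
        for k, m in enumerate(mids):
            if m <= 100.0:
                assert out[k] == FACE_GAZE
            elif 300.0 <= m <= 400.0:
                assert out[k] == AVERSION
            else:
                assert out[k] == MISSING

    def test_synthetic_ground_truth_agreement(self):
        from dyadgaze.pipeline import preprocess_session
        from dyadgaze.synthetic_data import SessionConfig, generate_session

        session = generate_session(
            SessionConfig(duration_ms=60_000, seed=4, coupling_strength=0.0)
        )
        pre = preprocess_session(session)
        for pid, rec in pre.items():
            truth = session.ground_truth.frame_directions[pid]
            est = rec.frame_directions
            covered = [(a, b) for a, b in zip(truth, est)
                       if b != MISSING and a != MISSING]
            agree = sum(a == b for a, b in covered) / len(covered)
            assert agree >= 0.99


class TestCoverage:
    def test_full_coverage(self):
        rep = coverage_report(["e"] * 10)
        assert rep.coverage == 1.0 and not rep.excluded

    def test_sixty_nine_percent_excluded(self):
        labels = ["e"] * 69 + [MISSING] * 31
        rep = coverage_report(labels)
        assert rep.coverage == pytest.approx(0.69)
        assert rep.excluded

    def test_pair_exclusion_rule(self):
        good = ["e"] * 10
        bad = ["e"] * 6 + [MISSING] * 4
        assert not pair_excluded(good, good)
        assert pair_excluded(good, bad)
        assert pair_excluded(bad, good)

    def test_25_of_28_pairs_pass_with_configured_gaps(self):
        # three pairs get blink/occlusion-scale losses dense enough to push
        # coverage below the 70% rule; the rest keep repairable dropouts
        from dyadgaze.pipeline import preprocess_session
        from dyadgaze.synthetic_data import SessionConfig, generate_session

        excluded = 0
        for pair in range(28):
            lossy = pair < 3
            config = SessionConfig(
                session_id=f"P{pair:02d}",
                duration_ms=20_000,
                seed=300 + pair,
                gap_rate=6.0 if lossy else 0.1,
                gap_length_dist=(lambda r: r.uniform(150, 400)) if lossy else None,
            )
            session = generate_session(config)
            pre = preprocess_session(session)
            if pair_excluded(
                list(pre["interviewer"].labeled_samples["aoi"]),
                list(pre["interviewee"].labeled_samples["aoi"]),
            ):
                excluded += 1
        assert excluded == 3


def test_label_track_marks_invalid_and_faceless_missing():
    t = np.arange(4) * FRAME_MS
    samples = make_samples(t, [150] * 4, [150] * 4, [True, False, True, True])
    faces = {0: FaceObservation(0, face_box=BOX), 1: FaceObservation(1, face_box=BOX),
             2: FaceObservation(2, face_box=BOX)}  # frame 3 has no face
    out = label_aoi_track(samples, faces)
    assert list(out["aoi"]) == ["e", MISSING, "e", MISSING]
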