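"""Feature encoding, windowing, CNN construction, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadgaze.gaze_models import (
    DIALOGUEACT137,
    SPEECHTAG20,
    EmptyDatasetError,
    TrainConfig,
    WindowSpec,
    accuracy,
    add_model_columns,
    backtest_splits,
    build_gazeresnet,
    build_gazevgg,
    build_model,
    cv_train_sets,
    encode_features,
    flatten_dim,
    frame_labels,
    make_windows,
    make_windows_multi,
    session_shuffled_cv,
    stack_windows,
    train,
    window_count,
)
from dyadgaze.gaze_preprocess import AVERSION, FACE_GAZE, MISSING


def _speechtag_frames(n=6):
    return pd.DataFrame(
        {
            "tag": ["Speech", "Thinking", "", "Micro Pause", "Speech", "Laugh"][:n],
            "sender": ["interviewee"] * n,
            "sender_gender": ["F"] * n,
            "is_same_person": ["0"] * n,
            "partner_gaze_fg": ["1", "0", "1", "1", "0", "1"][:n],
        }
    )


class TestEncoding:
    def test_speechtag_profile_is_20_channels(self):
        m = encode_features(_speechtag_frames(), SPEECHTAG20)
        assert m.shape == (6, 20)

    def test_dialogueact_profile_is_137_channels(self):
        frames = pd.DataFrame(
            {
                "sender": ["interviewer"],
                "sender_gender": ["M"],
                "is_same_person": ["1"],
                "partner_gaze_fg": ["0"],
                "communicative_function": ["Stalling"],
                "dimension": ["Time management"],
                "certainty": ["Uncertain"],
                "sentiment": [""],
                "functional_dep_offset": [3],
                "feedback_dep_offset": [0],
                "rhetorical_relation": ["Cause"],
                "rr_argument": [2],
            }
        )
        m = encode_features(frames, DIALOGUEACT137)
        assert m.shape == (1, 137)
        # one hot per non-empty attribute: sender, gender, same-person,
        # function, dimension, certainty, functional dep, RR, RR argument
        assert m.sum() == 9

    def test_one_hot_groups_sum_to_at_most_one(self):
        m = encode_features(_speechtag_frames(), SPEECHTAG20)
        offset = 0
        for group in SPEECHTAG20.groups:
            block = m[:, offset : offset + group.size]
            assert (block.sum(axis=1) <= 1).all()
            offset += group.size

    def test_empty_value_leaves_group_all_zero(self):
        m = encode_features(_speechtag_frames(), SPEECHTAG20)
        assert m[2, :14].sum() == 0  # frame with no tag

    def test_unknown_category_error_names_value(self):
        frames = _speechtag_frames()
        frames.loc[0, "tag"] = "Chit-chat"
        with pytest.raises(ValueError, match="Chit-chat"):
            encode_features(frames, SPEECHTAG20)

    def test_encoding_invertible_for_observed_groups(self):
        frames = _speechtag_frames()
        m = encode_features(frames, SPEECHTAG20)
        # decode the tag group by argmax wherever it is observed
        tags = list(SPEECHTAG20.groups[0].categories)
        for row in range(len(frames)):
            block = m[row, :14]
            if block.sum() == 1:
                assert tags[int(block.argmax())] == frames.loc[row, "tag"]

    def test_add_model_columns(self):
        frames = pd.DataFrame(
            {
                "sender": ["interviewer", "interviewee", ""],
                "gaze_interviewer": [FACE_GAZE, AVERSION, FACE_GAZE],
                "gaze_interviewee": [AVERSION, FACE_GAZE, MISSING],
            }
        )
        out = add_model_columns(frames, {"interviewer": "F", "interviewee": "M"})
        assert list(out["sender_gender"]) == ["F", "M", ""]
        assert list(out["is_same_person"]) == ["1", "0", "0"]
        assert list(out["partner_gaze_fg"]) == ["0", "1", "0"]


class TestWindowing:
    def test_eight_steps_window4_stride2_yields_three_4x2(self):
        matrix = np.arange(16, dtype=float).reshape(8, 2)
        labels = np.zeros(8, dtype=int)
        samples = make_windows(matrix, labels, WindowSpec(window=4, stride=2))
        assert len(samples) == 3
        assert all(s.features.shape == (4, 2) for s in samples)
        assert np.array_equal(samples[1].features, matrix[2:6])

    def test_t_equals_window_single_sample(self):
        samples = make_windows(np.zeros((9, 3)), np.zeros(9, int), WindowSpec())
        assert len(samples) == 1

    def test_t10_window9_stride3_one_sample(self):
        assert window_count(10, WindowSpec(window=9, stride=3)) == 1

    def test_label_is_final_frame_and_missing_dropped(self):
        labels = np.array([0, 0, 0, 1, -1, 1, 0, 0])
        samples = make_windows(np.zeros((8, 2)), labels, WindowSpec(window=4, stride=2))
        # ends at frames 3, 5, 7 -> labels 1, 1, 0; frame 4 is not an end
        assert [s.label for s in samples] == [1, 1, 0]
        labels[5] = -1
        samples = make_windows(np.zeros((8, 2)), labels, WindowSpec(window=4, stride=2))
        assert [s.end_frame for s in samples] == [3, 7]

    def test_empty_dataset_error(self):
        with pytest.raises(EmptyDatasetError):
            make_windows_multi([("S", np.zeros((5, 2)), np.zeros(5, int))],
                               WindowSpec(window=9))

    @settings(derandomize=True, max_examples=120)
    @given(st.integers(0, 50), st.integers(1, 10), st.integers(1, 5))
    def test_count_formula_matches_enumeration(self, t, window, stride):
        spec = WindowSpec(window=window, stride=stride)
        enumerated = sum(
            1 for start in range(0, t + 1, stride) if start + window <= t
        )
        assert window_count(t, spec) == enumerated

    def test_windows_never_cross_sessions(self):
        sessions = [
            ("A", np.zeros((10, 2)), np.zeros(10, int)),
            ("B", np.ones((12, 2)), np.zeros(12, int)),
        ]
        samples = make_windows_multi(sessions, WindowSpec(window=4, stride=2))
        for s in samples:
            expect = 0.0 if s.session_id == "A" else 1.0
            assert (s.features == expect).all()


class TestFlattenDim:
    def test_window9_profiles(self):
        spec = WindowSpec(window=9)
        assert flatten_dim(spec, SPEECHTAG20) == 180
        assert flatten_dim(spec, DIALOGUEACT137) == 1233

    def test_window1_is_channel_count(self):
        assert flatten_dim(WindowSpec(window=1, stride=1), SPEECHTAG20) == 20


def _conv_params(k, c_in, c_out):
    return k * c_in * c_out + c_out


def _bn_params(c):
    return 2 * c


def _dense_params(d_in, d_out):
    return d_in * d_out + d_out


class TestArchitectures:
    def test_output_shape_and_range(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=(5, 9, 20)).astype(float)
        for build in (build_gazevgg, build_gazeresnet):
            model = build((9, 20), filters=16)
            out = model.forward(x, train=False)
            assert out.shape == (5, 1)
            assert ((out >= 0) & (out <= 1)).all()

    def test_vgg_parameter_count_matches_hand_count(self):
        f, c, w = 16, 20, 9
        expect = (
            _conv_params(3, c, f) + _bn_params(f)
            + _conv_params(3, f, f) + _bn_params(f)
            + _conv_params(3, f, 2 * f) + _bn_params(2 * f)
            + _conv_params(3, 2 * f, 2 * f) + _bn_params(2 * f)
            + _dense_params((w // 2 // 2) * 2 * f, 64)
            + _dense_params(64, 1)
        )
        assert build_gazevgg((w, c), filters=f).n_params == expect

    def test_resnet_parameter_count_matches_hand_count(self):
        f, c, w = 16, 20, 9
        res_unit = lambda ch: (  # noqa: E731
            _conv_params(3, ch, ch) + _bn_params(ch)
            + _conv_params(3, ch, ch) + _bn_params(ch)
        )
        expect = (
            _conv_params(3, c, f) + _bn_params(f)      # stem
            + res_unit(f)
            + _conv_params(3, f, 2 * f) + _bn_params(2 * f)  # bridge
            + res_unit(2 * f)
            + _dense_params((w // 2 // 2) * 2 * f, 64)
            + _dense_params(64, 1)
        )
        assert build_gazeresnet((w, c), filters=f).n_params == expect

    def test_filters_32_has_more_parameters_than_16(self):
        assert (
            build_gazevgg((9, 20), 32).n_params > build_gazevgg((9, 20), 16).n_params
        )
        assert (
            build_gazeresnet((9, 20), 32).n_params
            > build_gazeresnet((9, 20), 16).n_params
        )

    def test_off_grid_filter_count_warns(self):
        with pytest.warns(UserWarning, match="16, 32"):
            build_gazevgg((9, 20), filters=8)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            build_model(TrainConfig(architecture="gazeLSTM"), (9, 20))


class TestTraining:
    def _toy(self, n=400):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=(n, 9, 20)).astype(float)
        y = x[:, -1, 0]
        return x, y

    def test_separable_toy_reaches_high_training_accuracy(self):
        x, y = self._toy()
        model = build_gazevgg((9, 20), filters=16, seed=1)
        train(model, x, y, TrainConfig(epochs=80, seed=2, first_block_filters=16))
        # training-set accuracy with dropout off
        assert accuracy(model, x, y) >= 0.99

    def test_fixed_seed_reproduces_final_loss(self):
        x, y = self._toy(200)
        losses = []
        for _ in range(2):
            model = build_gazeresnet((9, 20), filters=16, seed=1)
            hist = train(model, x, y,
                         TrainConfig(epochs=3, seed=5, first_block_filters=16))
            losses.append(hist["loss"][-1])
        assert losses[0] == losses[1]

    def test_history_tracks_validation(self):
        x, y = self._toy(120)
        model = build_gazevgg((9, 20), filters=16, seed=0)
        hist = train(model, x[:100], y[:100],
                     TrainConfig(epochs=2, seed=0, first_block_filters=16),
                     x_val=x[100:], y_val=y[100:])
        assert len(hist["val_accuracy"]) == 2
        assert accuracy(model, x[100:], y[100:]) == hist["val_accuracy"][-1]


class TestSplits:
    def test_backtest_five_splits_ratios(self):
        sessions = list(range(12))
        splits = backtest_splits(sessions, 5)
        assert len(splits) == 5
        blocks = np.array_split(np.array(sessions), 6)
        for k, (tr, val) in enumerate(splits, start=1):
            assert len(tr) == sum(len(b) for b in blocks[:k])
            assert val == list(blocks[k])
            assert len(tr) / len(val) == k

    def test_backtest_single_split_is_half_half(self):
        (tr, val), = backtest_splits(list(range(10)), 1)
        assert len(tr) == len(val) == 5

    def test_backtest_blocks_contiguous_and_ordered(self):
        splits = backtest_splits(list(range(13)), 3)
        for tr, val in splits:
            combined = tr + val
            assert combined == sorted(combined)
            assert max(tr) < min(val)

    def test_cv_folds_partition_sessions(self):
        sessions = [f"S{i}" for i in range(25)]
        folds = session_shuffled_cv(sessions, k=5, seed=3)
        assert all(len(f) == 5 for f in folds)
        flat = [s for f in folds for s in f]
        assert sorted(flat) == sorted(sessions)
        assert len(set(flat)) == 25

    def test_cv_shuffle_depends_on_seed_only(self):
        sessions = [f"S{i}" for i in range(10)]
        assert session_shuffled_cv(sessions, 2, seed=1) == session_shuffled_cv(
            sessions, 2, seed=1
        )
        assert session_shuffled_cv(sessions, 2, seed=1) != session_shuffled_cv(
            sessions, 2, seed=2
        )

    def test_cv_preserves_window_order_within_sessions(self):
        # windows carry their end frame; grouping by fold must leave the
        # within-session frame order strictly increasing
        from dyadgaze.gaze_models import make_windows

        sessions = {}
        for sid in "ABCD":
            labels = np.zeros(30, int)
            sessions[sid] = make_windows(
                np.zeros((30, 2)), labels, WindowSpec(), session_id=sid
            )
        folds = session_shuffled_cv(list(sessions), k=2, seed=0)
        for train_sids, val_sids in cv_train_sets(folds):
            for sid in train_sids + val_sids:
                ends = [w.end_frame for w in sessions[sid]]
                assert ends == sorted(ends)
                assert len(set(ends)) == len(ends)
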