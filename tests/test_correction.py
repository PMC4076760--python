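"""Error-sample construction, featurization, GBRT fitting, LOSO protocol."""

import numpy as np
import pandas as pd
import pytest

from ergolift.correction import (
    DEFAULT_PARAMETERS,
    N_FEATURES,
    DeltaDataset,
    ErrorCorrectionModel,
    ErrorCorrectionResults,
    GbrtConfig,
    SchemaMismatchError,
    build_delta_dataset,
    compute_delta,
    featurize,
    featurize_sequence,
    loso_evaluate,
    mirror_features,
    train_error_model,
)
from ergolift.geometry import frame_parameters, sequence_parameters
from ergolift.signal_prep import PairedFrame
from ergolift.skeleton import MIRROR_PERMUTATION, SkeletonFrame, SkeletonSequence
from ergolift.synthetic import SyntheticTrialSpec, generate_lift_trial

from conftest import random_frames, yaw_translate

FAST = GbrtConfig(n_estimators=60, max_train_samples=4000)


def _frames_to_sequence(frames):
    return SkeletonSequence(
        times=np.arange(len(frames)) / 30.0, data=np.stack([f.xyz for f in frames])
    )


def _dataset(features, deltas, subject, mirrored=None):
    n = len(features)
    return DeltaDataset(
        features=features,
        deltas=pd.DataFrame(deltas),
        subject=np.asarray(subject, dtype=object),
        mirrored=np.zeros(n, dtype=bool) if mirrored is None else mirrored,
    )


def _synthetic_dataset(rng, n_subjects=3, n_per_subject=400, noise=0.05):
    """Shared smooth pose-dependent deltas + per-sample noise."""
    frames = random_frames(rng, n_subjects * n_per_subject)
    features = featurize_sequence(_frames_to_sequence(frames))
    # deltas depend smoothly on the wrist-forward coordinate
    wrist_x = features[:, 18]  # left_wrist x_body
    deltas = {
        "H": 3.0 + 4.0 * wrist_x + rng.normal(0, noise, len(frames)),
        "V": -2.0 + 3.0 * np.abs(wrist_x) + rng.normal(0, noise, len(frames)),
        "A": 5.0 * np.sin(3.0 * wrist_x) + rng.normal(0, noise, len(frames)),
    }
    subject = np.repeat([f"S{i}" for i in range(n_subjects)], n_per_subject)
    return _dataset(features, deltas, subject)


class TestDeltaSamples:
    def test_identical_pair_gives_zero_deltas(self, base_frame):
        sample = compute_delta(PairedFrame(base_frame, base_frame))
        assert all(abs(v) < 1e-12 for v in sample.delta.values())
        assert sample.features.shape == (N_FEATURES,)

    def test_forward_hand_offset_gives_positive_h_delta(self, base_frame):
        from ergolift.skeleton import JOINT_INDEX, JointName

        q = base_frame.xyz.copy()
        for j in (JointName.LEFT_WRIST, JointName.RIGHT_WRIST):
            q[JOINT_INDEX[j], 0] += 0.05  # reference hands 5 cm farther forward
        sample = compute_delta(PairedFrame(base_frame, SkeletonFrame(0.0, q)))
        assert sample.delta["H"] == pytest.approx(5.0, abs=1e-9)

    def test_random_pairs_match_subtraction_oracle(self, rng):
        k_frames = random_frames(rng, 30)
        q_frames = random_frames(rng, 30)
        for k, q in zip(k_frames, q_frames):
            sample = compute_delta(PairedFrame(k, q))
            pk, pq = frame_parameters(k), frame_parameters(q)
            for p in DEFAULT_PARAMETERS:
                assert sample.delta[p] == pytest.approx(
                    getattr(pq, p) - getattr(pk, p), abs=1e-9
                )


class TestFeaturize:
    def test_feature_vector_length(self, base_frame):
        assert featurize(base_frame).shape == (N_FEATURES,)

    def test_world_yaw_leaves_features_unchanged(self, rng):
        for frame in random_frames(rng, 15):
            rotated = SkeletonFrame(0.0, yaw_translate(frame.xyz, 120.0, (1.0, -2.0)))
            np.testing.assert_allclose(featurize(rotated), featurize(frame), atol=1e-9)

    def test_mirror_features_apply_label_and_axis_permutation(self, rng):
        frames = random_frames(rng, 10)
        feats = featurize_sequence(_frames_to_sequence(frames))
        mirrored = mirror_features(feats)
        manual = feats.reshape(-1, 20, 3)[:, MIRROR_PERMUTATION, :].copy()
        manual[:, :, 1] *= -1
        np.testing.assert_allclose(mirrored, manual.reshape(-1, N_FEATURES), atol=0)

    def test_mirror_augmentation_doubles_samples_same_schema(self, rng):
        ds = _synthetic_dataset(rng, n_subjects=2, n_per_subject=50)
        aug = ds.mirror_augmented()
        assert len(aug) == 2 * len(ds)
        assert aug.features.shape[1] == N_FEATURES
        assert aug.mirrored.sum() == len(ds)


class TestTraining:
    def test_constant_delta_recovered_on_held_out_poses(self, rng):
        ds = _synthetic_dataset(rng, n_subjects=2, n_per_subject=300, noise=0.0)
        const = {p: np.full(len(ds), c) for p, c in zip(DEFAULT_PARAMETERS, (4.0, -2.5, 10.0))}
        ds = _dataset(ds.features, const, ds.subject)
        results = train_error_model(ds, config=FAST, seed=0)
        held_out = featurize_sequence(_frames_to_sequence(random_frames(rng, 50)))
        pred = results.predict(held_out)
        for p, c in zip(DEFAULT_PARAMETERS, (4.0, -2.5, 10.0)):
            np.testing.assert_allclose(pred[p], c, atol=0.01 * abs(c) + 1e-6)

    def test_linear_pose_dependence_learned(self, rng):
        ds = _synthetic_dataset(rng, n_subjects=2, n_per_subject=800, noise=0.0)
        train_mask = np.arange(len(ds)) % 2 == 0
        results = train_error_model(ds.subset(train_mask), config=FAST, seed=1)
        test = ds.subset(~train_mask)
        pred = results.predict(test.features)
        for p in DEFAULT_PARAMETERS:
            y = test.deltas[p].to_numpy()
            r2 = 1.0 - np.sum((y - pred[p]) ** 2) / np.sum((y - y.mean()) ** 2)
            assert r2 > 0.9

    def test_same_seed_reproduces_predictions_exactly(self, rng):
        ds = _synthetic_dataset(rng, n_subjects=2, n_per_subject=200)
        a = train_error_model(ds, config=FAST, seed=7).predict(ds.features)
        b = train_error_model(ds, config=FAST, seed=7).predict(ds.features)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_dataset_raises(self):
        empty = build_delta_dataset([], subject_id="S0")
        with pytest.raises(ValueError):
            ErrorCorrectionModel(empty)


class TestApplyCorrection:
    def _zero_delta_results(self, rng, bias=0.0):
        ds = _synthetic_dataset(rng, n_subjects=2, n_per_subject=300)
        deltas = {p: np.full(len(ds), bias) for p in DEFAULT_PARAMETERS}
        return train_error_model(_dataset(ds.features, deltas, ds.subject), config=FAST, seed=0)

    def test_zero_delta_model_leaves_raw_nearly_unchanged(self, rng):
        results = self._zero_delta_results(rng, bias=0.0)
        seq = generate_lift_trial(SyntheticTrialSpec(duration_s=10.0))
        table = results.correct_sequence(seq)
        assert len(table) == len(seq)
        for p in DEFAULT_PARAMETERS:
            np.testing.assert_allclose(table[f"{p}_corrected"], table[p], atol=1e-3)

    def test_constant_bias_model_shifts_by_bias(self, rng):
        results = self._zero_delta_results(rng, bias=3.0)
        seq = generate_lift_trial(SyntheticTrialSpec(duration_s=10.0))
        table = results.correct_sequence(seq)
        for p in DEFAULT_PARAMETERS:
            np.testing.assert_allclose(table[f"{p}_corrected"] - table[p], 3.0, atol=0.05)

    def test_raw_columns_match_sequence_parameters(self, rng):
        results = self._zero_delta_results(rng)
        seq = generate_lift_trial(SyntheticTrialSpec(duration_s=5.0))
        table = results.correct_sequence(seq)
        raw = sequence_parameters(seq)
        for p in DEFAULT_PARAMETERS:
            np.testing.assert_allclose(table[p], raw[p], atol=1e-12)


class TestLoso:
    def test_perfect_streams_give_near_zero_errors(self, rng):
        ds = _synthetic_dataset(rng, n_subjects=2, n_per_subject=200)
        zero = _dataset(
            ds.features, {p: np.zeros(len(ds)) for p in DEFAULT_PARAMETERS}, ds.subject
        )
        report = loso_evaluate(zero, config=FAST, seed=0)
        assert (report.table["raw_mae"] < 1e-9).all()
        assert (report.table["modeled_mae"] < 0.05).all()

    def test_one_row_per_subject_and_parameter(self, rng):
        ds = _synthetic_dataset(rng, n_subjects=3, n_per_subject=150)
        report = loso_evaluate(ds, config=FAST, seed=0)
        counts = report.table.groupby("subject").size()
        assert set(counts.index) == {"S0", "S1", "S2"}
        assert (counts == len(DEFAULT_PARAMETERS)).all()

    def test_shared_pose_bias_reduces_variance_for_all(self, rng):
        ds = _synthetic_dataset(rng, n_subjects=3, n_per_subject=500, noise=0.2)
        report = loso_evaluate(ds, config=FAST, seed=0)
        assert report.improved("variance").all()
        assert report.improved("mae").all()

    def test_single_subject_raises(self, rng):
        ds = _synthetic_dataset(rng, n_subjects=1, n_per_subject=100)
        with pytest.raises(ValueError):
            loso_evaluate(ds, config=FAST)

    def test_no_leakage_canary_corrupting_heldout_labels(self, rng):
        """Predictions for a held-out subject must not depend on its labels."""
        ds = _synthetic_dataset(rng, n_subjects=3, n_per_subject=200)
        held = ds.subject == "S2"
        corrupted = _dataset(
            ds.features,
            {
                p: np.where(held, 999.0, ds.deltas[p].to_numpy())
                for p in DEFAULT_PARAMETERS
            },
            ds.subject,
        )
        model_a = ErrorCorrectionModel(ds.subset(~held), config=FAST).fit(seed=3)
        model_b = ErrorCorrectionModel(corrupted.subset(~held), config=FAST).fit(seed=3)
        test_features = ds.features[held]
        pd.testing.assert_frame_equal(
            model_a.predict(test_features), model_b.predict(test_features)
        )


class TestPersistence:
    def test_save_load_roundtrip(self, rng, tmp_path):
        ds = _synthetic_dataset(rng, n_subjects=2, n_per_subject=200)
        results = train_error_model(ds, config=FAST, seed=0)
        path = tmp_path / "model.joblib"
        results.save(path)
        loaded = ErrorCorrectionResults.load(path)
        pd.testing.assert_frame_equal(
            loaded.predict(ds.features[:20]), results.predict(ds.features[:20])
        )
        assert path.with_suffix(".joblib.json").exists()

    def test_feature_count_mismatch_raises(self, rng):
        ds = _synthetic_dataset(rng, n_subjects=2, n_per_subject=100)
        results = train_error_model(ds, config=FAST, seed=0)
        with pytest.raises(SchemaMismatchError):
            results.predict(np.zeros((5, 10)))

    def test_summary_mentions_parameters_and_subjects(self, rng):
        ds = _synthetic_dataset(rng, n_subjects=2, n_per_subject=100)
        results = train_error_model(ds, config=FAST, seed=0)
        text = results.summary()
        for token in ("H", "V", "A", "S0", "S1", "Huber"):
            assert token in text
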