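"""Spatial extractor, temporal classifier and pipeline contracts.

All tests run the ``compact`` backbone at small input sizes; the
full-size topology contracts are exercised by the acceptance suite.
"""

import numpy as np
import pytest

import gaitpath as gp
from gaitpath.errors import CycleDetectionError, TrainingError, ValidationError
from gaitpath.io import NormalizedFrame
from gaitpath.model import (
    GaitPipeline,
    ModelConfig,
    PipelineConfig,
    TrainConfig,
    build_spatial_extractor,
    build_temporal_classifier,
    extract_feature_sequence,
    predict,
    train_classifier,
)


def _mc(**kw):
    base = dict(backbone="compact", input_side=32, feature_dim=32,
                lstm_units=16, frozen_blocks=0)
    base.update(kw)
    return ModelConfig(**base)


def _frames(n, side=32, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        mask = np.zeros((side, side), np.uint8)
        r, c = rng.integers(4, side - 10, size=2)
        mask[r : r + 8, c : c + 5] = 1
        out.append(NormalizedFrame(mask))
    return out


class TestSpatialExtractor:
    def test_compact_feature_length_matches_config(self):
        ex = build_spatial_extractor(_mc(feature_dim=128), seed=0)
        feats = ex.features(_frames(2))
        assert feats.shape == (2, 128)

    def test_deterministic_given_weights(self):
        ex = build_spatial_extractor(_mc(), seed=0)
        frames = _frames(3)
        assert np.array_equal(ex.features(frames), ex.features(frames))

    def test_feature_sequence_order_and_purity(self):
        ex = build_spatial_extractor(_mc(), seed=0)
        frames = _frames(9)
        frames[7] = NormalizedFrame(frames[2].mask.copy())
        fs = extract_feature_sequence(ex, frames)
        assert fs.vectors.shape == (9, 32)
        assert np.array_equal(fs.vectors[2], fs.vectors[7])
        singles = [ex.features([f])[0] for f in frames]
        assert np.allclose(fs.vectors, np.stack(singles), atol=1e-5)

    def test_wrong_arity_rejected(self):
        ex = build_spatial_extractor(_mc(), seed=0)
        with pytest.raises(ValidationError):
            extract_feature_sequence(ex, _frames(8))

    def test_finetune_loss_decreases(self):
        ex = build_spatial_extractor(_mc(), seed=1)
        frames = _frames(50, seed=2)
        labels = [i % 2 for i in range(50)]
        hist = ex.finetune(frames, labels, TrainConfig(learning_rate=1e-3, epochs=6,
                                                       batch_size=16, seed=0))
        assert hist["loss"][4] < hist["loss"][0]

    def test_single_class_finetune_rejected(self):
        ex = build_spatial_extractor(_mc(), seed=1)
        with pytest.raises(TrainingError):
            ex.finetune(_frames(10), [1] * 10, TrainConfig(epochs=1))

    def test_frozen_blocks_bit_identical_after_finetuning(self):
        ex = build_spatial_extractor(_mc(frozen_blocks=2), seed=3)
        before = [ex.block_parameters(0), ex.block_parameters(1), ex.block_parameters(2)]
        frames = _frames(40, seed=4)
        labels = [i % 2 for i in range(40)]
        ex.finetune(frames, labels, TrainConfig(learning_rate=1e-3, epochs=3,
                                                batch_size=16, seed=0))
        after = [ex.block_parameters(0), ex.block_parameters(1), ex.block_parameters(2)]
        for b in (0, 1):
            for x, y in zip(before[b], after[b]):
                assert np.array_equal(x, y)
        assert any(
            not np.array_equal(x, y) for x, y in zip(before[2], after[2])
        ), "unfrozen block should have moved"


def _feature_data(n_per_class, dim=32, classes=2, seed=0):
    rng = np.random.default_rng(seed)
    data, labels = [], []
    for c in range(classes):
        centre = rng.normal(scale=2.0, size=(9, dim))
        for _ in range(n_per_class):
            vecs = centre + rng.normal(scale=0.2, size=(9, dim))
            data.append(gp.FeatureSequence(vectors=vecs))
            labels.append(c)
    return data, labels


class TestTemporalClassifier:
    def test_fused_feature_is_twice_lstm_units(self):
        tc = build_temporal_classifier(_mc(lstm_units=16), seed=0)
        fused = tc.fused_features(np.zeros((3, 9, 32), np.float32))
        assert fused.shape == (3, 32)

    def test_inference_deterministic_despite_dropout(self):
        tc = build_temporal_classifier(_mc(), seed=0)
        x = np.random.default_rng(0).normal(size=(2, 9, 32)).astype(np.float32)
        assert np.array_equal(tc.predict_proba(x), tc.predict_proba(x))

    def test_tied_weights_reversal_swaps_halves(self):
        tc = build_temporal_classifier(_mc(), seed=0)
        for pf, pb in zip(tc.bilstm.fwd.params(), tc.bilstm.bwd.params()):
            pb.value = pf.value.copy()
        x = np.random.default_rng(1).normal(size=(1, 9, 32)).astype(np.float32)
        a = tc.fused_features(x)
        b = tc.fused_features(x[:, ::-1, :])
        u = tc.config.lstm_units
        assert np.allclose(a[:, :u], b[:, u:], atol=1e-6)
        assert np.allclose(a[:, u:], b[:, :u], atol=1e-6)

    def test_untrained_model_outputs_uniform_probabilities(self):
        tc = build_temporal_classifier(_mc(n_classes=5), seed=0)
        fs = gp.FeatureSequence(vectors=np.random.default_rng(2).normal(size=(9, 32)))
        probs = predict(tc, fs).probs
        assert np.allclose(probs, 0.2, atol=1e-9)
        assert abs(probs.sum() - 1.0) < 1e-6

    def test_separable_sequences_fit_to_full_accuracy(self):
        data, labels = _feature_data(10, seed=3)
        tc = build_temporal_classifier(_mc(n_classes=2), seed=0)
        _, hist = train_classifier(
            tc, data, TrainConfig(learning_rate=3e-3, epochs=200, batch_size=8, seed=0),
            labels=labels,
        )
        assert hist["accuracy"][-1] == 1.0

    def test_training_deterministic_under_seed(self):
        data, labels = _feature_data(5, seed=4)
        results = []
        for _ in range(2):
            tc = build_temporal_classifier(_mc(n_classes=2), seed=5)
            _, hist = train_classifier(
                tc, data, TrainConfig(learning_rate=1e-3, epochs=10, batch_size=4, seed=6),
                labels=labels,
            )
            results.append(hist["loss"][-1])
        assert results[0] == results[1]

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        data, labels = _feature_data(4, seed=7)
        tc = build_temporal_classifier(_mc(n_classes=2), seed=8)
        before = [p.value.copy() for p in tc.model.params()]
        train_classifier(tc, data, TrainConfig(learning_rate=0.0, epochs=2,
                                               batch_size=4, seed=0), labels=labels)
        for b, p in zip(before, tc.model.params()):
            assert np.array_equal(b, p.value)

    def test_label_permutation_equivariance(self):
        data, labels = _feature_data(8, classes=3, seed=9)
        perm = [2, 0, 1]
        cfg = TrainConfig(learning_rate=1e-3, epochs=25, batch_size=8, seed=11)
        tc1 = build_temporal_classifier(_mc(n_classes=3), seed=12)
        train_classifier(tc1, data, cfg, labels=labels)
        tc2 = build_temporal_classifier(_mc(n_classes=3), seed=12)
        train_classifier(tc2, data, cfg, labels=[perm[c] for c in labels])
        x = np.stack([d.vectors for d in data[:5]])
        p1 = tc1.predict_proba(x)
        p2 = tc2.predict_proba(x)
        # probability of original class c appears at permuted position perm[c]
        assert np.allclose(p2[:, perm], p1, atol=1e-4)


@pytest.fixture(scope="module")
def toy_pipeline():
    """A tiny trained pipeline on a 3-subject, 2-class synthetic cohort."""
    cohort = gp.generate_cohort(
        3, classes=("normal", "parkinsonian"), severities=(1,),
        directions=("left_to_right",), n_cycles=2, seed=21,
    )
    seqs = [c.sequence for c in cohort]
    pipe = GaitPipeline(
        _mc(n_classes=5),
        TrainConfig(learning_rate=1e-3, epochs=3, batch_size=32, seed=0),
        TrainConfig(learning_rate=3e-3, epochs=40, batch_size=16, seed=1),
        PipelineConfig(),
        seed=0,
    )
    pipe.fit(seqs)
    return pipe, seqs


class TestPipeline:
    def test_two_cycle_sequence_yields_two_vectors_and_one_decision(self, toy_pipeline):
        pipe, seqs = toy_pipeline
        per_cycle, decision = pipe.classify(seqs[0])
        assert len(per_cycle) == 2
        assert decision in gp.CLASS_LABELS
        for cp in per_cycle:
            assert abs(cp.probs.sum() - 1.0) < 1e-6

    def test_single_cycle_decision_is_cycle_argmax(self, toy_pipeline):
        pipe, _ = toy_pipeline
        cohort = gp.generate_cohort(
            1, classes=("normal",), severities=(1,),
            directions=("left_to_right",), n_cycles=1, seed=33,
        )
        per_cycle, decision = pipe.classify(cohort[0].sequence)
        assert len(per_cycle) == 1
        assert decision == per_cycle[0].decision

    def test_all_zero_sequence_raises_cycle_error(self, toy_pipeline):
        pipe, _ = toy_pipeline
        frames = [gp.SilhouetteFrame(np.zeros((40, 40), np.uint8)) for _ in range(30)]
        seq = gp.SilhouetteSequence(frames=frames)
        with pytest.raises(CycleDetectionError):
            pipe.classify(seq)

    def test_save_load_round_trip_preserves_predictions(self, toy_pipeline, tmp_path):
        pipe, seqs = toy_pipeline
        per_cycle, _ = pipe.classify(seqs[1])
        path = pipe.save(tmp_path / "ckpt.npz")
        loaded = GaitPipeline.load(path)
        per_cycle2, _ = loaded.classify(seqs[1])
        for a, b in zip(per_cycle, per_cycle2):
            assert np.allclose(a.probs, b.probs, atol=1e-6)
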