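"""Architecture contracts and small-scale training behavior of the network."""

import numpy as np
import pytest

from sferakit._autodiff import Tensor
from sferakit.preprocessing import SliceSample, VolumeNormalizer
from sferakit.sfera_model import (
    EncoderConfig,
    SferaModel,
    TrainConfig,
    build_model,
    fit_ridge_head,
    pretrain_finetune,
    reduced_config,
    train,
)

TINY = EncoderConfig(first_channels=2, feature_dim=8, lstm_hidden=8, stem_pool=4)


def _sample(rng, subject="s", idx=0):
    return SliceSample(pixels=rng.random((2, 150, 150)), subject_id=subject, slice_index=idx)


def _subject(rng, n_slices, subject="s"):
    return [_sample(rng, subject, i) for i in range(n_slices)]


def _toy_dataset(rng, n_subjects, n_slices=3):
    """Targets linear in mean slice intensity, so tiny models can learn them."""
    data = []
    for i in range(n_subjects):
        level = rng.uniform(0.2, 0.8)
        samples = [
            SliceSample(
                pixels=np.clip(level + 0.05 * rng.standard_normal((2, 150, 150)), 0, 1),
                subject_id=f"t{i}",
                slice_index=j,
            )
            for j in range(n_slices)
        ]
        data.append((samples, (level, level / 2)))
    return data


class TestEncoderStructure:
    def test_default_channel_doubling(self):
        cfg = EncoderConfig()
        assert cfg.block_channels == (32, 64, 128, 256, 512)

    def test_default_spatial_chain(self):
        """150 shrinks by floor halving through the five pools."""
        assert EncoderConfig().spatial_chain == (150, 75, 37, 18, 9, 4)

    def test_default_feature_length(self):
        model = build_model(EncoderConfig(), seed=0)
        rng = np.random.default_rng(0)
        features = model.encode_slices([_sample(rng)])
        assert features.shape == (1, 128)

    def test_five_residual_blocks(self):
        model = build_model(EncoderConfig(), seed=0)
        assert len(model.encoder.blocks) == 5

    def test_wrong_input_shape_rejected(self):
        with pytest.raises(ValueError):
            SliceSample(pixels=np.zeros((2, 100, 100)))

    def test_identical_inputs_identical_features(self):
        model = build_model(TINY, seed=0).eval()
        rng = np.random.default_rng(1)
        sample = _sample(rng)
        f1 = model.encode_slices([sample]).data
        f2 = model.encode_slices([sample]).data
        np.testing.assert_array_equal(f1, f2)


class TestAggregator:
    def test_embedding_length_fixed_across_sequence_lengths(self):
        model = build_model(TINY, seed=0).eval()
        rng = np.random.default_rng(2)
        e5 = model.embed(_subject(rng, 5)).data
        e12 = model.embed(_subject(rng, 12)).data
        assert e5.shape == e12.shape == (2 * TINY.lstm_hidden,)

    def test_single_slice_stack_accepted(self):
        model = build_model(TINY, seed=0).eval()
        rng = np.random.default_rng(3)
        assert model.embed(_subject(rng, 1)).data.shape == (16,)

    def test_slice_order_sensitivity(self):
        model = build_model(TINY, seed=0).eval()
        rng = np.random.default_rng(4)
        subject = _subject(rng, 6)
        fwd = model.embed(subject).data
        rev = model.embed(subject[::-1]).data
        assert not np.allclose(fwd, rev)

    def test_empty_sequence_rejected(self):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError):
            model.forward_subjects([[]])


class TestHeads:
    def test_zero_linear_head_predicts_zero(self):
        model = build_model(TINY, seed=0).eval()
        model.linear_head.weight.data[:] = 0.0
        model.linear_head.bias.data[:] = 0.0
        rng = np.random.default_rng(5)
        assert model.predict_normalized(_subject(rng, 4)) == (0.0, 0.0)

    def test_ridge_head_recovers_linear_map(self):
        """Bayesian ridge on noiseless linearly generated embeddings."""
        model = build_model(TINY, seed=0).eval()
        rng = np.random.default_rng(6)
        subjects = [_subject(rng, 3, subject=f"r{i}") for i in range(30)]
        embeddings = np.stack([model.embed(s).data for s in subjects])
        w = rng.normal(size=(embeddings.shape[1], 2))
        targets = embeddings @ w
        dataset = [(s, tuple(t)) for s, t in zip(subjects, targets)]
        fit_ridge_head(model, dataset)
        for s, t in dataset[:5]:
            pred = model.predict_normalized(s)
            assert pred[0] == pytest.approx(t[0], abs=1e-3)
            assert pred[1] == pytest.approx(t[1], abs=1e-3)

    def test_ridge_fit_leaves_encoder_unchanged(self):
        model = build_model(TINY, seed=0).eval()
        rng = np.random.default_rng(7)
        subject = _subject(rng, 3)
        before = model.embed(subject).data.copy()
        dataset = [(_subject(rng, 3, f"x{i}"), (0.1 * i, 0.05 * i)) for i in range(5)]
        fit_ridge_head(model, dataset)
        np.testing.assert_array_equal(before, model.embed(subject).data)

    def test_ridge_refit_deterministic(self):
        model = build_model(TINY, seed=0).eval()
        rng = np.random.default_rng(8)
        dataset = [(_subject(rng, 3, f"x{i}"), (0.1 * i, 0.05 * i)) for i in range(6)]
        fit_ridge_head(model, dataset)
        c1 = model.ridge_heads[0].coef_.copy()
        fit_ridge_head(model, dataset)
        np.testing.assert_array_equal(c1, model.ridge_heads[0].coef_)

    def test_unfitted_ridge_raises(self):
        model = build_model(TINY, seed=0)
        model.head = "ridge"
        rng = np.random.default_rng(9)
        with pytest.raises(RuntimeError):
            model.predict_normalized(_subject(rng, 2))


class TestTraining:
    def test_loss_decreases_on_learnable_data(self):
        rng = np.random.default_rng(10)
        dataset = _toy_dataset(rng, 24)
        model = build_model(TINY, seed=0)
        log = train(model, dataset, TrainConfig(epochs=8, seed=0))
        assert log[-1]["loss"] < log[0]["loss"]

    def test_loss_zero_for_perfect_predictions(self):
        from sferakit.sfera_model import _rmse_loss

        pred = Tensor(np.array([[0.3, 0.4], [0.1, 0.2]]))
        assert _rmse_loss(pred, pred.data.copy()).data == pytest.approx(0.0)

    def test_same_seed_same_final_loss(self):
        rng = np.random.default_rng(11)
        dataset = _toy_dataset(rng, 10)
        logs = []
        for _ in range(2):
            model = build_model(TINY, seed=3)
            logs.append(train(model, dataset, TrainConfig(epochs=3, seed=3)))
        assert logs[0][-1]["loss"] == pytest.approx(logs[1][-1]["loss"], abs=1e-12)

    def test_too_few_subjects(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError):
            train(build_model(TINY), _toy_dataset(rng, 1), TrainConfig(epochs=1))


class TestPretrainFinetune:
    def test_zero_finetune_epochs_preserves_weights(self):
        rng = np.random.default_rng(13)
        pre = _toy_dataset(rng, 8)
        fine = _toy_dataset(rng, 8)
        model = build_model(TINY, seed=0)
        pretrain_finetune(
            model, pre, fine, TrainConfig(epochs=2, seed=0), TrainConfig(epochs=0, seed=0)
        )
        reference = build_model(TINY, seed=0)
        train(reference, pre, TrainConfig(epochs=2, seed=0))
        for a, b in zip(model.state_arrays(), reference.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_both_phases_logged(self):
        rng = np.random.default_rng(14)
        model = build_model(TINY, seed=0)
        _, log = pretrain_finetune(
            model,
            _toy_dataset(rng, 6),
            _toy_dataset(rng, 6),
            TrainConfig(epochs=2, seed=0),
            TrainConfig(epochs=1, seed=0),
        )
        phases = [e["phase"] for e in log]
        assert phases == ["pretrain", "pretrain", "finetune"]


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        model = build_model(TINY, seed=0)
        rng = np.random.default_rng(15)
        dataset = _toy_dataset(rng, 6)
        train(model, dataset, TrainConfig(epochs=1, seed=0))
        subject = _subject(rng, 4)
        before = model.predict_normalized(subject)
        path = tmp_path / "model.npz"
        model.save(path)
        restored = SferaModel.load(path)
        assert restored.predict_normalized(subject) == before


class TestPrediction:
    def test_prediction_result_recomputes_ef(self):
        model = build_model(TINY, seed=0).eval()
        norm = VolumeNormalizer(edv_min=5.0, edv_max=30.0, esv_min=2.0, esv_max=15.0)
        rng = np.random.default_rng(16)
        result = model.predict(_subject(rng, 4), norm, slice_spacing_mm=8.0)
        assert result.ef == pytest.approx(
            (result.edv_ml - result.esv_ml) / result.edv_ml
        )

    def test_reduced_config_is_narrower(self):
        reduced = reduced_config()
        full = EncoderConfig()
        assert reduced.n_blocks == full.n_blocks == 5
        assert reduced.first_channels < full.first_channels
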