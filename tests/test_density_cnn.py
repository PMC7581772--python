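"""Density CNN: architecture arithmetic, augmentation, training, search."""

from dataclasses import replace

import numpy as np
import pytest

from mridensity.density_cnn import (
    AugmentationSpec,
    CNNConfig,
    DatasetSplit,
    apply_augmentation,
    augment,
    build_model,
    conv_output_sizes,
    draw_augmentation,
    filter_schedule,
    load_model,
    make_split,
    predict,
    sample_search_space,
    save_model,
    train,
)
from mridensity.volume import Volume


def independent_parameter_count(input_shape, f0, kernel=3, dense_width=128):
    """Hand count of trainable parameters, written from the layer list.

    conv: f_out * (f_in * k^3 + 1) weights+bias, plus one PReLU slope per
    channel; dense: out * (in + 1) plus PReLU slopes; linear head: in + 1.
    """
    filters = [f0, 2 * f0, 4 * f0, 4 * f0, 4 * f0]
    total, cin = 0, 1
    dims = list(input_shape)
    for f in filters:
        total += f * (cin * kernel**3 + 1) + f
        dims = [-(-d // 2) for d in dims]
        cin = f
    flat = cin * np.prod(dims)
    total += dense_width * (flat + 1) + dense_width
    total += dense_width * (dense_width + 1) + dense_width
    total += dense_width + 1
    return int(total)


class TestArchitecture:
    def test_stride_two_stack_halves_128_to_4(self):
        assert conv_output_sizes((128, 128, 128), 5) == [
            (64,) * 3, (32,) * 3, (16,) * 3, (8,) * 3, (4,) * 3,
        ]

    def test_stride_two_stack_halves_32_to_1(self):
        assert conv_output_sizes((32, 32, 32), 5)[-1] == (1, 1, 1)

    def test_filter_schedule_doubles_in_layers_two_and_three(self):
        assert filter_schedule(8, 5) == [8, 16, 32, 32, 32]
        assert filter_schedule(4, 5) == [4, 8, 16, 16, 16]

    def test_parameter_count_matches_hand_count(self):
        tm = build_model(CNNConfig(input_shape=(32, 32, 32), base_filters=8))
        assert tm.network.n_parameters() == independent_parameter_count((32, 32, 32), 8)

    def test_too_small_input_rejected_naming_dimension(self):
        with pytest.raises(ValueError, match="axis 1"):
            build_model(CNNConfig(input_shape=(16, 8, 16)))


class TestAugmentation:
    def test_zero_magnitude_is_identity(self):
        spec = AugmentationSpec(max_translation_voxels=0, max_rotation_deg=0.0)
        values = np.random.default_rng(0).random((16, 16, 16))
        out = augment(Volume(values), spec)
        assert np.allclose(out.values, values)

    def test_delta_spike_translates_exactly(self):
        values = np.zeros((32, 32, 32))
        values[16, 16, 16] = 1.0
        params = {"translation": (5, 0, 0), "rot_sagittal_deg": 0.0, "rot_transversal_deg": 0.0}
        out = apply_augmentation(values, params)
        assert out[21, 16, 16] == pytest.approx(1.0)
        assert out.sum() == pytest.approx(1.0)

    def test_no_anterior_posterior_translation(self):
        rng = np.random.default_rng(1)
        draws = [draw_augmentation(AugmentationSpec(), rng) for _ in range(200)]
        assert all(d["translation"][1] == 0 for d in draws)

    def test_translation_range_audit(self):
        """10000 draws: empirical extrema hit +-20, nothing outside."""
        rng = np.random.default_rng(2)
        spec = AugmentationSpec(max_translation_voxels=20)
        offsets = np.array(
            [d["translation"] for d in (draw_augmentation(spec, rng) for _ in range(10000))]
        )
        lr, si = offsets[:, 0], offsets[:, 2]
        for axis in (lr, si):
            assert axis.max() == 20 and axis.min() == -20
            assert np.all((axis >= -20) & (axis <= 20))

    def test_rotation_range_audit(self):
        rng = np.random.default_rng(3)
        spec = AugmentationSpec(max_rotation_deg=10.0)
        angles = np.array(
            [
                (d["rot_sagittal_deg"], d["rot_transversal_deg"])
                for d in (draw_augmentation(spec, rng) for _ in range(10000))
            ]
        )
        assert np.all(np.abs(angles) <= 10.0)
        assert angles.max() > 9.5 and angles.min() < -9.5


class TestSplit:
    def test_ranked_slicing(self):
        ids = [f"s{i}" for i in range(10)]
        split = make_split(ids, (6, 2, 2))
        assert split.train_ids == tuple(sorted(ids)[:6])
        assert split.val_ids == tuple(sorted(ids)[6:8])
        assert split.test_ids == tuple(sorted(ids)[8:])

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_split(["a", "b", "c"], (1, 1, 2))

    def test_cohort_sized_splits(self):
        # a 615-member cohort splits 400/50/165 with nothing left over
        ids = [f"study{i:04d}" for i in range(615)]
        split = make_split(ids, (400, 50, 165))
        assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (400, 50, 165)

    def test_empty_partition_rejected_downstream_by_train(self):
        ids = [f"s{i}" for i in range(4)]
        split = make_split(ids, (4, 0, 0))
        vols = {i: np.zeros((16, 16, 16)) for i in ids}
        labels = {i: 10.0 for i in ids}
        with pytest.raises(ValueError):
            train(vols, labels, split, CNNConfig(input_shape=(16, 16, 16), epochs=1))


def _toy_config(**kw):
    defaults = dict(
        input_shape=(16, 16, 16), base_filters=4, epochs=60,
        learning_rate=1e-2, batch_size=2, dropout_rate=0.0, seed=0,
    )
    defaults.update(kw)
    return CNNConfig(**defaults)


@pytest.fixture(scope="module")
def memorized_model():
    rng = np.random.default_rng(0)
    x = rng.random((16, 16, 16))
    # validation holds a copy of the training sample so the best-validation
    # checkpoint is exactly the memorizing one
    vols = {"a": x, "a-copy": x.copy()}
    labels = {"a": 30.0, "a-copy": 30.0}
    split = DatasetSplit(train_ids=("a",), val_ids=("a-copy",), test_ids=())
    model = train(vols, labels, split, _toy_config(epochs=400))
    return model, vols, labels


class TestTraining:
    def test_single_sample_memorization(self, memorized_model):
        model, vols, labels = memorized_model
        assert model.history["train_mae"].min() < 0.5
        assert predict(model, vols["a"]) == pytest.approx(labels["a"], abs=0.5)

    def test_history_length_and_loss_decreases_early(self, memorized_model):
        model, _, _ = memorized_model
        h = model.history
        assert len(h) == model.config.epochs
        assert h["train_mae"].iloc[4] < h["train_mae"].iloc[0]

    def test_constant_label_cohort_collapses_to_constant(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(6)]
        vols = {i: rng.random((16, 16, 16)) for i in ids}
        labels = {i: 15.0 for i in ids}
        split = make_split(ids, (4, 2, 0))
        model = train(vols, labels, split, _toy_config(epochs=300, learning_rate=3e-2, batch_size=4))
        preds = [predict(model, vols[i]) for i in ids]
        assert np.mean(np.abs(np.array(preds) - 15.0)) < 1.0

    def test_out_of_range_label_rejected(self):
        vols = {"a": np.zeros((16, 16, 16)), "b": np.zeros((16, 16, 16))}
        split = DatasetSplit(train_ids=("a",), val_ids=("b",), test_ids=())
        with pytest.raises(ValueError):
            train(vols, {"a": 150.0, "b": 10.0}, split, _toy_config(epochs=1))


class TestPredict:
    def test_inference_deterministic_with_dropout_layers(self):
        tm = build_model(CNNConfig(input_shape=(16, 16, 16), base_filters=4, seed=2))
        x = np.random.default_rng(0).random((16, 16, 16))
        assert predict(tm, x) == predict(tm, x)

    def test_training_mode_forward_passes_differ(self):
        tm = build_model(CNNConfig(input_shape=(16, 16, 16), base_filters=4, seed=2))
        x = np.random.default_rng(0).random((1, 1, 16, 16, 16))
        rng = np.random.default_rng(5)
        a = tm.network.forward(x, training=True, rng=rng)
        b = tm.network.forward(x, training=True, rng=rng)
        assert not np.array_equal(a, b)

    def test_zero_weight_model_outputs_zero(self):
        tm = build_model(CNNConfig(input_shape=(16, 16, 16), base_filters=4))
        for _, p, _ in tm.network.parameters():
            p[...] = 0.0
        assert predict(tm, np.random.default_rng(0).random((16, 16, 16))) == 0.0

    def test_shape_mismatch_names_expected_shape(self):
        tm = build_model(CNNConfig(input_shape=(16, 16, 16), base_filters=4))
        with pytest.raises(ValueError, match=r"16, 16, 16"):
            predict(tm, np.zeros((8, 8, 8)))

    def test_checkpoint_roundtrip(self, memorized_model, tmp_path):
        model, vols, _ = memorized_model
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert predict(loaded, vols["a"]) == predict(model, vols["a"])
        assert loaded.config == model.config


class TestSearch:
    def test_search_space_audit(self):
        """5000 draws: f0 in {4..32}, lr log-uniform over [1e-8, 1e-2]."""
        rng = np.random.default_rng(7)
        draws = [sample_search_space(rng) for _ in range(5000)]
        f0 = np.array([d["base_filters"] for d in draws])
        lr = np.array([d["learning_rate"] for d in draws])
        assert f0.min() == 4 and f0.max() == 32
        assert lr.min() >= 1e-8 and lr.max() <= 1e-2
        decades, _ = np.histogram(np.log10(lr), bins=6, range=(-8, -2))
        assert decades.min() > 5000 / 6 * 0.8 and decades.max() < 5000 / 6 * 1.2

    def test_budget_one_returns_single_sampled_config(self):
        from mridensity.density_cnn import search_hyperparameters

        rng = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(4)]
        vols = {i: rng.random((16, 16, 16)) for i in ids}
        labels = {i: float(10 + i_) for i_, i in enumerate(ids)}
        split = make_split(ids, (3, 1, 0))
        best, trials = search_hyperparameters(
            vols, labels, split, _toy_config(epochs=1), budget=1, seed=3
        )
        assert len(trials) == 1
        assert best.base_filters == trials["base_filters"].iloc[0]

    def test_zero_budget_rejected(self):
        from mridensity.density_cnn import search_hyperparameters

        with pytest.raises(ValueError):
            search_hyperparameters({}, {}, DatasetSplit((), (), ()), _toy_config(), 0, 0)
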