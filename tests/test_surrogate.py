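import numpy as np
import pytest

import soilct as sc
from soilct.surrogate import (CHANNEL_BAND_PAIRS, TrainingDataset,
                              build_channel_image)



class TestChannelImage:
    def test_single_band_slice(self, scheme):
        v = sc.CTVolume(np.full((2, 4, 4), 2500, dtype=int))
        image = build_channel_image(v, scheme, 0)
        assert image.shape == (4, 4, 3)
        assert np.all(image[..., 1] == 1)
        assert np.all(image[..., 0] == 0) and np.all(image[..., 2] == 0)

    def test_channels_partition(self, rng, scheme):
        v = sc.CTVolume(rng.integers(0, 6145, size=(3, 8, 8)))
        image = build_channel_image(v, scheme, 1)
        assert np.all(image.sum(axis=-1) == 1)

    def test_matches_binarize(self, rng, scheme):
        v = sc.CTVolume(rng.integers(0, 6145, size=(3, 8, 8)))
        image = build_channel_image(v, scheme, 2)
        for c, pair in enumerate(CHANNEL_BAND_PAIRS):
            expected = sc.binarize(v, set(pair), scheme).mask[2]
            assert np.array_equal(image[..., c], expected)

    def test_out_of_range_slice_errors(self, scheme):
        v = sc.CTVolume(np.zeros((2, 4, 4), dtype=int))
        with pytest.raises(IndexError):
            build_channel_image(v, scheme, 2)

    def test_hu_mode_in_unit_range(self, rng, scheme):
        v = sc.CTVolume(rng.integers(0, 6145, size=(2, 8, 8)))
        image = build_channel_image(v, scheme, 0, mode="hu")
        assert image.min() >= 0.0 and image.max() <= 1.0
        binary = build_channel_image(v, scheme, 0)
        assert np.array_equal(image > 0, binary > 0)


class TestAssembleDataset:
    def test_one_sample_per_slice(self, small_core, scheme):
        volume, _ = small_core
        ds = sc.assemble_dataset([volume], scheme, {3})
        assert len(ds) == volume.n_slices
        assert ds.images.shape == (volume.n_slices, 32, 32, 3)

    def test_all_void_target(self, scheme):
        v = sc.CTVolume(np.full((4, 8, 8), 2500, dtype=int))
        ds = sc.assemble_dataset([v], scheme, {5})
        assert np.all(ds.targets == 1.0)

    def test_targets_match_annotation(self, small_core, scheme):
        volume, _ = small_core
        ds = sc.assemble_dataset([volume], scheme, {3}, trim_min_size=60)
        profile = sc.annotate_volume(volume, scheme, {3}, trim_min_size=60)
        assert np.array_equal(ds.targets, profile.values)

    def test_empty_volume_list_errors(self, scheme):
        with pytest.raises(ValueError):
            sc.assemble_dataset([], scheme, {3})

    def test_reproducible(self, small_core, scheme):
        volume, _ = small_core
        a = sc.assemble_dataset([volume], scheme, {2})
        b = sc.assemble_dataset([volume], scheme, {2})
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.targets, b.targets)

    def test_provenance(self, small_core, scheme):
        volume, _ = small_core
        ds = sc.assemble_dataset([volume], scheme, {1})
        assert ds.provenance[0] == (volume.sample_id, 0)
        assert ds.provenance[-1] == (volume.sample_id, volume.n_slices - 1)


class TestSplitDataset:
    @pytest.fixture()
    def dataset(self, rng):
        return TrainingDataset(rng.random((400, 8, 8, 3)),
                               rng.random(400), frozenset({3}),
                               [("s", i) for i in range(400)])

    def test_80_20(self, dataset):
        train, test = sc.split_dataset(dataset, 0.8, seed=0)
        assert len(train) == 320 and len(test) == 80

    def test_deterministic(self, dataset):
        a = sc.split_dataset(dataset, 0.8, seed=3)
        b = sc.split_dataset(dataset, 0.8, seed=3)
        assert np.array_equal(a[0].targets, b[0].targets)

    def test_union_is_original(self, dataset):
        train, test = sc.split_dataset(dataset, 0.8, seed=1)
        combined = sorted(train.provenance + test.provenance)
        assert combined == sorted(dataset.provenance)

    def test_fraction_bounds(self, dataset):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                sc.split_dataset(dataset, bad)

    def test_too_small_errors(self, rng):
        ds = TrainingDataset(rng.random((1, 4, 4, 3)), [0.5], frozenset({1}))
        with pytest.raises(ValueError):
            sc.split_dataset(ds, 0.8)


class TestBuildModel:
    def test_mini_scalar_output(self):
        model = sc.build_model((16, 16), scale="mini", seed=0)
        out = model.predict(np.zeros((2, 16, 16, 3), dtype=np.float32))
        assert out.shape == (2,)

    def test_full_topology(self):
        model = sc.build_model((224, 224), scale="full", seed=0)
        convs = [l for l in model.net.layers if l.kind == "conv"]
        denses = [l for l in model.net.layers if l.kind == "dense"]
        assert len(convs) == 13
        assert len(denses) == 3
        assert denses[-1].out_features == 1

    def test_seeded_init_identical(self):
        a = sc.build_model((16, 16), scale="mini", seed=5)
        b = sc.build_model((16, 16), scale="mini", seed=5)
        for k, v in a.net.get_weights().items():
            assert np.array_equal(v, b.net.get_weights()[k])

    def test_input_too_small_errors(self):
        with pytest.raises(ValueError):
            sc.build_model((6, 6), scale="mini")

    def test_unknown_scale_errors(self):
        with pytest.raises(ValueError):
            sc.build_model((16, 16), scale="giant")


class TestTrainAndEvaluate:
    def test_constant_target_recovery(self, rng):
        # on pure-noise inputs, recovering the constant function needs
        # regularization pressure toward zero weights
        images = rng.random((120, 8, 8, 3)).astype(np.float32)
        held_out = rng.random((30, 8, 8, 3)).astype(np.float32)
        ds = TrainingDataset(images, np.full(120, 0.5), frozenset({3}))
        model = sc.build_model((8, 8), scale="mini", seed=0)
        cfg = sc.TrainingConfig(epochs=400, batch_size=32, learning_rate=3e-3,
                                patience=400, weight_decay=0.3, seed=0)
        model, history = sc.train(model, ds, cfg)
        preds = model.predict(held_out)
        assert np.all(np.abs(preds - 0.5) < 0.01)
        assert {"epoch", "train_rmse", "val_rmse"} <= set(history.columns)

    def test_training_reproducible(self, rng):
        images = rng.random((30, 8, 8, 3)).astype(np.float32)
        targets = rng.random(30)
        histories = []
        for _ in range(2):
            model = sc.build_model((8, 8), scale="mini", seed=1)
            ds = TrainingDataset(images, targets, frozenset({3}))
            cfg = sc.TrainingConfig(epochs=3, batch_size=8, seed=1)
            _, history = sc.train(model, ds, cfg)
            histories.append(history)
        assert histories[0].equals(histories[1])

    def test_evaluate_rmse_perfect_predictor(self, rng):
        ds = TrainingDataset(rng.random((10, 8, 8, 3)),
                             np.full(10, 0.25), frozenset({1}))

        class Perfect:
            def predict(self, images):
                return np.full(len(images), 0.25)

        assert sc.evaluate_rmse(Perfect(), ds) == 0.0

    def test_evaluate_rmse_constant_predictor_closed_form(self, rng):
        targets = np.array([0.0, 1.0] * 5)
        ds = TrainingDataset(rng.random((10, 8, 8, 3)), targets, frozenset({1}))

        class Constant:
            def predict(self, images):
                return np.full(len(images), 0.5)

        assert sc.evaluate_rmse(Constant(), ds) == pytest.approx(0.5)

    def test_evaluate_rmse_formula_oracle(self, rng):
        targets = rng.random(7)
        preds = rng.random(7)
        ds = TrainingDataset(rng.random((7, 8, 8, 3)), targets, frozenset({1}))

        class Fixed:
            def predict(self, images):
                return preds

        expected = np.sqrt(np.mean((preds - targets) ** 2))
        assert sc.evaluate_rmse(Fixed(), ds) == pytest.approx(expected)

    def test_empty_dataset_errors(self, rng):
        ds = TrainingDataset(np.zeros((0, 8, 8, 3)), np.zeros(0), frozenset({1}))
        model = sc.build_model((8, 8), scale="mini", seed=0)
        with pytest.raises(ValueError):
            sc.evaluate_rmse(model, ds)


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        model = sc.build_model((8, 8), scale="mini", seed=2)
        model.fitted_metrics = {"test_rmse": 0.125}
        sc.save_model(model, tmp_path / "m.npz")
        back = sc.load_model(tmp_path / "m.npz")
        x = rng.random((4, 8, 8, 3)).astype(np.float32)
        assert np.array_equal(model.predict(x), back.predict(x))
        assert back.fitted_metrics == {"test_rmse": 0.125}

    def test_trainable_flags_persist(self, tmp_path):
        model = sc.build_model((8, 8), scale="mini", seed=2)
        sc.freeze_conv(model)
        sc.save_model(model, tmp_path / "m.npz")
        back = sc.load_model(tmp_path / "m.npz")
        assert all(not l.trainable for l in back.conv_stack)
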