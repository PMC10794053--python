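import numpy as np
import pytest

from shootcount import (
    LossConfig,
    ModelConfig,
    SceneConfig,
    TrainConfig,
    build_model,
    generate_dataset,
    load_model,
    predict_count,
    train,
)


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    cfg = SceneConfig(
        image_size=48,
        n_crowns=(1, 1),
        crown_radius=(12.0, 16.0),
        shoots_per_crown=(4, 10),
        cluster_spread=2.0,
        perspective_gain=2.0,
        blob_sigma=1.0,
        background_texture_scale=8.0,
        seed=42,
    )
    root = tmp_path_factory.mktemp("tinyset")
    manifest = generate_dataset(cfg, 10, root)
    return manifest, root


class TestBuildModel:
    def test_shape_and_sign_contract(self):
        model = build_model(ModelConfig(seed=0))
        x = np.random.default_rng(0).normal(0, 0.3, (1, 3, 64, 64))
        out = model.forward(x)
        assert out.shape == (1, 1, 16, 16)
        assert (out >= 0).all()
        assert np.isfinite(out).all()

    def test_seeded_init_is_deterministic(self):
        m1 = build_model(ModelConfig(seed=9))
        m2 = build_model(ModelConfig(seed=9))
        for p1, p2 in zip(m1.params, m2.params):
            np.testing.assert_array_equal(p1, p2)

    def test_empty_dilations_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(head_dilations=())

    def test_stride_must_match_encoder(self):
        with pytest.raises(ValueError):
            ModelConfig(encoder_channels=(8, 16), output_stride=4)

    def test_backprop_matches_finite_difference(self):
        model = build_model(ModelConfig(seed=1))
        x = np.random.default_rng(1).normal(0, 0.3, (1, 3, 8, 8))
        model.backward(np.ones_like(model.forward(x)))
        conv = model.branches[0]
        g = conv.dW[0, 0, 1, 1]
        h = 1e-6
        conv.W[0, 0, 1, 1] += h
        f1 = model.forward(x).sum()
        conv.W[0, 0, 1, 1] -= 2 * h
        f2 = model.forward(x).sum()
        conv.W[0, 0, 1, 1] += h
        assert g == pytest.approx((f1 - f2) / (2 * h), rel=1e-4, abs=1e-8)

    def test_save_load_round_trip(self, tmp_path):
        model = build_model(ModelConfig(seed=3))
        x = np.random.default_rng(2).normal(0, 0.3, (1, 3, 16, 16))
        ref = model.forward(x)
        model.save(tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.forward(x), ref)


class TestPredictCount:
    def test_zero_final_weights_count_zero(self):
        model = build_model(ModelConfig(seed=0))
        model.project.W[...] = 0.0
        model.project.b[...] = 0.0
        img = np.zeros((48, 48, 3), dtype=np.uint8)
        dm, count = predict_count(model, img)
        assert count == 0.0

    def test_count_is_grid_sum(self):
        model = build_model(ModelConfig(seed=0))
        img = np.random.default_rng(0).integers(0, 255, (48, 48, 3), dtype=np.uint8)
        dm, count = predict_count(model, img)
        assert count == pytest.approx(dm.grid.sum(), abs=1e-6)
        assert dm.stride == 4

    def test_non_multiple_dims_padded(self):
        model = build_model(ModelConfig(seed=0))
        img = np.zeros((50, 45, 3), dtype=np.uint8)
        dm, _ = predict_count(model, img)
        assert dm.grid.shape == (13, 12)


class TestTrain:
    def test_one_epoch_smoke_logs_finite_losses(self, tiny_dataset):
        manifest, root = tiny_dataset
        model = build_model(ModelConfig(seed=0))
        cfg = TrainConfig(batch_size=4, learning_rate=1e-3, epochs=1, seed=0,
                          loss=LossConfig(max_iter=40, tol=1e-4))
        rec = train(model, manifest, root, cfg)
        assert len(rec.epochs) == 1
        e = rec.epochs[0]
        for key in ("count_loss", "ot_loss", "pixel_mse", "total", "val_mae"):
            assert np.isfinite(e[key])

    def test_logged_total_satisfies_breakdown_identity(self, tiny_dataset):
        manifest, root = tiny_dataset
        model = build_model(ModelConfig(seed=1))
        lc = LossConfig(max_iter=40, tol=1e-4)
        cfg = TrainConfig(batch_size=4, learning_rate=1e-3, epochs=1, seed=1, loss=lc)
        rec = train(model, manifest, root, cfg)
        e = rec.epochs[0]
        assert e["total"] == pytest.approx(
            e["count_loss"] + lc.lambda1 * e["ot_loss"] + lc.lambda2 * e["pixel_mse"],
            abs=1e-6,
        )

    def test_pure_count_regression_decreases_count_loss(self, tiny_dataset):
        manifest, root = tiny_dataset
        model = build_model(ModelConfig(seed=2))
        cfg = TrainConfig(
            batch_size=4, learning_rate=1e-3, epochs=6, seed=2,
            loss=LossConfig(lambda1=0.0, lambda2=0.0, max_iter=1, tol=1.0),
        )
        rec = train(model, manifest, root, cfg)
        losses = [e["count_loss"] for e in rec.epochs]
        assert losses[-1] < losses[0]

    def test_overlapping_folds_rejected(self, tiny_dataset):
        manifest, root = tiny_dataset
        ids = list(manifest["image_id"])
        model = build_model(ModelConfig(seed=0))
        with pytest.raises(ValueError):
            train(model, manifest, root, TrainConfig(epochs=1),
                  train_ids=ids[:5], val_ids=ids[4:6])

    def test_invalid_train_config(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
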