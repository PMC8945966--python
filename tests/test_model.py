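import numpy as np
import pytest

from ecg2bp.errors import ConfigError, DataError, ModelPersistenceError, ShapeError
from ecg2bp.labeling import label_frames
from ecg2bp.model import (
    ModelConfig,
    TrainConfig,
    build_model,
    load_model,
    predict,
    save_model,
    train,
)
from ecg2bp.preprocess import FramePair, preprocess_record
from ecg2bp.synth import SyntheticConfig, simulate_record

RNG = np.random.default_rng(123)


def random_frames(n, frame_len=128):
    return RNG.standard_normal((n, frame_len))


class TestArchitecture:
    def test_layer_structure(self):
        m = build_model(seed=0)
        # four conv layers with the configured filter progression
        for i, f in enumerate((32, 64, 128, 256)):
            assert m.params[f"conv{i}_W"].shape[0] == f
        assert "conv4_W" not in m.params
        # 128-unit feature layer, then FC 32 and 16, then the 2-output head
        assert m.params["fc0_W"].shape == (256, 128)
        assert m.params["fc1_W"].shape == (128, 32)
        assert m.params["fc2_W"].shape == (32, 16)
        assert m.params["fc3_W"].shape == (16, 2)

    def test_single_frame_two_outputs(self):
        m = build_model(seed=0)
        out = m.forward(random_frames(1))
        assert out.shape == (1, 2)

    def test_identical_frames_identical_outputs(self):
        m = build_model(seed=0)
        x = random_frames(1)
        out = m.forward(np.vstack([x, x]))
        np.testing.assert_array_equal(out[0], out[1])

    def test_build_deterministic_under_seed(self):
        x = random_frames(3)
        np.testing.assert_array_equal(build_model(seed=5).forward(x),
                                      build_model(seed=5).forward(x))

    def test_batch_invariance(self):
        m = build_model(seed=1)
        X = random_frames(7)
        batch = m.predict_mmhg(X)
        single = np.vstack([m.predict_mmhg(X[i:i + 1]) for i in range(7)])
        np.testing.assert_allclose(batch, single, atol=1e-5)

    def test_frame_len_divisibility_enforced(self):
        with pytest.raises(ConfigError):
            ModelConfig(frame_len=100)

    def test_wrong_frame_length_rejected(self):
        m = build_model(seed=0)
        with pytest.raises(ShapeError):
            m.forward(random_frames(2, frame_len=127))

    def test_conv_layer_count_fixed(self):
        with pytest.raises(ConfigError):
            ModelConfig(conv_filters=(32, 64, 128))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences on a tiny net."""
        cfg = ModelConfig(frame_len=16, conv_filters=(2, 3, 2, 2), kernel_size=3,
                          feature_dim=4, fc_nodes=(3, 2))
        m = build_model(cfg, seed=0)
        X = np.random.default_rng(1).standard_normal((4, 16))
        y = np.random.default_rng(2).standard_normal((4, 2)).astype(np.float32)

        def loss():
            return float(np.mean((m.forward(X) - y) ** 2))

        out, caches = m.forward(X, want_cache=True)
        err = (out - y).astype(np.float32)
        grads = m.backward(2.0 * err / err.size, caches)
        h = 1e-2
        for name in ("conv0_W", "conv3_b", "fc0_W", "fc3_W", "fc3_b"):
            p = m.params[name]
            flat_idx = np.random.default_rng(3).integers(0, p.size, size=3)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + h
                lp = loss()
                p[idx] = orig - h
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * h)
                ana = grads[name][idx]
                assert ana == pytest.approx(num, rel=0.05, abs=5e-4), name


@pytest.fixture(scope="module")
def coupled_frames():
    """~200 noise-free frames with a strong, clean HR->BP relation."""
    frames, labels = [], []
    for i, hr in enumerate((55, 65, 75, 85, 95)):
        cfg = SyntheticConfig(duration_s=60, hr_bpm=hr, hr_sd=1.0,
                              bp_drift=0.0, coupling=(90.0, 0.5),
                              coupling_noise_sd=0.0, pulse_pressure_sd=0.0,
                              noise_sd=0.0, powerline_amp=0.0,
                              wander_amp=0.0, seed=100 + i)
        rec, _ = simulate_record(cfg)
        fr = preprocess_record(rec)
        frames += fr
        labels += label_frames(fr, rec.fs)
    return frames[:200], labels[:200]


class TestTraining:
    def test_loss_decreases_an_order_of_magnitude(self, coupled_frames):
        frames, labels = coupled_frames
        m = build_model(seed=0)
        m, hist = train(m, frames, labels,
                        TrainConfig(max_epochs=50, patience=50, seed=0))
        assert hist.train_loss[-1] < 0.1 * hist.train_loss[0]

    def test_training_deterministic(self, coupled_frames):
        frames, labels = coupled_frames
        def go():
            m = build_model(seed=4)
            return train(m, frames[:64], labels[:64],
                         TrainConfig(max_epochs=5, patience=5, seed=4))
        m1, h1 = go()
        m2, h2 = go()
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_best_epoch_is_val_argmin_and_split_disjoint(self, coupled_frames):
        frames, labels = coupled_frames
        m = build_model(seed=2)
        m, hist = train(m, frames, labels,
                        TrainConfig(max_epochs=12, patience=12, seed=2))
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)
        tr, va = set(hist.train_indices), set(hist.val_indices)
        assert not (tr & va)
        assert len(tr) + len(va) == sum(l.valid for l in labels)

    def test_record_level_split_keeps_records_together(self, coupled_frames):
        frames, labels = coupled_frames
        m = build_model(seed=2)
        m, hist = train(m, frames, labels,
                        TrainConfig(max_epochs=2, patience=2, seed=2,
                                    split_mode="record"))
        valid = [f for f, l in zip(frames, labels) if l.valid]
        tr_recs = {valid[i].source_record for i in hist.train_indices}
        va_recs = {valid[i].source_record for i in hist.val_indices}
        assert not (tr_recs & va_recs)

    def test_empty_data_rejected(self):
        m = build_model(seed=0)
        with pytest.raises(DataError):
            train(m, [], [], TrainConfig())

    def test_prediction_ignores_abp_content(self, coupled_frames):
        """The estimator reads only the ECG path of a frame."""
        frames, labels = coupled_frames
        m = build_model(seed=0)
        f = frames[0]
        mutated = FramePair(ecg=f.ecg.copy(), abp=np.full(128, 999.0),
                            frame_index=f.frame_index)
        np.testing.assert_array_equal(predict(m, [f]), predict(m, [mutated]))


class TestPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path, labeled_frames):
        frames, labels, _ = labeled_frames
        m = build_model(seed=0)
        m, _ = train(m, frames, labels, TrainConfig(max_epochs=2, patience=2, seed=0))
        X = np.asarray([f.ecg for f in frames[:5]])
        save_model(m, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_array_equal(m.predict_mmhg(X), back.predict_mmhg(X))
        np.testing.assert_array_equal(m.target_mean, back.target_mean)

    def test_not_a_model_dir(self, tmp_path):
        with pytest.raises(ModelPersistenceError):
            load_model(tmp_path)

    def test_tampered_weights_rejected(self, tmp_path):
        m = build_model(seed=0)
        save_model(m, tmp_path / "m")
        w = tmp_path / "m" / "weights.npz"
        w.write_bytes(w.read_bytes()[:100])
        with pytest.raises(ModelPersistenceError):
            load_model(tmp_path / "m")

    def test_mismatched_config_rejected(self, tmp_path):
        import json
        m = build_model(seed=0)
        save_model(m, tmp_path / "m")
        cfgf = tmp_path / "m" / "config.json"
        meta = json.loads(cfgf.read_text())
        meta["config"]["frame_len"] = 256  # weights no longer fit
        cfgf.write_text(json.dumps(meta))
        with pytest.raises(ModelPersistenceError):
            load_model(tmp_path / "m")
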