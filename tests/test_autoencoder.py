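"""Semi-supervised auto-encoder: structure, losses, and training behavior."""

import math

import numpy as np
import pytest

from asdvoice import autoencoder as am
from asdvoice.nn.train import TrainConfig


def zeroed(model):
    for p in model.parameters():
        p.data[...] = 0.0
    return model


class TestConstruction:
    def test_default_shapes(self):
        model = am.init_autoencoder()
        view = model.parameters_view()
        assert [w.shape for w in view.weights] == [(88, 70), (70, 54),
                                                   (54, 70), (70, 88)]
        assert view.aux_weight.shape == (54, 2)
        assert model.config.latent_dim == 54

    def test_same_seed_bit_identical(self):
        a = am.init_autoencoder(am.AEConfig(seed=4))
        b = am.init_autoencoder(am.AEConfig(seed=4))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_asymmetric_dims_rejected(self):
        with pytest.raises(ValueError):
            am.AEConfig(layer_dims=(88, 70, 54, 60, 88))

    def test_bottleneck_required(self):
        with pytest.raises(ValueError):
            am.AEConfig(layer_dims=(88, 90, 100, 90, 88))

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            am.AEConfig(alpha=-0.1)


class TestForwardPasses:
    def test_zero_model_zero_input_gives_zero_latent(self):
        model = zeroed(am.init_autoencoder())
        z = am.encode(model, np.zeros(88))
        assert z.shape == (54,)
        np.testing.assert_array_equal(z, np.zeros(54))

    def test_encode_output_dim_and_determinism(self, rng):
        model = am.init_autoencoder()
        x = rng.standard_normal(88)
        z1, z2 = am.encode(model, x), am.encode(model, x)
        assert z1.shape == (54,)
        np.testing.assert_array_equal(z1, z2)

    def test_decode_zero_model_returns_bias(self):
        model = zeroed(am.init_autoencoder())
        model.decoder_layers[-1].b.data[...] = 2.5
        np.testing.assert_allclose(am.decode(model, np.zeros(54)), 2.5)

    def test_aux_zero_logits_is_uniform(self):
        model = zeroed(am.init_autoencoder())
        np.testing.assert_allclose(am.aux_classify(model, np.zeros(54)),
                                   [0.5, 0.5])

    def test_aux_probs_normalized(self, rng):
        model = am.init_autoencoder()
        p = am.aux_classify(model, rng.standard_normal((40, 54)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_input_length_errors(self):
        model = am.init_autoencoder()
        with pytest.raises(ValueError):
            am.encode(model, np.zeros(87))
        with pytest.raises(ValueError):
            am.decode(model, np.zeros(88))


class TestLosses:
    def test_recon_identity_and_offset(self, rng):
        y = rng.standard_normal((6, 88))
        assert am.recon_loss(y, y) == 0.0
        assert am.recon_loss(y + 1.0, y) == pytest.approx(1.0, abs=1e-12)

    def test_recon_matches_summation_oracle(self, rng):
        a, b = rng.standard_normal((7, 88)), rng.standard_normal((7, 88))
        oracle = np.abs(a - b).sum() / a.size
        assert am.recon_loss(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_recon_shape_mismatch(self):
        with pytest.raises(ValueError):
            am.recon_loss(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_aux_perfect_and_uniform(self):
        assert am.aux_loss([0.0, 1.0], [0.0, 1.0]) == pytest.approx(0.0, abs=1e-6)
        assert am.aux_loss([0.5, 0.5], [1.0, 0.0]) == pytest.approx(math.log(2),
                                                                   abs=1e-10)

    def test_aux_matches_neg_log_oracle(self, rng):
        for _ in range(100):
            p1 = rng.uniform(1e-3, 1 - 1e-3)
            label = rng.integers(0, 2)
            y = [1 - p1, p1]
            onehot = [1 - label, label]
            oracle = -math.log(y[label])
            assert am.aux_loss(y, onehot) == pytest.approx(oracle, abs=1e-10)

    def test_aux_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            am.aux_loss([0.7, 0.7], [1.0, 0.0])

    def test_total_is_weighted_sum(self, rng):
        assert am.total_loss(1.0, 0.5, 0.3) == pytest.approx(1.15, abs=1e-12)
        for _ in range(50):
            r, a, al = rng.uniform(0, 5, 3)
            assert am.total_loss(r, a, al) == r + al * a
        assert am.total_loss(2.0, 5.0, alpha=0.0) == 2.0
        assert am.total_loss(2.0, 0.0) == 2.0
        with pytest.raises(ValueError):
            am.total_loss(1.0, 1.0, alpha=-0.3)


class TestTraining:
    def test_reconstruction_convergence_on_low_rank_data(self, rng):
        H = rng.standard_normal((3000, 10))
        A = rng.standard_normal((10, 88))
        X = H @ A
        X = (X - X.mean(0)) / X.std(0)
        y = np.tile([1.0, 0.0], (3000, 1))
        model, hist = am.train_autoencoder(
            X[:2500], y[:2500], X[2500:], y[2500:],
            am.AEConfig(alpha=0.0, seed=1),
            TrainConfig(max_epochs=60, batch_size=256, seed=1))
        assert hist.train_loss[-1] < hist.train_loss[0]  # strict decrease
        rec = am.decode(model, am.encode(model, X[2500:]))
        assert am.recon_loss(rec, X[2500:]) < 0.1  # in SD units

    def test_aux_head_separates_and_sharpens_latent_space(self, rng):
        n = 2000
        X = rng.standard_normal((n, 88))
        lab = rng.integers(0, 2, n)  # 1 = ASD
        X[:, :20] += (lab[:, None] * 2 - 1) * 1.5  # class-mean gap of 3 SD
        y = np.zeros((n, 2))
        y[np.arange(n), lab] = 1.0
        model, _ = am.train_autoencoder(
            X[:1600], y[:1600], X[1600:], y[1600:],
            am.AEConfig(alpha=0.3, seed=2),
            TrainConfig(max_epochs=40, batch_size=256, seed=2))
        z = am.encode(model, X[1600:])
        held_lab = lab[1600:]
        acc = (am.aux_classify(model, z).argmax(axis=1) == held_lab).mean()
        assert acc > 0.9

        def separation(M, labels):
            a, t = M[labels == 1], M[labels == 0]
            dist = np.linalg.norm(a.mean(0) - t.mean(0))
            within = np.sqrt(np.mean(
                np.concatenate([a - a.mean(0), t - t.mean(0)]).var(axis=0)))
            return dist / within

        # semi-supervised bottleneck increases class separation over raw space
        assert separation(z, held_lab) > separation(X[1600:], held_lab)

    def test_identical_seeds_identical_history(self, rng):
        X = rng.standard_normal((300, 88))
        y = np.tile([1.0, 0.0], (300, 1))
        args = (X[:250], y[:250], X[250:], y[250:], am.AEConfig(seed=3),
                TrainConfig(max_epochs=5, batch_size=64, seed=3))
        _, h1 = am.train_autoencoder(*args)
        _, h2 = am.train_autoencoder(*args)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            am.train_autoencoder(np.empty((0, 88)), np.empty((0, 2)),
                                 np.zeros((1, 88)), np.array([[1.0, 0.0]]))


def test_checkpoint_roundtrip(tmp_path, rng):
    X = rng.standard_normal((200, 88))
    y = np.tile([0.0, 1.0], (200, 1))
    model, _ = am.train_autoencoder(X[:150], y[:150], X[150:], y[150:],
                                    am.AEConfig(seed=6),
                                    TrainConfig(max_epochs=3, batch_size=64, seed=6))
    am.save_checkpoint(model, tmp_path / "ae.json")
    back = am.load_checkpoint(tmp_path / "ae.json")
    x = rng.standard_normal((5, 88))
    np.testing.assert_array_equal(am.encode(model, x), am.encode(back, x))
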