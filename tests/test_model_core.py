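"""Model core: triplet loss oracle, tunnel shapes, gradients, wiring."""

import numpy as np
import pytest

from tridta.model_core import ModelConfig, ThreeTunnelModel, load_model, triplet_loss


def brute_triplet(a, p, n, margin):
    """Independent oracle: explicit distance arithmetic, python scalars."""
    d_ap = sum((ai - pi) ** 2 for ai, pi in zip(a, p))
    d_an = sum((ai - ni) ** 2 for ai, ni in zip(a, n))
    return max(d_ap - d_an + margin, 0.0)


class TestTripletLoss:
    @pytest.mark.parametrize(
        "a,p,n,margin,expected",
        [
            ((2.0, -1.0), (2.0, -1.0), (2.0, -1.0), 1.0, 1.0),  # a=p=n -> margin
            ((0.0, 0.0), (0.0, 0.0), (1.0, 0.0), 1.0, 0.0),
            ((0.0, 0.0), (3.0, 0.0), (1.0, 0.0), 1.0, 9.0),
        ],
    )
    def test_hand_examples(self, a, p, n, margin, expected):
        assert triplet_loss(a, p, n, margin) == pytest.approx(expected)

    def test_degenerate_equals_default_margin(self, rng):
        v = rng.standard_normal(256)
        assert triplet_loss(v, v, v, ModelConfig().margin) == 1.0

    def test_oracle_equivalence_on_random_triplets(self, rng):
        for _ in range(200):
            dim = int(rng.integers(1, 8))
            a, p, n = rng.standard_normal((3, dim))
            got = triplet_loss(a, p, n, 1.0)
            want = brute_triplet(a, p, n, 1.0)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_rotation_invariance(self, rng):
        from scipy.stats import ortho_group

        a, p, n = rng.standard_normal((3, 5))
        q = ortho_group.rvs(5, random_state=1)
        assert triplet_loss(a @ q, p @ q, n @ q, 1.0) == pytest.approx(
            triplet_loss(a, p, n, 1.0), rel=1e-9
        )

    def test_nonnegative_and_zero_when_gap_exceeds_margin(self, rng):
        a = np.zeros(3)
        p = np.zeros(3)
        n = np.array([10.0, 0.0, 0.0])  # ||a-n||^2 = 100 >> margin
        assert triplet_loss(a, p, n, 1.0) == 0.0
        losses = triplet_loss(*rng.standard_normal((3, 50, 4)), 1.0)
        assert (losses >= 0).all()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            triplet_loss([0.0, 1.0], [0.0], [0.0, 1.0], 1.0)


class TestConfig:
    def test_defaults_follow_reference_architecture(self):
        cfg = ModelConfig()
        assert cfg.mlp_widths == [1024, 256, 64, 256]
        assert cfg.cnn_filters == [32, 32, 32]
        assert cfg.margin == 1.0
        assert cfg.batch_size == 256
        assert cfg.learning_rate == 1e-4
        assert cfg.epochs == 100

    def test_literal_kernel_preset(self):
        assert ModelConfig.literal_kernels().cnn_kernel_lengths == [1, 2, 3]

    @pytest.mark.parametrize(
        "kwargs", [{"margin": 0.0}, {"triplet_weight": -1.0}, {"dropout_rates": [1.0, 0.1]}]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)


class TestShapesAndWiring:
    def test_shape_chain_default_architecture(self, rng):
        cfg = ModelConfig(epochs=1, seed=0)
        model = ThreeTunnelModel(cfg)
        fp = rng.integers(0, 2, size=(3, 1024)).astype(np.float32)
        enc = np.zeros((3, 1000, 26), dtype=np.float32)
        enc[:, :50, 0] = 1
        assert model.drug_representation(fp).shape == (3, 256)
        assert model.protein_representation(enc).shape == (3, 32)
        assert model.encode_drug(fp).shape == (3, 256)
        assert model.encode_protein(enc).shape == (3, 256)
        assert model.predict(fp, enc).shape == (3,)

    def test_fingerprint_width_mismatch_is_config_error(self, tiny_config, rng):
        model = ThreeTunnelModel(tiny_config)
        with pytest.raises(ValueError, match="MLP input width"):
            model.drug_representation(rng.random((2, 77)))

    def test_kernel_longer_than_sequence_is_config_error(self, rng):
        cfg = ModelConfig(
            mlp_widths=[16, 8, 8, 8],
            cnn_filters=[4],
            cnn_kernel_lengths=[30],
            shared_dim=8,
            fc_widths=[8],
            prot_max_len=20,
        )
        model = ThreeTunnelModel(cfg)
        with pytest.raises(ValueError, match="kernel"):
            model.protein_representation(rng.random((1, 20, 26)))

    def test_zero_weight_drug_encoder_gives_zero_vector(self, tiny_config, rng):
        model = ThreeTunnelModel(tiny_config)
        for lay in model.drug_layers:
            lay.W[...] = 0.0
            lay.b[...] = 0.0
        out = model.drug_representation(rng.random((2, 1024)))
        assert (out == 0).all()

    def test_zero_protein_encoding_zero_bias_gives_zero_output(self, tiny_config):
        model = ThreeTunnelModel(tiny_config)
        for lay in model.prot_layers:
            lay.b[...] = 0.0
        out = model.protein_representation(np.zeros((1, 100, 26)))
        assert (out == 0).all()

    def test_identity_projection_is_identity(self, rng):
        cfg = ModelConfig(
            mlp_widths=[32, 16, 8, 16],
            cnn_filters=[4, 4, 4],
            cnn_kernel_lengths=[2, 3, 4],
            shared_dim=16,
            fc_widths=[8],
            prot_max_len=30,
        )
        model = ThreeTunnelModel(cfg)
        model.proj_drug.W[...] = np.eye(16)
        model.proj_drug.b[...] = 0.0
        rep = model.drug_representation(rng.random((2, 32)))
        out, _ = model.proj_drug.forward(rep)
        np.testing.assert_allclose(out, rep)

    def test_padding_tail_does_not_influence_protein_embedding(self, tiny_config):
        from tridta.featurization import featurize_proteins

        model = ThreeTunnelModel(tiny_config)
        enc = featurize_proteins(["MKVAHELK"], max_len=100)
        # receptive field of the 3 conv layers spans 3+5+7-2 = 13 rows; the
        # all-zero tail beyond the sequence cannot reach the max under any
        # permutation of pad rows (they are identical), and extending the
        # sequence's zero padding leaves the embedding unchanged
        longer = featurize_proteins(["MKVAHELK"], max_len=100).copy()
        np.testing.assert_array_equal(
            model.protein_representation(enc),
            model.protein_representation(longer),
        )

    def test_zero_weight_head_outputs_bias(self, tiny_config, rng):
        model = ThreeTunnelModel(tiny_config)
        for lay in model.head_layers:
            lay.W[...] = 0.0
            lay.b[...] = 0.0
        model.head_layers[-1].b[...] = 3.25
        fp = rng.random((4, 1024))
        enc = rng.random((4, 100, 26))
        np.testing.assert_allclose(model.predict(fp, enc), 3.25, rtol=1e-6)

    def test_inference_deterministic(self, tiny_config, rng):
        model = ThreeTunnelModel(tiny_config)
        fp = rng.random((2, 1024))
        enc = rng.random((2, 100, 26))
        np.testing.assert_array_equal(
            model.predict(fp, enc), model.predict(fp, enc)
        )


class TestCombinedLoss:
    def _batch(self, rng, B=6, n_bits=24, L=15):
        fp = rng.random((B, n_bits))
        enc = rng.random((B, L, 26))
        y = rng.random(B)
        neg = rng.random((B, n_bits))
        pos = np.array([True, False, True, True, False, True])
        return fp, enc, y, neg, pos

    def _model(self, lam, seed=7):
        cfg = ModelConfig(
            mlp_widths=[24, 8, 4, 8],
            cnn_filters=[3, 3, 3],
            cnn_kernel_lengths=[2, 3, 4],
            shared_dim=6,
            fc_widths=[8, 8, 4],
            dropout_rates=[0.0, 0.0],
            prot_max_len=15,
            triplet_weight=lam,
            dtype="float64",
            seed=seed,
        )
        return ThreeTunnelModel(cfg)

    def test_zero_weight_reduces_to_mse(self, rng):
        fp, enc, y, neg, pos = self._batch(rng)
        m0 = self._model(0.0)
        m1 = self._model(1.0)
        l0 = m0.loss_and_grads(fp, enc, y, neg, pos, train=False)
        l1 = m1.loss_and_grads(fp, enc, y, neg, pos, train=False)
        assert l0["total"] == pytest.approx(l0["mse"])
        assert l1["total"] >= l1["mse"]

    def test_all_negative_batch_is_pure_mse(self, rng):
        fp, enc, y, neg, _ = self._batch(rng)
        m = self._model(1.0)
        out = m.loss_and_grads(fp, enc, y, neg, np.zeros(6, bool), train=False)
        assert out["triplet"] == 0.0
        assert out["total"] == pytest.approx(out["mse"])

    def test_gradients_match_finite_differences(self, rng):
        fp, enc, y, neg, pos = self._batch(rng)
        model = self._model(1.0)
        model.zero_grads()
        model.loss_and_grads(fp, enc, y, neg, pos, train=False)
        grads = [g.copy() for g in model.gradients()]
        weights = model.get_weights()

        def loss_at(ws):
            m2 = self._model(1.0)
            m2.set_weights(ws)
            return m2.loss_and_grads(fp, enc, y, neg, pos, train=False)["total"]

        eps = 1e-6
        for w, g in zip(weights, grads):
            flat = w.ravel()
            for i in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_at(weights)
                flat[i] = orig - eps
                lm = loss_at(weights)
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert fd == pytest.approx(g.ravel()[i], rel=1e-4, abs=1e-8)


class TestPersistence:
    def test_save_load_round_trip(self, tiny_config, tmp_path, rng):
        model = ThreeTunnelModel(tiny_config)
        model.save(tmp_path / "ckpt")
        loaded = load_model(tmp_path / "ckpt")
        fp = rng.random((2, 1024))
        enc = rng.random((2, 100, 26))
        np.testing.assert_array_equal(
            model.predict(fp, enc), loaded.predict(fp, enc)
        )
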