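import math

import numpy as np
import pytest

from gaitmood import (
    ConfigError,
    ContractError,
    LSTMCellWeights,
    NetworkConfig,
    build_model,
    build_network,
    count_parameters,
    forward,
    gru_memory_update,
    lstm_cell_step,
    lstm_layer_forward,
    predict,
)
from gaitmood._backend import LSTMLayer, softmax


def zero_weights(input_dim, units):
    z = np.zeros
    return LSTMCellWeights(
        W_ix=z((units, input_dim)), W_fx=z((units, input_dim)),
        W_ox=z((units, input_dim)), W_cx=z((units, input_dim)),
        W_ia=z((units, units)), W_fa=z((units, units)),
        W_oa=z((units, units)), W_ca=z((units, units)),
        b_i=z(units), b_f=z(units), b_o=z(units), b_c=z(units),
    )


class TestNetworkConfig:
    def test_default_is_tapered(self):
        cfg = NetworkConfig(input_dim=273)
        assert cfg.lstm_units == (128, 64, 64)
        assert cfg.mlp_units == (64, 32, 32)

    def test_non_tapered_rejected(self):
        with pytest.raises(ConfigError, match="tapered"):
            NetworkConfig(input_dim=10, lstm_units=(32, 64))

    def test_non_tapered_override(self):
        cfg = NetworkConfig(input_dim=10, lstm_units=(32, 64),
                            allow_non_tapered=True)
        assert cfg.lstm_units == (32, 64)

    def test_equal_units_allowed(self):
        NetworkConfig(input_dim=10, lstm_units=(64, 64), mlp_units=(32, 32))

    def test_invalid_dropout(self):
        with pytest.raises(ConfigError):
            NetworkConfig(input_dim=10, dropout_rate=1.0)

    def test_n_classes_minimum(self):
        with pytest.raises(ConfigError):
            NetworkConfig(input_dim=10, n_classes=1)


class TestLstmCellStep:
    def test_all_zero(self):
        w = zero_weights(3, 2)
        a, c = lstm_cell_step(w, np.zeros(3), np.zeros(2), np.zeros(2))
        np.testing.assert_array_equal(a, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    def test_saturated_forget_gate_preserves_memory(self):
        w = zero_weights(1, 1)
        w.b_f[:] = 50.0  # forget gate ~ 1
        _, c = lstm_cell_step(w, np.zeros(1), np.zeros(1), np.array([3.0]))
        assert c[0] == pytest.approx(3.0, abs=1e-12)

    def test_scalar_brute_force(self, rng):
        # independent evaluation of the five gate equations with math.*
        w = LSTMCellWeights.random(1, 1, rng)
        x, a_prev, c_prev = 0.7, -0.3, 0.9

        def sig(v):
            return 1.0 / (1.0 + math.exp(-v))

        i = sig(w.W_ix[0, 0] * x + w.W_ia[0, 0] * a_prev + w.b_i[0])
        f = sig(w.W_fx[0, 0] * x + w.W_fa[0, 0] * a_prev + w.b_f[0])
        o = sig(w.W_ox[0, 0] * x + w.W_oa[0, 0] * a_prev + w.b_o[0])
        g = math.tanh(w.W_cx[0, 0] * x + w.W_ca[0, 0] * a_prev + w.b_c[0])
        c_expected = f * c_prev + i * g
        a_expected = o * math.tanh(c_expected)

        a, c = lstm_cell_step(
            w, np.array([x]), np.array([a_prev]), np.array([c_prev])
        )
        assert c[0] == pytest.approx(c_expected, abs=1e-12)
        assert a[0] == pytest.approx(a_expected, abs=1e-12)

    def test_activation_bounded(self, rng):
        w = LSTMCellWeights.random(4, 3, rng, scale=2.0)
        a, _ = lstm_cell_step(w, rng.normal(size=4) * 5,
                              rng.uniform(-1, 1, 3), rng.normal(size=3))
        assert np.all(np.abs(a) < 1.0)

    def test_shape_mismatch(self, rng):
        w = LSTMCellWeights.random(3, 2, rng)
        with pytest.raises(ContractError):
            lstm_cell_step(w, np.zeros(4), np.zeros(2), np.zeros(2))


class TestGruMemoryUpdate:
    def test_gate_zero(self):
        c = gru_memory_update(np.zeros(3), np.arange(3.0), np.ones(3))
        np.testing.assert_array_equal(c, np.arange(3.0))

    def test_gate_one(self):
        c = gru_memory_update(np.ones(2), np.zeros(2), np.array([5.0, -1.0]))
        np.testing.assert_array_equal(c, [5.0, -1.0])

    def test_midpoint(self):
        c = gru_memory_update(np.array([0.5]), np.array([2.0]), np.array([4.0]))
        assert c[0] == pytest.approx(3.0)

    def test_gate_outside_unit_interval(self):
        with pytest.raises(ContractError):
            gru_memory_update(np.array([1.5]), np.zeros(1), np.zeros(1))


class TestLstmLayerForward:
    def test_t1_equals_single_step(self, rng):
        w = LSTMCellWeights.random(3, 2, rng)
        x = rng.normal(size=(1, 3))
        seq = lstm_layer_forward(w, x)
        a, _ = lstm_cell_step(w, x[0], np.zeros(2), np.zeros(2))
        np.testing.assert_allclose(seq[0], a, atol=1e-12)

    def test_zero_everything(self):
        w = zero_weights(3, 2)
        out = lstm_layer_forward(w, np.zeros((6, 3)))
        np.testing.assert_array_equal(out, 0.0)

    def test_last_step_option(self, rng):
        w = LSTMCellWeights.random(3, 2, rng)
        x = rng.normal(size=(5, 3))
        seq = lstm_layer_forward(w, x, return_sequence=True)
        last = lstm_layer_forward(w, x, return_sequence=False)
        np.testing.assert_array_equal(seq[-1], last)

    @pytest.mark.parametrize("trial", range(20))
    def test_backend_layer_equivalence(self, trial):
        # reference per-step cell vs the vectorized training-backend layer,
        # same weights mapped into the fused layout
        rng = np.random.default_rng(1000 + trial)
        d = int(rng.integers(1, 6))
        u = int(rng.integers(1, 9))
        t = int(rng.integers(1, 11))
        w = LSTMCellWeights.random(d, u, rng)
        x = rng.normal(size=(t, d))
        ref = lstm_layer_forward(w, x)
        layer = LSTMLayer(d, u, return_sequences=True,
                          rng=np.random.default_rng(0))
        wx, wh, b = w.to_fused()
        layer.params = {"Wx": wx, "Wh": wh, "b": b}
        out = layer.forward(x[None, :, :], training=False)
        np.testing.assert_allclose(out[0], ref, atol=1e-5)


class TestBuildNetworkAndCounts:
    def test_default_descriptors(self):
        spec = build_network(NetworkConfig(input_dim=273))
        weighted = [l for l in spec.layers if l.n_trainable > 0]
        assert len(weighted) == 7  # 3 LSTM + 3 dense + output
        assert [l.kind for l in weighted] == [
            "lstm", "lstm", "lstm", "dense", "dense", "dense", "output"
        ]
        assert weighted[0].fan_in == 273 and weighted[0].fan_out == 128
        assert spec.layers[-1].activation == "softmax"

    def test_batchnorm_adds_256(self):
        base = build_network(NetworkConfig(input_dim=273))
        bn = build_network(
            NetworkConfig(input_dim=273, batchnorm_after_first_mlp=True)
        )
        assert bn.total_params - base.total_params == 4 * 64 == 256
        descriptor = [l for l in bn.layers if l.kind == "batchnorm"]
        assert len(descriptor) == 1
        assert descriptor[0].n_trainable == 128 and descriptor[0].n_aux == 128

    def test_two_class_variant(self):
        spec = build_network(NetworkConfig(input_dim=48, n_classes=2))
        assert spec.layers[-1].fan_out == 2

    @pytest.mark.parametrize(
        "input_dim,batchnorm,expected",
        [(273, False, 295_684), (273, True, 295_940), (48, False, 180_484)],
    )
    def test_published_counts(self, input_dim, batchnorm, expected):
        cfg = NetworkConfig(input_dim=input_dim,
                            batchnorm_after_first_mlp=batchnorm)
        assert count_parameters(cfg) == expected
        assert build_network(cfg).total_params == expected
        assert build_model(cfg, seed=0).n_parameters == expected

    def test_closed_form_matches_built_model_50_fuzzed(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n_lstm = int(rng.integers(1, 4))
            n_mlp = int(rng.integers(1, 4))
            lstm_units = tuple(
                sorted((int(rng.integers(1, 12)) for _ in range(n_lstm)),
                       reverse=True)
            )
            mlp_units = tuple(
                sorted((int(rng.integers(1, 12)) for _ in range(n_mlp)),
                       reverse=True)
            )
            cfg = NetworkConfig(
                input_dim=int(rng.integers(1, 50)),
                lstm_units=lstm_units,
                mlp_units=mlp_units,
                n_classes=int(rng.integers(2, 6)),
                batchnorm_after_first_mlp=bool(rng.integers(0, 2)),
                dropout_position=1,
            )
            model = build_model(cfg, seed=0)
            assert model.n_parameters == count_parameters(cfg)
            assert build_network(cfg).total_params == count_parameters(cfg)


class TestForwardPredict:
    @pytest.fixture
    def small_model(self):
        cfg = NetworkConfig(input_dim=6, lstm_units=(4, 3), mlp_units=(3, 2),
                            dropout_position=1, sequence_length=5)
        return build_model(cfg, seed=0)

    def test_probabilities_sum_to_one(self, small_model, rng):
        x = rng.normal(size=(5, 6))
        p = forward(small_model, x)
        assert p.shape == (4,)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(p >= 0)

    def test_zeroed_final_layer_uniform(self, small_model, rng):
        # output layer is zero-initialized, so an untrained model is uniform
        p = forward(small_model, rng.normal(size=(5, 6)))
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_batch_contract(self, small_model, rng):
        x = rng.normal(size=(7, 5, 6))
        p = forward(small_model, x)
        assert p.shape == (7, 4)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_permutation_equivariance(self, small_model, rng):
        x = rng.normal(size=(6, 5, 6))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            forward(small_model, x)[perm], forward(small_model, x[perm]),
            atol=1e-12,
        )

    def test_width_mismatch_names_dims(self, small_model, rng):
        with pytest.raises(ContractError, match="6"):
            forward(small_model, rng.normal(size=(5, 9)))

    def test_predict_is_argmax(self, small_model, rng):
        x = rng.normal(size=(4, 5, 6))
        np.testing.assert_array_equal(
            predict(small_model, x), np.argmax(forward(small_model, x), axis=1)
        )

    def test_tie_break_lowest_index(self):
        assert int(np.argmax(np.array([0.25, 0.25, 0.25, 0.25]))) == 0

    def test_softmax_of_equal_logits_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros((2, 4))), 0.25)
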