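"""RBM stack: passes, CD-1 updates, greedy training, reconstruction."""

import itertools

import numpy as np
import pytest
from scipy.special import expit

from selattn.dbn import (
    DeepNetwork,
    RBMLayer,
    TrainingConfig,
    cd1_step,
    down_pass,
    free_energy_unnormalized_prob,
    iterate_generation,
    logistic,
    modular_masks,
    reconstruct,
    train_layer,
    train_network,
    up_pass,
)


def make_layer(w, bh=None, bv=None):
    w = np.asfortranarray(np.atleast_2d(np.asarray(w, float)))
    return RBMLayer(
        weights=w,
        hidden_bias=np.zeros(w.shape[1]) if bh is None else np.asarray(bh, float),
        visible_bias=np.zeros(w.shape[0]) if bv is None else np.asarray(bv, float),
    )


def zero_net(dims=(6, 4, 3, 2)):
    layers = [
        make_layer(np.zeros((nv, nh))) for nv, nh in zip(dims, dims[1:])
    ]
    return DeepNetwork(layers=layers, config=TrainingConfig(layer_sizes=dims[1:]))


class TestLogistic:
    def test_symmetry_and_saturation(self):
        assert logistic(0.0) == 0.5
        assert logistic(800.0) == 1.0
        assert logistic(-800.0) == 0.0

    def test_sums_to_one_with_negated_argument(self):
        x = np.linspace(-30, 30, 13)
        assert np.allclose(logistic(x) + logistic(-x), 1.0)


class TestPasses:
    def test_zero_weights_give_half_everywhere(self):
        layer = make_layer(np.zeros((5, 3)))
        assert np.allclose(up_pass(layer, np.ones(5)), 0.5)
        assert np.allclose(down_pass(layer, np.ones(3)), 0.5)

    def test_up_pass_matches_hand_computed_formula(self):
        # 2 visible, 1 hidden: w = (1, -1), b = 0.5, v = (1, 1) -> h = expit(0.5)
        layer = make_layer([[1.0], [-1.0]], bh=[0.5])
        h = up_pass(layer, np.array([1.0, 1.0]))
        assert h[0] == pytest.approx(expit(0.5))
        assert h[0] == pytest.approx(0.62245933, abs=1e-7)

    def test_down_pass_uses_same_weight_matrix(self):
        rng = np.random.default_rng(0)
        layer = make_layer(rng.normal(size=(4, 3)), bv=rng.normal(size=4))
        h = rng.random(3)
        expected = expit(layer.weights @ h + layer.visible_bias)
        assert np.allclose(down_pass(layer, h), expected)

    def test_down_of_up_matches_hand_computation(self):
        layer = make_layer([[0.5, -1.0], [2.0, 0.25]], bh=[0.1, -0.2], bv=[0.3, 0.0])
        v = np.array([1.0, 0.0])
        h = expit(v @ layer.weights + layer.hidden_bias)
        expected_v = expit(layer.weights @ h + layer.visible_bias)
        assert np.allclose(down_pass(layer, up_pass(layer, v)), expected_v)

    def test_dropout_mask_zeroes_hidden_outputs(self):
        rng = np.random.default_rng(1)
        layer = make_layer(rng.normal(size=(4, 3)))
        h = up_pass(layer, np.ones(4), dropout_mask=np.zeros(3))
        assert np.all(h == 0)

    def test_dimension_mismatch_raises(self):
        layer = make_layer(np.zeros((4, 3)))
        with pytest.raises(ValueError, match="visible dimension"):
            up_pass(layer, np.ones(5))
        with pytest.raises(ValueError, match="hidden dimension"):
            down_pass(layer, np.ones(4))

    def test_batched_up_pass_matches_single(self):
        rng = np.random.default_rng(2)
        layer = make_layer(rng.normal(size=(4, 3)), bh=rng.normal(size=3))
        batch = rng.random((5, 4))
        stacked = np.stack([up_pass(layer, v) for v in batch])
        assert np.allclose(up_pass(layer, batch), stacked)


class TestCD1Step:
    def test_deltas_match_outer_product_oracle(self):
        # Deterministic mode on a 2x1 toy: compare against the explicit
        # hand-written positive/negative outer-product difference.
        layer = make_layer([[0.4], [-0.3]], bh=[0.1], bv=[0.05, -0.05])
        v = np.array([1.0, 0.0])
        eps = 0.01
        w0 = layer.weights.copy()
        bh0, bv0 = layer.hidden_bias.copy(), layer.visible_bias.copy()
        # oracle, written out from the update rule
        hp = expit(v @ w0 + bh0)
        vm = expit(w0 @ hp + bv0)
        hm = expit(vm @ w0 + bh0)
        dw = eps * (np.outer(v, hp) - np.outer(vm, hm))
        cd1_step(
            layer, v, eps, dropout_mask=None,
            rng=np.random.default_rng(0), sampling="all_probabilities",
        )
        assert np.allclose(layer.weights, w0 + dw)
        assert np.allclose(layer.hidden_bias, bh0 + eps * (hp - hm))
        assert np.allclose(layer.visible_bias, bv0 + eps * (v - vm))

    def test_fixed_point_of_update_rule_gives_zero_delta(self):
        # Zero weights and v = 0.5: the negative phase reproduces (v+, h+).
        layer = make_layer(np.zeros((3, 2)))
        v = np.full(3, 0.5)
        cd1_step(layer, v, 0.1, None, np.random.default_rng(0), "all_probabilities")
        assert np.all(layer.weights == 0)
        assert np.all(layer.hidden_bias == 0)
        assert np.all(layer.visible_bias == 0)

    def test_zero_learning_rate_changes_nothing(self):
        rng = np.random.default_rng(3)
        layer = RBMLayer.initialize(5, 3, rng)
        w0 = layer.weights.copy()
        cd1_step(layer, rng.random(5), 0.0, None, rng)
        assert np.array_equal(layer.weights, w0)

    def test_masked_connections_receive_no_update(self):
        rng = np.random.default_rng(4)
        mask = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        layer = RBMLayer.initialize(3, 2, rng, connectivity_mask=mask)
        for _ in range(20):
            cd1_step(layer, rng.random(3), 0.1, None, rng)
        assert np.all(layer.weights[mask == 0] == 0)


class TestTraining:
    def test_zero_epochs_leave_parameters_unchanged(self):
        rng = np.random.default_rng(5)
        layer = RBMLayer.initialize(4, 3, rng)
        w0 = layer.weights.copy()
        log = train_layer(layer, np.eye(4), TrainingConfig(epochs=0), rng)
        assert log == []
        assert np.array_equal(layer.weights, w0)

    def test_reconstruction_error_decreases_on_orthogonal_patterns(self):
        rng = np.random.default_rng(6)
        layer = RBMLayer.initialize(8, 6, rng)
        data = np.kron(np.eye(4), np.ones(2))  # 4 orthogonal patterns
        cfg = TrainingConfig(epochs=200, learning_rate=0.05, dropout_p=0.0)
        log = train_layer(layer, data, cfg, rng)
        assert log[-1] < log[0]
        assert np.all(np.isfinite(layer.weights))

    def test_training_is_deterministic_given_seed(self):
        data = np.random.default_rng(7).random((10, 6))
        results = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            layer = RBMLayer.initialize(6, 4, rng)
            train_layer(layer, data, TrainingConfig(epochs=5), rng)
            results.append(layer.weights.copy())
        assert np.array_equal(results[0], results[1])

    def test_empty_data_raises(self):
        rng = np.random.default_rng(8)
        layer = RBMLayer.initialize(3, 2, rng)
        with pytest.raises(ValueError, match="empty"):
            train_layer(layer, np.empty((0, 3)), TrainingConfig(), rng)

    def test_greedy_training_decreases_error_in_every_layer(self):
        rng = np.random.default_rng(9)
        cfg = TrainingConfig(epochs=50, learning_rate=0.05, layer_sizes=(6, 4, 3))
        net = DeepNetwork.initialize(8, cfg, rng)
        data = np.kron(np.eye(4), np.ones(2))
        logs = train_network(net, data, rng, cfg)
        assert len(logs) == 3
        for log in logs:
            assert log[-1] < log[0]

    def test_greedy_training_leaves_lower_layers_untouched(self):
        # Layer 1 after stack training == layer 1 after solo training with
        # the same rng stream (upper-layer training consumes later draws).
        data = np.random.default_rng(10).random((6, 5))
        cfg = TrainingConfig(epochs=4, layer_sizes=(4, 3))
        rng = np.random.default_rng(11)
        net = DeepNetwork.initialize(5, cfg, rng)
        w_init = net.layers[0].weights.copy()
        rng_solo = np.random.default_rng(11)
        solo = DeepNetwork.initialize(5, cfg, rng_solo)
        train_network(net, data, rng, cfg)
        train_layer(solo.layers[0], data, cfg, rng_solo)
        assert not np.array_equal(net.layers[0].weights, w_init)
        assert np.array_equal(net.layers[0].weights, solo.layers[0].weights)

    def test_minibatch_update_matches_summed_online_statistics(self):
        # In deterministic mode with a frozen layer, the minibatch delta is
        # the sum of the per-pattern deltas computed from the same start.
        rng = np.random.default_rng(12)
        data = rng.random((4, 5))
        ref = RBMLayer.initialize(5, 3, np.random.default_rng(13))
        deltas = np.zeros_like(ref.weights)
        for v in data:
            layer = ref.copy()
            cd1_step(layer, v, 0.01, None, rng, "all_probabilities")
            deltas += layer.weights - ref.weights
        batch_layer = ref.copy()
        from selattn.dbn import _cd1_minibatch

        _cd1_minibatch(batch_layer, data, 0.01, None, rng, "all_probabilities")
        assert np.allclose(batch_layer.weights, ref.weights + deltas)


class TestReconstruct:
    def test_zero_weight_net_outputs_half_everywhere(self):
        net = zero_net()
        out = reconstruct(net, np.ones(6), depth=3)
        assert np.allclose(out, 0.5)

    def test_matches_manual_composition_of_passes(self):
        rng = np.random.default_rng(14)
        cfg = TrainingConfig(layer_sizes=(4, 3, 2), test_scale="none")
        net = DeepNetwork.initialize(6, cfg, rng)
        v = rng.random(6)
        acts = v
        for k in range(3):
            acts = up_pass(net.layers[k], acts)
        for k in reversed(range(3)):
            acts = down_pass(net.layers[k], acts)
        assert np.allclose(reconstruct(net, v, depth=3), acts)

    def test_retention_scaling_halves_hidden_activations(self):
        rng = np.random.default_rng(15)
        cfg = TrainingConfig(layer_sizes=(3,), dropout_p=0.5, test_scale="retention")
        net = DeepNetwork.initialize(4, cfg, rng)
        v = rng.random(4)
        h = 0.5 * up_pass(net.layers[0], v)
        assert np.allclose(reconstruct(net, v, depth=1), down_pass(net.layers[0], h))

    def test_filter_excluding_all_neurons_yields_logistic_of_visible_bias(self):
        rng = np.random.default_rng(16)
        cfg = TrainingConfig(layer_sizes=(4, 3), test_scale="none")
        net = DeepNetwork.initialize(5, cfg, rng)
        net.layers[0].visible_bias = rng.normal(size=5)
        filt = [np.zeros(4), np.zeros(3)]
        out = reconstruct(net, rng.random(5), depth=2, class_filter=filt)
        assert np.allclose(out, expit(net.layers[0].visible_bias))

    def test_invalid_depth_raises(self):
        net = zero_net()
        with pytest.raises(ValueError):
            reconstruct(net, np.ones(6), depth=4)
        with pytest.raises(ValueError):
            reconstruct(net, np.ones(6), depth=0)


class TestIterateGeneration:
    def test_one_step_equals_reconstruct(self):
        rng = np.random.default_rng(17)
        cfg = TrainingConfig(layer_sizes=(4, 3, 2), test_scale="none")
        net = DeepNetwork.initialize(6, cfg, rng)
        v = rng.random(6)
        seq = iterate_generation(net, v, steps=1)
        assert len(seq) == 1
        assert np.allclose(seq[0], reconstruct(net, v, depth=3))

    def test_fixed_point_input_gives_constant_sequence(self):
        net = zero_net()  # reconstruct(x) = 0.5 everywhere, so 0.5 is fixed
        seq = iterate_generation(net, np.full(6, 0.5), steps=4)
        for x in seq:
            assert np.allclose(x, 0.5)

    def test_rejects_zero_steps(self):
        with pytest.raises(ValueError):
            iterate_generation(zero_net(), np.ones(6), steps=0)


class TestEnergyModel:
    def test_cd_training_raises_probability_of_training_patterns(self):
        # 3-visible/2-hidden RBM; unnormalized p*(v) = sum_h exp(-E(v,h))
        # by brute-force enumeration over all 2^5 states.
        rng = np.random.default_rng(0)
        layer = RBMLayer.initialize(3, 2, rng)
        pats = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        cfg = TrainingConfig(epochs=500, learning_rate=0.05, dropout_p=0.0)
        train_layer(layer, pats, cfg, rng)
        probs = {
            v: free_energy_unnormalized_prob(layer, np.array(v, float))
            for v in itertools.product([0, 1], repeat=3)
        }
        train_min = min(probs[(1, 0, 1)], probs[(0, 1, 0)])
        other_max = max(
            p for k, p in probs.items() if k not in [(1, 0, 1), (0, 1, 0)]
        )
        assert train_min > other_max


class TestNetworkPlumbing:
    def test_initialization_statistics(self):
        rng = np.random.default_rng(18)
        layer = RBMLayer.initialize(500, 400, rng)
        assert abs(layer.weights.mean()) < 0.005
        assert abs(layer.weights.std() - 0.1) < 0.005
        assert np.all(layer.hidden_bias == 0) and np.all(layer.visible_bias == 0)

    def test_adjacent_dim_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            DeepNetwork(
                layers=[make_layer(np.zeros((4, 3))), make_layer(np.zeros((2, 2)))]
            )

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(19)
        cfg = TrainingConfig(layer_sizes=(4, 3))
        net = DeepNetwork.initialize(5, cfg, rng)
        path = str(tmp_path / "net.npz")
        net.save(path)
        back = DeepNetwork.load(path)
        for a, b in zip(net.layers, back.layers):
            assert np.allclose(a.weights, b.weights)
            assert np.allclose(a.hidden_bias, b.hidden_bias)
            assert np.allclose(a.visible_bias, b.visible_bias)

    def test_modular_masks_block_structure(self):
        masks = modular_masks((2, 3), ((2, 2), None))
        m = masks[0]
        assert m.shape == (5, 4)
        assert np.all(m[:2, :2] == 1) and np.all(m[2:, 2:] == 1)
        assert np.all(m[:2, 2:] == 0) and np.all(m[2:, :2] == 0)
        assert masks[1] is None

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(dropout_p=1.0)
        with pytest.raises(ValueError):
            TrainingConfig(sampling="nope")
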