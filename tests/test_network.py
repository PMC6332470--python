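"""Network descriptions, BN folding, pooling merge, conversion fidelity."""

import numpy as np
import pytest

from adsnn import ASNParams, compute_constants, f_S, normalized_params
from adsnn.network import (
    LayerSpec,
    NetworkSpec,
    SpikingNetwork,
    conv2d_forward,
    convert,
    fold_batchnorm,
    fold_network,
    forward_ann,
    merge_pooling,
    pool_forward,
    softmax,
)
from adsnn.training import fixture_network
from adsnn import io as net_io


def random_bn(n, rng, eps=1e-3):
    return LayerSpec(
        kind="batchnorm",
        bn_mean=rng.normal(size=n),
        bn_var=rng.uniform(0.5, 2.0, size=n),
        bn_scale=rng.uniform(0.5, 1.5, size=n),
        bn_offset=rng.normal(size=n),
        bn_eps=eps,
    )


def identity_bn(n):
    return LayerSpec(
        kind="batchnorm",
        bn_mean=np.zeros(n),
        bn_var=np.ones(n),
        bn_scale=np.ones(n),
        bn_offset=np.zeros(n),
        bn_eps=0.0,
    )


class TestBatchnormFolding:
    def test_identity_bn_leaves_layer_unchanged(self):
        layer = LayerSpec(kind="dense", weights=np.eye(3), bias=np.arange(3.0))
        folded = fold_batchnorm(layer, identity_bn(3))
        np.testing.assert_array_equal(folded.weights, layer.weights)
        np.testing.assert_array_equal(folded.bias, layer.bias)

    def test_folding_identity_bn_is_idempotent(self):
        rng = np.random.default_rng(0)
        layer = LayerSpec(kind="dense", weights=rng.normal(size=(4, 3)), bias=rng.normal(size=4))
        once = fold_batchnorm(layer, identity_bn(4))
        twice = fold_batchnorm(once, identity_bn(4))
        np.testing.assert_array_equal(once.weights, twice.weights)

    def test_folded_dense_matches_unfolded_forward(self):
        rng = np.random.default_rng(1)
        layer = LayerSpec(kind="dense", weights=rng.normal(size=(5, 3)), bias=rng.normal(size=5))
        bn = random_bn(5, rng)
        folded = fold_batchnorm(layer, bn)
        x = rng.normal(size=(100, 3))
        direct = x @ folded.weights.T + folded.bias
        sigma = np.sqrt(bn.bn_var + bn.bn_eps)
        via_bn = bn.bn_scale * ((x @ layer.weights.T + layer.bias) - bn.bn_mean) / sigma + bn.bn_offset
        np.testing.assert_allclose(direct, via_bn, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        layer = LayerSpec(kind="dense", weights=np.eye(3))
        with pytest.raises(ValueError):
            fold_batchnorm(layer, identity_bn(4))

    def test_fold_network_preserves_function(self, trained_spec):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 3.0, size=(100, 4))
        before = forward_ann(trained_spec, x)
        after = forward_ann(fold_network(trained_spec), x)
        assert np.abs(before - after).max() <= 1e-6


class TestPooling:
    def test_avg_pool_of_constant_map(self):
        x = np.full((1, 2, 4, 4), 0.7)
        np.testing.assert_allclose(pool_forward(x, 2, "avg"), 0.7)

    def test_avg_pool_window_means(self):
        x = np.arange(16.0).reshape(1, 1, 4, 4)
        out = pool_forward(x, 2, "avg")
        np.testing.assert_allclose(
            out[0, 0], [[2.5, 4.5], [10.5, 12.5]]
        )

    def test_max_pool_window_maxima(self):
        x = np.arange(16.0).reshape(1, 1, 4, 4)
        out = pool_forward(x, 2, "max")
        np.testing.assert_allclose(out[0, 0], [[5.0, 7.0], [13.0, 15.0]])

    def test_merge_requires_weighted_successor(self):
        pool = LayerSpec(kind="maxpool", pool_size=2)
        with pytest.raises(ValueError):
            merge_pooling(pool, LayerSpec(kind="maxpool", pool_size=2))

    def test_merged_spiking_max_pool_matches_analog(self, default_params):
        """Constant input through conv+maxpool: the spiking network's decoded
        readout converges to the analog reference within coding precision."""
        rng = np.random.default_rng(3)
        layers = [
            LayerSpec(kind="input"),
            LayerSpec(kind="conv2d", weights=rng.uniform(0, 0.4, size=(2, 1, 3, 3)),
                      bias=np.zeros(2)),
            LayerSpec(kind="maxpool", pool_size=2),
            LayerSpec(kind="dense", weights=rng.uniform(-0.3, 0.6, size=(3, 8)),
                      bias=np.zeros(3)),
            LayerSpec(kind="readout", weights=rng.normal(size=(2, 3)), bias=np.zeros(2)),
        ]
        spec = NetworkSpec(layers=layers, params=default_params)
        x = rng.uniform(0.2, 1.0, size=(1, 1, 4, 4))
        analog = forward_ann(spec, x)
        net = convert(spec, default_params)
        net.reset(x.shape[1:], batch=1)
        for _ in range(800):
            out, _, _ = net.step(x)
        np.testing.assert_allclose(softmax(out), analog, atol=0.05)


class TestForwardAnn:
    def test_zero_weights_give_uniform_softmax(self):
        layers = [
            LayerSpec(kind="input"),
            LayerSpec(kind="readout", weights=np.zeros((4, 2)), bias=np.zeros(4)),
        ]
        spec = NetworkSpec(layers=layers, params=ASNParams())
        out = forward_ann(spec, np.array([[0.3, 0.9]]))
        np.testing.assert_allclose(out, 0.25)

    def test_subthreshold_activations_are_clipped(self, default_params):
        layers = [
            LayerSpec(kind="input"),
            LayerSpec(kind="dense", weights=-np.ones((3, 2)), bias=np.full(3, -1.0)),
            LayerSpec(kind="readout", weights=np.ones((2, 3)), bias=np.zeros(2)),
        ]
        spec = NetworkSpec(layers=layers, params=default_params)
        out, hidden = forward_ann(spec, np.array([[1.0, 1.0]]), return_hidden=True)
        assert np.all(hidden[1] == 0.0)
        np.testing.assert_allclose(out, 0.5)

    def test_fixture_matches_manual_composition(self, default_params):
        spec = fixture_network(default_params)
        constants = compute_constants(default_params)
        x = np.array([1.0, 0.0])
        z1 = np.array(
            [1.0 * f_S(1.0, constants) + (-0.5) * f_S(0.0, constants) + 0.0,
             0.25 * f_S(1.0, constants) + 1.0 * f_S(0.0, constants) + 0.1]
        )
        a1 = np.array([f_S(z1[0], constants), f_S(z1[1], constants)])
        logits = np.array(
            [1.2 * a1[0] - 0.6 * a1[1] + 0.05, -0.4 * a1[0] + 1.0 * a1[1] - 0.05]
        )
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(forward_ann(spec, x)[0], expected, atol=1e-12)

    def test_conv2d_same_padding_shape(self):
        x = np.zeros((2, 3, 8, 8))
        w = np.zeros((5, 3, 3, 3))
        assert conv2d_forward(x, w).shape == (2, 5, 8, 8)
        assert conv2d_forward(x, w, stride=2).shape == (2, 5, 4, 4)
        assert conv2d_forward(x, w, padding="valid").shape == (2, 5, 6, 6)


class TestConversion:
    def test_spikes_off_mode_reproduces_analog_forward(self, trained_spec, blobs):
        net = convert(trained_spec)
        np.testing.assert_allclose(
            net.forward_analog(blobs.X_test),
            forward_ann(trained_spec, blobs.X_test),
            atol=1e-6,
        )

    def test_conversion_keeps_analog_weights(self, trained_spec):
        net_a = convert(trained_spec, normalized_params(ASNParams(theta0=0.05)))
        net_b = convert(trained_spec, normalized_params(ASNParams(theta0=0.25)))
        assert net_a.params.h != net_b.params.h
        for sa, sb in zip(net_a.stages, net_b.stages):
            np.testing.assert_array_equal(sa.layer.weights, sb.layer.weights)
        np.testing.assert_array_equal(
            trained_spec.layers[1].weights, trained_spec.layers[1].weights
        )

    def test_fixture_steady_state_tracks_analog_activations(self, default_params):
        spec = fixture_network(default_params)
        x = np.array([[1.0, 0.4]])
        probs, hidden = forward_ann(spec, x, return_hidden=True)
        net = convert(spec, default_params)
        net.reset((2,), batch=1)
        outs = []
        for _ in range(1500):
            out, _, _ = net.step(x[0])
            outs.append(out[0])
        # readout activations approach the analog logits (bias included)
        analog_logits = hidden[1] @ spec.layers[2].weights.T + spec.layers[2].bias
        steady = np.mean(outs[800:], axis=0)
        np.testing.assert_allclose(steady, analog_logits[0], rtol=0.1, atol=0.02)

    def test_unsupported_structure_rejected(self, default_params):
        layers = [
            LayerSpec(kind="input"),
            LayerSpec(kind="maxpool", pool_size=2),
            LayerSpec(kind="readout", weights=np.ones((2, 4)), bias=np.zeros(2)),
        ]
        spec = NetworkSpec(layers=layers, params=default_params)
        with pytest.raises(ValueError):
            SpikingNetwork(spec, default_params)

    def test_spec_requires_input_and_readout_ends(self):
        with pytest.raises(ValueError):
            NetworkSpec(layers=[LayerSpec(kind="input")], params=ASNParams())
        with pytest.raises(ValueError):
            NetworkSpec(
                layers=[
                    LayerSpec(kind="dense", weights=np.eye(2)),
                    LayerSpec(kind="readout", weights=np.eye(2)),
                ],
                params=ASNParams(),
            )


class TestContainerRoundTrip:
    def test_save_load_preserves_network(self, trained_spec, tmp_path):
        path = tmp_path / "net.npz"
        net_io.save_network(trained_spec, path)
        loaded = net_io.load_network(path)
        assert len(loaded.layers) == len(trained_spec.layers)
        for a, b in zip(loaded.layers, trained_spec.layers):
            assert a.kind == b.kind
            if b.weights is not None:
                np.testing.assert_array_equal(a.weights, b.weights)
            if b.bn_mean is not None:
                np.testing.assert_array_equal(a.bn_mean, b.bn_mean)
        assert loaded.params == trained_spec.params
        assert loaded.metadata == trained_spec.metadata

    def test_version_checked(self, trained_spec, tmp_path):
        import json
        path = tmp_path / "net.npz"
        net_io.save_network(trained_spec, path)
        data = dict(np.load(path, allow_pickle=False))
        manifest = json.loads(str(data["manifest"]))
        manifest["version"] = 99
        data["manifest"] = np.array(json.dumps(manifest))
        np.savez(path, **data)
        with pytest.raises(ValueError):
            net_io.load_network(path)
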