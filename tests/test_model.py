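"""Architecture semantics: gating, accumulation, causality, receptive
fields, attention, variants, and parameter accounting."""

import numpy as np
import pytest

from eegwavenet.autodiff import Tensor
from eegwavenet.errors import ParameterError
from eegwavenet.model import (
    ChannelAttention, DualPathModel, GatedDilatedLayer, Initializer,
    ModelConfig, VARIANTS, WaveBlock, build_model, count_parameters,
    receptive_field,
)


def _init(seed=0, dtype=np.float64):
    return Initializer(np.random.default_rng(seed), dtype)


def _numgrad_free_forward(layer, x):
    out, gated = layer.forward(Tensor(x))
    return out.data, gated.data


# --------------------------------------------------------------------------
# gated dilated layers


def test_zero_weight_layer_outputs_zero(rng):
    layer = GatedDilatedLayer(3, 4, 3, 2, _init())
    for p in layer.parameters():
        p.data[...] = 0.0
    x = rng.standard_normal((2, 20, 3))
    res, gated = _numgrad_free_forward(layer, x)
    np.testing.assert_array_equal(gated, 0.0)  # tanh(0) * sigmoid(0) = 0
    np.testing.assert_array_equal(res, 0.0)


@pytest.mark.parametrize("dilation", [1, 4])
def test_layer_causality(rng, dilation):
    """Perturbing the input at time t changes outputs only at times >= t."""
    layer = GatedDilatedLayer(3, 4, 3, dilation, _init())
    x = rng.standard_normal((1, 30, 3))
    res0, gated0 = _numgrad_free_forward(layer, x)
    t = 17
    x2 = x.copy()
    x2[0, t, :] += 1.0
    res1, gated1 = _numgrad_free_forward(layer, x2)
    assert np.array_equal(res1[0, :t], res0[0, :t])
    assert np.array_equal(gated1[0, :t], gated0[0, :t])
    assert not np.array_equal(res1[0, t:], res0[0, t:])


def test_wave_block_sums_gated_outputs(rng):
    """Block output equals the brute-force sum of per-layer gated outputs
    captured by instrumentation."""
    block = WaveBlock(3, (1, 2, 4), 5, 3, _init())
    x = rng.standard_normal((2, 25, 3))
    out = block.forward(Tensor(x)).data

    acc = np.zeros_like(out)
    h = Tensor(x)
    for layer in block.layers:
        h, gated = layer.forward(h)
        acc += gated.data
    np.testing.assert_allclose(out, acc, rtol=1e-12)


def test_single_layer_block_is_its_gated_output(rng):
    block = WaveBlock(3, (1,), 5, 3, _init())
    x = rng.standard_normal((1, 15, 3))
    out = block.forward(Tensor(x)).data
    _, gated = block.layers[0].forward(Tensor(x))
    np.testing.assert_array_equal(out, gated.data)


# --------------------------------------------------------------------------
# receptive field


@pytest.mark.parametrize("kernel,dilations,expected", [
    (2, [1], 2),
    (2, [1, 2, 4, 8], 16),
    (3, [1, 2, 4, 8, 16, 32, 64, 128], 511),
])
def test_receptive_field_matches_perturbation_probe(kernel, dilations, expected):
    """1 + (k-1) * sum(d) equals a brute-force delta-response probe."""
    assert receptive_field(dilations, kernel) == expected

    length = expected + 40
    rng = np.random.default_rng(1)
    h0 = Tensor(np.zeros((1, length, 1)))
    h1 = Tensor(np.zeros((1, length, 1)))
    h1.data[0, 0, 0] = 1.0
    cin = 1
    for d in dilations:
        w = Tensor(rng.standard_normal((kernel, cin, 2)))
        b = Tensor(np.zeros(2))
        h0 = h0.causal_conv1d(w, b, d)
        h1 = h1.causal_conv1d(w, b, d)
        cin = 2
    affected = np.any(h0.data != h1.data, axis=2)[0]
    assert affected.sum() == expected
    assert np.all(affected[:expected])  # a contiguous span starting at t=0


# --------------------------------------------------------------------------
# attention


def test_attention_weights_sum_to_one(rng):
    att = ChannelAttention(6, _init())
    h = Tensor(rng.standard_normal((4, 9, 6)))
    w = att.attention_weights(h).data
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)


def test_attention_uniform_at_zero_weights(rng):
    att = ChannelAttention(5, _init())
    att.w.data[...] = 0.0
    att.b.data[...] = 0.0
    h = Tensor(rng.standard_normal((2, 7, 5)))
    w = att.attention_weights(h).data
    np.testing.assert_allclose(w, 1.0 / 5.0, atol=1e-12)
    out = att.forward(h).data
    np.testing.assert_allclose(out, h.data / 5.0, atol=1e-12)


def test_attention_permutation_equivariance(rng):
    """Permuting channels (with W, b permuted consistently) permutes the
    output identically."""
    c = 6
    att = ChannelAttention(c, _init(3))
    h = rng.standard_normal((2, 8, c))
    perm = np.random.default_rng(4).permutation(c)

    out = att.forward(Tensor(h)).data

    att_p = ChannelAttention(c, _init(3))
    att_p.w.data = att.w.data[np.ix_(perm, perm)]
    att_p.b.data = att.b.data[perm]
    out_p = att_p.forward(Tensor(h[:, :, perm])).data
    np.testing.assert_allclose(out_p, out[:, :, perm], rtol=1e-10)


# --------------------------------------------------------------------------
# assembled variants


def test_full_model_softmax_output(tiny_model_config, rng):
    model = build_model(tiny_model_config, "full", seed=0)
    x = rng.standard_normal((3, tiny_model_config.input_len,
                             tiny_model_config.n_input_channels))
    p = model.predict_proba(x)
    assert p.shape == (3, 2)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(p >= 0)


@pytest.mark.parametrize("variant", VARIANTS)
def test_softmax_valid_for_all_variants(tiny_model_config, rng, variant):
    model = build_model(tiny_model_config, variant, seed=1)
    x = rng.standard_normal((2, tiny_model_config.input_len,
                             tiny_model_config.n_input_channels))
    p = model.predict_proba(x)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_conv_path_causality(tiny_model_config, rng):
    """Zeroing inputs after time t never changes pre-pooling block
    activations at times <= t."""
    model = build_model(tiny_model_config, "ablation1", seed=0)
    x = rng.standard_normal((1, tiny_model_config.input_len,
                             tiny_model_config.n_input_channels))
    t = 23
    x_cut = x.copy()
    x_cut[0, t:, :] = 0.0
    a0 = model._forward_path1(Tensor(x), until_block=0).data
    a1 = model._forward_path1(Tensor(x_cut), until_block=0).data
    np.testing.assert_array_equal(a0[0, :t], a1[0, :t])


def test_baseline_has_no_recurrent_path1_and_no_path2(tiny_model_config):
    model = build_model(tiny_model_config, "baseline", seed=0)
    assert model.path1_rnn is None
    assert not model.use_path2
    assert not hasattr(model, "window_rnn")


def test_unknown_variant_error(tiny_model_config):
    with pytest.raises(ParameterError) as exc:
        build_model(tiny_model_config, "ablation9")
    assert "full" in str(exc.value)


# --------------------------------------------------------------------------
# parameter accounting


def test_closed_form_examples():
    from eegwavenet.model import _dense_params, _lstm_params

    assert _dense_params(80, 2) == 162
    assert _lstm_params(32, 64) == 24832


@pytest.mark.parametrize("variant", VARIANTS)
def test_count_matches_instantiated_arrays(tiny_model_config, variant):
    model = build_model(tiny_model_config, variant, seed=0)
    assert model.n_parameters() == count_parameters(tiny_model_config, variant)


@pytest.mark.parametrize("variant", VARIANTS)
def test_reference_count_matches_arrays(variant):
    cfg = ModelConfig()
    model = DualPathModel(cfg, variant, seed=0)
    assert model.n_parameters() == count_parameters(cfg, variant)


def test_reference_full_count_and_budget():
    cfg = ModelConfig()
    n = count_parameters(cfg, "full")
    assert n == 244_882
    assert n <= cfg.param_budget == 244_992


def test_ablation3_count_is_path2_plus_head():
    from eegwavenet.model import _dense_params, _lstm_params

    cfg = ModelConfig()
    manual = (_lstm_params(cfg.n_input_channels, cfg.window_rnn_units)
              + _dense_params(cfg.window_rnn_units, cfg.window_rnn_units)
              + _lstm_params(cfg.window_rnn_units, cfg.path2_rnn_units)
              + _dense_params(cfg.path2_rnn_units, cfg.path2_dense_units)
              + _dense_params(cfg.path2_dense_units, cfg.n_classes))
    assert count_parameters(cfg, "ablation3") == manual


def test_variant_containment():
    cfg = ModelConfig()
    params = {v: count_parameters(cfg, v) for v in VARIANTS}
    assert params["baseline"] < params["ablation1"] <= params["full"]
    assert params["ablation3"] < params["full"]


def test_config_validation():
    with pytest.raises(ParameterError):
        ModelConfig(block_dilations=((1, 2, 2),))
    with pytest.raises(ParameterError):
        ModelConfig(input_len=1001, window_len=250)
    with pytest.raises(ParameterError):
        receptive_field([], 3)


def test_reduced_reference_caps_dilations():
    cfg = ModelConfig.reduced_reference(seg_seconds=10.0, max_dilation=32)
    assert cfg.input_len == 2500
    assert all(max(blk) <= 32 for blk in cfg.block_dilations)
    assert cfg.block_dilations[3] == (1, 2, 4, 8, 16)


# --------------------------------------------------------------------------
# variant-level gradient check (end to end through both paths)


def numgrad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        fp = f()
        arr[i] = old - eps
        fm = f()
        arr[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.mark.parametrize("variant", ["full", "baseline", "ablation3"])
def test_model_gradients_match_finite_differences(tiny_model_config, rng,
                                                  variant):
    model = build_model(tiny_model_config, variant, seed=1)
    x = rng.standard_normal((3, tiny_model_config.input_len,
                             tiny_model_config.n_input_channels))
    y = np.array([0, 1, 1])

    def lossval():
        l, _ = model.loss(x, y, train=False)
        return float(l.data)

    for p in model.parameters():
        p.grad = None
    loss, _ = model.loss(x, y, train=False)
    loss.backward()
    # spot-check a few parameter tensors end to end
    params = model.parameters()
    for p in (params[0], params[len(params) // 2], params[-1], params[-2]):
        ng = numgrad(lossval, p.data)
        scale = max(np.abs(ng).max(), 1e-8)
        np.testing.assert_allclose(p.grad, ng, atol=2e-5 * scale, rtol=2e-5)
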