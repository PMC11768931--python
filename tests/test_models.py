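"""Architectures, parameter/FLOP accounting, initialization, quantization."""

import numpy as np
import pytest

from callernet import nn
from callernet.models import (
    ElephantCallerNetConfig, RawNetConfig, YamNet1dConfig,
    build_elephant_caller_net, build_mobilenet_v2_raw, build_rawnet_residual,
    build_spectrogram_cnn, build_yamnet_1d, fit_svm_spectral,
    residual_block_1d, waveform_grid,
)
from callernet.nn import (
    ShapeError, UnsupportedLayerError, count_parameters, dequantize_tensor,
    estimate_flops, quantize_int8, quantize_tensor, quantized_size_bytes,
    serialized_size_bytes,
)


RAW_BUILDERS = {
    "ecn": lambda n: build_elephant_caller_net(ElephantCallerNetConfig(input_samples=n)),
    "mobilenet": lambda n: build_mobilenet_v2_raw(input_samples=n),
    "yamnet": lambda n: build_yamnet_1d(),
    "rawnet": lambda n: build_rawnet_residual(),
}


@pytest.mark.parametrize("name", sorted(RAW_BUILDERS))
def test_raw_models_emit_probability_rows(name):
    n = 6000
    model = RAW_BUILDERS[name](n)
    x = np.random.default_rng(0).standard_normal((4, n)).astype(np.float32) * 0.1
    model.eval()
    probs = model(x)
    assert probs.shape == (4, 3)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert (probs >= 0).all()


# --- MobileNetV2 ------------------------------------------------------------

def test_mobilenet_single_channel_three_class_parameter_count():
    model = build_mobilenet_v2_raw(n_classes=3, in_channels=1)
    assert count_parameters(model) == 2_227_139


def test_mobilenet_head_arithmetic():
    p3 = count_parameters(build_mobilenet_v2_raw(n_classes=3, in_channels=1))
    p2 = count_parameters(build_mobilenet_v2_raw(n_classes=2, in_channels=1))
    assert p3 - p2 == 1281  # one 1280-weight row plus its bias


def test_mobilenet_param_count_is_grid_independent():
    a = build_mobilenet_v2_raw(input_samples=96_000)
    b = build_mobilenet_v2_raw(input_samples=6144, grid=(64, 96))
    assert count_parameters(a) == count_parameters(b)
    assert waveform_grid(96_000) == (300, 320)


def test_mobilenet_rejects_untileable_grid():
    with pytest.raises(ShapeError):
        build_mobilenet_v2_raw(input_samples=96_000, grid=(100, 100))


# --- ElephantCallerNet ------------------------------------------------------

def test_elephant_caller_net_parameter_band():
    model = build_elephant_caller_net()
    assert 4.2e6 <= count_parameters(model) <= 5.2e6


def test_elephant_caller_net_shape_error_names_stage():
    cfg = ElephantCallerNetConfig(input_samples=64)
    model = build_elephant_caller_net(cfg)
    with pytest.raises(ShapeError):
        model(np.zeros((1, 64), dtype=np.float32))


def test_elephant_caller_net_config_validation():
    with pytest.raises(ValueError):
        ElephantCallerNetConfig(dropout_p=1.2).validate()
    with pytest.raises(ValueError):
        ElephantCallerNetConfig(tfeb_kernel=4).validate()
    with pytest.raises(ValueError):
        ElephantCallerNetConfig(n_classes=1).validate()


# --- YAMNet-style and RawNet-style -----------------------------------------

def test_yamnet_width_doubling_quadruples_pointwise_params():
    def pointwise_params(model):
        return sum(m.weight.size for m in model.modules()
                   if isinstance(m, nn.Conv1d) and m.kernel_size == 1 and m.groups == 1)

    base = build_yamnet_1d(YamNet1dConfig())
    wide = build_yamnet_1d(YamNet1dConfig(
        stem_channels=64, blocks=((128, 2), (256, 2), (256, 1), (512, 2), (512, 1), (1024, 2))))
    ratio = pointwise_params(wide) / pointwise_params(base)
    assert 3.5 <= ratio <= 4.5


def test_depthwise_parameter_count_is_definitional():
    conv = nn.Conv1d(32, 32, 9, groups=32, bias=True)
    assert count_parameters(conv) == 32 * 9 + 32


def test_residual_block_identity_when_body_zeroed():
    block = residual_block_1d(64, 64, 3, 0.2, np.random.default_rng(0))
    block.eval()
    for m in block.body.modules():
        if isinstance(m, nn.Conv1d):
            m.weight.data[...] = 0.0
    x = np.random.default_rng(1).standard_normal((2, 64, 50)).astype(np.float32)
    assert np.allclose(block(x), x, atol=1e-6)


def test_residual_block_analytic_parameter_count():
    C, k = 64, 3
    block = residual_block_1d(C, C, k, 0.2, np.random.default_rng(0))
    assert count_parameters(block) == 2 * C * C * k + 4 * C  # convs + two affine BNs
    proj = residual_block_1d(32, 64, k, 0.2, np.random.default_rng(0))
    assert count_parameters(proj) == 32 * 64 * k + 64 * 64 * k + 4 * 64 + 32 * 64


# --- initialization ---------------------------------------------------------

def test_kaiming_variance_matches_two_over_fan_in():
    conv = nn.Conv1d(16, 128, 9, rng=np.random.default_rng(0))
    fan_in = 16 * 9
    w = conv.weight.data
    assert w.size >= 10_000
    assert abs(w.var() * fan_in / 2.0 - 1.0) < 0.2
    lin = nn.Linear(512, 256, rng=np.random.default_rng(1))
    assert abs(lin.weight.data.var() * 512 / 2.0 - 1.0) < 0.2


# --- parameter counting primitives ------------------------------------------

@pytest.mark.parametrize("layer,expected", [
    (nn.Linear(10, 3), 33),
    (nn.Conv1d(1, 8, 9, bias=True), 80),
    (nn.Conv2d(3, 8, 3, bias=False), 216),
    (nn.BatchNorm(16), 32),
])
def test_count_parameters_primitive_layers(layer, expected):
    assert count_parameters(layer) == expected


# --- FLOPs ------------------------------------------------------------------

def test_linear_flops_definition():
    est = estimate_flops(nn.Linear(100, 30), (100,))
    assert est.per_input == 2 * 100 * 30 + 30


def test_conv1d_flops_definition():
    conv = nn.Conv1d(4, 8, 5, stride=1, padding=0, bias=True)
    L_out = 100 - 5 + 1
    est = estimate_flops(conv, (4, 100))
    assert est.per_input == 2 * L_out * 8 * 4 * 5 + L_out * 8


def test_flops_linear_in_batch_and_additive():
    model = build_yamnet_1d()
    e1 = estimate_flops(model, (6000,), batch=1)
    e32 = estimate_flops(model, (6000,), batch=32)
    assert e32.per_batch == 32 * e1.per_input
    seq = nn.Sequential(nn.Linear(10, 20), nn.ReLU(), nn.Linear(20, 5))
    total = estimate_flops(seq, (10,)).per_input
    parts = (estimate_flops(nn.Linear(10, 20), (10,)).per_input +
             estimate_flops(nn.ReLU(), (20,)).per_input +
             estimate_flops(nn.Linear(20, 5), (20,)).per_input)
    assert total == parts


def test_flops_unsupported_layer_is_explicit():
    class Mystery(nn.Module):
        def forward(self, x):
            return x

    with pytest.raises(UnsupportedLayerError):
        estimate_flops(nn.Sequential(nn.Linear(4, 4), Mystery()), (4,))


# --- quantization -----------------------------------------------------------

def test_quantized_checkpoint_is_compact():
    model = build_yamnet_1d()
    q = quantize_int8(model)
    assert quantized_size_bytes(q) <= 0.35 * serialized_size_bytes(model)


def test_quantize_round_trip_error_bound():
    rng = np.random.default_rng(0)
    w = rng.standard_normal((64, 32)).astype(np.float32)
    qv, scale = quantize_tensor(w)
    err = np.abs(dequantize_tensor(qv, scale) - w).max()
    assert err <= scale / 2 + 1e-7


def test_quantized_predictions_agree_with_float(small_call_clips):
    model = build_yamnet_1d(seed=3)
    model.eval()
    q = quantize_int8(model)
    q.eval()
    x = np.stack([np.resize(c.samples, 8000) for c in small_call_clips * 3])
    assert (model.predict(x) == q.predict(x)).mean() >= 0.90


# --- SVM --------------------------------------------------------------------

def test_svm_separable_blobs_and_order_invariance():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(0, 0.3, (20, 2)), rng.normal(4, 0.3, (20, 2))])
    y = np.array([0] * 20 + [1] * 20)
    clf = fit_svm_spectral(x, y)
    assert (clf.predict(x) == y).all()
    perm = rng.permutation(40)
    clf2 = fit_svm_spectral(x[perm], y[perm])
    assert np.array_equal(clf.predict(x), clf2.predict(x))


def test_svm_rbf_solves_xor_where_linear_cannot():
    x = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
    y = np.array([0, 0, 1, 1])
    rbf = fit_svm_spectral(x, y, gamma=2.0)
    assert (rbf.predict(x) == y).all()
    linear = fit_svm_spectral(x, y, kernel="linear")
    assert (linear.predict(x) == y).mean() < 1.0  # XOR is linearly inseparable


def test_svm_single_class_rejected():
    with pytest.raises(ValueError):
        fit_svm_spectral(np.zeros((5, 2)), np.zeros(5))


# --- spectrogram CNN --------------------------------------------------------

def test_spectrogram_cnn_forward_shape():
    model = build_spectrogram_cnn((25, 28))
    x = np.random.default_rng(0).standard_normal((2, 25, 28)).astype(np.float32)
    model.eval()
    assert model(x).shape == (2, 3)
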