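"""Gradient and layer correctness of the NumPy network core."""

import numpy as np
import pytest

from gestage.nn import Adam, BatchNorm2d, Conv2d, Linear, MaxPool2d, Tensor, \
    adapt_first_conv, build_backbone
from gestage.nn.tensor import bilinear_upsample, dtype_context


def numeric_grad(fn, array, eps=1e-6):
    """Central finite differences of a scalar-valued fn at `array`."""
    grad = np.zeros_like(array)
    it = np.nditer(array, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = array[idx]
        array[idx] = orig + eps
        fp = fn()
        array[idx] = orig - eps
        fm = fn()
        array[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad


@pytest.mark.parametrize("op_name", ["relu", "abs", "channel_max", "clip",
                                     "upsample", "matmul", "div", "spatial_max"])
def test_primitive_gradients_match_finite_differences(op_name):
    """Each autograd primitive's backward agrees with central differences."""
    with dtype_context(np.float64):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 4, 5, 5))
        w = rng.normal(size=(20, 7))

        def forward():
            t = Tensor(x, requires_grad=True)
            tw = Tensor(w, requires_grad=True)
            if op_name == "relu":
                out = t.relu().mean()
            elif op_name == "abs":
                out = t.abs().mean()
            elif op_name == "channel_max":
                out = t.max_over_axis(1).mean()
            elif op_name == "clip":
                out = t.clip(-0.5, 0.75).mean()
            elif op_name == "upsample":
                out = t.reshape(8, 5, 5).upsample_bilinear((9, 11)).mean()
            elif op_name == "matmul":
                out = t.reshape(10, 20).matmul(tw).mean()
            elif op_name == "div":
                out = (t / (t.abs() + 1.5)).mean()
            elif op_name == "spatial_max":
                out = t.max_over_spatial().mean()
            return t, tw, out

        t, tw, out = forward()
        out.backward()
        fd = numeric_grad(lambda: float(forward()[2].data), x)
        assert np.allclose(t.grad, fd, rtol=1e-5, atol=1e-7)


@pytest.mark.parametrize("layer_name", ["conv", "conv_bias", "bn", "linear",
                                        "maxpool"])
def test_layer_gradients_match_finite_differences(layer_name):
    with dtype_context(np.float64):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3, 2, 6, 6))
        if layer_name in ("conv", "conv_bias"):
            layer = Conv2d(2, 3, 3, stride=2, padding=1,
                           bias=layer_name == "conv_bias", rng=rng)
        elif layer_name == "bn":
            layer = BatchNorm2d(2)
        elif layer_name == "maxpool":
            layer = MaxPool2d(3, 2, 1)
        else:
            layer = Linear(72, 4, rng=rng)

        def forward():
            t = Tensor(x, requires_grad=True)
            inp = t.reshape(3, 72) if layer_name == "linear" else t
            return t, (layer(inp) ** 2).mean()

        t, out = forward()
        out.backward()
        fd_x = numeric_grad(lambda: float(forward()[1].data), x)
        assert np.allclose(t.grad, fd_x, rtol=1e-5, atol=1e-7)
        for p in layer.parameters():
            analytic = p.grad.copy()
            fd_p = numeric_grad(lambda: float(forward()[1].data), p.data)
            # BatchNorm running-stat updates during fd probing do not affect
            # train-mode outputs, so the comparison is valid
            assert np.allclose(analytic, fd_p, rtol=1e-5, atol=1e-7)


def test_conv2d_matches_direct_convolution():
    """im2col convolution equals an explicit quadruple loop."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
    conv = Conv2d(3, 4, 3, stride=2, padding=1, rng=rng)
    out = conv(Tensor(x)).data
    w = conv.weight.data
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    expected = np.zeros_like(out)
    for n in range(2):
        for co in range(4):
            for i in range(out.shape[2]):
                for j in range(out.shape[3]):
                    patch = xp[n, :, 2 * i:2 * i + 3, 2 * j:2 * j + 3]
                    expected[n, co, i, j] = np.sum(patch * w[co])
    assert np.allclose(out, expected, atol=1e-5)


def test_bilinear_upsample_constant_and_bounds():
    const = np.full((4, 6), 3.25)
    up = bilinear_upsample(const, (13, 17))
    assert up.shape == (13, 17)
    assert np.allclose(up, 3.25, atol=1e-6)
    rng = np.random.default_rng(1)
    arr = rng.normal(size=(7, 7))
    up = bilinear_upsample(arr, (224, 224))
    assert up.max() <= arr.max() + 1e-6 and up.min() >= arr.min() - 1e-6


def test_adam_minimizes_quadratic():
    target = np.array([3.0, -2.0], dtype=np.float32)
    p = Tensor(np.zeros(2, dtype=np.float32), requires_grad=True)
    opt = Adam([p], lr=0.1)
    for _ in range(300):
        loss = ((p - Tensor(target)) ** 2).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.allclose(p.data, target, atol=1e-2)


@pytest.mark.parametrize("in_channels", [1, 3, 5])
def test_tiny_backbone_forward_backward_all_slice_counts(in_channels):
    net = build_backbone("tiny", in_channels, seed=0)
    x = Tensor(np.random.default_rng(0).normal(
        size=(2, in_channels, 64, 64)).astype(np.float32))
    feats = net.forward_features(x)
    assert feats.data.shape == (2, net.feature_channels, 8, 8)
    y = net.head(feats)
    assert y.data.shape == (2,) and np.all(np.isfinite(y.data))
    (y ** 2).mean().backward()
    assert net.stem.weight.grad is not None
    assert np.any(net.stem.weight.grad != 0)


def test_resnet18_feature_contract():
    """Standard residual architecture: K=512 last-stage channels."""
    net = build_backbone("resnet18", 1, seed=0)
    assert net.feature_channels == 512
    x = Tensor(np.random.default_rng(0).normal(
        size=(1, 1, 64, 64)).astype(np.float32))
    feats = net.forward_features(x)
    assert feats.data.shape == (1, 512, 2, 2)
    assert np.isfinite(net.head(feats).data).all()


def test_resnet50_first_layer_parameterized_by_slices():
    net = build_backbone("resnet50", 5, seed=0)
    assert net.feature_channels == 2048
    assert net.stem.weight.data.shape == (64, 5, 7, 7)


def test_adapt_first_conv_preserves_uniform_response():
    """Channel adaptation: mean kernel replicated, response to a constant
    input preserved for any slice count."""
    rng = np.random.default_rng(2)
    w3 = rng.normal(size=(8, 3, 7, 7))
    for c in (1, 5):
        wc = adapt_first_conv(w3, c)
        assert wc.shape == (8, c, 7, 7)
        # response to an all-ones input patch is unchanged
        assert np.allclose(wc.sum(axis=(1, 2, 3)), w3.sum(axis=(1, 2, 3)),
                           rtol=1e-4, atol=1e-4)
    assert np.array_equal(adapt_first_conv(w3, 3), w3)


def test_backbone_weight_loading_adapts_first_conv(tmp_path):
    donor = build_backbone("tiny", 3, seed=1)
    path = tmp_path / "weights.npz"
    np.savez(path, **donor.state_dict())
    net = build_backbone("tiny", 5, seed=2, weights=str(path))
    expected = adapt_first_conv(donor.stem.weight.data, 5)
    assert np.allclose(net.stem.weight.data, expected)
    # non-stem layers inherit the donor weights verbatim
    assert np.array_equal(net.fc.weight.data, donor.fc.weight.data)
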