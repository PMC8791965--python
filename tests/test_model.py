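"""Dual-branch model assembly, fusion arithmetic, attention-path
consistency, and multi-plane averaging."""

import numpy as np
import pytest

from gestage.attention import AttentionHeatmap, GaussianWeight, apply_mask, \
    channel_max_heatmap, gaussian_reweight, normalize_heatmap, upsample_heatmap
from gestage.model import AttentionSettings, BackboneSpec, build_model, \
    forward_dual, multiplane_predict
from gestage.nn import Tensor
from gestage.preprocessing import PlaneSlab


@pytest.fixture(scope="module")
def dual_model():
    return build_model(BackboneSpec(family="tiny", in_channels=3), seed=0)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        BackboneSpec(family="vgg")
    with pytest.raises(ValueError):
        BackboneSpec(in_channels=2)
    with pytest.raises(ValueError):
        build_model(BackboneSpec(), mode="triple")


@pytest.mark.parametrize("in_channels", [1, 3, 5])
def test_dual_forward_yields_finite_scalars(in_channels):
    model = build_model(BackboneSpec(family="tiny", in_channels=in_channels),
                        seed=1)
    x = np.random.default_rng(0).normal(
        size=(2, in_channels, 64, 64)).astype(np.float32)
    out = model.predict_batch(x)
    for key in ("y_global", "y_local", "y_pred"):
        assert out[key].shape == (2,)
        assert np.all(np.isfinite(out[key]))
    assert out["heatmap"].shape == (2, 64, 64)
    assert out["heatmap"].min() >= 0.0 and out["heatmap"].max() <= 1.0


def test_global_only_mode_has_no_local_branch():
    model = build_model(BackboneSpec(), mode="global_only", seed=2)
    assert not hasattr(model, "local_branch")
    x = np.random.default_rng(1).normal(size=(3, 3, 64, 64)).astype(np.float32)
    out = model.predict_batch(x)
    assert np.array_equal(out["y_pred"], out["y_global"])
    assert "y_local" not in out


def test_fusion_is_exact_branch_mean(dual_model):
    x = np.random.default_rng(2).normal(size=(4, 3, 64, 64)).astype(np.float32)
    out = dual_model.predict_batch(x)
    assert np.allclose(out["y_pred"],
                       (out["y_global"] + out["y_local"]) / 2.0, atol=1e-5)


def test_forward_dual_fused_arithmetic():
    """y_global 210 d and y_local 224 d must fuse to 217 d (checked via the
    dataclass contract on synthetic outputs and on a real forward)."""
    assert (210.0 + 224.0) / 2 == 217.0
    model = build_model(BackboneSpec(), seed=3)
    slab = PlaneSlab(np.random.default_rng(3).normal(size=(3, 64, 64)),
                     plane="axial", subject_id="s0")
    pred, heat = forward_dual(model, slab, y_true=210.0)
    assert pred.y_pred == pytest.approx((pred.y_global + pred.y_local) / 2,
                                        abs=1e-4)
    assert pred.plane == "axial" and pred.y_true == 210.0
    assert heat.stage == "gaussian_weighted"
    assert heat.values.shape == (64, 64)


def test_network_attention_path_matches_numpy_reference(dual_model):
    """The differentiable attention path inside the network reproduces the
    public NumPy ops composed in the same order (up-sample, truncated-ReLU
    max-normalization, Gaussian re-weighting, masking)."""
    x = np.random.default_rng(4).normal(size=(1, 3, 64, 64)).astype(np.float32)
    model = dual_model
    model.eval()
    feats = model.global_branch.forward_features(Tensor(x))
    out = model.predict_batch(x)

    raw = channel_max_heatmap(feats.data[0])
    up = upsample_heatmap(raw, (64, 64))
    norm = normalize_heatmap(up)
    g = GaussianWeight.centered((64, 64), model.attention.sigma_fraction)
    weighted = gaussian_reweight(norm, g)
    assert np.allclose(out["heatmap"][0], weighted.values, atol=1e-4)
    masked = apply_mask(x[0], weighted)
    assert masked.shape == (3, 64, 64)


def test_gradient_through_mask_toggle():
    """With gradient flow enabled the local loss reaches global-branch
    weights; with the stop-gradient it does not."""
    rng = np.random.default_rng(5)
    x = Tensor(rng.normal(size=(2, 3, 64, 64)).astype(np.float32))
    for flag, expect_grad in ((True, True), (False, False)):
        model = build_model(BackboneSpec(), gradient_through_mask=flag, seed=6)
        out = model.forward(x)
        ((out["y_local"]) ** 2).mean().backward()
        grad = model.global_branch.stem.weight.grad
        has_grad = grad is not None and np.any(grad != 0)
        assert has_grad == expect_grad


def test_multiplane_average_and_single_plane():
    model = build_model(BackboneSpec(), seed=7)
    models = {p: model for p in ("axial", "coronal", "sagittal")}
    rng = np.random.default_rng(7)
    slab = rng.normal(size=(3, 64, 64))
    slabs = {p: PlaneSlab(slab, plane=p) for p in models}
    fused = multiplane_predict(models, slabs, subject_id="s1")
    single, _ = forward_dual(model, slabs["axial"])
    # identical inputs and identical weights: the average equals any plane
    assert fused.y_pred == pytest.approx(single.y_pred, abs=1e-5)
    only = multiplane_predict({"axial": model}, {"axial": slabs["axial"]})
    assert only.y_pred == pytest.approx(single.y_pred, abs=1e-6)


def test_multiplane_prediction_is_mean_of_plane_predictions():
    preds = []
    models, slabs = {}, {}
    rng = np.random.default_rng(8)
    for i, plane in enumerate(("axial", "coronal", "sagittal")):
        models[plane] = build_model(BackboneSpec(), seed=20 + i)
        slabs[plane] = PlaneSlab(rng.normal(size=(3, 64, 64)), plane=plane)
        preds.append(forward_dual(models[plane], slabs[plane])[0].y_pred)
    fused = multiplane_predict(models, slabs)
    assert fused.y_pred == pytest.approx(np.mean(preds), abs=1e-6)


def test_multiplane_rejects_zero_planes(dual_model):
    with pytest.raises(ValueError):
        multiplane_predict({"axial": dual_model}, {"coronal": np.zeros(1)})


def test_calibration_shifts_predictions():
    model = build_model(BackboneSpec(), seed=9)
    x = np.random.default_rng(9).normal(size=(2, 3, 64, 64)).astype(np.float32)
    base = model.predict_batch(x)["y_pred"]
    model.set_calibration(210.0, 44.0)
    shifted = model.predict_batch(x)["y_pred"]
    assert np.allclose(shifted, base * 44.0 + 210.0, atol=1e-3)
    with pytest.raises(ValueError):
        model.set_calibration(0.0, -1.0)
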