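"""Dual-branch age-regression network with attention plumbing.

The global branch regresses age from the full multi-slice input. Its last
convolutional feature block is turned into a soft attention mask (channel
max -> bilinear up-sampling -> truncated-ReLU normalization -> Gaussian
center prior), which multiplies the input image to form the local branch's
input. Each branch predicts one scalar age; the fused prediction is their
arithmetic mean. The whole path — including the mask — is differentiable,
so gradients of the local-branch loss reach the global branch's weights
and the framework trains end to end; a stop-gradient switch exists for
ablation.

Multi-plane prediction averages the fused per-plane predictions of
independent per-plane networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import AttentionHeatmap, GaussianWeight
from .nn import Module, Tensor, build_backbone
from .preprocessing import PlaneSlab

__all__ = ["BackboneSpec", "AttentionSettings", "AgePrediction",
           "DualBranchModel", "build_model", "forward_dual",
           "multiplane_predict"]

_FAMILIES = ("tiny", "resnet18", "resnet50")


@dataclass(frozen=True)
class BackboneSpec:
    """Backbone configuration; ``in_channels`` equals the slice count."""

    family: str = "tiny"
    in_channels: int = 3
    input_size: int = 64
    pool: str = "avg"
    weights: str | None = None   # optional .npz with saved backbone weights

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown backbone family {self.family!r}; "
                             f"choose from {_FAMILIES}")
        if self.in_channels not in (1, 3, 5):
            raise ValueError("in_channels must be 1, 3, or 5")
        if self.family == "tiny" and self.input_size < 32:
            raise ValueError("tiny backbone needs input_size >= 32")


@dataclass(frozen=True)
class AttentionSettings:
    """Heatmap post-processing: truncation percentile of the normalization
    ceiling (100 = plain max) and the Gaussian center prior (sigma as a
    fraction of the image side; center defaults to the image center)."""

    percentile: float = 100.0
    sigma_fraction: float = 0.25
    center: tuple[float, float] | None = None


@dataclass
class AgePrediction:
    """Per-branch, fused, and (optionally) true age for one input, in days."""

    y_pred: float
    y_global: float
    y_local: float | None = None
    y_true: float | None = None
    plane: str | None = None
    subject_id: str = ""


class DualBranchModel(Module):
    """Paired global/local regression networks with shared attention plumbing.

    The branches do not share weights. Output calibration (an affine map
    applied to both heads) is set from training labels so freshly
    initialized heads start near the cohort mean age.
    """

    def __init__(self, spec: BackboneSpec, mode: str = "dual",
                 attention: AttentionSettings | None = None,
                 gradient_through_mask: bool = True, seed: int = 0):
        super().__init__()
        if mode not in ("dual", "global_only"):
            raise ValueError(f"unknown mode {mode!r}")
        self.spec = spec
        self.mode = mode
        self.attention = attention or AttentionSettings()
        self.gradient_through_mask = gradient_through_mask
        self.global_branch = build_backbone(
            spec.family, spec.in_channels, pool=spec.pool, seed=seed,
            weights=spec.weights)
        if mode == "dual":
            self.local_branch = build_backbone(
                spec.family, spec.in_channels, pool=spec.pool, seed=seed + 1,
                weights=spec.weights)
        self._buffers["y_calibration"] = np.array([0.0, 1.0], dtype=np.float32)

    # -- calibration -------------------------------------------------------

    def set_calibration(self, loc: float, scale: float) -> None:
        if scale <= 0:
            raise ValueError("calibration scale must be positive")
        self._buffers["y_calibration"][:] = (loc, scale)

    def _calibrate(self, z: Tensor) -> Tensor:
        loc, scale = self._buffers["y_calibration"]
        return z * float(scale) + float(loc)

    # -- forward -----------------------------------------------------------

    def _gaussian(self, shape: tuple[int, int]) -> np.ndarray:
        att = self.attention
        if att.center is None:
            g = GaussianWeight.centered(shape, att.sigma_fraction)
        else:
            g = GaussianWeight(att.center,
                               att.sigma_fraction * (shape[0] + shape[1]) / 2)
        return g.array(shape).astype(np.float32)

    def forward(self, x: Tensor) -> dict:
        """Run both branches on a batch (N, C, H, W); returns calibrated
        per-branch and fused predictions plus the soft mask."""
        n, _, hh, ww = x.data.shape
        feats = self.global_branch.forward_features(x)
        y_global = self._calibrate(self.global_branch.head(feats))
        if self.mode == "global_only":
            return {"y_global": y_global, "y_local": None,
                    "y_pred": y_global, "mask": None}
        # attention path: channel max -> upsample -> truncated ReLU -> Gaussian
        raw = feats.abs().max_over_axis(1)               # (N, h, w)
        up = raw.upsample_bilinear((hh, ww))             # (N, H, W)
        if self.attention.percentile >= 100.0:
            # max-normalization: the clamp is a no-op on a non-negative map,
            # so divide by the per-sample maximum, kept differentiable
            peak = up.reshape(n, 1, hh, ww).max_over_spatial().reshape(n, 1, 1)
            normalized = up / (peak + 1e-12)
        else:
            # percentile ceiling (robust variant); the ceiling itself is a
            # data-dependent constant outside the gradient path
            ceiling = np.percentile(up.data, self.attention.percentile,
                                    axis=(1, 2))
            ceiling = np.maximum(ceiling, 1e-12)[:, None, None]
            normalized = up.clip(0.0, ceiling) * Tensor(1.0 / ceiling)
        weighted = normalized * Tensor(self._gaussian((hh, ww))[None])
        mask = weighted if self.gradient_through_mask else weighted.detach()
        masked = x * mask.reshape(n, 1, hh, ww)
        y_local = self._calibrate(
            self.local_branch.head(self.local_branch.forward_features(masked)))
        y_pred = (y_global + y_local) * 0.5
        return {"y_global": y_global, "y_local": y_local, "y_pred": y_pred,
                "mask": weighted}

    def predict_batch(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Inference on a (N, C, H, W) array; returns NumPy predictions and
        the gaussian-weighted heatmaps."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(Tensor(np.asarray(x, dtype=np.float32)))
        finally:
            self.train(was_training)
        result = {"y_global": out["y_global"].data.copy(),
                  "y_pred": out["y_pred"].data.copy()}
        if out["y_local"] is not None:
            result["y_local"] = out["y_local"].data.copy()
            result["heatmap"] = out["mask"].data.copy()
        return result


def build_model(spec: BackboneSpec, mode: str = "dual",
                attention: AttentionSettings | None = None,
                gradient_through_mask: bool = True,
                seed: int = 0) -> DualBranchModel:
    """Assemble a dual-branch (or global-only) age-regression network."""
    return DualBranchModel(spec, mode=mode, attention=attention,
                           gradient_through_mask=gradient_through_mask,
                           seed=seed)


def _slab_array(slab) -> np.ndarray:
    if isinstance(slab, PlaneSlab):
        return slab.pixels
    return np.asarray(slab, dtype=np.float64)


def forward_dual(model: DualBranchModel, slab,
                 y_true: float | None = None
                 ) -> tuple[AgePrediction, AttentionHeatmap | None]:
    """Single-input forward pass returning the fused prediction and the
    gaussian-weighted attention heatmap."""
    arr = _slab_array(slab)
    out = model.predict_batch(arr[None])
    plane = getattr(slab, "plane", None)
    subject_id = getattr(slab, "subject_id", "")
    y_local = float(out["y_local"][0]) if "y_local" in out else None
    pred = AgePrediction(
        y_pred=float(out["y_pred"][0]), y_global=float(out["y_global"][0]),
        y_local=y_local, y_true=y_true, plane=plane, subject_id=subject_id)
    heatmap = None
    if "heatmap" in out:
        heatmap = AttentionHeatmap(out["heatmap"][0],
                                   stage="gaussian_weighted")
    return pred, heatmap


def multiplane_predict(models: dict[str, DualBranchModel],
                       slabs: dict[str, object],
                       y_true: float | None = None,
                       subject_id: str = "") -> AgePrediction:
    """Average fused per-plane predictions over the available planes."""
    planes = [p for p in slabs if p in models]
    if not planes:
        raise ValueError("no plane with both a model and an input available")
    fused, globals_, locals_ = [], [], []
    for plane in planes:
        pred, _ = forward_dual(models[plane], slabs[plane])
        fused.append(pred.y_pred)
        globals_.append(pred.y_global)
        locals_.append(pred.y_local)
    y_local = (None if any(v is None for v in locals_)
               else float(np.mean(locals_)))
    return AgePrediction(
        y_pred=float(np.mean(fused)), y_global=float(np.mean(globals_)),
        y_local=y_local, y_true=y_true, plane="+".join(planes),
        subject_id=subject_id)
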