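"""Attention-guided mask inference.

The soft localization map is read from the last convolutional layer of the
global branch: for feature activations f_k(x, y) over K channels, the raw
heatmap is H(x, y) = max_k |f_k(x, y)|. The raw map is up-sampled to the
input resolution, normalized to [0, 1] with a truncated-ReLU (clamp to
[0, ceiling] then rescale, where the ceiling defaults to the map maximum
but may be a lower percentile for robustness to single-pixel spikes), and
re-weighted by a centered 2-D Gaussian that encodes the prior that the
fetal brain lies near the image center. The resulting soft mask multiplies
the input image to form the local-branch input; no hard cropping or
thresholding is performed.

These functions are the plain-NumPy reference path. The differentiable
twin used inside the network lives in :mod:`gestage.model`; a test asserts
the two paths agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.tensor import bilinear_upsample

__all__ = [
    "AttentionHeatmap",
    "GaussianWeight",
    "channel_max_heatmap",
    "normalize_heatmap",
    "upsample_heatmap",
    "gaussian_reweight",
    "apply_mask",
]

_STAGES = ("raw", "normalized", "gaussian_weighted")


@dataclass
class AttentionHeatmap:
    """A spatial attention map with its processing stage.

    Stages: ``raw`` (non-negative channel-max activations), ``normalized``
    (truncated-ReLU rescaled to [0, 1]), ``gaussian_weighted`` (after the
    center-prior product, still within [0, 1]).
    """

    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("heatmap must be 2-D")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("heatmap contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GaussianWeight:
    """Isotropic 2-D Gaussian prior with peak value 1 at ``center``.

    center : (row, col) in pixels; sigma : standard deviation in pixels.
    """

    center: tuple[float, float]
    sigma: float
    peak: float = field(default=1.0, init=False)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def array(self, shape: tuple[int, int]) -> np.ndarray:
        rows = np.arange(shape[0], dtype=np.float64)[:, None]
        cols = np.arange(shape[1], dtype=np.float64)[None, :]
        d2 = (rows - self.center[0]) ** 2 + (cols - self.center[1]) ** 2
        return np.exp(-d2 / (2.0 * self.sigma ** 2))

    @classmethod
    def centered(cls, shape: tuple[int, int],
                 sigma_fraction: float = 0.25) -> "GaussianWeight":
        """Gaussian centered on the image with sigma a fraction of the
        (mean) image side; 0.25 covers a centered brain at a 224-px input
        while decaying strongly toward the borders."""
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
        return cls(center=center, sigma=sigma_fraction * (shape[0] + shape[1]) / 2.0)


def channel_max_heatmap(features: np.ndarray) -> AttentionHeatmap:
    """H(x, y) = max over channels k of |f_k(x, y)| for a (K, h, w) block."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 3 or features.shape[0] < 1:
        raise ValueError("expected a non-empty (K, h, w) feature block")
    if not np.all(np.isfinite(features)):
        raise ValueError("feature block contains non-finite values")
    return AttentionHeatmap(np.abs(features).max(axis=0), stage="raw")


def normalize_heatmap(heatmap: AttentionHeatmap,
                      q: float = 100.0) -> AttentionHeatmap:
    """Truncated-ReLU normalization to [0, 1].

    Values are clamped below at 0 and above at the q-th percentile of the
    map (q = 100 means the maximum), then divided by that ceiling. An
    all-zero (or all-non-positive) map passes through as zeros so that
    degenerate early-training feature maps do not halt training.
    """
    if heatmap.stage not in ("raw",):
        raise ValueError("normalize_heatmap expects a raw-stage heatmap")
    if not 0.0 < q <= 100.0:
        raise ValueError("percentile q must lie in (0, 100]")
    values = heatmap.values
    ceiling = float(np.percentile(values, q))
    if ceiling <= 0.0:
        return AttentionHeatmap(np.zeros_like(values), stage="normalized")
    out = np.clip(values, 0.0, ceiling) / ceiling
    return AttentionHeatmap(out, stage="normalized")


def upsample_heatmap(heatmap: AttentionHeatmap,
                     target: tuple[int, int]) -> AttentionHeatmap:
    """Bilinear up-sampling to the input resolution (stage preserved).

    Interpolation weights are convex, so values stay within the source map's
    [min, max] range.
    """
    h, w = heatmap.shape
    if target[0] < h or target[1] < w:
        raise ValueError(f"target {target} smaller than source {(h, w)}")
    out = bilinear_upsample(heatmap.values, (int(target[0]), int(target[1])))
    return AttentionHeatmap(out, stage=heatmap.stage)


def gaussian_reweight(heatmap: AttentionHeatmap,
                      weight: GaussianWeight) -> AttentionHeatmap:
    """Multiply a normalized heatmap by the Gaussian center prior.

    The product never exceeds the input (the Gaussian peaks at 1) and the
    value at the Gaussian center is unchanged.
    """
    if heatmap.stage != "normalized":
        raise ValueError("gaussian_reweight expects a normalized heatmap")
    return AttentionHeatmap(heatmap.values * weight.array(heatmap.shape),
                            stage="gaussian_weighted")


def apply_mask(image: np.ndarray, heatmap: AttentionHeatmap) -> np.ndarray:
    """Per-slice elementwise product of image and soft mask.

    `image` is (H, W) or (n_slices, H, W); the masked result feeds the
    local branch.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape[-2:] != heatmap.shape:
        raise ValueError(f"image spatial dims {image.shape[-2:]} do not match "
                         f"heatmap {heatmap.shape}")
    return image * heatmap.values
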