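"""Slice selection, cropping, per-sample normalization, and dataset splits.

The network consumes a small odd number of slices (1, 3, or 5) centered on
the middle slice of each plane's stack — the middle slice is assumed to
contain the largest cross-section of the brain. Inputs are cropped to a
fixed square (randomly during training, centered at evaluation), and each
multi-slice slab is normalized by its own joint mean and standard
deviation. Splits are subject-level so no subject leaks across partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PlaneSlab", "SplitAssignment", "select_slices", "crop",
           "normalize_sample", "split_dataset", "finetune_split"]

_VALID_SLICES = (1, 3, 5)


@dataclass
class PlaneSlab:
    """A single-plane, multi-slice network input (slices, height, width)."""

    pixels: np.ndarray
    plane: str = "axial"
    subject_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError("PlaneSlab pixels must be (slices, height, width)")
        if self.pixels.shape[0] % 2 == 0:
            raise ValueError("slice count must be odd")

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SplitAssignment:
    """Subject-level train/val/test partition."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def subjects(self, partition: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == partition]


def _subject_ids(manifest) -> list[str]:
    if isinstance(manifest, pd.DataFrame):
        return [str(s) for s in manifest["subject_id"]]
    return [str(getattr(s, "subject_id", s)) for s in manifest]


def middle_index(length: int) -> int:
    """Middle slice index; for even stacks the lower of the middle pair."""
    return (length - 1) // 2


def select_slices(stack: np.ndarray, n_slices: int,
                  plane: str = "axial", subject_id: str = "") -> PlaneSlab:
    """Middle slice plus its immediate neighbors, in ascending order."""
    stack = np.asarray(stack, dtype=np.float64)
    if n_slices not in _VALID_SLICES:
        raise ValueError(f"n_slices must be one of {_VALID_SLICES}")
    if stack.shape[0] < n_slices:
        raise ValueError(
            f"subject {subject_id or '<unknown>'}: stack has {stack.shape[0]} "
            f"slices, fewer than the requested {n_slices}")
    mid = middle_index(stack.shape[0])
    half = n_slices // 2
    picked = stack[mid - half:mid + half + 1]
    return PlaneSlab(picked.copy(), plane=plane, subject_id=subject_id)


def crop(slab: PlaneSlab, size: int, mode: str = "center",
         seed: int = 0) -> PlaneSlab:
    """Crop (after symmetric zero-padding when the image is smaller than the
    target) to size x size; random mode draws one offset shared by all
    slices of the slab."""
    if mode not in ("random", "center"):
        raise ValueError(f"unknown crop mode {mode!r}")
    pixels = slab.pixels
    _, h, w = pixels.shape
    pad_h = max(0, size - h)
    pad_w = max(0, size - w)
    if pad_h or pad_w:
        pixels = np.pad(pixels, ((0, 0),
                                 (pad_h // 2, pad_h - pad_h // 2),
                                 (pad_w // 2, pad_w - pad_w // 2)))
        _, h, w = pixels.shape
    if mode == "center":
        top, left = (h - size) // 2, (w - size) // 2
    else:
        rng = np.random.default_rng(seed)
        top = int(rng.integers(0, h - size + 1))
        left = int(rng.integers(0, w - size + 1))
    out = pixels[:, top:top + size, left:left + size]
    return PlaneSlab(out.copy(), plane=slab.plane, subject_id=slab.subject_id)


def normalize_sample(slab: PlaneSlab) -> PlaneSlab:
    """(x - mean) / sd using the slab's own joint moments across all slices.

    Idempotent and invariant to positive affine rescaling of the input.
    """
    pixels = slab.pixels
    sd = pixels.std()
    if sd == 0:
        raise ValueError(
            f"subject {slab.subject_id or '<unknown>'}: constant slab cannot "
            "be normalized")
    out = (pixels - pixels.mean()) / sd
    return PlaneSlab(out, plane=slab.plane, subject_id=slab.subject_id)


def split_dataset(manifest, fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
                  seed: int = 0) -> SplitAssignment:
    """Random subject-level split: floor(n*f_train) train, floor(n*f_val)
    validation, remainder test."""
    ids = _subject_ids(manifest)
    if len(ids) == 0:
        raise ValueError("empty manifest")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in manifest")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    n = len(ids)
    n_train = int(np.floor(n * fractions[0]))
    n_val = int(np.floor(n * fractions[1]))
    order = np.random.default_rng(seed).permutation(n)
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            part = "train"
        elif rank < n_train + n_val:
            part = "val"
        else:
            part = "test"
        assignment[ids[idx]] = part
    return SplitAssignment(assignment, tuple(fractions), seed)


def finetune_split(manifest, fraction: float = 0.20,
                   seed: int = 0) -> tuple[list[str], list[str]]:
    """Site-adaptation split: floor(fraction*n) subjects for fine-tuning,
    the rest held out for testing."""
    ids = _subject_ids(manifest)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 subjects to form an adaptation set")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n_adapt = int(np.floor(fraction * n))
    order = np.random.default_rng(seed).permutation(n)
    adapt = [ids[i] for i in order[:n_adapt]]
    test = [ids[i] for i in order[n_adapt:]]
    return adapt, test
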