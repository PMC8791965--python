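"""Synthetic multi-plane phantom subjects with known age labels.

Each phantom subject mimics the data regime of a fetal brain MRI study: a
bright, roughly centered object (the "brain") whose size and internal
texture complexity grow monotonically with a latent age label, embedded in
darker background clutter (maternal tissue) and Gaussian noise, rendered
as independent axial/coronal/sagittal slice stacks. The object is a filled
ellipse with a band-limited sinusoidal internal texture — the simplest
geometry whose area and complexity can encode age monotonically, which is
all the regression and attention-localization experiments need. A
ground-truth binary mask of the middle-slice object accompanies every
plane, so attention localization is testable without any real MRI.

Ages are in days throughout; weeks appear only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PhantomConfig", "PhantomSubject", "generate_subject",
           "generate_cohort", "degrade", "PLANES"]

PLANES = ("axial", "coronal", "sagittal")


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; defaults give the desk-scale study conditions.

    The age range 126–280 days (18–40 weeks) matches the clinically relevant
    second/third-trimester window. Object semi-axes grow linearly from 8% to
    30% of the image side over the age range, texture frequency from 2 to 8
    cycles per image (a gyrification proxy), so both area and internal
    complexity are strictly increasing in age.
    """

    image_size: int = 64
    age_range: tuple[float, float] = (126.0, 280.0)
    radius_fractions: tuple[float, float] = (0.08, 0.30)
    texture_frequencies: tuple[float, float] = (2.0, 8.0)
    clutter_count: int = 6
    clutter_intensity: float = 0.35
    noise_sd: float = 0.05
    center_jitter_sd: float = 2.0
    slices_per_plane: int = 5
    aspect_ratio: float = 0.8  # minor/major semi-axis ratio of the object
    object_intensity: float = 0.75
    texture_amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if self.image_size < 64:
            raise ValueError("image_size must be at least 64")
        if not self.radius_fractions[0] < self.radius_fractions[1]:
            raise ValueError("object radius map must be strictly increasing")
        if self.slices_per_plane < 5:
            raise ValueError("slices_per_plane must be at least 5")
        if self.noise_sd < 0 or self.center_jitter_sd < 0:
            raise ValueError("noise/jitter standard deviations must be >= 0")

    def object_radius(self, age_days: float) -> tuple[float, float]:
        """Strictly increasing map from age to (major, minor) semi-axes, px."""
        lo, hi = self.age_range
        t = (age_days - lo) / (hi - lo)
        frac = self.radius_fractions[0] + t * (
            self.radius_fractions[1] - self.radius_fractions[0])
        a = frac * self.image_size
        return a, a * self.aspect_ratio

    def texture_frequency(self, age_days: float) -> float:
        """Monotone map from age to texture spatial frequency, cycles/image."""
        lo, hi = self.age_range
        t = (age_days - lo) / (hi - lo)
        f0, f1 = self.texture_frequencies
        return f0 + t * (f1 - f0)


@dataclass
class PhantomSubject:
    subject_id: str
    age_days: float
    planes: dict[str, np.ndarray]       # plane -> (slices, H, W) float in [0,1]
    truth_masks: dict[str, np.ndarray]  # plane -> (H, W) bool, middle slice
    site_tag: str = "phantom"
    meta: dict = field(default_factory=dict)

    def middle_slice(self, plane: str) -> np.ndarray:
        stack = self.planes[plane]
        return stack[(stack.shape[0] - 1) // 2]


def _ellipse_interior(size: int, center: tuple[float, float],
                      semi_axes: tuple[float, float],
                      theta: float) -> np.ndarray:
    """Boolean interior of a rotated ellipse on a size x size grid
    (0-based row/col indices, origin top-left)."""
    rows = np.arange(size, dtype=np.float64)[:, None] - center[0]
    cols = np.arange(size, dtype=np.float64)[None, :] - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = rows * ct + cols * st
    v = -rows * st + cols * ct
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _render_plane(config: PhantomConfig, age_days: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    size = config.image_size
    n_slices = config.slices_per_plane
    half = n_slices // 2

    jitter = rng.normal(0.0, config.center_jitter_sd, size=2)
    center = ((size - 1) / 2.0 + jitter[0], (size - 1) / 2.0 + jitter[1])
    a, b = config.object_radius(age_days)
    theta = rng.uniform(0.0, np.pi)
    freq = config.texture_frequency(age_days)
    tex_angle = rng.uniform(0.0, np.pi)
    tex_phase = rng.uniform(0.0, 2 * np.pi)

    rows = np.arange(size, dtype=np.float64)[:, None]
    cols = np.arange(size, dtype=np.float64)[None, :]
    carrier = np.sin(2 * np.pi * freq *
                     (rows * np.cos(tex_angle) + cols * np.sin(tex_angle))
                     / size + tex_phase)

    background = np.full((size, size), 0.08, dtype=np.float64)
    for _ in range(config.clutter_count):
        c_center = (rng.uniform(0, size - 1), rng.uniform(0, size - 1))
        c_axes = (rng.uniform(0.04, 0.14) * size, rng.uniform(0.04, 0.14) * size)
        c_theta = rng.uniform(0.0, np.pi)
        c_int = config.clutter_intensity * rng.uniform(0.6, 1.2)
        background[_ellipse_interior(size, c_center, c_axes, c_theta)] += c_int

    stack = np.empty((n_slices, size, size), dtype=np.float64)
    truth_mask = None
    for i, offset in enumerate(range(-half, half + 1)):
        # adjacent slices cut the object off-equator: shrink the ellipse
        scale = np.sqrt(max(0.0, 1.0 - (offset / (half + 1)) ** 2))
        img = background.copy()
        if scale > 0:
            interior = _ellipse_interior(size, center, (a * scale, b * scale),
                                         theta)
            img[interior] = (config.object_intensity
                             + config.texture_amplitude * carrier[interior])
            if offset == 0:
                truth_mask = interior
        img += rng.normal(0.0, config.noise_sd, size=(size, size))
        stack[i] = np.clip(img, 0.0, 1.0)
    return stack, truth_mask


def generate_subject(config: PhantomConfig, age_days: float, seed: int,
                     subject_id: str | None = None,
                     site_tag: str = "phantom") -> PhantomSubject:
    """Render one subject: three independent plane stacks plus truth masks.

    Deterministic given (config, age_days, seed).
    """
    lo, hi = config.age_range
    if not lo <= age_days <= hi:
        raise ValueError(
            f"age {age_days} d outside the configured range [{lo}, {hi}] d")
    planes: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for i, plane in enumerate(PLANES):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        stack, mask = _render_plane(config, age_days, rng)
        planes[plane] = stack
        masks[plane] = mask
    return PhantomSubject(
        subject_id=subject_id or f"phantom_{seed:06d}",
        age_days=float(age_days), planes=planes, truth_masks=masks,
        site_tag=site_tag)


def sample_ages(config: PhantomConfig, n: int, rng: np.random.Generator,
                sampler: str = "uniform") -> np.ndarray:
    """Draw age labels. ``uniform`` covers the range evenly; ``skewed``
    mimics the clinical scarcity of late-third-trimester scans by placing
    only 5% of the mass on the top 15% of the range (vs 15% under uniform),
    the rest uniform over the lower 85%."""
    lo, hi = config.age_range
    if sampler == "uniform":
        return rng.uniform(lo, hi, size=n)
    if sampler == "skewed":
        knot = lo + 0.85 * (hi - lo)
        upper = rng.random(n) < 0.05
        ages = rng.uniform(lo, knot, size=n)
        ages[upper] = rng.uniform(knot, hi, size=int(upper.sum()))
        return ages
    raise ValueError(f"unknown sampler {sampler!r}")


def generate_cohort(config: PhantomConfig, n: int, seed: int,
                    sampler: str = "uniform",
                    site_tag: str = "phantom") -> list[PhantomSubject]:
    """Generate ``n`` subjects with reproducibly derived per-subject seeds."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 982451653]))
    ages = sample_ages(config, n, rng, sampler=sampler)
    subjects = []
    for i, age in enumerate(ages):
        sub_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0]
                       % (2 ** 31))
        subjects.append(generate_subject(
            config, float(age), sub_seed,
            subject_id=f"{site_tag}_{i:04d}", site_tag=site_tag))
    return subjects


def degrade(subject: PhantomSubject, contrast_scale: float = 1.0,
            extra_noise_sd: float = 0.0, ghosting_amplitude: float = 0.0,
            ghost_shift: int = 8, seed: int = 0,
            site_tag: str | None = None) -> PhantomSubject:
    """Simulate a domain-shifted acquisition site.

    Intensities are scaled by ``contrast_scale``, an optional shifted
    low-amplitude copy is blended in as a motion-ghosting proxy
    (out = (1-a)*img + a*shift(img)), fresh Gaussian noise is added, and
    the result is clipped to [0, 1]. Age label and truth masks are
    untouched; the site tag is updated.
    """
    if contrast_scale <= 0:
        raise ValueError("contrast_scale must be positive")
    if extra_noise_sd < 0:
        raise ValueError("extra noise standard deviation must be >= 0")
    if not 0.0 <= ghosting_amplitude < 1.0:
        raise ValueError("ghosting_amplitude must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    new_planes = {}
    for plane, stack in subject.planes.items():
        out = contrast_scale * stack
        if ghosting_amplitude > 0:
            ghost = np.roll(out, ghost_shift, axis=-1)
            out = (1.0 - ghosting_amplitude) * out + ghosting_amplitude * ghost
        if extra_noise_sd > 0:
            out = out + rng.normal(0.0, extra_noise_sd, size=out.shape)
        new_planes[plane] = np.clip(out, 0.0, 1.0)
    return replace(subject, planes=new_planes,
                   truth_masks={p: m.copy() for p, m in
                                subject.truth_masks.items()},
                   site_tag=site_tag or subject.site_tag + "_degraded")
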