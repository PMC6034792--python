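"""Synthetic en-face angiogram phantoms with ground truth.

A phantom is a bright curvilinear vessel network over a darker background
with one contiguous dark avascular region (disc, ellipse, or irregular
blob). Vessels are grown as seeded biased random walks with branching and
rasterized at their physical diameters; region intensities are drawn from
per-region Gaussian models, multiplicative speckle noise is applied, and
a device profile (gain/offset) modulates global brightness and contrast.
Everything is deterministic given the spec seed: geometry and rendering
use independent streams derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from octaquant.errors import ValidationError
from octaquant.octa_io import (
    LABEL_AVASCULAR,
    LABEL_VASCULAR,
    AnnotationSet,
    OCTAImage,
)

AVASCULAR_SHAPES = ("disc", "ellipse", "irregular")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic angiogram generator."""

    size_px: int = 300
    pixel_size_um: float = 10.0
    avascular_shape: str = "disc"
    avascular_radius_um: float = 600.0
    ellipse_axis_ratio: float = 0.6
    irregularity: float = 0.25
    n_vessel_seeds: int = 30
    branch_prob: float = 0.02
    vessel_diameter_range_um: tuple[float, float] = (20.0, 80.0)
    step_px: float = 2.0
    turn_sd_rad: float = 0.15
    vessel_mean: float = 200.0
    vessel_sd: float = 15.0
    background_mean: float = 40.0
    background_sd: float = 8.0
    avascular_mean: float = 10.0
    avascular_sd: float = 4.0
    speckle_sd: float = 0.05
    brightness: float = 1.0
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.avascular_shape not in AVASCULAR_SHAPES:
            raise ValidationError(f"avascular_shape must be one of {AVASCULAR_SHAPES}")
        if not (self.vessel_mean > self.background_mean > self.avascular_mean >= 0):
            raise ValidationError(
                "intensity model must satisfy vessel mean > background mean "
                "> avascular mean >= 0"
            )
        if self.size_px < 16:
            raise ValidationError("size_px must be at least 16")
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be positive")


@dataclass
class PhantomGroundTruth:
    """Masks and true region means behind a generated phantom."""

    vessel_mask: np.ndarray
    avascular_mask: np.ndarray
    true_means: dict[str, float]
    spec: PhantomSpec


def _avascular_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.size_px
    r_px = spec.avascular_radius_um / spec.pixel_size_um
    if 2 * r_px >= n:
        raise ValidationError(
            f"avascular region (radius {r_px:.1f} px) larger than the {n} px image"
        )
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    if spec.avascular_shape == "disc":
        return dy**2 + dx**2 <= r_px**2
    if spec.avascular_shape == "ellipse":
        theta = rng.uniform(0, np.pi)
        c, s = np.cos(theta), np.sin(theta)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        b = r_px * spec.ellipse_axis_ratio
        return (u / r_px) ** 2 + (v / b) ** 2 <= 1.0
    # irregular: disc boundary perturbed by low-frequency radial harmonics
    angle = np.arctan2(dy, dx)
    radius = np.full_like(angle, r_px)
    for k in range(2, 6):
        amp = spec.irregularity * r_px / k
        phase = rng.uniform(0, 2 * np.pi)
        radius = radius + amp * np.cos(k * angle + phase)
    return dy**2 + dx**2 <= radius**2


def _stamp_disc(mask: np.ndarray, y: float, x: float, radius_px: float) -> None:
    n = mask.shape[0]
    r = max(radius_px, 0.5)
    y0, y1 = int(max(0, np.floor(y - r))), int(min(n - 1, np.ceil(y + r)))
    x0, x1 = int(max(0, np.floor(x - r))), int(min(n - 1, np.ceil(x + r)))
    if y1 < y0 or x1 < x0:
        return
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    mask[y0 : y1 + 1, x0 : x1 + 1] |= (yy - y) ** 2 + (xx - x) ** 2 <= r**2


def _vessel_mask(spec: PhantomSpec, avascular: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = spec.size_px
    mask = np.zeros((n, n), dtype=bool)
    d_lo, d_hi = spec.vessel_diameter_range_um
    max_steps = int(2.0 * n / spec.step_px)
    # (y, x, direction, diameter_um) walkers; branching appends children
    walkers = []
    for _ in range(spec.n_vessel_seeds):
        edge = rng.integers(0, 4)
        t = rng.uniform(0, n)
        y, x = [(0.0, t), (n - 1.0, t), (t, 0.0), (t, n - 1.0)][edge]
        direction = np.arctan2((n / 2 - y), (n / 2 - x)) + rng.normal(0, 0.4)
        walkers.append((y, x, direction, rng.uniform(d_lo, d_hi)))
    budget = 6 * spec.n_vessel_seeds  # cap on total branches
    while walkers and budget > 0:
        y, x, direction, diam = walkers.pop(0)
        budget -= 1
        radius_px = diam / (2.0 * spec.pixel_size_um)
        for _ in range(max_steps):
            if not (0 <= y < n and 0 <= x < n):
                break
            _stamp_disc(mask, y, x, radius_px)
            direction += rng.normal(0, spec.turn_sd_rad)
            y += spec.step_px * np.sin(direction)
            x += spec.step_px * np.cos(direction)
            if rng.random() < spec.branch_prob and budget > 0:
                child_dir = direction + rng.choice((-1, 1)) * rng.uniform(0.4, 1.1)
                walkers.append((y, x, child_dir, max(d_lo, diam * 0.7)))
    mask &= ~avascular  # the avascular region has no flow signal
    return mask


def _render(
    spec: PhantomSpec,
    avascular: np.ndarray,
    vessels: np.ndarray,
    rng: np.random.Generator,
    brightness_factor: float = 1.0,
) -> np.ndarray:
    n = spec.size_px
    img = spec.background_mean + spec.background_sd * rng.normal(size=(n, n))
    noise_v = rng.normal(size=(n, n))
    noise_a = rng.normal(size=(n, n))
    img[vessels] = spec.vessel_mean + spec.vessel_sd * noise_v[vessels]
    img[avascular] = spec.avascular_mean + spec.avascular_sd * noise_a[avascular]
    img *= 1.0 + spec.speckle_sd * rng.normal(size=(n, n))
    img = spec.brightness * brightness_factor * img + spec.offset
    return np.clip(img, 0.0, 255.0)


def generate_phantom(spec: PhantomSpec) -> tuple[OCTAImage, PhantomGroundTruth]:
    """Generate one phantom image plus its ground truth. Deterministic per seed."""
    rng_geom = np.random.default_rng(spec.seed)
    rng_noise = np.random.default_rng((spec.seed, 0x5EED))
    avascular = _avascular_mask(spec, rng_geom)
    vessels = _vessel_mask(spec, avascular, rng_geom)
    pixels = _render(spec, avascular, vessels, rng_noise)
    image = OCTAImage(pixels=pixels, pixel_size_um=spec.pixel_size_um, device_label="phantom")
    truth = PhantomGroundTruth(
        vessel_mask=vessels,
        avascular_mask=avascular,
        true_means={
            "vessel": spec.vessel_mean,
            "background": spec.background_mean,
            "avascular": spec.avascular_mean,
        },
        spec=spec,
    )
    return image, truth


def simulate_repeat_series(
    spec: PhantomSpec,
    n: int,
    brightness_jitter_pct: float,
    seeds: Sequence[int],
) -> list[OCTAImage]:
    """Repeat acquisitions of one phantom eye.

    Geometry is fixed by ``spec.seed``; each repeat gets fresh noise and a
    multiplicative brightness factor drawn as 1 + Normal(0, jitter/100)
    from its own seed.
    """
    if n < 2:
        raise ValidationError("need at least 2 repeats")
    if len(seeds) != n:
        raise ValidationError(f"need exactly {n} seeds, got {len(seeds)}")
    if brightness_jitter_pct < 0:
        raise ValidationError("brightness_jitter_pct must be non-negative")
    rng_geom = np.random.default_rng(spec.seed)
    avascular = _avascular_mask(spec, rng_geom)
    vessels = _vessel_mask(spec, avascular, rng_geom)
    series = []
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        factor = 1.0 + (brightness_jitter_pct / 100.0) * rng.normal()
        pixels = _render(spec, avascular, vessels, rng, brightness_factor=factor)
        series.append(
            OCTAImage(
                pixels=pixels,
                pixel_size_um=spec.pixel_size_um,
                device_label="phantom",
                acquisition_index=i,
            )
        )
    return series


def sample_annotations(
    truth: PhantomGroundTruth,
    n_per_class: int = 400,
    margin_px: int = 4,
    seed: int = 0,
    annotation_id: str = "",
) -> AnnotationSet:
    """Draw scribble-like annotations from the phantom's true regions.

    Avascular pixels are sampled from the eroded avascular region and
    vascular pixels from outside its dilated boundary, so repeated draws
    land at different locations within the same true regions — emulating
    repeated manual annotation.
    """
    rng = np.random.default_rng(seed)
    structure = np.ones((2 * margin_px + 1, 2 * margin_px + 1), dtype=bool)
    av_pool = ndimage.binary_erosion(truth.avascular_mask, structure=structure)
    vs_pool = ~ndimage.binary_dilation(truth.avascular_mask, structure=structure)
    labels = np.zeros(truth.avascular_mask.shape, dtype=np.uint8)
    for pool, lbl, name in (
        (av_pool, LABEL_AVASCULAR, "avascular"),
        (vs_pool, LABEL_VASCULAR, "vascular"),
    ):
        idx = np.flatnonzero(pool.ravel())
        if len(idx) == 0:
            raise ValidationError(f"no candidate pixels for class {name}")
        chosen = rng.choice(idx, size=min(n_per_class, len(idx)), replace=False)
        labels.ravel()[chosen] = lbl
    return AnnotationSet(label_image=labels, annotation_id=annotation_id or f"scribbles-{seed}")
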