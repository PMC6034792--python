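"""Per-pixel multi-scale feature stack used as classifier input.

Scales are expressed in micrometers so they stay physically meaningful
across devices with different pixel calibrations. A scale corresponds
roughly to the diameter of the structure it responds to; the Gaussian
sigma used for the operators is ``scale_um / (2 * pixel_size_um)`` pixels.

Operator bank (per scale): Gaussian smoothing, gradient magnitude,
Laplacian, smaller/larger Hessian eigenvalue, local variance — plus the
raw intensity once, so F = 6 * n_scales + 1. The smaller Hessian
eigenvalue is the classic bright-tubular-structure response: strongly
negative on a vessel whose diameter matches the scale, which prevents
the narrow interspace between small vessels from being mistaken for an
avascular region.

All convolutions use reflective boundary handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from octaquant.errors import ValidationError
from octaquant.octa_io import OCTAImage

OPERATORS = (
    "gaussian",
    "gradient_magnitude",
    "laplacian",
    "hessian_eig_small",
    "hessian_eig_large",
    "local_variance",
)

#: default expected vessel diameter range (capillaries .. large peripapillary
#: vessels) in micrometers
DEFAULT_VESSEL_DIAMETER_RANGE_UM = (10.0, 160.0)

_BOUNDARY = "reflect"
# wide kernel support keeps derivative kernels near-exactly zero-sum
_TRUNCATE = 6.0


@dataclass
class FeatureStack:
    """Stack of per-pixel features over the image grid.

    ``features`` has shape (H, W, F); ``feature_names[k]`` describes
    channel k as ``"operator@scale_um"`` (or ``"raw"``).
    """

    features: np.ndarray
    feature_names: list[str]
    scales_um: tuple[float, ...]

    def __post_init__(self):
        if self.features.ndim != 3:
            raise ValidationError("feature array must be (H, W, F)")
        if self.features.shape[2] != len(self.feature_names):
            raise ValidationError("feature_names length must match channel count")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("feature stack contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.features.shape[2]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.features.shape[:2]

    def as_matrix(self) -> np.ndarray:
        """Flatten to (H*W, F) for the classifier."""
        return self.features.reshape(-1, self.n_features)


def default_scales(
    pixel_size_um: float,
    vessel_diameter_range_um: tuple[float, float] = DEFAULT_VESSEL_DIAMETER_RANGE_UM,
) -> list[float]:
    """Geometric ladder of scales (factor 2) covering the vessel-size range.

    The ladder starts at the range minimum and doubles until a rung reaches
    or exceeds the maximum, so both endpoints are covered. Rungs smaller
    than one pixel are dropped.
    """
    lo, hi = (float(v) for v in vessel_diameter_range_um)
    if not (0 < lo < hi):
        raise ValidationError("vessel diameter range must satisfy 0 < min < max")
    if not (pixel_size_um > 0):
        raise ValidationError("pixel_size_um must be positive")
    if hi < pixel_size_um:
        raise ValidationError(
            "no resolvable vessel: maximum vessel diameter "
            f"{hi} um is below the pixel size {pixel_size_um} um"
        )
    ladder = []
    s = lo
    while True:
        ladder.append(s)
        if s >= hi:
            break
        s *= 2.0
    ladder = [s for s in ladder if s >= pixel_size_um]
    if not ladder:
        raise ValidationError("all scales fall below one pixel")
    return ladder


def _hessian_eigenvalues(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    # sigma**2 scale normalization keeps responses comparable across scales
    hrr = ndimage.gaussian_filter(img, sigma, order=(2, 0), mode=_BOUNDARY, truncate=_TRUNCATE) * sigma**2
    hcc = ndimage.gaussian_filter(img, sigma, order=(0, 2), mode=_BOUNDARY, truncate=_TRUNCATE) * sigma**2
    hrc = ndimage.gaussian_filter(img, sigma, order=(1, 1), mode=_BOUNDARY, truncate=_TRUNCATE) * sigma**2
    half_trace = 0.5 * (hrr + hcc)
    root = np.sqrt(np.square(0.5 * (hrr - hcc)) + np.square(hrc))
    return half_trace - root, half_trace + root


def _local_variance(img: np.ndarray, sigma: float) -> np.ndarray:
    mean = ndimage.gaussian_filter(img, sigma, mode=_BOUNDARY, truncate=_TRUNCATE)
    mean_sq = ndimage.gaussian_filter(img * img, sigma, mode=_BOUNDARY, truncate=_TRUNCATE)
    return np.maximum(mean_sq - mean * mean, 0.0)


def compute_features(image: OCTAImage, scales_um: list[float] | None = None) -> FeatureStack:
    """Compute the multi-scale feature stack for ``image``.

    Deterministic; every channel is finite. Raises if a scale converts to
    sigma below 0.5 px (unresolvable).
    """
    if scales_um is None:
        scales_um = default_scales(image.pixel_size_um)
    if not scales_um:
        raise ValidationError("scales_um must be non-empty")
    img = image.pixels
    if not np.all(np.isfinite(img)):
        raise ValidationError("image contains non-finite pixels")

    channels: list[np.ndarray] = [img]
    names: list[str] = ["raw"]
    for scale in scales_um:
        sigma = scale / (2.0 * image.pixel_size_um)
        if sigma < 0.5:
            raise ValidationError(
                f"scale {scale} um converts to sigma {sigma:.3f} px < 0.5 px"
            )
        smooth = ndimage.gaussian_filter(img, sigma, mode=_BOUNDARY, truncate=_TRUNCATE)
        grad = ndimage.gaussian_gradient_magnitude(img, sigma, mode=_BOUNDARY, truncate=_TRUNCATE) * sigma
        lap = ndimage.gaussian_laplace(img, sigma, mode=_BOUNDARY, truncate=_TRUNCATE) * sigma**2
        eig_small, eig_large = _hessian_eigenvalues(img, sigma)
        var = _local_variance(img, sigma)
        channels.extend([smooth, grad, lap, eig_small, eig_large, var])
        names.extend(f"{op}@{scale:g}" for op in OPERATORS)

    stack = np.stack(channels, axis=-1)
    return FeatureStack(features=stack, feature_names=names, scales_um=tuple(scales_um))
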