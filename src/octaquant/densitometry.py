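"""Gray-level vessel densitometry over regions of interest.

Both the mean gray value and the integrated (summed) gray-level density
are reported for every measurement; their relative fluctuation across a
repeat series is identical whenever the pixel count is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from octaquant.errors import ValidationError
from octaquant.octa_io import OCTAImage
from octaquant.roi_geometry import ROIMask


@dataclass
class DensityMeasurement:
    mean_gray: float
    integrated_density: float
    n_pixels: int
    roi_role: str
    band_width_um: float | None = None
    layer: str = "other"
    subject_id: str = ""
    eye: str = ""
    acquisition_index: int = 0

    def __post_init__(self):
        if self.n_pixels <= 0:
            raise ValidationError("n_pixels must be positive")
        if not (0 <= self.mean_gray <= 255):
            raise ValidationError("mean_gray must lie in [0, 255]")


def mean_gray_in_roi(image: OCTAImage, roi: ROIMask) -> DensityMeasurement:
    """Arithmetic mean and sum of intensities over the ROI pixels."""
    if roi.mask.shape != image.shape:
        raise ValidationError(
            f"ROI shape {roi.mask.shape} does not match image shape {image.shape}"
        )
    n = roi.area_px
    if n == 0:
        raise ValidationError("empty ROI: no pixels to measure")
    values = image.pixels[roi.mask]
    total = float(values.sum())
    return DensityMeasurement(
        mean_gray=total / n,
        integrated_density=total,
        n_pixels=n,
        roi_role=roi.role,
        band_width_um=roi.band_width_um,
        layer=image.layer,
        subject_id=image.subject_id,
        eye=image.eye,
        acquisition_index=image.acquisition_index,
    )


def whole_image_mean(image: OCTAImage) -> DensityMeasurement:
    """Mean gray value over every pixel of the image."""
    total = float(image.pixels.sum())
    n = image.pixels.size
    return DensityMeasurement(
        mean_gray=total / n,
        integrated_density=total,
        n_pixels=n,
        roi_role="whole_image",
        layer=image.layer,
        subject_id=image.subject_id,
        eye=image.eye,
        acquisition_index=image.acquisition_index,
    )
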