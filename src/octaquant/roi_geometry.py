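"""Avascular-core extraction and peripapillary annulus construction.

The avascular core is the largest 8-connected component of the classifier
mask (holes filled, small specks discarded). The annulus at a physical
band width w is the set of pixels outside the core whose exact Euclidean
distance to the core is at most ``w / pixel_size_um`` pixels — a
morphological dilation by a Euclidean disc, minus the core, clipped at
image borders. Distances are taken from the exact Euclidean distance
transform; band widths stay real-valued (no rounding of the radius).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from octaquant.errors import ValidationError
from octaquant.pixel_rf import SegmentationMask

ROI_ROLES = ("avascular_core", "annulus", "whole_image")


@dataclass
class ROIMask:
    """A binary region of interest with its physical bookkeeping."""

    mask: np.ndarray
    role: str
    pixel_size_um: float
    band_width_um: float | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("ROI mask must be 2D")
        if self.role not in ROI_ROLES:
            raise ValidationError(f"role must be one of {ROI_ROLES}")
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be positive")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2


def um_to_px(length_um: float, pixel_size_um: float) -> float:
    """Physical length to pixels as an exact ratio (never rounded here)."""
    if length_um < 0 or not (pixel_size_um > 0):
        raise ValidationError("lengths must be non-negative and pixel size positive")
    return length_um / pixel_size_um


def extract_avascular_region(
    seg: SegmentationMask,
    min_area_px: int,
    pixel_size_um: float = 1.0,
) -> ROIMask:
    """Largest 8-connected avascular component, holes filled.

    Components smaller than ``min_area_px`` are ignored. If two candidate
    components have exactly equal area, the one whose first pixel in
    row-major order comes first wins (documented tie-break).
    """
    labeled = measure.label(seg.mask, connectivity=2)
    if labeled.max() == 0:
        raise ValidationError("no avascular region found")
    flat = labeled.ravel()
    areas = np.bincount(flat)[1:]  # skip background label 0
    candidates = [lbl for lbl, a in enumerate(areas, start=1) if a >= min_area_px]
    if not candidates:
        raise ValidationError("no avascular region found")
    first_index = {lbl: int(np.argmax(flat == lbl)) for lbl in candidates}
    best = max(candidates, key=lambda lbl: (areas[lbl - 1], -first_index[lbl]))
    core = ndimage.binary_fill_holes(labeled == best)
    return ROIMask(mask=core, role="avascular_core", pixel_size_um=pixel_size_um)


def build_peripapillary_annulus(
    core: ROIMask,
    band_width_um: float,
    pixel_size_um: float | None = None,
) -> ROIMask:
    """Annular band of physical width ``band_width_um`` around the core.

    annulus = { p outside core : EuclideanDistance(p, core) <= w_px }
    with w_px = band_width_um / pixel_size_um; clipped at image borders.
    """
    if pixel_size_um is None:
        pixel_size_um = core.pixel_size_um
    if core.area_px == 0:
        raise ValidationError("core mask is empty")
    if not (band_width_um > 0):
        raise ValidationError("band_width_um must be positive")
    if band_width_um < pixel_size_um:
        raise ValidationError(
            f"band width {band_width_um} um is below one pixel ({pixel_size_um} um)"
        )
    radius_px = um_to_px(band_width_um, pixel_size_um)
    dist = ndimage.distance_transform_edt(~core.mask)
    annulus = (dist > 0) & (dist <= radius_px)
    return ROIMask(
        mask=annulus,
        role="annulus",
        pixel_size_um=pixel_size_um,
        band_width_um=float(band_width_um),
    )
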