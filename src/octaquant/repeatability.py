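"""Repeatability statistics: fluctuation of repeat series and stage differences.

Reporting convention
--------------------
Relative fluctuation is 100 * sd / mean (a coefficient of variation in
percent). Reported values are *truncated* (floored), not rounded, at the
stated decimal precision; the full-precision value is always retained
alongside. The standard deviation uses the population formula (divide by
n) by default, with a sample-formula flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from octaquant.errors import PipelineStageError, ValidationError
from octaquant.octa_io import AnnotationSet, OCTAImage, PipelineConfig


@dataclass
class FluctuationStats:
    """Mean / sd / relative fluctuation of a repeat series."""

    n: int
    mean_value: float
    sd: float
    relative_fluctuation_pct: float
    reported_pct: float
    report_decimals: int
    sample_sd: bool = False


def truncate_at_precision(x: float, decimals: int) -> float:
    """floor(x * 10^d) / 10^d, with a guard against float representation error.

    Values within 1e-9 (relative) of an exact decimal are snapped to it
    before flooring, so e.g. 21.6 stays 21.6 instead of dropping to 21.5.
    """
    if x < 0:
        raise ValidationError("truncate_at_precision requires x >= 0")
    if decimals < 0:
        raise ValidationError("decimals must be >= 0")
    scaled = x * 10.0**decimals
    nearest = round(scaled)
    if abs(scaled - nearest) <= 1e-9 * max(1.0, abs(scaled)):
        scaled = nearest
    return math.floor(scaled) / 10.0**decimals


def fluctuation_stats(
    values: Sequence[float],
    report_decimals: int = 2,
    sample_sd: bool = False,
) -> FluctuationStats:
    """Mean, sd, and relative fluctuation (%) of a repeat series.

    Requires n >= 2 and a positive mean.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size < 2:
        raise ValidationError(f"need at least 2 values, got {arr.size}")
    mean = float(arr.mean())
    if mean <= 0:
        raise ValidationError("mean of the series must be positive")
    sd = float(arr.std(ddof=1 if sample_sd else 0))
    rel = relative_fluctuation_pct(sd, mean)
    return FluctuationStats(
        n=int(arr.size),
        mean_value=mean,
        sd=sd,
        relative_fluctuation_pct=rel,
        reported_pct=truncate_at_precision(rel, report_decimals),
        report_decimals=report_decimals,
        sample_sd=sample_sd,
    )


def relative_fluctuation_pct(sd: float, mean: float) -> float:
    """100 * sd / mean (coefficient of variation in percent)."""
    if mean <= 0:
        raise ValidationError("mean must be positive")
    if sd < 0:
        raise ValidationError("sd must be non-negative")
    return 100.0 * sd / mean


def stage_difference_percent(mean_earlier: float, mean_later: float) -> float:
    """Percent decrease between consecutive stage means:
    100 * (mean_earlier - mean_later) / mean_earlier."""
    if mean_earlier <= 0:
        raise ValidationError("mean_earlier must be positive")
    return 100.0 * (mean_earlier - mean_later) / mean_earlier


def annotation_repeatability(
    image: OCTAImage,
    annotation_sets: Sequence[AnnotationSet],
    config: PipelineConfig,
) -> FluctuationStats:
    """Fluctuation of the measured density across repeated manual annotations.

    For each annotation set, the full pipeline is run on ``image``
    (train -> predict -> avascular core -> annulus at the first configured
    band width -> mean gray value) and the fluctuation statistics of the
    resulting densities are returned. Any stage failure aborts with the
    failing annotation's id.
    """
    from octaquant.densitometry import mean_gray_in_roi
    from octaquant.feature_bank import compute_features, default_scales
    from octaquant.pixel_rf import predict, train
    from octaquant.roi_geometry import build_peripapillary_annulus, extract_avascular_region

    if len(annotation_sets) < 2:
        raise ValidationError("need at least 2 annotation sets")

    scales = list(config.scales_um) or default_scales(image.pixel_size_um)
    stack = compute_features(image, scales)
    band = config.band_widths_um[0]

    densities = []
    for aset in annotation_sets:
        try:
            model = train(stack, aset, config)
            seg = predict(model, stack, config.threshold)
            core = extract_avascular_region(
                seg, config.min_area_px, pixel_size_um=image.pixel_size_um
            )
            annulus = build_peripapillary_annulus(core, band)
            densities.append(mean_gray_in_roi(image, annulus).mean_gray)
        except Exception as exc:  # noqa: BLE001 - re-raise with annotation id
            raise PipelineStageError(
                "annotation_repeatability",
                f"failed for annotation {aset.annotation_id!r}: {exc}",
            ) from exc
    return fluctuation_stats(densities, config.report_decimals, config.sample_sd)
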