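"""I/O for en-face angiograms, sparse annotations, binary masks, and configuration.

Conventions
-----------
* Images are normalized to 8-bit range [0, 255] on load; higher bit depths
  are rescaled linearly (full dtype range maps onto [0, 255]).
* Pixel calibration is isotropic and derived from the declared field of
  view: ``pixel_size_um = 1000 * field_of_view_mm / width_px``.
* Coordinates are 0-based, row-major, origin at top-left.
* Masks are written as single-channel PNG with 0 = background and
  255 = foreground; annotations are single-channel PNG with values
  0 = unlabeled, 1 = avascular, 2 = vascular.
* RGB inputs are collapsed to gray by channel averaging.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from octaquant.errors import ValidationError

LAYERS = ("SCN", "DCN", "other")

LABEL_UNLABELED = 0
LABEL_AVASCULAR = 1
LABEL_VASCULAR = 2

_CLASS_NAMES = {LABEL_AVASCULAR: "avascular", LABEL_VASCULAR: "vascular"}


@dataclass
class OCTAImage:
    """A 2D 8-bit-range en-face angiogram with physical calibration.

    ``pixels`` is a float array with values in [0, 255]; ``pixel_size_um``
    is the isotropic physical size of one pixel in micrometers.
    """

    pixels: np.ndarray
    pixel_size_um: float
    layer: str = "other"
    device_label: str = ""
    subject_id: str = ""
    eye: str = ""
    acquisition_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("image must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("image contains non-finite pixel values")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValidationError("pixel intensities must lie in [0, 255]")
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be positive")
        if self.layer not in LAYERS:
            raise ValidationError(f"layer must be one of {LAYERS}, got {self.layer!r}")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class AnnotationSet:
    """Sparse pixel labels used to train the classifier.

    ``label_image`` has the same shape as the target image with values
    0 (unlabeled), 1 (avascular), 2 (vascular). Both annotated classes
    must be present.
    """

    label_image: np.ndarray
    annotation_id: str = ""

    def __post_init__(self):
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValidationError("annotation label image must be 2D")
        values = np.unique(self.label_image)
        bad = set(values.tolist()) - {LABEL_UNLABELED, LABEL_AVASCULAR, LABEL_VASCULAR}
        if bad:
            raise ValidationError(f"annotation contains invalid label values {sorted(bad)}")
        for lbl, name in _CLASS_NAMES.items():
            if not np.any(self.label_image == lbl):
                raise ValidationError(f"no annotated pixels for class {name}")

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.label_image == label))


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters, serializable as a flat key-value file.

    ``scales_um`` empty means "derive a default scale ladder from the
    image's pixel size at run time".
    """

    scales_um: tuple[float, ...] = ()
    band_widths_um: tuple[float, ...] = (640.0, 920.0, 1960.0)
    n_trees: int = 100
    max_features: str = "sqrt"
    max_depth: int | None = None
    seed: int = 0
    train_cap_per_class: int = 10_000
    threshold: float = 0.5
    min_area_px: int = 50
    report_decimals: int = 2
    sample_sd: bool = False

    def __post_init__(self):
        self.scales_um = tuple(float(s) for s in self.scales_um)
        self.band_widths_um = tuple(float(b) for b in self.band_widths_um)
        if any(s <= 0 for s in self.scales_um):
            raise ValidationError("scales_um must be strictly positive")
        if not self.band_widths_um or any(b <= 0 for b in self.band_widths_um):
            raise ValidationError("band_widths_um must be non-empty and positive")
        if not (0 < self.threshold < 1):
            raise ValidationError("threshold must lie in (0, 1)")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(repr(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kv: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"malformed config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            kv[key] = val
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in kv:
                continue
            raw = kv.pop(f.name)
            if f.name in ("scales_um", "band_widths_um"):
                kwargs[f.name] = tuple(float(x) for x in raw.split(",") if x.strip()) if raw else ()
            elif f.name == "max_depth":
                kwargs[f.name] = None if raw in ("None", "") else int(raw)
            elif f.name == "max_features":
                kwargs[f.name] = raw
            elif f.name == "threshold":
                kwargs[f.name] = float(raw)
            elif f.name == "sample_sd":
                kwargs[f.name] = raw == "True"
            else:
                kwargs[f.name] = int(raw)
        if kv:
            raise ValidationError(f"unknown config keys: {sorted(kv)}")
        return cls(**kwargs)


def _to_gray(raw: np.ndarray) -> np.ndarray:
    if raw.ndim == 3:
        raw = raw[..., :3].mean(axis=2)
    if raw.ndim != 2:
        raise ValidationError(f"cannot interpret array of shape {raw.shape} as a 2D image")
    return raw


def _rescale_to_8bit(gray: np.ndarray, dtype: np.dtype) -> np.ndarray:
    gray = gray.astype(np.float64)
    if np.issubdtype(dtype, np.integer) and np.iinfo(dtype).max > 255:
        return gray * (255.0 / np.iinfo(dtype).max)
    if np.issubdtype(dtype, np.floating):
        top = gray.max()
        if top > 255 or (0 < top <= 1.0):
            return gray * (255.0 / top)
    return gray


def read_image(
    path: str | Path,
    field_of_view_mm: float,
    layer: str = "other",
    device_label: str = "",
    **metadata,
) -> OCTAImage:
    """Read an en-face angiogram and attach physical calibration.

    ``pixel_size_um = 1000 * field_of_view_mm / width_px``. Intensities are
    mapped to [0, 255]; 16-bit rasters are rescaled so the dtype maximum
    maps to 255; RGB is averaged to gray.
    """
    if not (field_of_view_mm > 0):
        raise ValidationError("field_of_view_mm must be positive")
    raw = iio.imread(Path(path))
    gray = _rescale_to_8bit(_to_gray(np.asarray(raw)), np.asarray(raw).dtype)
    if gray.size == 0:
        raise ValidationError(f"zero-size image: {path}")
    pixel_size_um = 1000.0 * field_of_view_mm / gray.shape[1]
    return OCTAImage(
        pixels=np.clip(gray, 0, 255),
        pixel_size_um=pixel_size_um,
        layer=layer,
        device_label=device_label,
        **metadata,
    )


def read_annotations(path: str | Path, image: OCTAImage) -> AnnotationSet:
    """Read a label raster (values 0/1/2) and validate it against ``image``."""
    raw = np.asarray(iio.imread(Path(path)))
    if raw.ndim == 3:
        raw = raw[..., 0]
    if raw.shape != image.shape:
        raise ValidationError(
            f"annotation shape {raw.shape} does not match image shape {image.shape}"
        )
    return AnnotationSet(label_image=raw.astype(np.uint8), annotation_id=Path(path).stem)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as single-channel PNG (0 background, 255 foreground)."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1, 255, True, False)).all():
        raise ValidationError("mask must be binary")
    out = np.where(mask.astype(bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), out)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask written by :func:`write_mask`; returns a bool array."""
    raw = np.asarray(iio.imread(Path(path)))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return raw > 127


def write_annotations(aset: AnnotationSet, path: str | Path) -> None:
    """Write the label raster as single-channel PNG with literal values 0/1/2."""
    iio.imwrite(Path(path), aset.label_image.astype(np.uint8))


def write_density_csv(measurements: Sequence, path: str | Path) -> None:
    """Write density measurements as a CSV table (one row each)."""
    import pandas as pd

    rows = [dataclasses.asdict(m) for m in measurements]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
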