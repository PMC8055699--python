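"""Image normalization: cropping, histogram matching and intensity complement.

All rasters are 8-bit grayscale.  Coordinates are 0-based ``(row, col)`` with
row 0 at the top; windows are half-open.  Physical pixel spacing is carried
along so downstream length measurements can be reported in millimetres when
the scanner metadata is known; by default spacing is 1.0 and lengths come out
in pixel units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .errors import BoundsError

#: Default crop window for native 1000x1414 CASIA2 exports (row_start,
#: row_stop, col_start, col_stop), producing a 629x1102 region anchored at
#: the top-left corner.  Only the output size is standardized; the offset is
#: an overridable choice.
CASIA2_CROP: Tuple[int, int, int, int] = (0, 629, 0, 1102)


@dataclass
class GrayImage:
    """A 2-D 8-bit grayscale raster with optional physical pixel spacing.

    Parameters
    ----------
    pixels
        2-D array of intensities in ``[0, 255]``; stored as ``uint8``.
    spacing_y, spacing_x
        Physical size of one pixel along rows / columns (mm).  Defaults to
        1.0 so that, absent metadata, all lengths are in pixel units.
    provenance
        Free-text source tag (file path, synthetic seed, ...).
    """

    pixels: np.ndarray
    spacing_y: float = 1.0
    spacing_x: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got ndim={px.ndim}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"image must be at least 2x2, got {px.shape}")
        if px.dtype != np.uint8:
            arr = px.astype(float)
            if not np.isfinite(arr).all():
                raise ValueError("image contains non-finite intensities")
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError(
                    f"intensities outside [0, 255]: min={arr.min()}, max={arr.max()}"
                )
            px = np.rint(arr).astype(np.uint8)
        if not (self.spacing_y > 0 and self.spacing_x > 0):
            raise ValueError("pixel spacing must be positive")
        self.pixels = px

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def spacing(self) -> Tuple[float, float]:
        return (self.spacing_y, self.spacing_x)

    def histogram(self) -> np.ndarray:
        """256-bin intensity histogram (counts)."""
        return np.bincount(self.pixels.ravel(), minlength=256)


@dataclass
class PreprocessConfig:
    """Settings for the normalization stage.

    ``crop_window`` is ``(row_start, row_stop, col_start, col_stop)``,
    half-open; ``None`` means no cropping (the full frame is used).  For
    native CASIA2 rasters pass :data:`CASIA2_CROP`.  ``reference`` is a
    256-bin histogram (counts) to match against; ``None`` selects the
    package's canonical synthetic reference.
    """

    crop_window: Optional[Tuple[int, int, int, int]] = None
    reference: Optional[np.ndarray] = field(default=None, repr=False)
    apply_complement: bool = True

    def __post_init__(self) -> None:
        if self.crop_window is not None:
            r0, r1, c0, c1 = self.crop_window
            if not (r0 < r1 and c0 < c1):
                raise ValueError(f"empty crop window {self.crop_window}")
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            validate_reference_histogram(ref)
            self.reference = ref


def validate_reference_histogram(hist: np.ndarray) -> None:
    hist = np.asarray(hist, dtype=float)
    if hist.shape != (256,):
        raise ValueError(f"reference histogram must have 256 bins, got {hist.shape}")
    if (hist < 0).any():
        raise ValueError("reference histogram has negative bins")
    if hist.sum() <= 0:
        raise ValueError("reference histogram sums to zero")


def crop_to_roi(image: GrayImage, config: PreprocessConfig) -> GrayImage:
    """Extract the configured rectangular region as an exact subarray copy."""
    if config.crop_window is None:
        return replace(image, pixels=image.pixels.copy())
    r0, r1, c0, c1 = config.crop_window
    h, w = image.shape
    if r0 < 0 or c0 < 0:
        raise BoundsError(f"crop start ({r0}, {c0}) is negative")
    if r1 > h:
        raise BoundsError(f"crop row_stop {r1} exceeds image height {h}")
    if c1 > w:
        raise BoundsError(f"crop col_stop {c1} exceeds image width {w}")
    return replace(image, pixels=image.pixels[r0:r1, c0:c1].copy())


def _cdf(hist: np.ndarray) -> np.ndarray:
    hist = np.asarray(hist, dtype=float)
    c = np.cumsum(hist)
    return c / c[-1]


def build_matching_lut(source_hist: np.ndarray, reference_hist: np.ndarray) -> np.ndarray:
    """256-entry lookup table for CDF-inversion histogram matching.

    Level ``v`` maps to the smallest level ``u`` whose reference CDF reaches
    the source CDF at ``v`` (ties broken toward the lower output level).
    The mapping is monotone non-decreasing by construction.
    """
    src_cdf = _cdf(source_hist)
    ref_cdf = _cdf(reference_hist)
    # tolerate floating round-off at the top of the CDF
    lut = np.searchsorted(ref_cdf, src_cdf - 1e-12, side="left")
    return np.clip(lut, 0, 255).astype(np.uint8)


def match_histogram(image: GrayImage, reference_histogram: np.ndarray) -> GrayImage:
    """Remap intensities so the empirical CDF approximates the reference CDF.

    A constant image carries no rank information; it is mapped to the
    reference's median bin and a warning is emitted.
    """
    validate_reference_histogram(reference_histogram)
    hist = image.histogram()
    if np.count_nonzero(hist) < 2:
        warnings.warn(
            "constant input image: mapped to the reference median bin",
            stacklevel=2,
        )
        ref_cdf = _cdf(reference_histogram)
        median_bin = int(np.searchsorted(ref_cdf, 0.5, side="left"))
        return replace(image, pixels=np.full(image.shape, median_bin, dtype=np.uint8))
    lut = build_matching_lut(hist, reference_histogram)
    return replace(image, pixels=lut[image.pixels])


def complement(image: GrayImage) -> GrayImage:
    """Photographic negative: every pixel v becomes 255 - v."""
    return replace(image, pixels=(255 - image.pixels.astype(np.uint8)))
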