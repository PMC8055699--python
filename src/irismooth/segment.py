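"""Binarization of the enhanced scan and extraction of the iris border.

The segmentation route is: deterministic 2-means thresholding on the 256-bin
intensity histogram, morphological cleanup (closing, small-object removal,
small-hole filling), then outer-boundary extraction of the dominant
component(s).  Foreground/border components use 8-connectivity; the
background test defining the outer boundary uses 4-connectivity (the
standard complementary pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .errors import SegmentationError
from .preprocess import GrayImage


@dataclass
class BinaryMask:
    """Boolean raster inheriting the source image's pixel spacing."""

    pixels: np.ndarray
    spacing_y: float = 1.0
    spacing_x: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not (self.spacing_y > 0 and self.spacing_x > 0):
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def spacing(self) -> Tuple[float, float]:
        return (self.spacing_y, self.spacing_x)

    def area(self) -> int:
        return int(self.pixels.sum())


class BorderMask(BinaryMask):
    """A :class:`BinaryMask` whose foreground is a (set of) border curve(s)."""


@dataclass
class SegmentationConfig:
    k: int = 2
    max_iter: int = 100
    tol: float = 0.5
    min_area: int = 50
    closing_radius: int = 2
    #: which intensity cluster is iris tissue; on complemented scans the
    #: iris is the darker of the two clusters.
    foreground: str = "dark"

    def __post_init__(self) -> None:
        if self.k != 2:
            raise ValueError("only k=2 (tissue vs background) is supported")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.min_area < 0 or self.closing_radius < 0:
            raise ValueError("min_area and closing_radius must be >= 0")
        if self.foreground not in ("dark", "bright"):
            raise ValueError("foreground must be 'dark' or 'bright'")


def histogram_two_means(
    hist: np.ndarray,
    init: Tuple[float, float],
    tol: float = 0.5,
    max_iter: int = 100,
) -> Tuple[float, float, int]:
    """Lloyd's algorithm with K=2 on a 256-bin histogram.

    Returns ``(c_low, c_high, cut)`` where bins ``<= cut`` belong to the low
    cluster.  Deterministic: no random initialization.
    """
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(hist.size, dtype=float)
    c0, c1 = sorted(float(c) for c in init)
    if c0 == c1:
        c1 = c0 + 1.0
    for _ in range(max_iter):
        mid = (c0 + c1) / 2.0
        low = levels <= mid
        w_low, w_high = hist[low].sum(), hist[~low].sum()
        n0 = (hist[low] * levels[low]).sum() / w_low if w_low > 0 else c0
        n1 = (hist[~low] * levels[~low]).sum() / w_high if w_high > 0 else c1
        if abs(n0 - c0) < tol and abs(n1 - c1) < tol:
            c0, c1 = n0, n1
            break
        c0, c1 = n0, n1
    cut = int(np.floor((c0 + c1) / 2.0))
    return c0, c1, cut


def adaptive_kmeans_binarize(image: GrayImage, config: SegmentationConfig) -> BinaryMask:
    """Threshold the image by 2-means clustering of its gray-level histogram.

    Centroids are initialized at the 10th and 90th percentile intensities and
    iterated until both move by less than ``config.tol`` gray levels.  The
    returned foreground is the cluster named by ``config.foreground``.
    """
    hist = image.histogram()
    if np.count_nonzero(hist) < 2:
        raise SegmentationError("single gray level, cannot form 2 classes")
    init = (
        float(np.percentile(image.pixels, 10)),
        float(np.percentile(image.pixels, 90)),
    )
    if init[0] == init[1]:
        # heavily skewed histogram: fall back to the extreme occupied bins
        occupied = np.nonzero(hist)[0]
        init = (float(occupied[0]), float(occupied[-1]))
    _, _, cut = histogram_two_means(hist, init, tol=config.tol, max_iter=config.max_iter)
    dark = image.pixels <= cut
    fg = dark if config.foreground == "dark" else ~dark
    return BinaryMask(fg, image.spacing_y, image.spacing_x)


def morphological_clean(mask: BinaryMask, config: SegmentationConfig) -> BinaryMask:
    """Close small gaps, drop tiny components, and fill tiny holes.

    After cleaning every foreground component has area >= ``min_area``.
    Idempotent: a second application is a no-op.
    """
    px = mask.pixels
    if config.closing_radius > 0:
        px = morphology.closing(px, morphology.disk(config.closing_radius))
    if config.min_area > 1:
        # keep components with area >= min_area, fill holes with area < min_area
        px = morphology.remove_small_objects(px, max_size=config.min_area - 1, connectivity=2)
        px = morphology.remove_small_holes(px, max_size=config.min_area - 1)
    if not px.any():
        raise SegmentationError("no iris component survives cleaning")
    return BinaryMask(px, mask.spacing_y, mask.spacing_x)


_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity


def extract_border(mask: BinaryMask, n_components: int = 1) -> BorderMask:
    """Outer boundary of the ``n_components`` largest foreground components.

    A border pixel is a foreground pixel with at least one 4-neighbor in the
    background (pixels beyond the frame count as background).  Components are
    ranked by area, ties broken by topmost-then-leftmost first pixel; only
    the boundaries of the top ``n_components`` are kept.
    """
    labels, n = ndi.label(mask.pixels, structure=ndi.generate_binary_structure(2, 2))
    if n == 0:
        raise SegmentationError("mask has no foreground component")
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    # ndi.label assigns ids in raster-scan order, so a stable sort on -area
    # breaks ties topmost-then-leftmost automatically.
    order = np.argsort(-areas, kind="stable") + 1
    keep = np.isin(labels, order[: max(1, n_components)])
    interior = ndi.binary_erosion(keep, structure=_CROSS, border_value=0)
    return BorderMask(keep & ~interior, mask.spacing_y, mask.spacing_x)
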