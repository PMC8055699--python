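"""Reading and writing of images, masks, configs, and measurement tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from PIL import Image

from .preprocess import GrayImage, PreprocessConfig
from .segment import BinaryMask, SegmentationConfig

# ITU-R 601 luminance weights for RGB inputs
_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(
    path: Union[str, Path],
    spacing: Optional[Tuple[float, float]] = None,
) -> GrayImage:
    """Load PNG/TIFF/JPEG as 8-bit grayscale.

    RGB inputs are reduced with ITU-R 601 luminance weights; higher-depth
    grayscale is linearly rescaled from its dtype range to [0, 255].
    """
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _LUMA
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) * (255.0 / 65535.0)
    elif arr.dtype == bool:
        arr = arr.astype(float) * 255.0
    arr = np.clip(np.asarray(arr, dtype=float), 0, 255)
    sy, sx = spacing if spacing is not None else (1.0, 1.0)
    return GrayImage(arr, spacing_y=sy, spacing_x=sx, provenance=str(path))


def save_image(image: GrayImage, path: Union[str, Path]) -> None:
    Image.fromarray(image.pixels).save(str(path))


def save_mask(mask: BinaryMask, path: Union[str, Path]) -> None:
    """Write a mask as a 0/255 PNG."""
    Image.fromarray(mask.pixels.astype(np.uint8) * 255).save(str(path))


def load_mask(
    path: Union[str, Path], spacing: Optional[Tuple[float, float]] = None
) -> BinaryMask:
    with Image.open(str(path)) as im:
        arr = np.asarray(im.convert("L"))
    sy, sx = spacing if spacing is not None else (1.0, 1.0)
    return BinaryMask(arr > 127, sy, sx)


def load_config(path: Union[str, Path]) -> dict:
    """Read a pipeline config file (JSON) into keyword dictionaries.

    Recognized top-level keys: ``preprocess`` (crop_window, reference —
    either a 256-bin list or a path to a reference image — and
    apply_complement), ``segmentation`` (SegmentationConfig fields),
    ``snap_radius``, ``resample_step``.
    """
    path = Path(path)
    raw = json.loads(path.read_text())
    out: dict = {}
    pre = dict(raw.get("preprocess", {}))
    if "crop_window" in pre and pre["crop_window"] is not None:
        pre["crop_window"] = tuple(int(v) for v in pre["crop_window"])
    ref = pre.get("reference")
    if isinstance(ref, str):
        ref_path = Path(ref)
        if not ref_path.is_absolute():
            ref_path = path.parent / ref_path
        pre["reference"] = load_image(ref_path).histogram()
    elif isinstance(ref, list):
        pre["reference"] = np.asarray(ref, dtype=float)
    out["preprocess"] = PreprocessConfig(**pre)
    out["segmentation"] = SegmentationConfig(**raw.get("segmentation", {}))
    out["snap_radius"] = float(raw.get("snap_radius", 10.0))
    out["resample_step"] = int(raw.get("resample_step", 7))
    return out
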