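"""TIFF and CSV I/O with pixel-size metadata.

Pixel size travels in the TIFF ImageDescription as a small JSON blob and,
redundantly, in the standard X/YResolution tags (pixels per centimeter);
readers accept either, or an explicit override.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .errors import DataError
from .imaging import Image

__all__ = ["read_image", "write_image", "write_mask", "write_labels"]


def write_image(path, img: Image) -> None:
    """Write a float32 TIFF carrying the pixel size in its metadata."""
    px_cm = 1e7 / img.pixel_size_nm  # pixels per centimeter
    desc = json.dumps({"pixel_size_nm": img.pixel_size_nm, "channel": img.channel})
    tifffile.imwrite(
        Path(path),
        img.counts.astype(np.float32),
        description=desc,
        resolution=(px_cm, px_cm),
        resolutionunit="CENTIMETER",
    )


def write_mask(path, mask: np.ndarray, pixel_size_nm: float) -> None:
    """Write a binary mask as 8-bit 0/255 TIFF."""
    img = Image(counts=(mask > 0).astype(np.uint8) * 255, pixel_size_nm=pixel_size_nm)
    write_image(path, img)


def write_labels(path, labels: np.ndarray, pixel_size_nm: float) -> None:
    """Write an integer label image as 16-bit TIFF."""
    px_cm = 1e7 / pixel_size_nm
    desc = json.dumps({"pixel_size_nm": pixel_size_nm, "channel": "labels"})
    tifffile.imwrite(
        Path(path), labels.astype(np.uint16), description=desc,
        resolution=(px_cm, px_cm), resolutionunit="CENTIMETER",
    )


def _pixel_size_from_tags(page) -> Optional[float]:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if num == 0:
        return None
    per_unit = Fraction(int(num), int(den))
    unit = getattr(unit, "value", unit)
    if unit == 3:        # centimeter
        nm_per_unit = 1e7
    elif unit == 2:      # inch
        nm_per_unit = 2.54e7
    else:
        return None
    return float(nm_per_unit / per_unit)


def read_image(
    path, pixel_size_nm: Optional[float] = None, frame: Optional[int] = None
) -> Image:
    """Read a TIFF into an Image, resolving the pixel size from metadata.

    Raises DataError for unreadable files, for multi-frame stacks without a
    ``frame`` selection, and for missing pixel-size metadata without an
    explicit ``pixel_size_nm`` override.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            n_pages = len(tif.pages)
            if n_pages > 1 and frame is None:
                raise DataError(
                    f"{path} has {n_pages} frames; select one with frame="
                )
            page = tif.pages[frame or 0]
            data = page.asarray()
            desc = page.tags.get("ImageDescription")
            meta = {}
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                except (json.JSONDecodeError, TypeError):
                    meta = {}
            px = pixel_size_nm or meta.get("pixel_size_nm") or _pixel_size_from_tags(page)
            channel = meta.get("channel", "")
    except DataError:
        raise
    except Exception as exc:  # tifffile raises several flavours
        raise DataError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 2:
        raise DataError(f"{path}: expected a 2D frame, got shape {data.shape}")
    if px is None:
        raise DataError(
            f"{path} carries no pixel-size metadata; pass pixel_size_nm explicitly"
        )
    return Image(counts=np.asarray(data, dtype=float), pixel_size_nm=float(px),
                 channel=channel)
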