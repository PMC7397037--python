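"""Calibrated 2D confocal images and their file I/O.

A :class:`ConfocalImage` is a single optical section: a non-negative 2D
intensity grid plus the physical pixel size in micrometres.  All downstream
geometry (areas, distances, spot scales) is expressed in µm and converted
via ``pixel_size`` exactly once, at measurement time.

Conventions
-----------
* Image coordinates are (row, col), 0-based, origin at the top-left.
* TIFF files written by this module carry the pixel size twice: as a JSON
  ``ImageDescription`` ``{"pixel_size_um": ...}`` and as an X/Y resolution
  tag in pixels per micrometre.  The reader accepts either, preferring the
  JSON description; an explicit override always wins.
* Masks are single-plane TIFFs with 0 = background, 255 = foreground.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import CalibrationError, UnsupportedFormatError

VALID_CHANNELS = ("granules", "dna")


@dataclass(frozen=True)
class ConfocalImage:
    """A calibrated single-plane fluorescence image.

    Parameters
    ----------
    pixels
        2D array of non-negative intensities (arbitrary fluorescence units).
    pixel_size
        Edge length of one (square) pixel in µm; strictly positive.
    channel
        Which stain the image shows: ``"granules"`` (PNA-FITC) or
        ``"dna"`` (chromatin counterstain).
    """

    pixels: np.ndarray
    pixel_size: float
    channel: str = "granules"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise UnsupportedFormatError(
                f"expected a 2D grid, got {px.ndim} axes with shape {px.shape}"
            )
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise UnsupportedFormatError(
                f"grid must be at least 16 px on each axis, got {px.shape}"
            )
        if np.any(px < 0):
            raise ValueError("intensities must be non-negative")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise CalibrationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"channel must be one of {VALID_CHANNELS}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size**2

    @property
    def field_area_um2(self) -> float:
        return self.pixels.size * self.pixel_size**2


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    page = tf.pages[0]
    desc = page.tags.get("ImageDescription")
    if desc is not None:
        try:
            meta = json.loads(desc.value)
            if isinstance(meta, dict) and "pixel_size_um" in meta:
                return float(meta["pixel_size_um"])
        except (ValueError, TypeError):
            pass
    xres = page.tags.get("XResolution")
    if xres is not None:
        num, den = xres.value
        # resolution tag read as pixels per micrometre; (1, 1) is the
        # writer default for uncalibrated files, not a real calibration
        if num and (num, den) != (1, 1):
            return float(den) / float(num)
    return None


def read_image(
    path: str | Path,
    pixel_size_override: float | None = None,
    channel: str = "granules",
) -> ConfocalImage:
    """Read a single-plane grayscale TIFF or PNG as a :class:`ConfocalImage`.

    Integer pixel data are preserved losslessly.  The pixel size comes from
    file metadata unless ``pixel_size_override`` is given, which always
    takes precedence.

    Raises
    ------
    UnsupportedFormatError
        For multi-plane or multi-channel (RGB) input, naming the axis.
    CalibrationError
        If no pixel size is available from metadata or override.
    """
    path = Path(path)
    meta_ps: float | None = None
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            if len(tf.pages) > 1:
                raise UnsupportedFormatError(
                    f"{path.name}: multi-plane TIFF ({len(tf.pages)} pages along the plane axis)"
                )
            arr = tf.pages[0].asarray()
            meta_ps = _pixel_size_from_tiff(tf)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        raise UnsupportedFormatError(
            f"{path.name}: expected single-channel data, got {arr.shape[-1]} "
            "samples along the channel axis"
        )
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{path.name}: expected 2 axes, got {arr.ndim}")
    pixel_size = pixel_size_override if pixel_size_override is not None else meta_ps
    if pixel_size is None:
        raise CalibrationError(
            f"{path.name}: no pixel size in metadata and no override given"
        )
    return ConfocalImage(pixels=arr, pixel_size=float(pixel_size), channel=channel)


def write_image(image: ConfocalImage, path: str | Path) -> None:
    """Write a :class:`ConfocalImage` to TIFF with its calibration embedded."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ps = image.pixel_size
    tifffile.imwrite(
        path,
        image.pixels,
        description=json.dumps({"pixel_size_um": ps, "channel": image.channel}),
        resolution=(1.0 / ps, 1.0 / ps),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a 0/255 single-plane TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def read_mask_array(path: str | Path) -> np.ndarray:
    """Read a 0/255 TIFF mask back as a boolean array."""
    arr = tifffile.imread(Path(path))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"mask must be single-plane, got {arr.ndim} axes")
    return arr > 0
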