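"""Radiograph container and image I/O.

All pipeline stages operate on :class:`RadiographImage`, a thin wrapper
around a 2-D float array of 8-bit-scale intensities (0-255). Color inputs
are collapsed to luminance on load; 16-bit inputs are rescaled linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

__all__ = ["RadiographImage", "load_image", "save_image"]

# ITU-R 601 luminance weights for RGB -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class RadiographImage:
    """A single-channel radiograph with intensities on the 0-255 scale.

    Parameters
    ----------
    pixels
        2-D float64 array, values in [0, 255].
    label
        Optional class tag, ``"cancerous"`` or ``"healthy"``.
    source_id
        Identifier of the originating file or generator seed.
    offset
        (row, col) of this image's origin within its parent image, if it
        was produced by cropping; (0, 0) otherwise.
    """

    pixels: np.ndarray
    label: Optional[str] = None
    source_id: str = ""
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D intensity matrix, got ndim={px.ndim}")
        if px.size == 0:
            raise ValueError("zero-area image")
        if px.min() < 0 or px.max() > 255:
            raise ValueError(
                f"intensities must lie in [0, 255]; got range "
                f"[{px.min():g}, {px.max():g}]"
            )
        if self.label is not None and self.label not in ("cancerous", "healthy"):
            raise ValueError(f"unknown label {self.label!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "RadiographImage":
        """Return a copy carrying the same metadata but new pixel data."""
        return replace(self, pixels=pixels)


def as_image(obj) -> RadiographImage:
    """Coerce a bare array into a RadiographImage; pass images through."""
    if isinstance(obj, RadiographImage):
        return obj
    return RadiographImage(pixels=np.asarray(obj, dtype=np.float64))


def load_image(path: str | Path) -> RadiographImage:
    """Read a PNG/TIFF/JPEG radiograph as a single-channel 0-255 image.

    RGB(A) inputs are converted with ITU-R 601 luminance weights; images
    stored with more than 8 bits per sample are rescaled linearly so the
    dtype maximum maps to 255.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise OSError(f"could not read image file {path}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"zero-area image: {path}")
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[..., :3] @ _LUMA
        else:  # single-channel stored with an explicit axis
            arr = arr[..., 0]
    arr = arr.astype(np.float64)
    if np.issubdtype(raw.dtype, np.integer) and raw.dtype.itemsize > 1:
        arr = arr * (255.0 / np.iinfo(raw.dtype).max)
    arr = np.clip(arr, 0.0, 255.0)
    return RadiographImage(pixels=arr, source_id=str(path))


def save_image(img: RadiographImage, path: str | Path) -> None:
    """Write an image as 8-bit grayscale (rounded to nearest integer)."""
    data = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)
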