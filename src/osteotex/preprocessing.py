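"""Denoising and sharpening of input radiographs.

X-ray images collected from heterogeneous sources carry impulse noise;
a 3x3 median filter removes it. Median filtering also blurs fine
structure, so an unsharp mask restores edge contrast afterwards.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import PreprocessConfig
from .image import RadiographImage

__all__ = ["median_filter_3x3", "sharpen", "preprocess"]


def median_filter_3x3(img: RadiographImage) -> RadiographImage:
    """Replace each pixel by the median of its 3x3 neighborhood.

    Borders are handled by edge replication, so the output has the same
    shape as the input. Requires at least a 3x3 image.
    """
    if img.height < 3 or img.width < 3:
        raise ValueError(
            f"median filter needs an image of at least 3x3, got {img.shape}"
        )
    out = ndimage.median_filter(img.pixels, size=3, mode="nearest")
    return img.with_pixels(out)


def sharpen(
    img: RadiographImage, amount: float = 1.0, sigma: float = 1.0
) -> RadiographImage:
    """Unsharp masking: ``out = clip(img + amount * (img - blur(img)))``.

    ``amount`` scales the high-frequency residual (0 leaves the image
    untouched); ``sigma`` is the Gaussian blur scale in pixels. Output is
    clipped back to [0, 255].
    """
    if amount < 0:
        raise ValueError(f"sharpen amount must be non-negative, got {amount}")
    if amount == 0:
        return img
    blurred = ndimage.gaussian_filter(img.pixels, sigma=sigma, mode="nearest")
    out = np.clip(img.pixels + amount * (img.pixels - blurred), 0.0, 255.0)
    return img.with_pixels(out)


def preprocess(
    img: RadiographImage, config: PreprocessConfig | None = None
) -> RadiographImage:
    """Run the configured denoise + sharpen chain."""
    cfg = config or PreprocessConfig()
    out = img
    if cfg.median_filter:
        out = median_filter_3x3(out)
    if cfg.sharpen:
        out = sharpen(out, amount=cfg.sharpen_amount, sigma=cfg.sharpen_sigma)
    return out
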