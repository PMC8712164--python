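"""First-order intensity statistics.

Variance and standard deviation use the population form (divide by n).
Skewness is the histogram-weighted third central moment normalized by
``(N - 1) * sigma^3``, which keeps it scale-free.

Shannon entropy follows the pipeline's reference protocol: the image is
resized to 70x70 pixels (bilinear, rounded back to integers) and rotated
by 35 degrees (nearest-neighbor, zero fill) before the gray-level
histogram is formed; pixels introduced by rotation padding are excluded
so no artificial gray level enters the histogram. The protocol can be
disabled in config, in which case the raw pixels are histogrammed — that
mode has closed-form answers and is what the unit tests exercise.

The entropy-derived features are ``D(X) = E(X) * sigma`` (entropy
weighted by the spread of the same pixel set) and the trained feature
``E(X) * D(X) = E(X)^2 * sigma``.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import transform

from .config import EntropyConfig
from .image import RadiographImage

__all__ = [
    "variance",
    "std",
    "skewness",
    "shannon_entropy",
    "weighted_entropy",
    "entropy_product",
    "intensity_features",
]


def _pixels(img: RadiographImage | np.ndarray) -> np.ndarray:
    if isinstance(img, RadiographImage):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def variance(img: RadiographImage | np.ndarray) -> float:
    """Population variance ``(1/n) sum (X_i - mu)^2`` of all pixels."""
    x = _pixels(img)
    if x.size == 0:
        raise ValueError("empty image")
    return float(np.var(x))


def std(img: RadiographImage | np.ndarray) -> float:
    """Population standard deviation (square root of :func:`variance`)."""
    return float(np.sqrt(variance(img)))


def skewness(
    img: RadiographImage | np.ndarray, denominator: str = "n_minus_1"
) -> float:
    """Asymmetry of the gray-level distribution.

    ``sum_s (GL_s - mu)^3 * count_s / ((N - 1) * sigma^3)`` over the
    gray-level histogram, with sigma the population std. A constant image
    has no skew and returns 0 with a warning. ``denominator`` selects the
    alternative reading ``(N - 1)^3 * sigma^3`` for comparison.
    """
    x = _pixels(img).ravel()
    n = x.size
    if n == 0:
        raise ValueError("empty image")
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        warnings.warn("constant image has undefined skewness; returning 0",
                      stacklevel=2)
        return 0.0
    third = float(((x - mu) ** 3).sum())
    if denominator == "n_minus_1":
        denom = (n - 1) * sigma**3
    elif denominator == "n_minus_1_cubed":
        denom = (n - 1) ** 3 * sigma**3
    else:
        raise ValueError(f"unknown skewness denominator mode {denominator!r}")
    return third / denom


def entropy_pixel_set(
    img: RadiographImage | np.ndarray, config: EntropyConfig | None = None
) -> np.ndarray:
    """The 1-D pixel sample the entropy features are computed over.

    With the protocol enabled this is the resized + rotated image with
    rotation-padding pixels masked out; otherwise the raw pixels.
    """
    cfg = config or EntropyConfig()
    x = _pixels(img)
    if x.size == 0:
        raise ValueError("empty image")
    if not cfg.enabled_protocol:
        return x.ravel()
    resized = transform.resize(
        x, cfg.resize_to, order=1, preserve_range=True, anti_aliasing=False
    )
    resized = np.rint(resized)
    rotated = transform.rotate(
        resized, cfg.rotate_deg, order=0, preserve_range=True, cval=0.0
    )
    valid = transform.rotate(
        np.ones_like(resized), cfg.rotate_deg, order=0, preserve_range=True, cval=0.0
    )
    return rotated[valid > 0.5]


def shannon_entropy(
    img: RadiographImage | np.ndarray, config: EntropyConfig | None = None
) -> float:
    """``E(X) = -sum_y p(y) log2 p(y)`` over the gray values present,
    with ``p(y)`` the frequency of value ``y`` in the protocol pixel set."""
    x = entropy_pixel_set(img, config)
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def weighted_entropy(
    img: RadiographImage | np.ndarray, config: EntropyConfig | None = None
) -> float:
    """``D(X) = E(X) * sigma``, sigma taken over the same pixel set as E(X)."""
    x = entropy_pixel_set(img, config)
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    e = float(-(p * np.log2(p)).sum())
    return e * float(x.std())


def entropy_product(
    img: RadiographImage | np.ndarray, config: EntropyConfig | None = None
) -> float:
    """The trained scalar ``E(X) * D(X) = E(X)^2 * sigma``."""
    x = entropy_pixel_set(img, config)
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    e = float(-(p * np.log2(p)).sum())
    return e * e * float(x.std())


def intensity_features(
    img: RadiographImage | np.ndarray,
    config: EntropyConfig | None = None,
    skewness_denominator: str = "n_minus_1",
) -> dict[str, float]:
    """Skewness, entropy and the entropy product of one image."""
    x = entropy_pixel_set(img, config)
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    e = float(-(p * np.log2(p)).sum())
    sigma = float(x.std())
    return {
        "skewness": skewness(img, denominator=skewness_denominator),
        "entropy": e,
        "entropy_product": e * e * sigma,
    }
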