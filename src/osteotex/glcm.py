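"""Gray-level co-occurrence matrix and its four Haralick features.

The GLCM entry ``A[i, j]`` is the probability that quantized gray levels
``i`` and ``j`` co-occur at a fixed pixel offset. Four scalar statistics
summarize it:

- contrast      ``sum (i-j)^2 A_ij``       — local intensity variation
- correlation   ``sum (i-mu_i)(j-mu_j) A_ij / (sigma_i sigma_j)``
- energy        ``sum A_ij^2``             — angular second moment
- homogeneity   ``sum A_ij / (1 + |i-j|)`` — inverse difference

Defaults follow common Haralick practice: 64 gray levels by uniform
binning of [0, 255], unit distance, the four offsets 0/45/90/135 degrees
accumulated into one symmetric, normalized matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage.feature import graycomatrix

from .config import GLCMConfig
from .image import RadiographImage

__all__ = [
    "GLCMMatrix",
    "compute_glcm",
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
    "glcm_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GLCMMatrix:
    """Normalized co-occurrence matrix with its quantization metadata."""

    A: np.ndarray
    levels: int
    distance: int
    angles_deg: Tuple[float, ...]
    symmetric: bool

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=np.float64)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("GLCM must be a square matrix")
        if A.min() < 0:
            raise ValueError("GLCM entries must be non-negative")
        if not np.isclose(A.sum(), 1.0):
            raise ValueError(f"GLCM must be normalized to sum 1, got {A.sum():g}")
        object.__setattr__(self, "A", A)


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin [0, 255] intensities into ``levels`` integer levels."""
    q = np.floor(np.asarray(pixels, dtype=np.float64) * levels / 256.0)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def compute_glcm(
    img: RadiographImage, config: GLCMConfig | None = None
) -> GLCMMatrix:
    """Accumulate co-occurrence counts over the configured offsets and
    normalize to a probability matrix."""
    cfg = config or GLCMConfig()
    if cfg.levels < 2:
        raise ValueError(f"need at least 2 gray levels, got {cfg.levels}")
    if cfg.distance < 1:
        raise ValueError(f"distance must be >= 1, got {cfg.distance}")
    if min(img.shape) <= cfg.distance:
        raise ValueError(
            f"image {img.shape} too small for co-occurrence distance {cfg.distance}"
        )
    q = quantize(img.pixels, cfg.levels)
    angles = np.deg2rad(cfg.angles_deg)
    counts = graycomatrix(
        q,
        distances=[cfg.distance],
        angles=angles,
        levels=cfg.levels,
        symmetric=cfg.symmetric,
        normed=False,
    )[:, :, 0, :].astype(np.float64)
    total = counts.sum(axis=2)  # accumulate over the angle set
    if total.sum() == 0:
        raise ValueError("no co-occurring pixel pairs at the requested offsets")
    A = total / total.sum()
    return GLCMMatrix(
        A=A,
        levels=cfg.levels,
        distance=cfg.distance,
        angles_deg=tuple(cfg.angles_deg),
        symmetric=cfg.symmetric,
    )


def _index_grids(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = A.shape[0]
    return np.meshgrid(np.arange(n), np.arange(n), indexing="ij")


def contrast(glcm: GLCMMatrix) -> float:
    i, j = _index_grids(glcm.A)
    return float(((i - j) ** 2 * glcm.A).sum())


def correlation(glcm: GLCMMatrix) -> float:
    """GLCM correlation in [-1, 1]; defined as 0 (with a warning) when a
    marginal variance vanishes, e.g. for a constant image."""
    A = glcm.A
    i, j = _index_grids(A)
    pi = A.sum(axis=1)
    pj = A.sum(axis=0)
    idx = np.arange(A.shape[0])
    mu_i = float(idx @ pi)
    mu_j = float(idx @ pj)
    var_i = float(((idx - mu_i) ** 2) @ pi)
    var_j = float(((idx - mu_j) ** 2) @ pj)
    if var_i <= 0 or var_j <= 0:
        warnings.warn(
            "GLCM marginal variance is zero (constant image); "
            "correlation defined as 0",
            stacklevel=2,
        )
        return 0.0
    cov = float(((i - mu_i) * (j - mu_j) * A).sum())
    return cov / np.sqrt(var_i * var_j)


def energy(glcm: GLCMMatrix) -> float:
    return float((glcm.A**2).sum())


def homogeneity(glcm: GLCMMatrix) -> float:
    i, j = _index_grids(glcm.A)
    return float((glcm.A / (1.0 + np.abs(i - j))).sum())


def glcm_features(
    img: RadiographImage, config: GLCMConfig | None = None
) -> dict[str, float]:
    """Convenience: the four Haralick features of one image."""
    g = compute_glcm(img, config)
    return {
        "contrast": contrast(g),
        "correlation": correlation(g),
        "energy": energy(g),
        "homogeneity": homogeneity(g),
    }
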