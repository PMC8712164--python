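"""Edge detection and region-of-interest extraction.

The bone outline is found with the Canny detector (Sobel and Prewitt
magnitudes are available for comparison), and the region of interest is
the tight bounding box of the largest 8-connected edge component —
typically the shaft outline in a long-bone radiograph.

Coordinate convention, repo-wide: 0-based row-major indices, boxes as
half-open intervals ``[min, max)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage import feature, filters

from .config import EdgeConfig
from .image import RadiographImage

__all__ = ["EdgeMap", "ROIBox", "NoROIError", "detect_edges", "extract_roi", "crop"]

logger = logging.getLogger(__name__)

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class EdgeMap:
    """Boolean edge mask plus a record of how it was produced."""

    mask: np.ndarray
    detector: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("edge mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def n_edge_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ROIBox:
    """Half-open pixel box ``rows [row_min, row_max), cols [col_min, col_max)``."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_min < self.row_max and 0 <= self.col_min < self.col_max):
            raise ValueError(f"degenerate ROI box {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min, self.col_max - self.col_min)


class NoROIError(ValueError):
    """Raised when an edge map has no edge pixels; callers should fall
    back to the full image."""


def detect_edges(
    img: RadiographImage,
    method: str = "canny",
    config: EdgeConfig | None = None,
) -> EdgeMap:
    """Compute a boolean edge mask.

    Canny uses Gaussian smoothing at ``sigma`` with hysteresis thresholds
    expressed as fractions of the smoothed gradient-magnitude maximum.
    Sobel and Prewitt threshold their gradient magnitude at ``threshold``
    times its maximum.
    """
    cfg = config or EdgeConfig()
    pixels = img.pixels / 255.0  # detectors operate on [0, 1] floats

    if method == "canny":
        if cfg.sigma <= 0:
            raise ValueError("canny sigma must be positive")
        if not (0 <= cfg.low < cfg.high <= 1):
            raise ValueError(
                f"hysteresis fractions must satisfy 0 <= low < high <= 1, "
                f"got low={cfg.low}, high={cfg.high}"
            )
        smoothed = ndimage.gaussian_filter(pixels, sigma=cfg.sigma, mode="nearest")
        gmax = float(filters.sobel(smoothed).max())
        mask = feature.canny(
            pixels,
            sigma=cfg.sigma,
            low_threshold=cfg.low * gmax,
            high_threshold=cfg.high * gmax,
        )
        params = {"sigma": cfg.sigma, "low": cfg.low, "high": cfg.high}
    elif method in ("sobel", "prewitt"):
        grad = filters.sobel(pixels) if method == "sobel" else filters.prewitt(pixels)
        gmax = float(grad.max())
        # flat images leave only float rounding noise in the gradient
        if gmax > 1e-9:
            mask = grad > cfg.threshold * gmax
        else:
            mask = np.zeros_like(grad, dtype=bool)
        params = {"threshold": cfg.threshold}
    else:
        raise ValueError(f"unknown edge detector {method!r}")

    return EdgeMap(mask=mask, detector=method, params=params)


def extract_roi(edges: EdgeMap) -> ROIBox:
    """Bounding box of the largest 8-connected edge component.

    Ties on component size are broken by the smallest ``(row_min,
    col_min)`` corner. Raises :class:`NoROIError` on an empty mask.
    """
    if not edges.mask.any():
        raise NoROIError(
            "edge map contains no edge pixels; fall back to the full image"
        )
    labels, n = ndimage.label(edges.mask, structure=_EIGHT_CONN)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best_size = sizes.max()
    slices = ndimage.find_objects(labels)
    candidates = [
        (sl[0].start, sl[1].start, sl)
        for lab, sl in enumerate(slices, start=1)
        if sizes[lab - 1] == best_size
    ]
    _, _, sl = min(candidates)
    return ROIBox(
        row_min=sl[0].start, row_max=sl[0].stop,
        col_min=sl[1].start, col_max=sl[1].stop,
    )


def crop(img: RadiographImage, box: ROIBox) -> RadiographImage:
    """Extract the sub-image inside ``box``; the offset is recorded in
    the result's metadata."""
    if box.row_max > img.height or box.col_max > img.width:
        raise ValueError(f"box {box} exceeds image bounds {img.shape}")
    sub = img.pixels[box.row_min : box.row_max, box.col_min : box.col_max]
    return RadiographImage(
        pixels=sub.copy(),
        label=img.label,
        source_id=img.source_id,
        offset=(img.offset[0] + box.row_min, img.offset[1] + box.col_min),
    )
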