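"""Histogram-of-oriented-gradients descriptor.

Small fixed geometry tuned for low-resolution bone crops: the input is
resized to 25x25 pixels, gradients are taken by centered differences,
unsigned orientations (0-180 degrees) are binned into 6 bins with
magnitude-weighted linear interpolation between adjacent bins, and
histograms are formed over 3x3-pixel cells. 25 is not divisible by 3, so
the final partial pixel row/column is dropped, leaving an 8x8 cell grid
and a descriptor of length 8 * 8 * 6 = 384. Each cell histogram is L2
normalized independently (no multi-cell blocks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform

from .config import HOGConfig
from .image import RadiographImage

__all__ = ["HOGDescriptor", "compute_hog", "hog_summary"]

_EPS = 1e-6


@dataclass(frozen=True)
class HOGDescriptor:
    vector: np.ndarray
    cells: tuple[int, int]
    bins: int
    cell_size: int

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=np.float64)
        expected = self.cells[0] * self.cells[1] * self.bins
        if v.size != expected:
            raise ValueError(
                f"descriptor length {v.size} != cells x bins = {expected}"
            )
        object.__setattr__(self, "vector", v)


def compute_hog(
    img: RadiographImage | np.ndarray, config: HOGConfig | None = None
) -> HOGDescriptor:
    """Compute the descriptor of one image (any input size)."""
    cfg = config or HOGConfig()
    pixels = img.pixels if isinstance(img, RadiographImage) else np.asarray(img, float)
    if pixels.size == 0:
        raise ValueError("empty image")
    resized = transform.resize(
        pixels, cfg.resize_to, order=1, preserve_range=True, anti_aliasing=False
    )

    gy, gx = np.gradient(resized)  # centered differences in the interior
    mag = np.hypot(gx, gy)
    ang = np.mod(np.rad2deg(np.arctan2(gy, gx)), 180.0)  # unsigned orientation

    bin_width = 180.0 / cfg.bins
    # fractional bin position; bin centers at (k + 0.5) * width
    pos = ang / bin_width - 0.5
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    lo_bin = np.mod(lo, cfg.bins)
    hi_bin = np.mod(lo + 1, cfg.bins)
    w_lo = mag * (1.0 - frac)
    w_hi = mag * frac

    n_rows = cfg.resize_to[0] // cfg.cell_size
    n_cols = cfg.resize_to[1] // cfg.cell_size
    cs = cfg.cell_size
    out = np.empty((n_rows, n_cols, cfg.bins))
    for r in range(n_rows):
        for c in range(n_cols):
            sl = np.s_[r * cs : (r + 1) * cs, c * cs : (c + 1) * cs]
            hist = np.bincount(
                lo_bin[sl].ravel(), weights=w_lo[sl].ravel(), minlength=cfg.bins
            )
            hist += np.bincount(
                hi_bin[sl].ravel(), weights=w_hi[sl].ravel(), minlength=cfg.bins
            )
            out[r, c] = hist / np.sqrt((hist**2).sum() + _EPS**2)

    return HOGDescriptor(
        vector=out.reshape(-1),
        cells=(n_rows, n_cols),
        bins=cfg.bins,
        cell_size=cs,
    )


def hog_summary(desc: HOGDescriptor) -> float:
    """Mean of the descriptor entries — the per-image scalar used for
    distribution summaries (classification uses the full vector)."""
    return float(desc.vector.mean())
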