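"""Hough line accumulator and the Gini inequality index of its votes.

Long straight structures (a healthy bone shaft outline) concentrate
Hough votes into few accumulator cells; scattered, irregular edges
spread them out. Treating the accumulator counts as "incomes", the Gini
index scores that concentration: 0 for perfectly equal counts, towards
1 when a single cell holds all the votes.

For values sorted ascending, ``GI = 2 sum_i i * X_(i) / (n sum X) -
(n + 1) / n``, equivalent to the mean-absolute-difference form
``sum_{i,j} |x_i - x_j| / (2 n sum x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import HoughConfig
from .segmentation import EdgeMap

__all__ = ["HoughAccumulator", "hough_accumulate", "gini_index", "hough_gini_feature"]


@dataclass(frozen=True)
class HoughAccumulator:
    """Vote counts indexed by (rho bin, theta bin); thetas span [-90, 90)."""

    counts: np.ndarray
    rho_resolution: float
    theta_bins: int

    @property
    def total_votes(self) -> int:
        return int(self.counts.sum())


def hough_accumulate(
    edges: EdgeMap, theta_bins: int = 180, rho_resolution: float = 1.0
) -> HoughAccumulator:
    """Standard line Hough transform of a boolean edge mask.

    Every edge pixel ``(x, y)`` casts one vote per theta bin at
    ``rho = x cos(theta) + y sin(theta)``, binned at ``rho_resolution``
    pixels. Theta bins uniformly cover [-90, 90) degrees.
    """
    if theta_bins < 2:
        raise ValueError(f"need at least 2 theta bins, got {theta_bins}")
    if rho_resolution <= 0:
        raise ValueError("rho resolution must be positive")
    rows, cols = np.nonzero(edges.mask)
    if rows.size == 0:
        raise ValueError("empty edge mask: Hough accumulator undefined")
    thetas = np.deg2rad(np.linspace(-90.0, 90.0, theta_bins, endpoint=False))
    x = cols[:, None].astype(np.float64)  # x = column, y = row
    y = rows[:, None].astype(np.float64)
    rho = x * np.cos(thetas)[None, :] + y * np.sin(thetas)[None, :]
    h, w = edges.mask.shape
    max_rho = float(np.hypot(h, w))
    half = int(np.ceil(max_rho / rho_resolution))
    idx = np.rint(rho / rho_resolution).astype(np.int64) + half
    n_rho = 2 * half + 1
    flat = idx * theta_bins + np.arange(theta_bins)[None, :]
    counts = np.bincount(flat.ravel(), minlength=n_rho * theta_bins)
    counts = counts.reshape(n_rho, theta_bins)
    return HoughAccumulator(
        counts=counts, rho_resolution=rho_resolution, theta_bins=theta_bins
    )


def gini_index(values) -> float:
    """Gini inequality index of a non-negative sequence.

    Result lies in ``[0, (n-1)/n]``: 0 for equal values, the upper bound
    for a one-hot vector. Requires at least one strictly positive entry.
    """
    x = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty value sequence")
    if x[0] < 0:
        raise ValueError("Gini index requires non-negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero value sequence: Gini index undefined")
    i = np.arange(1, n + 1)
    return float(2.0 * (i @ x) / (n * total) - (n + 1) / n)


def hough_gini_feature(
    edges: EdgeMap, config: HoughConfig | None = None
) -> float:
    """Gini index of the Hough accumulator of an edge map.

    By default the full flattened accumulator (zero-vote cells included —
    they are legitimate zero incomes) is scored; config offers excluding
    zeros or averaging per-theta-column Gini values instead.
    """
    cfg = config or HoughConfig()
    acc = hough_accumulate(
        edges, theta_bins=cfg.theta_bins, rho_resolution=cfg.rho_resolution
    )
    counts = acc.counts.astype(np.float64)
    if cfg.gini_per_column:
        ginis = []
        for col in counts.T:
            vals = col if cfg.gini_include_zeros else col[col > 0]
            if vals.sum() > 0:
                ginis.append(gini_index(vals))
        return float(np.mean(ginis))
    vals = counts.ravel()
    if not cfg.gini_include_zeros:
        vals = vals[vals > 0]
    return gini_index(vals)
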