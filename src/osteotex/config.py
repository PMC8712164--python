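"""Pipeline configuration.

Every tunable of the feature pipeline lives here so a run is fully
described by one object. Defaults reproduce the pipeline's reference
protocol: 3x3 median filter + unsharp mask, Canny edges, ROI crop,
64-level symmetric GLCM averaged over four offsets, the 70x70/35-degree
entropy protocol, a 180-bin Hough accumulator, and a 25x25/3px-cell/6-bin
HOG descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

__all__ = [
    "PreprocessConfig",
    "EdgeConfig",
    "GLCMConfig",
    "EntropyConfig",
    "HoughConfig",
    "HOGConfig",
    "PipelineConfig",
]


@dataclass(frozen=True)
class PreprocessConfig:
    median_filter: bool = True
    sharpen: bool = True
    sharpen_amount: float = 1.0
    sharpen_sigma: float = 1.0


@dataclass(frozen=True)
class EdgeConfig:
    method: str = "canny"  # canny | sobel | prewitt
    sigma: float = 1.0  # Gaussian smoothing for Canny
    low: float = 0.1  # hysteresis low, fraction of gradient max
    high: float = 0.2  # hysteresis high, fraction of gradient max
    threshold: float = 0.25  # Sobel/Prewitt cutoff, fraction of gradient max


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 64
    distance: int = 1
    angles_deg: Tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True


@dataclass(frozen=True)
class EntropyConfig:
    # The reference protocol resizes to 70x70 then rotates 35 degrees
    # before histogramming; disable for closed-form unit checks.
    enabled_protocol: bool = True
    resize_to: Tuple[int, int] = (70, 70)
    rotate_deg: float = 35.0


@dataclass(frozen=True)
class HoughConfig:
    theta_bins: int = 180
    rho_resolution: float = 1.0
    gini_include_zeros: bool = True
    gini_per_column: bool = False  # mean of per-theta-column Gini instead


@dataclass(frozen=True)
class HOGConfig:
    resize_to: Tuple[int, int] = (25, 25)
    cell_size: int = 3
    bins: int = 6


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all stage configurations plus pipeline-level switches."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    edges: EdgeConfig = field(default_factory=EdgeConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    hough: HoughConfig = field(default_factory=HoughConfig)
    hog: HOGConfig = field(default_factory=HOGConfig)
    use_roi: bool = True  # crop to the largest edge component's bbox
    skewness_denominator: str = "n_minus_1"  # or "n_minus_1_cubed"
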