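"""Synthetic bone-phantom generator.

Real bone radiographs are not redistributable, so the pipeline is
validated on phantoms that reproduce the statistical contrasts between
classes rather than anatomy: a healthy phantom is a smooth, bright
vertical shaft with mild regular trabecular banding over a dark
background plus Gaussian sensor noise; a cancerous phantom carries an
elliptical lesion with a ragged (radially perturbed) boundary whose
interior is drawn from a handful of widely spaced gray levels — pixel
intensities scattered over a wide range (high variance) yet concentrated
on few distinct values (low entropy) — with light speckle on top.

Consequences measurable downstream, in aggregate: lesion regions have
lower Shannon entropy than the same region of a healthy phantom, and
cancerous phantoms have lower intensity skewness than healthy ones.
No direction is built in for the Hough-Gini feature.

Every phantom is a pure function of its spec (including the seed):
identical spec -> bit-identical image.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import RadiographImage

__all__ = ["PhantomSpec", "generate_phantom", "generate_phantom_with_region",
           "generate_dataset", "effect_size_overrides"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom; intensities on the 0-255 scale.

    ``lesion_gray_levels`` controls in-lesion entropy (fewer levels =
    lower entropy); ``lesion_depth`` sets how far below the bone level
    the darkest lesion gray level reaches; ``lesion_raggedness`` in
    [0, 1] scales the radial perturbation of the lesion boundary.
    """

    label: str = "healthy"
    image_size: tuple[int, int] = (256, 256)
    shaft_width: int = 96
    background_level: float = 110.0
    bone_level: float = 185.0
    trabecular_amp: float = 24.0
    trabecular_period: float = 30.0
    trabecular_texture_sd: float = 10.0
    lesion_raggedness: float = 0.45
    lesion_speckle_sd: float = 2.0
    lesion_gray_levels: int = 4
    lesion_depth: float = 170.0
    canal_depth: float = 45.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("cancerous", "healthy"):
            raise ValueError(f"unknown label {self.label!r}")
        if not (0 <= self.lesion_raggedness <= 1):
            raise ValueError("lesion_raggedness must lie in [0, 1]")
        for name in ("background_level", "bone_level"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.lesion_gray_levels < 1:
            raise ValueError("need at least one lesion gray level")
        if min(self.image_size) < 32:
            raise ValueError("phantoms smaller than 32x32 are not supported")


def _ragged_ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    raggedness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ellipse whose radius is perturbed by smooth random harmonics."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = (rr - center[0]) / semi_axes[0]
    dc = (cc - center[1]) / semi_axes[1]
    rho = np.hypot(dr, dc)
    phi = np.arctan2(dr, dc)
    pert = np.zeros_like(phi)
    for k in range(2, 6):  # low harmonics: lobed, ragged outline
        a, b = rng.normal(0.0, 1.0 / k, size=2)
        pert += a * np.cos(k * phi) + b * np.sin(k * phi)
    return rho < 1.0 + 0.4 * raggedness * pert


def generate_phantom(spec: PhantomSpec) -> RadiographImage:
    """Render one phantom radiograph from its spec."""
    return generate_phantom_with_region(spec)[0]


def generate_phantom_with_region(
    spec: PhantomSpec,
) -> tuple[RadiographImage, np.ndarray]:
    """Render a phantom plus its (potential) lesion-region mask.

    The region mask is defined for healthy phantoms too — it marks where
    the lesion *would* be for the same seed — which gives matched
    region-level controls for class-contrast studies.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    img = np.full((h, w), spec.background_level, dtype=np.float64)

    # Per-image nuisance variation so the two classes overlap in feature
    # space instead of separating trivially.
    bone = spec.bone_level + rng.uniform(-15.0, 15.0)
    width = int(round(spec.shaft_width * rng.uniform(0.85, 1.15)))
    width = min(width, w - 16)
    cc_shaft = w / 2 + rng.integers(-6, 7)
    cr_shaft = h / 2 + rng.integers(-4, 5)
    half_len = 0.42 * h * rng.uniform(0.92, 1.05)
    phase = rng.uniform(0, 2 * np.pi)
    # exposure/texture gain differs between acquisitions; raw intensity
    # statistics are sensitive to it, normalized gradient histograms not
    tex_gain = rng.uniform(0.7, 1.4)
    amp = spec.trabecular_amp * tex_gain * rng.uniform(0.8, 1.2)
    tex_sd = spec.trabecular_texture_sd * tex_gain
    noise_sd = spec.noise_sd * rng.uniform(0.7, 1.5)

    # Finite long bone: a rounded superellipse fully inside the frame, so
    # its edge contour closes into a single connected component and its
    # bounding box contains little background.
    rr, cc = np.mgrid[0:h, 0:w]
    s = (np.abs((rr - cr_shaft) / half_len) ** 8
         + np.abs((cc - cc_shaft) / (width / 2)) ** 8)
    bone_mask = s < 1.0
    # trabecular structure: regular banding along the shaft plus a smooth
    # random field, giving the healthy interior a rich gray-level spread
    banding = amp * np.sin(2 * np.pi * rr / spec.trabecular_period + phase)
    field = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=3.0)
    field *= tex_sd / max(field.std(), 1e-12)
    img[bone_mask] = bone + banding[bone_mask] + field[bone_mask]
    # brighter cortical shell near the bone boundary
    cortex = bone_mask & (s > 0.55)
    img[cortex] += 25.0

    # medullary canal: a dark, smooth, straight band along the shaft
    # axis, present in every bone. It overlaps the lesion's intensity
    # range, so first-order statistics of the two classes overlap; only
    # its straight, smooth outline distinguishes it from a lesion.
    canal_hw = 0.30 * (width / 2) * rng.uniform(0.7, 1.4)
    canal_depth = spec.canal_depth * rng.uniform(0.7, 1.3)
    t = ((cc - cc_shaft) / canal_hw) ** 2 + np.abs((rr - cr_shaft)
                                                   / (0.85 * half_len)) ** 8
    canal = (t < 1.0) & bone_mask
    img[canal] -= canal_depth * np.cos(0.5 * np.pi * np.sqrt(t[canal]))

    # Lesion geometry is drawn for both labels (keeping the random
    # streams aligned, so a healthy phantom with the same seed provides
    # the matched "same region" control) but applied only if cancerous.
    # Lytic lesions arise in the medulla: the lesion sits on the canal,
    # overlapping its intensity range, so only its ragged blob shape
    # (not its brightness) distinguishes it from normal anatomy.
    r0 = cr_shaft + rng.uniform(-0.15, 0.15) * half_len
    cc0 = cc_shaft + rng.uniform(-0.3, 0.3) * canal_hw
    a = rng.uniform(0.10, 0.17) * h
    b = canal_hw * rng.uniform(1.0, 1.5)
    mask = _ragged_ellipse_mask(
        (h, w), (r0, cc0), (a, b), spec.lesion_raggedness, rng
    )
    mask &= bone_mask  # lesion lives inside the bone

    if spec.label == "cancerous":
        k = spec.lesion_gray_levels
        # all levels darker than the bone: a lytic lesion, left tail.
        # The darkest compartment is a small necrotic core (~6% of the
        # area) reaching far below the canal floor: a strong asymmetry
        # (skewness) cue that barely moves the bulk statistics. The
        # remaining compartments sit in the canal's intensity range.
        depth = spec.lesion_depth * rng.uniform(0.85, 1.15)
        if k > 1:
            levels = np.concatenate([
                [max(bone - depth, 5.0)],
                np.linspace(bone - 0.38 * depth, bone - 0.20 * depth, k - 1),
            ])
            core = 0.06  # small necrotic core, nearly radio-black
            cum = np.concatenate([[core], np.full(k - 1, (1 - core) / (k - 1))])
            cuts = np.cumsum(cum)[:-1]
        else:
            levels = np.array([max(bone - depth, 5.0)])
            cuts = np.array([])
        # spatially coherent compartments: quantize a smooth field into
        # the k dominant levels (few gray values, wide intensity spread)
        u = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=5.0)
        edges_q = np.quantile(u[mask], cuts) if k > 1 else np.array([])
        fill = levels[np.digitize(u[mask], edges_q)]
        fill += rng.normal(0.0, spec.lesion_speckle_sd, size=fill.size)
        img[mask] = fill

    img += rng.normal(0.0, noise_sd, size=img.shape)
    np.clip(img, 0.0, 255.0, out=img)
    return RadiographImage(
        pixels=img, label=spec.label, source_id=f"phantom-seed{spec.seed}"
    ), mask


def effect_size_overrides(level: str) -> dict:
    """Preset spec overrides for a weaker or stronger class contrast."""
    presets = {
        "low": {"lesion_depth": 120.0, "lesion_raggedness": 0.25,
                "lesion_gray_levels": 6},
        "default": {},
        "high": {"lesion_depth": 240.0, "lesion_raggedness": 0.65,
                 "lesion_gray_levels": 3, "noise_sd": 1.5},
    }
    if level not in presets:
        raise ValueError(f"unknown effect size {level!r}; use low|default|high")
    return presets[level]


def generate_dataset(
    n_cancerous: int,
    n_healthy: int,
    spec_overrides: Optional[dict] = None,
    seed: int = 42,
) -> tuple[list[RadiographImage], pd.DataFrame]:
    """Generate a labeled phantom set with a reproducible manifest.

    Per-image seeds are derived from the master seed via a counter-based
    seed sequence, so datasets of any size are reproducible and images
    are independent. Returns the images and a manifest DataFrame with
    columns (id, label, seed, spec).
    """
    if n_cancerous < 1 or n_healthy < 1:
        raise ValueError("need at least one phantom per class")
    base = spec_overrides or {}
    n = n_cancerous + n_healthy
    child_seeds = np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF
    images: list[RadiographImage] = []
    records = []
    labels = ["cancerous"] * n_cancerous + ["healthy"] * n_healthy
    for i, (label, s) in enumerate(zip(labels, child_seeds)):
        spec = PhantomSpec(label=label, seed=int(s), **base)
        img = generate_phantom(spec)
        img = replace(img, source_id=f"phantom_{i:03d}")
        images.append(img)
        records.append(
            {
                "id": f"phantom_{i:03d}",
                "label": label,
                "seed": int(s),
                "spec": json.dumps(asdict(spec), sort_keys=True),
            }
        )
    return images, pd.DataFrame.from_records(records)
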