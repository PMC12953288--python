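"""Synthetic adipophilin-style tissue-section images with exact ground truth.

Renders an 8-bit raster mimicking a scanned immunostained liver section as
the DIA chain sees it: dark slide background, mid-intensity textured tissue,
and bright elliptical droplet lumina each wrapped in a one-pixel darker rim
(the stained droplet membrane).  Every rendered droplet is recorded in a
ground-truth table whose area is the *rendered* pixel count times the pixel
area — the pixel-exact quantity a segmenter can be audited against, free of
rasterization error.

Per-class area sampling is log-uniform within ranges margined away from the
1 and 100 um^2 class bounds, so discretization can never flip a droplet's
intended size class (a retry guard enforces this).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse

from ..morphometry import SizeClass, classify_droplet_area

__all__ = ["ImageSpec", "GroundTruthDroplet", "PlacementError", "generate_image"]

BACKGROUND_INTENSITY = 40
TISSUE_INTENSITY = 120
TISSUE_TEXTURE_SD = 12.0
LUMEN_INTENSITY = 235
RIM_INTENSITY = 80

#: Default per-class sampling ranges (um^2), margined off the 1/100 bounds.
DEFAULT_AREA_RANGES: dict[str, tuple[float, float]] = {
    "tiny": (0.2, 0.7),
    "small": (2.0, 80.0),
    "large": (150.0, 800.0),
}


class PlacementError(RuntimeError):
    """Requested droplets cannot be placed without overlap."""


@dataclass(frozen=True)
class GroundTruthDroplet:
    """Ground truth for one rendered droplet."""

    droplet_id: int
    center_xy: tuple[float, float]  # (x, y) = (col, row)
    area_um2: float
    axis_ratio: float
    size_class: SizeClass


@dataclass
class ImageSpec:
    """Parameters of one synthetic section image.

    The default 0.25 um/pixel calibration corresponds to a ~40x scan, so a
    1 um^2 droplet spans ~16 pixels and even tiny droplets are resolvable
    objects with measurable shape.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.25
    n_tiny: int = 0
    n_small: int = 0
    n_large: int = 0
    area_dist_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AREA_RANGES)
    )
    axis_ratio_range: tuple[float, float] = (0.7, 1.0)
    tissue_fraction: float = 0.8
    overlap_allowed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if min(self.n_tiny, self.n_small, self.n_large) < 0:
            raise ValueError("droplet counts must be non-negative")
        if not 0 < self.tissue_fraction <= 1:
            raise ValueError("tissue_fraction must lie in (0, 1]")
        lo, hi = self.axis_ratio_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("axis_ratio_range must satisfy 0 < lo <= hi <= 1")
        bounds = {"tiny": (0.0, 1.0), "small": (1.0, 100.0), "large": (100.0, np.inf)}
        px_area = self.pixel_size_um**2
        for cls, (class_lo, class_hi) in bounds.items():
            a_lo, a_hi = self.area_dist_params[cls]
            if not (class_lo <= a_lo <= a_hi) or a_hi >= class_hi:
                raise ValueError(
                    f"{cls} area range ({a_lo}, {a_hi}) violates class bounds "
                    f"[{class_lo}, {class_hi})"
                )
            if a_lo / px_area < 2:
                raise ValueError(
                    f"{cls} droplets of {a_lo} um^2 span < 2 pixels at "
                    f"{self.pixel_size_um} um/pixel"
                )


def _tissue_rect(spec: ImageSpec) -> tuple[int, int, int, int]:
    """Centered rectangle (r0, r1, c0, c1) covering tissue_fraction of the raster."""
    h = int(round(spec.height_px * np.sqrt(spec.tissue_fraction)))
    w = int(round(spec.width_px * np.sqrt(spec.tissue_fraction)))
    r0 = (spec.height_px - h) // 2
    c0 = (spec.width_px - w) // 2
    return r0, r0 + h, c0, c0 + w


def generate_image(
    spec: ImageSpec,
) -> tuple[np.ndarray, list[GroundTruthDroplet], np.ndarray]:
    """Render a synthetic section image.

    Returns
    -------
    image : uint8 2-D array
    ground_truth : list of :class:`GroundTruthDroplet` (ids in placement
        order: large, then small, then tiny)
    tissue_mask : boolean array, True on tissue

    Raises
    ------
    PlacementError
        If ``overlap_allowed`` is False and a droplet cannot be placed in
        1000 rejection-sampling attempts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    px_area = spec.pixel_size_um**2

    r0, r1, c0, c1 = _tissue_rect(spec)
    tissue_mask = np.zeros((h, w), dtype=bool)
    tissue_mask[r0:r1, c0:c1] = True

    image = np.full((h, w), BACKGROUND_INTENSITY, dtype=float)
    texture = rng.normal(0.0, TISSUE_TEXTURE_SD, size=(h, w))
    image[tissue_mask] = TISSUE_INTENSITY + texture[tissue_mask]

    # place large first for easier packing; ids follow placement order
    requests = [
        ("large", spec.n_large),
        ("small", spec.n_small),
        ("tiny", spec.n_tiny),
    ]
    placed: list[tuple[float, float, float]] = []  # (row, col, clearance radius)
    ground_truth: list[GroundTruthDroplet] = []
    droplet_id = 1
    lumen = np.zeros((h, w), dtype=bool)
    rim = np.zeros((h, w), dtype=bool)

    for cls_name, count in requests:
        a_lo, a_hi = spec.area_dist_params[cls_name]
        for _ in range(count):
            for attempt in range(1000):
                area_um2 = np.exp(rng.uniform(np.log(a_lo), np.log(a_hi)))
                q = rng.uniform(*spec.axis_ratio_range)
                theta = rng.uniform(0.0, np.pi)
                area_px = area_um2 / px_area
                r_major = np.sqrt(area_px / (np.pi * q))
                r_minor = r_major * q
                margin = r_major + 2.0  # keep rim inside tissue, off neighbours
                if (r1 - r0) <= 2 * margin or (c1 - c0) <= 2 * margin:
                    continue
                row = rng.uniform(r0 + margin, r1 - margin)
                col = rng.uniform(c0 + margin, c1 - margin)
                if not spec.overlap_allowed and any(
                    np.hypot(row - pr, col - pc) < margin + prad
                    for pr, pc, prad in placed
                ):
                    continue
                rr, cc = ellipse(row, col, r_major, r_minor, shape=(h, w), rotation=theta)
                if rr.size < 2:
                    continue
                rendered_um2 = rr.size * px_area
                if classify_droplet_area(rendered_um2) != SizeClass(cls_name):
                    continue  # rasterization pushed it over a class bound
                placed.append((row, col, margin))
                mask_d = np.zeros((h, w), dtype=bool)
                mask_d[rr, cc] = True
                lumen |= mask_d
                ring = _ring(mask_d)
                rim |= ring & ~lumen
                ground_truth.append(
                    GroundTruthDroplet(
                        droplet_id=droplet_id,
                        center_xy=(col, row),
                        area_um2=float(rendered_um2),
                        axis_ratio=float(q),
                        size_class=SizeClass(cls_name),
                    )
                )
                droplet_id += 1
                break
            else:
                raise PlacementError(
                    f"could not place {cls_name} droplet {droplet_id} "
                    f"after 1000 attempts"
                )

    rim &= ~lumen
    image[rim & tissue_mask] = RIM_INTENSITY
    image[lumen] = LUMEN_INTENSITY
    return np.clip(np.round(image), 0, 255).astype(np.uint8), ground_truth, tissue_mask


def _ring(mask: np.ndarray) -> np.ndarray:
    """One-pixel 8-connected outer contour of a boolean mask."""
    from scipy import ndimage as ndi

    return ndi.binary_dilation(mask, structure=np.ones((3, 3), bool)) & ~mask
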