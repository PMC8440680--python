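"""Fovea-centered ring and quadrant region-of-interest masks.

The measurement grid is an annulus between a 4 mm and a 6 mm diameter
circle centered on the fovea, optionally split into four 90° sectors with
diagonal (±45°) boundaries — the superior / inferior / nasal / temporal
convention used for perifoveal grids.  The annulus deliberately excludes
the central 3 mm zone where late-stage lesions would contaminate the
choriocapillaris signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import EnFaceImage

RING = "ring"
QUADRANT_KINDS = (
    "superior_quadrant",
    "inferior_quadrant",
    "nasal_quadrant",
    "temporal_quadrant",
)
ROI_KINDS = (RING,) + QUADRANT_KINDS


@dataclass(frozen=True)
class RoiMask:
    """Boolean pixel set for the ring or one of its quadrants."""

    mask: np.ndarray
    roi_kind: str
    pixel_scale_um: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if self.roi_kind not in ROI_KINDS:
            raise ValueError(f"unknown roi_kind {self.roi_kind!r}")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.pixel_count * self.pixel_scale_um**2

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6


def _offsets_um(image: EnFaceImage) -> tuple[np.ndarray, np.ndarray]:
    fr, fc = image.fovea_center
    h, w = image.shape
    dr = (np.arange(h)[:, None] - fr) * image.pixel_scale_um
    dc = (np.arange(w)[None, :] - fc) * image.pixel_scale_um
    return np.broadcast_to(dr, (h, w)), np.broadcast_to(dc, (h, w))


def build_ring_mask(
    image: EnFaceImage,
    inner_diameter_mm: float = 4.0,
    outer_diameter_mm: float = 6.0,
) -> RoiMask:
    """Annulus mask: pixel centers with ``inner_radius <= d < outer_radius``.

    Distances are Euclidean, measured in physical units from the fovea
    center to each pixel center.  ``inner_diameter_mm = 0`` degenerates to
    the full disc.  Membership uses a half-open radial interval so that
    concentric rings tile without double counting.
    """
    if inner_diameter_mm < 0 or inner_diameter_mm >= outer_diameter_mm:
        raise ValueError("require 0 <= inner diameter < outer diameter")
    dr, dc = _offsets_um(image)
    d = np.hypot(dr, dc)
    r_in = inner_diameter_mm * 1000.0 / 2.0
    r_out = outer_diameter_mm * 1000.0 / 2.0
    mask = (d >= r_in) & (d < r_out)
    return RoiMask(mask=mask, roi_kind=RING, pixel_scale_um=image.pixel_scale_um)


def _sector_mask(image: EnFaceImage, quadrant: str, eye_side: str) -> np.ndarray:
    """90° sector with diagonal boundaries through the fovea center.

    Row index increases downward and row 0 is anatomically superior, so the
    superior sector is Δrow < 0 with |Δcol| <= |Δrow|.  Boundary pixels
    (|Δcol| = |Δrow|) belong to the superior/inferior sectors.  Horizontal
    sectors are mapped to nasal/temporal by laterality: in a right-eye (OD)
    en-face image the nasal side is the left image half, mirrored for OS.
    """
    dr, dc = _offsets_um(image)
    adr, adc = np.abs(dr), np.abs(dc)
    if quadrant == "superior_quadrant":
        return (dr < 0) & (adc <= adr)
    if quadrant == "inferior_quadrant":
        return (dr > 0) & (adc <= adr)
    if eye_side not in ("OD", "OS"):
        raise ValueError("eye_side must be 'OD' or 'OS' for nasal/temporal quadrants")
    left = (adc > adr) & (dc < 0)
    right = (adc > adr) & (dc > 0)
    nasal_is_left = eye_side == "OD"
    if quadrant == "nasal_quadrant":
        return left if nasal_is_left else right
    if quadrant == "temporal_quadrant":
        return right if nasal_is_left else left
    raise ValueError(f"unknown quadrant {quadrant!r}")


def build_quadrant_mask(
    ring: RoiMask, image: EnFaceImage, quadrant: str, eye_side: str = "OD"
) -> RoiMask:
    """Intersect the ring with one diagonal-bounded 90° sector.

    The four quadrants are pairwise disjoint and partition the ring exactly.
    The superior quadrant — the sector analysed in reticular-pseudodrusen
    studies, where lesions appear first — is independent of laterality.
    """
    if quadrant not in QUADRANT_KINDS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    if ring.mask.shape != image.shape:
        raise ValueError("ring mask and image dimensions differ")
    sector = _sector_mask(image, quadrant, eye_side)
    return RoiMask(
        mask=ring.mask & sector,
        roi_kind=quadrant,
        pixel_scale_um=image.pixel_scale_um,
    )
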