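"""Phansalkar local adaptive thresholding for flow-deficit binarization.

Phansalkar's method extends Sauvola/Niblack thresholding with an
exponential correction term for low-contrast images.  With intensities
normalized to [0, 1], the local threshold at each pixel is

    t = mu * (1 + p * exp(-q * mu) + k * (sigma / r - 1))

where ``mu`` and ``sigma`` are the mean and standard deviation over a
circular window around the pixel.  A pixel is a flow-deficit (FD) pixel iff
its normalized intensity is strictly below ``t``; ties are perfused.

Conventions fixed here (implementations in the wild differ on all three):
a circular window, mirror padding at image borders, and normalization by a
fixed division by 255 rather than per-image min–max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import EnFaceImage


@dataclass(frozen=True)
class PhansalkarParams:
    """Window radius and the k, r, p, q coefficients of the threshold formula.

    Defaults are the values of the method's original publication (k = 0.25,
    r = 0.5, p = 2, q = 10), which are also the common implementation
    defaults, with a 15-pixel window radius.
    """

    radius_px: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if not self.r > 0:
            raise ValueError("r must be positive")


@dataclass(frozen=True)
class BinaryFdMap:
    """Boolean flow-deficit map (True = FD pixel) plus the parameters used."""

    mask: np.ndarray
    params_used: PhansalkarParams


def disk_footprint(radius_px: int) -> np.ndarray:
    """Boolean circular footprint: offsets with Euclidean norm <= radius."""
    rr, cc = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    return (rr * rr + cc * cc) <= radius_px * radius_px


def _check_radius(image: EnFaceImage, params: PhansalkarParams) -> None:
    if params.radius_px >= min(image.shape):
        raise ValueError(
            f"window radius {params.radius_px} px too large for image {image.shape}"
        )


def phansalkar_formula(mu, sigma, params: PhansalkarParams | None = None):
    """Threshold t = mu·(1 + p·exp(−q·mu) + k·(sigma/r − 1)) on the [0, 1] scale.

    At mu = 0.5, sigma = 0 with the default coefficients this evaluates to
    0.5·(1 + 2e⁻⁵ − 0.25) ≈ 0.381738.
    """
    if params is None:
        params = PhansalkarParams()
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    return mu * (1.0 + params.p * np.exp(-params.q * mu) + params.k * (sigma / params.r - 1.0))


def phansalkar_threshold_map(image: EnFaceImage, params: PhansalkarParams) -> np.ndarray:
    """Per-pixel Phansalkar threshold on the normalized [0, 1] scale.

    Window sums are accumulated in exact integer arithmetic before the
    single floating-point division, so the result is independent of
    summation order and reproducible across platforms.
    """
    _check_radius(image, params)
    fp = disk_footprint(params.radius_px).astype(np.int64)
    n = int(fp.sum())
    x = image.pixels.astype(np.int64)
    s1 = ndimage.correlate(x, fp, mode="reflect")
    s2 = ndimage.correlate(x * x, fp, mode="reflect")
    mu = s1 / (255.0 * n)
    var = s2 / (255.0**2 * n) - mu * mu
    sd = np.sqrt(np.clip(var, 0.0, None))
    return phansalkar_formula(mu, sd, params)


def phansalkar_threshold(
    image: EnFaceImage, params: PhansalkarParams | None = None
) -> BinaryFdMap:
    """Binarize an en-face image; True marks pixels below the local threshold."""
    if params is None:
        params = PhansalkarParams()
    t = phansalkar_threshold_map(image, params)
    norm = image.pixels / 255.0
    return BinaryFdMap(mask=norm < t, params_used=params)
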