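"""En-face image container and grayscale I/O.

An en-face choriocapillaris OCTA scan is stored as an 8-bit grayscale
grid with a physical pixel scale (µm per pixel edge) and the fovea-center
coordinate the measurement grid is anchored to.  The commercial 6 × 6 mm
scan pattern of 300 × 300 A-scans corresponds to the default scale of
20 µm/pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

DEFAULT_PIXEL_SCALE_UM = 20.0


@dataclass(frozen=True)
class EnFaceImage:
    """A 2D 8-bit en-face scan with physical scale and fovea anchor.

    Parameters
    ----------
    pixels
        2D array of grey levels; coerced to ``uint8`` (values must lie in
        [0, 255]).
    pixel_scale_um
        Physical edge length of one pixel in micrometres.
    fovea_center
        ``(row, col)`` pixel coordinate of the fovea.  ``None`` selects the
        geometric image center, matching devices that center the scan on
        fixation.
    """

    pixels: np.ndarray
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    fovea_center: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("grey levels must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if not self.pixel_scale_um > 0:
            raise ValueError("pixel_scale_um must be positive")
        if self.fovea_center is None:
            h, w = px.shape
            object.__setattr__(self, "fovea_center", ((h - 1) / 2.0, (w - 1) / 2.0))
        r, c = self.fovea_center
        h, w = px.shape
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError(f"fovea_center {self.fovea_center} outside image bounds {px.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_scale_um**2


def load_image(
    path,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    fovea_center: tuple[float, float] | None = None,
) -> EnFaceImage:
    """Read an 8-bit grayscale PNG/TIFF as an :class:`EnFaceImage`."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        # tolerate grayscale saved with redundant channels
        if arr.shape[2] in (3, 4) and np.all(arr[..., 0] == arr[..., 1]) and np.all(
            arr[..., 0] == arr[..., 2]
        ):
            arr = arr[..., 0]
        else:
            raise ValueError(f"{path}: expected single-channel grayscale image")
    return EnFaceImage(arr, pixel_scale_um=pixel_scale_um, fovea_center=fovea_center)


def save_image(path, image: EnFaceImage) -> None:
    """Write the pixel grid as an 8-bit single-channel image."""
    iio.imwrite(path, image.pixels)


def save_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 image for visual audit."""
    iio.imwrite(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))
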