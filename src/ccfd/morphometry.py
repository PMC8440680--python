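"""Flow-deficit morphometry inside a region of interest.

Connected components of the binary flow-deficit map are clipped to the ROI,
filtered by a physical minimum size, and summarized as per-ROI metrics:
FD count, total FD area and FD %, a log-binned power-law fit of the FD
size distribution, and grey-level intensity statistics of the raw image.

The minimum-size filter removes FDs whose equivalent circular diameter
2·sqrt(area/π) falls below 24 µm; deficits that small are indistinguishable
from speckle noise and are considered physiologically irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage import measure

from .binarize import BinaryFdMap
from .geometry import RoiMask
from .image import EnFaceImage


class UnderdeterminedFitError(ValueError):
    """Raised when fewer than three non-empty bins support a regression."""


@dataclass(frozen=True)
class FlowDeficitComponent:
    label: int
    pixel_count: int
    area_um2: float
    centroid: tuple[float, float]

    @property
    def equivalent_diameter_um(self) -> float:
        return 2.0 * np.sqrt(self.area_um2 / np.pi)


@dataclass(frozen=True)
class FlowDeficitSet:
    """Labeled FD components surviving the size filter, with the ROI used."""

    components: tuple[FlowDeficitComponent, ...]
    roi: RoiMask
    min_size_filter_um: float

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([c.area_um2 for c in self.components], dtype=float)

    @property
    def total_area_um2(self) -> float:
        return float(self.areas_um2.sum()) if self.components else 0.0


@dataclass(frozen=True)
class FdMetrics:
    fd_count: int
    fd_total_area_um2: float
    fd_percent: float
    roi_kind: str


@dataclass(frozen=True)
class SizeDistributionFit:
    """Least-squares line log10(count) = m·log10(area) + c over log bins."""

    bin_centers_log10_area: np.ndarray
    bin_counts: np.ndarray
    m: float
    c: float
    r_squared: float
    n_bins_used: int


@dataclass(frozen=True)
class IntensityStats:
    """Grey-level statistics of raw (pre-threshold) ROI pixels.

    ``kurtosis`` is the excess kurtosis m4/m2² − 3 from population moments
    (0 for a normal distribution); ``sd`` uses the n−1 denominator.  The
    256-bin histogram is fitted with a sixth-order polynomial, frequency
    versus grey level, stored as ascending-power coefficients.
    """

    mean: float
    sd: float
    kurtosis: float
    histogram: np.ndarray
    poly6_coefficients: np.ndarray
    poly6_r_squared: float
    zero_variance: bool = field(default=False)


def extract_flow_deficits(
    fd_map: BinaryFdMap, roi: RoiMask, min_equiv_diameter_um: float = 24.0
) -> FlowDeficitSet:
    """Label FD components within the ROI and drop those below the size cutoff.

    The binary map is intersected with the ROI before labeling, so a
    component straddling the ROI boundary contributes only its in-ROI
    pixels; quadrant metrics therefore add up to the ring metric.
    Components are 8-connected (diagonal touches merge, matching the
    confluent appearance of real deficits) and labeled in deterministic
    raster order.
    """
    if fd_map.mask.shape != roi.mask.shape:
        raise ValueError(
            f"FD map {fd_map.mask.shape} and ROI {roi.mask.shape} dimensions differ"
        )
    clipped = fd_map.mask & roi.mask
    labels = measure.label(clipped, connectivity=2)
    px_area = roi.pixel_scale_um**2
    comps = []
    for rp in measure.regionprops(labels):
        area_um2 = rp.area * px_area
        if 2.0 * np.sqrt(area_um2 / np.pi) < min_equiv_diameter_um:
            continue
        comps.append(
            FlowDeficitComponent(
                label=int(rp.label),
                pixel_count=int(rp.area),
                area_um2=float(area_um2),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    return FlowDeficitSet(
        components=tuple(comps), roi=roi, min_size_filter_um=min_equiv_diameter_um
    )


def fd_metrics(fds: FlowDeficitSet) -> FdMetrics:
    """Total FD area as a percentage of the ROI area, plus the FD count."""
    if fds.roi.pixel_count == 0:
        raise ValueError("empty ROI")
    total = fds.total_area_um2
    return FdMetrics(
        fd_count=len(fds.components),
        fd_total_area_um2=total,
        fd_percent=100.0 * total / fds.roi.area_um2,
        roi_kind=fds.roi.roi_kind,
    )


def fit_log_binned_counts(
    bin_centers_log10_area: np.ndarray, bin_counts: np.ndarray
) -> SizeDistributionFit:
    """Unweighted least squares of log10(count) on log10(area); empty bins dropped."""
    centers = np.asarray(bin_centers_log10_area, dtype=float)
    counts = np.asarray(bin_counts)
    if np.any(counts < 0):
        raise ValueError("bin counts must be non-negative")
    keep = counts > 0
    if keep.sum() < 3:
        raise UnderdeterminedFitError(
            f"only {int(keep.sum())} non-empty bins; need >= 3 for a regression"
        )
    x = centers[keep]
    y = np.log10(counts[keep].astype(float))
    res = sps.linregress(x, y)
    return SizeDistributionFit(
        bin_centers_log10_area=centers,
        bin_counts=counts,
        m=float(res.slope),
        c=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_bins_used=int(keep.sum()),
    )


def log_bin_areas(
    areas_um2: np.ndarray, bin_decades: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram areas in equal-width log10 bins spanning [min, max].

    Returns (bin centers in log10 µm², counts).  Centers are the geometric
    bin midpoints, i.e. arithmetic midpoints on the log scale.
    """
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size == 0:
        raise UnderdeterminedFitError("no flow deficits to bin")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    la = np.log10(areas)
    lo, hi = la.min(), la.max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_decades - 1e-9)))
    edges = lo + np.arange(n_bins + 1) * bin_decades
    counts, _ = np.histogram(la, bins=edges)
    centers = edges[:-1] + bin_decades / 2.0
    return centers, counts


def fit_size_distribution(
    fds: FlowDeficitSet | np.ndarray, bin_decades: float = 0.2
) -> SizeDistributionFit:
    """Log-bin FD areas and fit log10(number) = m·log10(area) + c.

    Accepts a :class:`FlowDeficitSet` or a raw array of areas in µm².
    Raises :class:`UnderdeterminedFitError` when fewer than three bins are
    occupied (e.g. all deficits the same size), rather than reporting a
    meaningless line.
    """
    areas = fds.areas_um2 if isinstance(fds, FlowDeficitSet) else np.asarray(fds, float)
    centers, counts = log_bin_areas(areas, bin_decades=bin_decades)
    return fit_log_binned_counts(centers, counts)


def excess_kurtosis(values: np.ndarray) -> float:
    """Excess kurtosis m4/m2² − 3 using population (biased) moments."""
    return float(sps.kurtosis(np.asarray(values, float), fisher=True, bias=True))


def intensity_stats(image: EnFaceImage, roi: RoiMask) -> IntensityStats:
    """Mean, SD, excess kurtosis, histogram and poly-6 histogram fit of ROI pixels.

    Computed on the raw grayscale image (all ROI pixels, deficits included),
    before any thresholding.  A constant ROI yields sd = 0 and NaN kurtosis
    with ``zero_variance`` set.
    """
    if image.shape != roi.mask.shape:
        raise ValueError("image and ROI dimensions differ")
    vals = image.pixels[roi.mask]
    if vals.size == 0:
        raise ValueError("empty ROI")
    hist = np.bincount(vals, minlength=256).astype(np.int64)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    zero_var = sd == 0.0
    kurt = float("nan") if zero_var else excess_kurtosis(vals)
    levels = np.arange(256, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(levels, hist.astype(float), 6)
    fitted = np.polynomial.polynomial.polyval(levels, coeffs)
    ss_res = float(((hist - fitted) ** 2).sum())
    ss_tot = float(((hist - hist.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return IntensityStats(
        mean=mean,
        sd=sd,
        kurtosis=kurt,
        histogram=hist,
        poly6_coefficients=coeffs,
        poly6_r_squared=r2,
        zero_variance=zero_var,
    )
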