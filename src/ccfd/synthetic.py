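"""Seeded synthetic en-face OCTA images and cohort tables.

The study's raw scans are not public, so this module fabricates the two
inputs every downstream stage needs:

* en-face choriocapillaris images — a speckled perfused background with
  dark flow-deficit (FD) blobs whose areas follow a truncated power law,
  together with the ground-truth FD mask; and
* per-eye metric tables with prescribed 2 (group) × 2 (timepoint) cell
  means, so the statistics layer can be exercised with known effects.

Blobs are axis-aligned ellipses with aspect ratio drawn uniformly from
[1, 3], placed with uniform random centers inside the 6 mm disc; overlaps
are allowed and merge in the truth mask, producing the confluent deficits
characteristic of diseased choriocapillaris.  Grey levels are clipped to
[0, 255] and rounded, since the pipeline consumes 8-bit images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import RoiMask, build_ring_mask
from .image import EnFaceImage

GROUPS = ("RPD", "control")
TIMEPOINTS = ("baseline", "follow_up")

#: Hard cap on blob placements per image; hitting it raises GenerationError.
PLACEMENT_ATTEMPT_CAP = 10_000


class GenerationError(RuntimeError):
    """Target FD coverage unreachable within the placement-attempt cap."""


@dataclass(frozen=True)
class ImageSynthesisParams:
    """Knobs of the en-face image generator.

    Grey-level defaults give a well-separated bimodal image (perfused
    background near 170, deficits near 40) whose ROI mean and SD land in
    the range reported for 6 × 6 mm choriocapillaris scans.  The area law
    defaults — exponent 2.0 on [1,000, 40,000] µm² — are free parameters:
    the empirical FD area exponent of real scans is not established, so
    they were chosen once to give deficits from just above the 24 µm noise
    cutoff up to ~0.2 mm confluent patches.
    """

    width_px: int = 300
    height_px: int = 300
    pixel_scale_um: float = 20.0
    bg_mean: float = 170.0
    bg_sd: float = 12.0
    fd_mean: float = 40.0
    fd_sd: float = 10.0
    target_fd_fraction: float = 0.35
    area_pareto_exponent: float = 2.0
    area_min_um2: float = 1_000.0
    area_max_um2: float = 40_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fd_mean < self.bg_mean:
            raise ValueError("fd_mean must be below bg_mean")
        if not self.area_min_um2 < self.area_max_um2:
            raise ValueError("require area_min_um2 < area_max_um2")
        if not 0.0 <= self.target_fd_fraction <= 0.9:
            raise ValueError("target_fd_fraction must lie in [0, 0.9]")
        if not self.area_pareto_exponent > 1:
            raise ValueError("area_pareto_exponent must exceed 1")


@dataclass(frozen=True)
class SyntheticImageBundle:
    """Generated image plus its ground truth."""

    image: EnFaceImage
    truth_mask: np.ndarray
    realized_fd_fraction: float
    roi: RoiMask
    blob_areas_um2: np.ndarray = field(default_factory=lambda: np.empty(0))


def truncated_pareto_cdf(x, exponent: float, lo: float, hi: float):
    """CDF of the power-law density ∝ x^(−exponent) truncated to [lo, hi]."""
    a = 1.0 - exponent
    x = np.clip(np.asarray(x, dtype=float), lo, hi)
    return (x**a - lo**a) / (hi**a - lo**a)


def sample_truncated_pareto(
    rng: np.random.Generator, exponent: float, lo: float, hi: float, size=None
):
    """Inverse-CDF sampling from the truncated power law."""
    a = 1.0 - exponent
    u = rng.random(size)
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


def _rasterize_ellipse(
    truth: np.ndarray, cy: float, cx: float, a_px: float, b_px: float
) -> tuple[slice, slice]:
    """Set pixels whose centers fall inside the axis-aligned ellipse.

    Ellipses smaller than a pixel still mark the nearest pixel so every
    sampled blob leaves a footprint.  Returns the touched bounding slices.
    """
    h, w = truth.shape
    r0 = max(0, int(np.floor(cy - a_px)))
    r1 = min(h, int(np.ceil(cy + a_px)) + 1)
    c0 = max(0, int(np.floor(cx - b_px)))
    c1 = min(w, int(np.ceil(cx + b_px)) + 1)
    if r0 >= r1 or c0 >= c1:
        return slice(0, 0), slice(0, 0)
    rr = np.arange(r0, r1)[:, None]
    cc = np.arange(c0, c1)[None, :]
    inside = ((rr - cy) / a_px) ** 2 + ((cc - cx) / b_px) ** 2 <= 1.0
    if not inside.any():
        r = min(max(int(round(cy)), 0), h - 1)
        c = min(max(int(round(cx)), 0), w - 1)
        truth[r, c] = True
        return slice(r, r + 1), slice(c, c + 1)
    truth[r0:r1, c0:c1] |= inside
    return slice(r0, r1), slice(c0, c1)


def generate_cc_image(params: ImageSynthesisParams) -> SyntheticImageBundle:
    """Generate one seeded en-face image with its ground-truth FD mask.

    Blobs are placed until the FD pixel fraction inside the 6 mm disc first
    reaches ``target_fd_fraction``; identical parameters and seed give
    bit-identical output.  Raises :class:`GenerationError` if the target is
    still unreached after ``PLACEMENT_ATTEMPT_CAP`` placements.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.height_px, params.width_px)
    blank = EnFaceImage(np.zeros(shape, dtype=np.uint8), params.pixel_scale_um)
    disc = build_ring_mask(blank, inner_diameter_mm=0.0, outer_diameter_mm=6.0)
    roi_px = disc.pixel_count
    target_px = params.target_fd_fraction * roi_px

    truth = np.zeros(shape, dtype=bool)
    covered = 0
    blob_areas: list[float] = []
    disc_radius_px = 3000.0 / params.pixel_scale_um
    fr, fc = blank.fovea_center
    attempts = 0
    while covered < target_px:
        if attempts >= PLACEMENT_ATTEMPT_CAP:
            raise GenerationError(
                f"FD coverage {covered / roi_px:.3f} below target "
                f"{params.target_fd_fraction} after {attempts} placements"
            )
        attempts += 1
        area = float(
            sample_truncated_pareto(
                rng, params.area_pareto_exponent, params.area_min_um2, params.area_max_um2
            )
        )
        aspect = rng.uniform(1.0, 3.0)
        # semi-axes (µm) of an ellipse with the sampled area and aspect ratio
        long_um = np.sqrt(area * aspect / np.pi)
        short_um = np.sqrt(area / (aspect * np.pi))
        if rng.integers(2):
            long_um, short_um = short_um, long_um
        rad = disc_radius_px * np.sqrt(rng.random())
        ang = rng.uniform(0.0, 2.0 * np.pi)
        cy = fr + rad * np.sin(ang)
        cx = fc + rad * np.cos(ang)
        before = truth.copy()
        rs, cs = _rasterize_ellipse(
            truth, cy, cx, long_um / params.pixel_scale_um, short_um / params.pixel_scale_um
        )
        gained = int((truth[rs, cs] & disc.mask[rs, cs]).sum()) - int(
            (before[rs, cs] & disc.mask[rs, cs]).sum()
        )
        covered += gained
        blob_areas.append(area)

    bg = rng.normal(params.bg_mean, params.bg_sd, size=shape)
    n_fd = int(truth.sum())
    if n_fd:
        bg[truth] = rng.normal(params.fd_mean, params.fd_sd, size=n_fd)
    pixels = np.rint(np.clip(bg, 0.0, 255.0)).astype(np.uint8)
    image = EnFaceImage(pixels, pixel_scale_um=params.pixel_scale_um)
    return SyntheticImageBundle(
        image=image,
        truth_mask=truth,
        realized_fd_fraction=covered / roi_px,
        roi=disc,
        blob_areas_um2=np.array(blob_areas),
    )


# ---------------------------------------------------------------------------
# Cohort synthesis

#: Default 2 × 2 cell means/SDs per metric for the ring ROI, patterned on
#: published 6 × 6 mm choriocapillaris measurements in eyes with reticular
#: pseudodrusen versus healthy controls (FD % rising in patients over five
#: years while the mean decorrelation signal falls).
DEFAULT_COHORT_MEANS = {
    "fd_percent": {
        ("RPD", "baseline"): 36.39,
        ("RPD", "follow_up"): 43.44,
        ("control", "baseline"): 32.29,
        ("control", "follow_up"): 34.81,
    },
    "intensity_mean": {
        ("RPD", "baseline"): 103.63,
        ("RPD", "follow_up"): 86.71,
        ("control", "baseline"): 117.37,
        ("control", "follow_up"): 114.12,
    },
}
DEFAULT_COHORT_SDS = {
    "fd_percent": {
        ("RPD", "baseline"): 4.10,
        ("RPD", "follow_up"): 2.80,
        ("control", "baseline"): 2.08,
        ("control", "follow_up"): 3.12,
    },
    "intensity_mean": {
        ("RPD", "baseline"): 8.47,
        ("RPD", "follow_up"): 3.51,
        ("control", "baseline"): 5.73,
        ("control", "follow_up"): 6.09,
    },
}


@dataclass(frozen=True)
class CohortSynthesisParams:
    """Cell means/SDs per metric for the 2 × 2 design, plus the within-subject
    correlation of the baseline/follow-up pair."""

    n_per_group: int = 8
    metric_means: dict = field(default_factory=lambda: DEFAULT_COHORT_MEANS)
    metric_sds: dict = field(default_factory=lambda: DEFAULT_COHORT_SDS)
    within_subject_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not -1.0 <= self.within_subject_correlation <= 1.0:
            raise ValueError("within_subject_correlation must lie in [-1, 1]")
        for metric, cells in self.metric_means.items():
            if metric not in self.metric_sds:
                raise ValueError(f"missing SDs for metric {metric!r}")
            for g in GROUPS:
                for t in TIMEPOINTS:
                    if (g, t) not in cells:
                        raise ValueError(f"metric {metric!r} missing cell {(g, t)}")
                    sd = self.metric_sds[metric].get((g, t))
                    if sd is None:
                        raise ValueError(f"metric {metric!r} missing SD cell {(g, t)}")
                    if not sd > 0:
                        raise ValueError("metric SDs must all be positive")


def generate_cohort(params: CohortSynthesisParams) -> pd.DataFrame:
    """Long-format cohort table: subject_id, group, timepoint, metric, value.

    Each subject's (baseline, follow-up) pair is drawn from a bivariate
    normal with the prescribed cell means/SDs and within-subject
    correlation; groups are balanced and the draw is fully seeded.
    """
    rng = np.random.default_rng(params.seed)
    rho = params.within_subject_correlation
    rows = []
    for metric, cells in params.metric_means.items():
        sds = params.metric_sds[metric]
        for group in GROUPS:
            mu = np.array([cells[(group, t)] for t in TIMEPOINTS])
            sd = np.array([sds[(group, t)] for t in TIMEPOINTS])
            cov = np.array(
                [
                    [sd[0] ** 2, rho * sd[0] * sd[1]],
                    [rho * sd[0] * sd[1], sd[1] ** 2],
                ]
            )
            draws = rng.multivariate_normal(mu, cov, size=params.n_per_group)
            for i in range(params.n_per_group):
                sid = f"{group}_{i + 1:02d}"
                for j, t in enumerate(TIMEPOINTS):
                    rows.append((sid, group, t, metric, float(draws[i, j])))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "timepoint", "metric", "value"]
    )


def shift_interaction(
    params: CohortSynthesisParams, metric: str, delta: float
) -> CohortSynthesisParams:
    """Return params with the RPD follow-up cell of ``metric`` shifted by ``delta``.

    Convenience for power/type-I simulations: ``delta = 0`` on an otherwise
    parallel design gives the no-interaction null.
    """
    means = {m: dict(cells) for m, cells in params.metric_means.items()}
    means[metric][("RPD", "follow_up")] += delta
    return replace(params, metric_means=means)
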