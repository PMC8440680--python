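import numpy as np
import pytest

from ccfd import (
    BinaryFdMap,
    EnFaceImage,
    PhansalkarParams,
    RoiMask,
    UnderdeterminedFitError,
    excess_kurtosis,
    extract_flow_deficits,
    fd_metrics,
    fit_log_binned_counts,
    fit_size_distribution,
    intensity_stats,
    log_bin_areas,
)
from ccfd.synthetic import sample_truncated_pareto
from helpers import binned_slope_oracle


def full_roi(shape, scale=20.0):
    return RoiMask(np.ones(shape, dtype=bool), "ring", scale)


def fd_map(mask):
    return BinaryFdMap(np.asarray(mask, bool), PhansalkarParams())


class TestSizeFilter:
    def test_single_pixel_component_removed_30px_retained(self):
        """At 20 um/px: 1 px = 400 um^2, equivalent diameter 22.57 um < 24 um
        (removed); 30 px = 12,000 um^2, diameter 123.6 um (retained)."""
        m = np.zeros((20, 20), bool)
        m[2, 2] = True               # isolated single pixel
        m[10:13, 5:15] = True        # 30-pixel block
        fds = extract_flow_deficits(fd_map(m), full_roi(m.shape))
        assert len(fds.components) == 1
        assert fds.components[0].pixel_count == 30
        assert fds.components[0].area_um2 == pytest.approx(12_000.0)

    def test_empty_map_yields_empty_set_and_zero_metrics(self):
        fds = extract_flow_deficits(fd_map(np.zeros((10, 10), bool)), full_roi((10, 10)))
        assert fds.components == ()
        metrics = fd_metrics(fds)
        assert metrics.fd_count == 0 and metrics.fd_percent == 0.0

    def test_component_clipped_to_roi(self):
        """A deficit straddling the ROI boundary counts only its in-ROI pixels."""
        m = np.zeros((10, 10), bool)
        m[4, 0:8] = True  # 8-pixel line
        roi = np.zeros((10, 10), bool)
        roi[:, 0:4] = True  # ROI covers only the first 4 columns
        fds = extract_flow_deficits(
            BinaryFdMap(m, PhansalkarParams()), RoiMask(roi, "ring", 20.0),
            min_equiv_diameter_um=0.0,
        )
        assert len(fds.components) == 1
        assert fds.components[0].pixel_count == 4

    def test_lowering_cutoff_never_decreases_count_or_percent(self):
        rng = np.random.default_rng(0)
        m = rng.random((60, 60)) < 0.2
        roi = full_roi(m.shape)
        prev_count, prev_pct = -1, -1.0
        for cutoff in (60.0, 24.0, 0.0):
            fds = extract_flow_deficits(fd_map(m), roi, cutoff)
            metrics = fd_metrics(fds)
            assert metrics.fd_count >= prev_count
            assert metrics.fd_percent >= prev_pct
            prev_count, prev_pct = metrics.fd_count, metrics.fd_percent

    def test_diagonal_touches_merge(self):
        m = np.zeros((8, 8), bool)
        m[2, 2] = m[3, 3] = m[4, 4] = True
        fds = extract_flow_deficits(fd_map(m), full_roi(m.shape), 0.0)
        assert len(fds.components) == 1

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_flow_deficits(fd_map(np.zeros((5, 5), bool)), full_roi((6, 6)))


class TestFdPercent:
    def test_exact_ratio(self):
        roi = np.zeros((10, 10), bool)
        roi[:10, :10] = True
        m = np.zeros((10, 10), bool)
        m[0:5, 0:5] = True  # 25 of 100 pixels
        fds = extract_flow_deficits(
            fd_map(m), RoiMask(roi, "ring", 20.0), min_equiv_diameter_um=0.0
        )
        assert fd_metrics(fds).fd_percent == pytest.approx(25.0)

    def test_empty_roi_rejected(self):
        fds = extract_flow_deficits(
            fd_map(np.zeros((5, 5), bool)), RoiMask(np.zeros((5, 5), bool), "ring", 20.0)
        )
        with pytest.raises(ValueError):
            fd_metrics(fds)


class TestSizeDistributionFit:
    def test_exact_line_recovered_to_machine_precision(self):
        centers = np.arange(2.0, 4.2, 0.2)
        counts = 10 ** (-1.0 * centers + 4.0)  # counts lying exactly on the line
        fit = fit_log_binned_counts(centers, counts)
        assert fit.m == pytest.approx(-1.0, abs=1e-12)
        assert fit.c == pytest.approx(4.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_identical_areas_underdetermined(self):
        with pytest.raises(UnderdeterminedFitError):
            fit_size_distribution(np.full(50, 1234.5))

    def test_two_bins_underdetermined(self):
        with pytest.raises(UnderdeterminedFitError):
            fit_log_binned_counts(np.array([2.0, 2.2, 2.4]), np.array([5, 0, 3]))

    def test_matches_independent_binning_oracle(self):
        """Slope of a truncated power-law sample agrees with a brute-force
        oracle that bins the same draws identically."""
        rng = np.random.default_rng(42)
        areas = sample_truncated_pareto(rng, 2.0, 1_000.0, 40_000.0, size=4000)
        fit = fit_size_distribution(areas, bin_decades=0.2)
        m_ref, c_ref = binned_slope_oracle(areas, 0.2)
        assert fit.m == pytest.approx(m_ref, abs=1e-9)
        assert fit.c == pytest.approx(c_ref, abs=1e-9)

    def test_histogram_spans_min_to_max(self):
        areas = np.array([500.0, 700.0, 5_000.0, 50_000.0, 52_000.0])
        centers, counts = log_bin_areas(areas, 0.2)
        assert counts.sum() == areas.size


class TestIntensityStats:
    def test_kurtosis_closed_forms(self):
        rng = np.random.default_rng(123)
        assert excess_kurtosis(rng.normal(size=100_000)) == pytest.approx(0.0, abs=0.1)
        assert excess_kurtosis(rng.uniform(0, 255, size=100_000)) == pytest.approx(
            -1.2, abs=0.1
        )

    def test_histogram_conserves_roi_pixel_count(self):
        rng = np.random.default_rng(5)
        img = EnFaceImage(rng.integers(0, 256, (50, 50), dtype=np.uint8))
        roi = RoiMask(rng.random((50, 50)) < 0.5, "ring", 20.0)
        stats = intensity_stats(img, roi)
        assert stats.histogram.sum() == roi.pixel_count
        assert stats.mean == pytest.approx(float(img.pixels[roi.mask].mean()))

    def test_constant_roi_flags_zero_variance(self):
        img = EnFaceImage(np.full((20, 20), 77, np.uint8))
        stats = intensity_stats(img, full_roi((20, 20)))
        assert stats.zero_variance
        assert stats.sd == 0.0
        assert np.isnan(stats.kurtosis)

    def test_poly6_fit_has_seven_coefficients(self):
        rng = np.random.default_rng(8)
        img = EnFaceImage(rng.normal(128, 30, (80, 80)).clip(0, 255).astype(np.uint8))
        stats = intensity_stats(img, full_roi((80, 80)))
        assert stats.poly6_coefficients.shape == (7,)
        assert 0.0 <= stats.poly6_r_squared <= 1.0

    def test_empty_roi_rejected(self):
        img = EnFaceImage(np.zeros((5, 5), np.uint8))
        with pytest.raises(ValueError):
            intensity_stats(img, RoiMask(np.zeros((5, 5), bool), "ring", 20.0))
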