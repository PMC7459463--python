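"""Spectral estimation and conditioning: Welch PSD, log binning, banding, resampling."""

import numpy as np
import pytest

import fes
from fes.errors import BandError, ExtrapolationError, SizingError, ValidationError


class TestEstimatePsd:
    def test_white_noise_level_and_parseval(self, rng):
        """Unit-variance white noise at 1 kHz: flat PSD at 2/fs, and the
        integrated density equals the sample variance (Parseval) within 5%."""
        x = rng.standard_normal(2**18)
        ts = fes.TimeSeriesRecord(samples=x, sampling_rate=1000.0)
        ps = fes.estimate_psd(ts)
        assert ps.density.mean() == pytest.approx(2.0 / 1000.0, rel=0.02)
        df = ps.frequencies[1] - ps.frequencies[0]
        assert ps.density.sum() * df == pytest.approx(x.var(), rel=0.05)
        assert ps.n_averages == 127

    def test_sinusoid_concentrates_at_its_bin(self):
        fs, f0 = 1024.0, 100.0  # f0 on the segment-1024 bin grid
        t = np.arange(4096) / fs
        ts = fes.TimeSeriesRecord(np.sin(2 * np.pi * f0 * t), fs)
        ps = fes.estimate_psd(ts, segment_length=1024)
        assert ps.frequencies[np.argmax(ps.density)] == pytest.approx(f0)

    def test_deterministic_for_fixed_input(self, rng):
        ts = fes.TimeSeriesRecord(rng.standard_normal(8192), 100.0)
        a = fes.estimate_psd(ts, segment_length=1024)
        b = fes.estimate_psd(ts, segment_length=1024)
        np.testing.assert_array_equal(a.density, b.density)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal(8192)
        a = fes.estimate_psd(fes.TimeSeriesRecord(x, 100.0), segment_length=512)
        b = fes.estimate_psd(fes.TimeSeriesRecord(3.0 * x, 100.0), segment_length=512)
        np.testing.assert_allclose(b.density, 9.0 * a.density, rtol=1e-12)

    def test_dc_bin_dropped(self, rng):
        ps = fes.estimate_psd(
            fes.TimeSeriesRecord(rng.standard_normal(4096), 100.0), segment_length=256
        )
        assert ps.frequencies[0] > 0

    def test_too_short_series_raises_sizing_error(self, rng):
        ts = fes.TimeSeriesRecord(rng.standard_normal(1000), 100.0)
        with pytest.raises(SizingError):
            fes.estimate_psd(ts, segment_length=1024)

    def test_nonfinite_samples_rejected(self):
        with pytest.raises(ValidationError):
            fes.TimeSeriesRecord([1.0, np.nan, 2.0], 10.0)

    @pytest.mark.parametrize("overlap", [-0.1, 1.0, 1.5])
    def test_bad_overlap_rejected(self, rng, overlap):
        ts = fes.TimeSeriesRecord(rng.standard_normal(4096), 100.0)
        with pytest.raises(ValidationError):
            fes.estimate_psd(ts, segment_length=256, overlap_fraction=overlap)


class TestLogBinSpectrum:
    def test_noop_when_input_coarser_than_grid(self, power_law):
        ps = power_law(1.0, f_lo=1.0, f_hi=100.0, n=4)  # 1.5 points/decade
        out = fes.log_bin_spectrum(ps, bins_per_decade=2)
        np.testing.assert_allclose(out.frequencies, ps.frequencies, rtol=1e-12)
        np.testing.assert_allclose(out.density, ps.density, rtol=1e-12)

    def test_power_law_slope_preserved(self):
        f = np.linspace(0.1, 100.0, 5000)  # linear grid, 3 decades
        ps = fes.PowerSpectrum(frequencies=f, density=1.0 / f)
        binned = fes.log_bin_spectrum(ps, bins_per_decade=12)
        before = fes.endpoint_slope(ps, ps.f_min, ps.f_max)
        after = fes.endpoint_slope(binned, binned.f_min, binned.f_max)
        assert after == pytest.approx(before, rel=0.01)
        assert after == pytest.approx(-1.0, rel=0.01)

    def test_point_count_bounded_by_bins(self):
        f = np.linspace(1.0, 100.0, 1000)  # 2 decades
        ps = fes.PowerSpectrum(frequencies=f, density=np.ones_like(f))
        out = fes.log_bin_spectrum(ps, bins_per_decade=10)
        assert len(out) <= 20

    def test_degenerate_output_raises(self):
        ps = fes.PowerSpectrum(frequencies=[10.0, 11.0], density=[1.0, 1.0])
        with pytest.raises(BandError):
            fes.log_bin_spectrum(ps, bins_per_decade=1)


class TestSelectBand:
    def test_full_support_is_identity(self, power_law):
        ps = power_law(1.0)
        out = fes.select_band(ps, ps.f_min, ps.f_max)
        np.testing.assert_array_equal(out.frequencies, ps.frequencies)

    def test_filters_closed_interval(self):
        f = np.geomspace(0.1, 100.0, 31)  # 10 points/decade
        ps = fes.PowerSpectrum(frequencies=f, density=np.ones_like(f))
        out = fes.select_band(ps, 1.0, 10.0)
        assert out.f_min >= 1.0 and out.f_max <= 10.0
        assert len(out) == 11  # both endpoints on-grid, closed interval

    def test_disjoint_band_raises(self, power_law):
        ps = power_law(1.0, f_lo=1.0, f_hi=100.0)
        with pytest.raises(BandError):
            fes.select_band(ps, 500.0, 900.0)

    def test_nested_composition(self, power_law):
        ps = power_law(1.5, f_lo=0.1, f_hi=500.0)
        once = fes.select_band(ps, 2.0, 50.0)
        twice = fes.select_band(fes.select_band(ps, 1.0, 100.0), 2.0, 50.0)
        np.testing.assert_array_equal(once.frequencies, twice.frequencies)
        np.testing.assert_array_equal(once.density, twice.density)


class TestResampleToGrid:
    def test_identity_on_source_grid(self, power_law):
        ps = power_law(0.7)
        out = fes.resample_to_grid(ps, ps.frequencies)
        np.testing.assert_allclose(out.density, ps.density, rtol=1e-12)

    def test_exact_on_power_laws(self, power_law):
        ps = power_law(1.3, level=2.5, n=50)
        targets = np.geomspace(0.2, 400.0, 77)
        out = fes.resample_to_grid(ps, targets)
        np.testing.assert_allclose(out.density, 2.5 * targets ** (-1.3), rtol=1e-10)

    def test_loglog_midpoint(self):
        ps = fes.PowerSpectrum(frequencies=[1.0, 100.0], density=[1.0, 0.01])
        out = fes.resample_to_grid(ps, [1.0, 10.0, 100.0])
        assert out.density[1] == pytest.approx(0.1, rel=1e-12)

    def test_extrapolation_refused(self, power_law):
        ps = power_law(1.0, f_lo=1.0, f_hi=100.0)
        with pytest.raises(ExtrapolationError):
            fes.resample_to_grid(ps, [0.5, 10.0])


class TestDefaultBand:
    def test_meaningful_band_rule(self, power_law):
        ps = power_law(1.0, f_lo=0.5, f_hi=500.0)
        lo, hi = fes.default_band(ps, nyquist=500.0)
        assert lo == pytest.approx(1.0)
        assert hi == pytest.approx(400.0)
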