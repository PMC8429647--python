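"""Preprocessing chain: SNR screening, smoothing, rubberband, despiking,
area normalization — each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from marginspec.core import Modality, SpectralDataset, Spectrum, WavenumberAxis
from marginspec.errors import ConfigError, ModalityError, NormalizationError
from marginspec.preprocess import (
    PreprocessConfig,
    area_normalize,
    preprocess_dataset,
    reject_low_snr,
    remove_cosmic_rays,
    rubberband_baseline,
    savitzky_golay,
)

from conftest import gaussian_band, make_dataset


# ---------------------------------------------------------------------------
# SNR rejection
# ---------------------------------------------------------------------------

class TestRejectLowSnr:
    def test_scaled_down_spectra_rejected(self, ftir_axis, rng):
        """100 band spectra, 10 scaled x0.01: exactly those 10 fall below SNR 3."""
        x = ftir_axis.values
        base = gaussian_band(x, 1650, 60, 1.0) + gaussian_band(x, 2900, 80, 0.5)
        spectra, labels = [], []
        weak = set(rng.choice(100, size=10, replace=False).tolist())
        for i in range(100):
            amp = 0.01 if i in weak else 1.0
            spectra.append(amp * base + rng.normal(0, 0.004, x.size))
            labels.append("tumor")
        ds = make_dataset(ftir_axis, spectra, labels)
        kept, rejected = reject_low_snr(ds, PreprocessConfig(snr_min=3.0))
        assert set(np.nonzero(rejected)[0].tolist()) == weak
        assert len(kept) == 90

    def test_pure_noise_rejected(self, ftir_axis, rng):
        noise = rng.normal(0, 1.0, (2, len(ftir_axis)))
        ds = make_dataset(ftir_axis, noise, ["tumor", "tumor"])
        _, rejected = reject_low_snr(ds, PreprocessConfig(snr_min=3.0))
        assert rejected.all()

    def test_noiseless_band_retained(self, ftir_axis):
        y = gaussian_band(ftir_axis.values, 1650, 60, 1.0)
        ds = make_dataset(ftir_axis, [y, y], ["tumor", "tumor"])
        _, rejected = reject_low_snr(ds, PreprocessConfig(snr_min=1e6))
        assert not rejected.any()  # noise floor -> infinite SNR

    def test_noise_window_outside_axis(self, ftir_axis):
        ds = make_dataset(ftir_axis, np.ones((2, len(ftir_axis))), ["t", "t"])
        with pytest.raises(ConfigError):
            reject_low_snr(ds, PreprocessConfig(noise_window=(8000.0, 9000.0)))


# ---------------------------------------------------------------------------
# Savitzky-Golay
# ---------------------------------------------------------------------------

def sg_oracle(y, window, order):
    """Per-point local least-squares refit, edges by terminal-window fit."""
    half = window // 2
    n = y.size
    out = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        if i < half:
            lo = 0
        elif i > n - 1 - half:
            lo = n - window
        else:
            lo = i - half
        sl = slice(lo, lo + window)
        coeffs = np.polyfit(idx[sl] - idx[sl][0], y[sl], order)
        out[i] = np.polyval(coeffs, i - idx[sl][0])
    return out


class TestSavitzkyGolay:
    def test_constant_unchanged(self, ftir_axis):
        s = Spectrum(ftir_axis, np.full(len(ftir_axis), 3.7))
        out = savitzky_golay(s, 13, 5)
        assert np.allclose(out.intensity, 3.7, atol=1e-12)

    def test_polynomial_reproduction(self, ftir_axis):
        """A degree-5 polynomial is a fixed point of window-13 order-5 SG."""
        t = np.linspace(-1, 1, len(ftir_axis))
        y = 1 + t - 2 * t**2 + 0.5 * t**3 - t**4 + 0.2 * t**5
        out = savitzky_golay(Spectrum(ftir_axis, y), 13, 5)
        assert np.allclose(out.intensity, y, atol=1e-9)

    def test_matches_local_least_squares_oracle(self, rng):
        axis = WavenumberAxis(np.arange(1000.0, 1050.0, 1.0))
        y = rng.normal(size=50)
        out = savitzky_golay(Spectrum(axis, y), 7, 3)
        assert np.allclose(out.intensity, sg_oracle(y, 7, 3), atol=1e-10)

    def test_linearity(self, rng, ftir_axis):
        x = rng.normal(size=len(ftir_axis))
        y = rng.normal(size=len(ftir_axis))
        a, b = 2.5, -1.3
        sx = savitzky_golay(Spectrum(ftir_axis, x), 13, 5).intensity
        sy = savitzky_golay(Spectrum(ftir_axis, y), 13, 5).intensity
        sxy = savitzky_golay(Spectrum(ftir_axis, a * x + b * y), 13, 5).intensity
        assert np.allclose(sxy, a * sx + b * sy, atol=1e-9)

    @pytest.mark.parametrize("window,order", [(12, 5), (7, 9)])
    def test_invalid_params(self, ftir_axis, window, order):
        s = Spectrum(ftir_axis, np.zeros(len(ftir_axis)))
        with pytest.raises(ConfigError):
            savitzky_golay(s, window, order)


# ---------------------------------------------------------------------------
# Rubberband baseline
# ---------------------------------------------------------------------------

def hull_oracle(x, y):
    """O(n^2) chord oracle: at each point, the highest chord that stays
    weakly below every data point."""
    n = x.size
    best = np.full(n, -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            slope = (y[j] - y[i]) / (x[j] - x[i])
            line = y[i] + slope * (x - x[i])
            if np.all(line <= y + 1e-12):
                seg = slice(i, j + 1)
                best[seg] = np.maximum(best[seg], line[seg])
    best[0], best[-1] = y[0], y[-1]
    return best


class TestRubberband:
    def test_convex_spectrum_fully_flattened(self):
        axis = WavenumberAxis(np.linspace(1000, 1100, 51))
        y = (axis.values - 1050.0) ** 2  # convex: every point on the hull
        _, corr = rubberband_baseline(Spectrum(axis, y))
        assert np.allclose(corr.intensity, 0.0, atol=1e-9)

    def test_gaussian_band_height_preserved(self, ftir_axis):
        y = gaussian_band(ftir_axis.values, 2000, 100, 2.0)
        base, corr = rubberband_baseline(Spectrum(ftir_axis, y))
        assert np.allclose(base.intensity, 0.0, atol=1e-9)  # flat endpoint line
        assert corr.intensity.max() == pytest.approx(2.0, abs=1e-9)

    def test_matches_chord_oracle(self, rng):
        axis = WavenumberAxis(np.sort(rng.uniform(1000, 2000, 200)))
        y = rng.normal(size=200)
        base, corr = rubberband_baseline(Spectrum(axis, y))
        assert np.allclose(base.intensity, hull_oracle(axis.values, y), atol=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_nonnegative_and_zero_at_endpoints(self, seed):
        rng = np.random.default_rng(seed)
        axis = WavenumberAxis(np.arange(1000.0, 1100.0, 2.0))
        y = rng.normal(size=len(axis))
        _, corr = rubberband_baseline(Spectrum(axis, y))
        assert np.all(corr.intensity >= 0.0)
        assert corr.intensity[0] == pytest.approx(0.0, abs=1e-12)
        assert corr.intensity[-1] == pytest.approx(0.0, abs=1e-12)

    def test_idempotent_on_corrected_output(self, rng, ftir_axis):
        y = np.abs(rng.normal(size=len(ftir_axis))) + gaussian_band(
            ftir_axis.values, 1650, 60, 5.0
        )
        _, corr = rubberband_baseline(Spectrum(ftir_axis, y))
        base2, corr2 = rubberband_baseline(corr)
        assert np.allclose(base2.intensity, 0.0, atol=1e-12)
        assert np.allclose(corr2.intensity, corr.intensity, atol=1e-12)


# ---------------------------------------------------------------------------
# Cosmic-ray removal
# ---------------------------------------------------------------------------

def raman_axis():
    return WavenumberAxis(np.arange(500.0, 3200.0, 1.0))


class TestDespike:
    def test_single_spike_removed_others_untouched(self, rng):
        axis = raman_axis()
        x = axis.values
        y = gaussian_band(x, 1440, 15, 1.0) + rng.normal(0, 0.01, x.size)
        spiked = y.copy()
        spiked[700] += 0.5  # 50 sigma
        ds = make_dataset(axis, [spiked], ["tumor"], Modality.RAMAN)
        out, n_spikes = remove_cosmic_rays(ds)
        assert n_spikes == 1
        cleaned = out.intensities[0]
        assert abs(cleaned[700] - y[700]) < 0.05
        mask = np.ones(x.size, bool)
        mask[700] = False
        assert np.allclose(cleaned[mask], spiked[mask], atol=1e-12)

    def test_spike_free_identity(self, rng):
        axis = raman_axis()
        y = gaussian_band(axis.values, 1003, 7, 1.0) + rng.normal(0, 0.01, len(axis))
        ds = make_dataset(axis, [y], ["tumor"], Modality.RAMAN)
        out, n_spikes = remove_cosmic_rays(ds)
        assert n_spikes == 0
        assert np.array_equal(out.intensities[0], y)

    def test_recovery_rate_and_no_band_damage(self, rng):
        """>=95% of injected width<=2 spikes removed; genuine bands
        (width >= 5 points) never replaced."""
        axis = raman_axis()
        x = axis.values
        clean = (
            gaussian_band(x, 1003, 7, 0.8)
            + gaussian_band(x, 1440, 15, 1.0)
            + gaussian_band(x, 2900, 25, 1.2)
        )
        n_injected, n_recovered, band_damage = 0, 0, 0
        band_mask = clean > 0.02
        for _ in range(20):
            y = clean + rng.normal(0, 0.01, x.size)
            spiked = y.copy()
            positions = rng.choice(np.arange(50, x.size - 50), 3, replace=False)
            for pos in positions:
                width = int(rng.integers(1, 3))
                spiked[pos : pos + width] += rng.uniform(0.4, 1.5)
                n_injected += 1
            ds = make_dataset(axis, [spiked], ["t"], Modality.RAMAN)
            out, _ = remove_cosmic_rays(ds)
            cleaned = out.intensities[0]
            for pos in positions:
                if abs(cleaned[pos] - y[pos]) < 0.1:
                    n_recovered += 1
            changed = ~np.isclose(cleaned, spiked, atol=1e-12)
            spike_zone = np.zeros(x.size, bool)
            for pos in positions:
                spike_zone[pos - 1 : pos + 3] = True
            band_damage += int(np.sum(changed & band_mask & ~spike_zone))
        assert n_recovered >= 0.95 * n_injected
        assert band_damage == 0

    def test_ftir_modality_rejected(self, ftir_axis):
        ds = make_dataset(ftir_axis, np.ones((2, len(ftir_axis))), ["t", "t"])
        with pytest.raises(ModalityError):
            remove_cosmic_rays(ds)


# ---------------------------------------------------------------------------
# Area normalization
# ---------------------------------------------------------------------------

class TestAreaNormalize:
    def test_rectangle(self):
        axis = WavenumberAxis(np.linspace(1000, 1001, 11))  # span 1 cm^-1
        s = area_normalize(Spectrum(axis, np.full(11, 2.0)))
        assert np.trapezoid(s.intensity, axis.values) == pytest.approx(1.0, abs=1e-12)

    def test_unit_area_identity(self, ftir_axis):
        y = gaussian_band(ftir_axis.values, 1650, 60, 1.0)
        y = y / np.trapezoid(y, ftir_axis.values)
        out = area_normalize(Spectrum(ftir_axis, y))
        assert np.allclose(out.intensity, y, atol=1e-12)

    def test_random_positive_unit_integral(self, rng, ftir_axis):
        y = rng.random(len(ftir_axis)) + 0.1
        out = area_normalize(Spectrum(ftir_axis, y))
        # independent trapezoid sum
        x = ftir_axis.values
        total = float(np.sum(0.5 * (out.intensity[1:] + out.intensity[:-1]) * np.diff(x)))
        assert total == pytest.approx(1.0, abs=1e-10)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(1e-6, 1e6))
    def test_scale_invariance(self, c):
        axis = WavenumberAxis(np.arange(1000.0, 1100.0, 4.0))
        rng = np.random.default_rng(5)
        y = rng.random(len(axis)) + 0.5
        a = area_normalize(Spectrum(axis, y)).intensity
        b = area_normalize(Spectrum(axis, c * y)).intensity
        assert np.allclose(a, b, rtol=1e-9)

    def test_zero_area_raises(self, ftir_axis):
        with pytest.raises(NormalizationError):
            area_normalize(Spectrum(ftir_axis, np.zeros(len(ftir_axis))))


# ---------------------------------------------------------------------------
# Whole chain
# ---------------------------------------------------------------------------

class TestChain:
    def test_chain_outputs_normalized_baseline_corrected(self, rng, ftir_axis):
        x = ftir_axis.values
        rows = [
            gaussian_band(x, 1650, 60, 1.0)
            + gaussian_band(x, 2900, 90, 0.6)
            + 0.1
            + 1e-4 * (x - 900)  # drift
            + rng.normal(0, 1e-3, x.size)
            for _ in range(5)
        ]
        ds = make_dataset(ftir_axis, rows, ["tumor"] * 5)
        out, report = preprocess_dataset(ds, PreprocessConfig.for_modality("ftir"))
        assert report["n_rejected_snr"] == 0
        areas = np.trapezoid(out.intensities, x, axis=1)
        assert np.allclose(areas, 1.0, atol=1e-9)
        assert np.all(out.intensities >= 0.0)

    def test_normalize_then_normalize_is_identity(self, rng, ftir_axis):
        y = rng.random(len(ftir_axis)) + 0.2
        once = area_normalize(Spectrum(ftir_axis, y))
        twice = area_normalize(once)
        assert np.allclose(once.intensity, twice.intensity, atol=1e-12)
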