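"""Spectral signatures: FFT magnitude, radial curves, Butterworth bands."""

import numpy as np
import pytest

import radiopos as rp
from radiopos.freq_signature import _radial_frequency_grid
from radiopos.io_prep import ValidationError

from conftest import random_image


def brute_force_magnitude(pixels):
    """Direct double-sum DFT with 1/(MN) normalization, centred."""
    f = pixels.astype(np.float64)
    m, n = f.shape
    x = np.arange(m)[:, None]
    y = np.arange(n)[None, :]
    out = np.empty((m, n), dtype=np.complex128)
    for uc in range(m):
        u = uc - m // 2  # centred index -> signed frequency
        for vc in range(n):
            v = vc - n // 2
            phase = np.exp(-2j * np.pi * (u * x / m + v * y / n))
            out[uc, vc] = (f * phase).sum() / (m * n)
    return np.abs(out)


def brute_force_curve(mag, fraction, n_bins):
    """Ring means by explicit per-cell enumeration."""
    m, n = mag.shape
    fu = np.fft.fftshift(np.fft.fftfreq(m))
    fv = np.fft.fftshift(np.fft.fftfreq(n))
    r_max = np.hypot(fu[:, None], fv[None, :]).max()
    r_lim = fraction * r_max
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(m):
        for j in range(n):
            r = np.hypot(fu[i], fv[j])
            if r <= 0 or r > r_lim:
                continue
            b = min(int(r / r_lim * n_bins), n_bins - 1)
            sums[b] += mag[i, j]
            counts[b] += 1
    curve = np.full(n_bins, np.nan)
    curve[counts > 0] = sums[counts > 0] / counts[counts > 0]
    idx = np.arange(n_bins)
    good = counts > 0
    curve[~good] = np.interp(idx[~good], idx[good], curve[good])
    return curve


class TestFftMagnitude:
    def test_constant_image_is_pure_dc(self):
        img = rp.RadiographImage(pixels=np.full((8, 8), 77))
        mag = rp.fft_magnitude(img)
        assert mag[4, 4] == pytest.approx(77.0)
        off_dc = mag.copy()
        off_dc[4, 4] = 0
        assert np.abs(off_dc).max() < 1e-9

    def test_centre_equals_image_mean(self, rng):
        img = random_image(rng, (10, 12))
        mag = rp.fft_magnitude(img)
        assert mag[5, 6] == pytest.approx(img.pixels.mean(), rel=1e-12)

    @pytest.mark.parametrize("shape", [(5, 5), (8, 8), (7, 12)])
    def test_matches_double_sum_oracle(self, rng, shape):
        img = random_image(rng, shape)
        mag = rp.fft_magnitude(img)
        oracle = brute_force_magnitude(img.pixels)
        scale = max(oracle.max(), 1.0)
        assert np.abs(mag - oracle).max() / scale < 1e-9


class TestLowFreqCurve:
    def test_constant_image_gives_zero_curve(self):
        img = rp.RadiographImage(pixels=np.full((200, 200), 500))
        sig = rp.low_freq_curve(rp.fft_magnitude(img), fraction=0.05, n_bins=16)
        assert np.all(sig.curve == 0)
        assert sig.auc == 0

    def test_matches_ring_enumeration_oracle(self, rng):
        img = random_image(rng, (64, 64))
        mag = rp.fft_magnitude(img)
        sig = rp.low_freq_curve(mag, fraction=0.1, n_bins=32)
        np.testing.assert_allclose(
            sig.curve, brute_force_curve(mag, 0.1, 32), rtol=1e-12, atol=1e-12
        )

    def test_high_frequency_checkerboard_is_invisible(self, rng):
        # smooth blob vs blob + Nyquist checkerboard: identical low-freq curves
        m = 64
        yy, xx = np.mgrid[:m, :m]
        blob = 20000 * np.exp(-(((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 12.0**2)))
        base = np.round(blob).astype(np.int64) + 1000
        checker = 500 * ((-1) ** (yy + xx))
        a = rp.low_freq_curve(
            rp.fft_magnitude(rp.RadiographImage(pixels=base)), 0.05, 32
        )
        b = rp.low_freq_curve(
            rp.fft_magnitude(rp.RadiographImage(pixels=base + checker)), 0.05, 32
        )
        np.testing.assert_allclose(a.curve, b.curve, rtol=1e-9, atol=1e-9)

    def test_transpose_invariance_for_isotropic_input(self):
        m = 96
        yy, xx = np.mgrid[:m, :m]
        blob = np.round(
            30000 * np.exp(-(((yy - 48) ** 2 + (xx - 48) ** 2) / (2 * 15.0**2)))
        ).astype(np.int64)
        a = rp.low_freq_curve(rp.fft_magnitude(rp.RadiographImage(pixels=blob)), 0.06, 24)
        b = rp.low_freq_curve(
            rp.fft_magnitude(rp.RadiographImage(pixels=blob.T.copy())), 0.06, 24
        )
        np.testing.assert_allclose(a.curve, b.curve, rtol=1e-6, atol=1e-6)

    def test_curve_scales_linearly_with_gain(self, rng):
        img = random_image(rng, (64, 64), hi=20000)
        tripled = img.with_pixels(img.pixels * 3)
        a = rp.low_freq_curve(rp.fft_magnitude(img), 0.1, 32)
        b = rp.low_freq_curve(rp.fft_magnitude(tripled), 0.1, 32)
        np.testing.assert_allclose(b.curve, 3 * a.curve, rtol=1e-9)
        assert b.auc == pytest.approx(3 * a.auc, rel=1e-9)

    def test_auc_recomputable_and_nonnegative(self, rng):
        img = random_image(rng, (64, 64))
        sig = rp.low_freq_curve(rp.fft_magnitude(img), 0.1, 32)
        assert sig.auc >= 0
        assert sig.auc == pytest.approx(float(np.trapezoid(sig.curve)))

    def test_too_small_band_rejected(self, rng):
        img = random_image(rng, (16, 16))
        with pytest.raises(ValidationError):
            rp.low_freq_curve(rp.fft_magnitude(img), fraction=0.001, n_bins=32)

    def test_invalid_fraction_rejected(self, rng):
        img = random_image(rng, (16, 16))
        with pytest.raises(ValidationError):
            rp.low_freq_curve(rp.fft_magnitude(img), fraction=0.7)


class TestButterworthBand:
    def test_nyquist_wide_band_is_identity_minus_mean(self, rng):
        img = random_image(rng, (32, 32), lo=10000, hi=50000)
        out = rp.butterworth_band(img, rp.BandSpec(0.0, 0.5, order=1))
        f = img.pixels.astype(float)
        expected = np.floor(np.clip(f - f.mean(), 0, 65535) + 0.5)
        assert np.abs(out.pixels - expected).max() <= 1

    def test_constant_image_filters_to_zero(self):
        img = rp.RadiographImage(pixels=np.full((16, 16), 4000))
        out = rp.butterworth_band(img, rp.BandSpec(0.05, 0.3))
        assert (out.pixels == 0).all()

    @pytest.mark.parametrize("order", [2, 3])
    def test_in_band_grating_passes_out_of_band_blocked(self, order):
        m = 128
        x = np.arange(m)[None, :] * np.ones((m, 1))
        band = rp.BandSpec(0.05, 0.25, order=order)
        responses = []
        for freq in (0.12, 0.48):
            grating = np.round(30000 + 12000 * np.sin(2 * np.pi * freq * x)).astype(
                np.int64
            )
            out = rp.butterworth_band(rp.RadiographImage(pixels=grating), band)
            responses.append(out.pixels.astype(float).std())
        assert responses[0] / responses[1] > 10

    def test_band_validation(self):
        with pytest.raises(ValidationError):
            rp.BandSpec(0.3, 0.2)
        with pytest.raises(ValidationError):
            rp.BandSpec(0.0, 0.6)


class TestBuildLibrary:
    def _groups(self, rng, n_each):
        return {
            p: [random_image(rng, (80, 80)) for _ in range(n_each)]
            for p in rp.POSITIONS
        }

    def test_single_image_library_equals_its_curve(self, rng):
        groups = self._groups(rng, 1)
        lib = rp.build_library(groups, fraction=0.1, n_bins=16)
        img = groups["head"][0]
        sig = rp.compute_signature(rp.preprocess(img), fraction=0.1, n_bins=16)
        np.testing.assert_allclose(lib.entries["head"].curve, sig.curve)

    def test_mean_of_identical_members(self, rng):
        img = random_image(rng, (80, 80))
        groups = {p: [img, img, img] for p in rp.POSITIONS}
        lib = rp.build_library(groups, fraction=0.1, n_bins=16)
        sig = rp.compute_signature(rp.preprocess(img), fraction=0.1, n_bins=16)
        for p in rp.POSITIONS:
            np.testing.assert_allclose(lib.entries[p].curve, sig.curve)

    def test_two_member_arithmetic_mean(self, rng):
        a, b = random_image(rng, (80, 80)), random_image(rng, (80, 80))
        groups = {p: [a, b] for p in rp.POSITIONS}
        lib = rp.build_library(groups, fraction=0.1, n_bins=16)
        ca = rp.compute_signature(rp.preprocess(a), fraction=0.1, n_bins=16).curve
        cb = rp.compute_signature(rp.preprocess(b), fraction=0.1, n_bins=16).curve
        np.testing.assert_allclose(lib.entries["lungs"].curve, (ca + cb) / 2)

    def test_missing_position_rejected(self, rng):
        groups = self._groups(rng, 1)
        del groups["pelvis"]
        with pytest.raises(ValidationError, match="pelvis"):
            rp.build_library(groups, fraction=0.1, n_bins=16)

    def test_save_load_roundtrip(self, tmp_path, small_library):
        small_library.save(tmp_path / "lib.json")
        back = rp.SignatureLibrary.load(tmp_path / "lib.json")
        assert back.fraction == small_library.fraction
        assert back.n_bins == small_library.n_bins
        assert back.norm == small_library.norm
        for p in rp.POSITIONS:
            np.testing.assert_array_equal(
                back.entries[p].curve, small_library.entries[p].curve
            )

    def test_csv_export(self, tmp_path, small_library):
        small_library.export_csv(tmp_path / "curves.csv")
        lines = (tmp_path / "curves.csv").read_text().strip().split("\n")
        assert lines[0] == "position,bin_index,amplitude"
        assert len(lines) == 1 + 6 * small_library.n_bins
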