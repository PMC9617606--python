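"""SSNR model, CTF, Wiener deconvolution, and statistical masks."""

import numpy as np
import pytest
from scipy import optimize

from isotomo.preprocess import (DeconvParams, MaskParams, ctf_1d, deconvolve,
                                density_mask, make_mask, ssnr, std_mask,
                                wiener_gain)
from isotomo.tomio import Tomogram


@pytest.fixture
def params():
    return DeconvParams(snrfalloff=1.0, strength=1.0, highpass_freq=0.02,
                        defocus=4.0, voltage=300.0, cs=2.7,
                        amplitude_contrast=0.07, pixel_size=10.0)


class TestSsnr:
    def test_zero_at_dc(self, params):
        assert ssnr(0.0, params) == 0.0

    def test_value_beyond_highpass(self, params):
        # independent scalar computation: H = 1 for f >= f_hp
        got = ssnr(0.05, params)
        assert got == pytest.approx(10.0 * np.exp(-5.0), rel=1e-12)

    def test_strictly_decreasing_beyond_highpass(self, params):
        f = np.linspace(params.highpass_freq, 0.5, 200)
        v = ssnr(f, params)
        assert (np.diff(v) < 0).all()

    def test_negative_frequency_rejected(self, params):
        with pytest.raises(ValueError):
            ssnr(-0.1, params)

    def test_nonnegative(self, params):
        assert (ssnr(np.linspace(0, 0.5, 100), params) >= 0).all()


class TestCtf:
    def test_dc_value_is_minus_amplitude_contrast(self, params):
        assert ctf_1d(0.0, params) == pytest.approx(-params.amplitude_contrast)

    def test_bounded(self, params):
        v = ctf_1d(np.linspace(0, 0.5, 2000), params)
        assert (np.abs(v) <= 1.0 + 1e-12).all()

    def test_first_zero_matches_root_finder(self, params):
        # independent oracle: brute-force root of CTF on a fine grid + brentq
        f = np.linspace(1e-5, 0.5, 20000)
        v = ctf_1d(f, params)
        sign_change = np.flatnonzero(np.diff(np.sign(v)) != 0)[0]
        bracket = (f[sign_change], f[sign_change + 1])
        root = optimize.brentq(lambda x: float(ctf_1d(x, params)), *bracket)
        assert bracket[0] <= root <= bracket[1]
        assert abs(float(ctf_1d(root, params))) < 1e-9

    def test_underfocus_gives_negative_low_freq_contrast(self, params):
        assert ctf_1d(0.02, params) < 0


class TestWienerDeconvolve:
    def test_gain_approaches_inverse_ctf_at_huge_snr(self, params):
        p = DeconvParams(**{**params.__dict__, "strength": 12.0})
        f = np.array([0.05, 0.1, 0.2])
        np.testing.assert_allclose(wiener_gain(f, p), 1.0 / ctf_1d(f, p), rtol=1e-3)

    def test_gain_zero_where_ssnr_zero(self, params):
        assert wiener_gain(np.array([0.0]), params)[0] == 0.0

    def test_gain_finite_at_ctf_zeros(self, params):
        f = np.linspace(0.0, 0.5, 5000)
        assert np.isfinite(wiener_gain(f, params)).all()

    def test_white_noise_output_spectrum_matches_gain(self, params, rng):
        # oracle: |W(f)|^2 computed directly on the same radial grid
        data = rng.standard_normal((48, 48, 48)).astype(np.float32)
        vol = Tomogram(data, pixel_size=params.pixel_size)
        out = deconvolve(vol, params)
        fin = np.abs(np.fft.fftn(data)) ** 2
        fout = np.abs(np.fft.fftn(out.data)) ** 2
        freqs = [np.fft.fftfreq(48)] * 3
        kz, ky, kx = np.meshgrid(*freqs, indexing="ij")
        f = np.sqrt(kz ** 2 + ky ** 2 + kx ** 2).ravel()
        w2 = wiener_gain(f, params) ** 2
        # exclude near-suppressed frequencies where float32 round-off dominates
        sel = (w2 > 1e-4) & (fin.ravel() > 0)
        ratio = fout.ravel()[sel] / fin.ravel()[sel]
        np.testing.assert_allclose(ratio, w2[sel], rtol=1e-3)

    def test_linearity(self, params, rng):
        a = rng.standard_normal((16, 16, 16)).astype(np.float32)
        b = rng.standard_normal((16, 16, 16)).astype(np.float32)
        pa, pb = 2.0, -0.5
        lhs = deconvolve(Tomogram(pa * a + pb * b, pixel_size=10.0), params).data
        rhs = (pa * deconvolve(Tomogram(a, pixel_size=10.0), params).data
               + pb * deconvolve(Tomogram(b, pixel_size=10.0), params).data)
        np.testing.assert_allclose(lhs, rhs, atol=1e-4)

    def test_dc_preserved(self, params, rng):
        data = rng.standard_normal((16, 16, 16)).astype(np.float32) + 5.0
        out = deconvolve(Tomogram(data, pixel_size=10.0), params)
        assert out.data.mean() == pytest.approx(data.mean(), rel=1e-5)


class TestMasks:
    def test_density_mask_all_true_at_100_percent(self, random_tomogram):
        p = MaskParams(density_percentage=100.0)
        assert density_mask(random_tomogram, p).all()

    def test_density_mask_keeps_half_of_random_field(self, random_tomogram):
        p = MaskParams(density_percentage=50.0, gaussian_sigma=0.0, max_window=1)
        mask = density_mask(random_tomogram, p)
        assert abs(mask.mean() - 0.5) < 0.01

    def test_density_mask_concentrates_on_blob(self):
        data = np.zeros((32, 32, 32), dtype=np.float32)
        data[14:18, 14:18, 14:18] = -10.0  # dense = dark before inversion
        tomo = Tomogram(data, pixel_size=1.0)
        p = MaskParams(density_percentage=2.0, gaussian_sigma=1.0, max_window=3)
        mask = density_mask(tomo, p)
        assert mask[15, 15, 15]
        assert not mask[2, 2, 2]

    def test_std_mask_all_true_at_100(self, random_tomogram):
        assert std_mask(random_tomogram, MaskParams(std_percentage=100.0)).all()

    def test_std_mask_empty_on_constant_volume(self):
        tomo = Tomogram(np.ones((16, 16, 16), dtype=np.float32), pixel_size=1.0)
        with pytest.warns(UserWarning):
            mask = std_mask(tomo, MaskParams(std_percentage=50.0))
        assert not mask.any()

    def test_std_mask_selects_textured_half(self, rng):
        data = np.zeros((16, 16, 32), dtype=np.float32)
        data[:, :, 16:] = rng.standard_normal((16, 16, 16))
        tomo = Tomogram(data, pixel_size=1.0)
        mask = std_mask(tomo, MaskParams(std_percentage=50.0, std_window=3))
        in_textured = mask[:, :, 16:].sum()
        assert in_textured / mask.sum() >= 0.95

    def test_intersection_subset_of_parents(self, random_tomogram):
        p = MaskParams(density_percentage=40.0, std_percentage=60.0)
        inter = make_mask(random_tomogram, p)
        assert not (inter & ~density_mask(random_tomogram, p)).any()
        assert not (inter & ~std_mask(random_tomogram, p)).any()

    def test_z_crop_slice_arithmetic(self):
        data = np.random.default_rng(0).standard_normal((100, 8, 8)).astype(np.float32)
        tomo = Tomogram(data, pixel_size=1.0)
        p = MaskParams(density_percentage=100.0, std_percentage=100.0, z_crop=0.1)
        mask = make_mask(tomo, p)
        assert not mask[:10].any()
        assert not mask[90:].any()
        assert mask[10:90].all()

    def test_all_true_with_defaults_disabled(self, random_tomogram):
        p = MaskParams(density_percentage=100.0, std_percentage=100.0, z_crop=0.0)
        assert make_mask(random_tomogram, p).all()


def test_mask_params_validation():
    with pytest.raises(ValueError):
        MaskParams(density_percentage=0.0)
    with pytest.raises(ValueError):
        MaskParams(max_window=4)
    with pytest.raises(ValueError):
        MaskParams(z_crop=0.5)
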