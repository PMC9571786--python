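"""Wavelet transform: filter shape, linearity, oracle equivalence,
synchrosqueezing, inversion and RGB rendering."""

import numpy as np
import pytest

from ramangrade.tfr import (
    RGBImage,
    Scalogram,
    WaveletParams,
    bilinear_resize,
    cwt,
    gmw_frequency_response,
    invert_cwt,
    jet_colormap,
    project_to_band,
    scalogram_to_rgb,
    synchrosqueeze,
)


class TestGmwFilter:
    def test_peak_at_morse_peak_frequency(self):
        p = WaveletParams(gamma=3, beta=60)
        n = 4096
        resp = gmw_frequency_response(p, 1.0, n)
        peak_omega = 2 * np.pi * np.argmax(resp) / n
        assert peak_omega == pytest.approx((60 / 3) ** (1 / 3), rel=1e-3)

    def test_zero_response_at_dc(self):
        resp = gmw_frequency_response(WaveletParams(), 1.0, 64)
        assert resp[0] == 0.0

    def test_doubling_scale_halves_peak_frequency(self):
        p = WaveletParams()
        n = 8192
        f1 = np.argmax(gmw_frequency_response(p, 2.0, n))
        f2 = np.argmax(gmw_frequency_response(p, 4.0, n))
        assert f2 == pytest.approx(f1 / 2, abs=1)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            gmw_frequency_response(WaveletParams(), 0.0, 64)


class TestCwt:
    def test_zero_signal_gives_zero_scalogram(self):
        sc = cwt(np.zeros(64), WaveletParams(nv=8))
        assert np.abs(sc.values).max() == 0.0

    def test_linearity(self, rng):
        p = WaveletParams(nv=8)
        x = rng.standard_normal(64)
        a = cwt(3.5 * x, p).values
        b = 3.5 * cwt(x, p).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="8"):
            cwt(np.ones(5), WaveletParams())

    def test_tone_ridge_at_matching_scale(self):
        p = WaveletParams(nv=16)
        f0 = 0.08
        x = np.cos(2 * np.pi * f0 * np.arange(512))
        sc = cwt(x, p)
        ridge_row = np.argmax(np.abs(sc.values).mean(axis=1))
        freqs = p.scale_to_frequency(sc.scales)
        # within one voice of the tone frequency
        assert abs(np.log2(freqs[ridge_row] / f0)) <= 1.0 / p.nv + 1e-9

    def test_oracle_direct_quadrature_equivalence(self, rng):
        """The fast FFT transform matches an O(N^2) direct evaluation of the
        wavelet integral at randomly chosen (scale, translation) pairs."""
        p = WaveletParams(nv=8)
        n = 48
        x = rng.standard_normal(n)
        sc = cwt(x, p, boundary="periodic")
        k = np.arange(n)
        for ai in rng.choice(len(sc.scales), 10, replace=False):
            Psi = gmw_frequency_response(p, sc.scales[ai], n)
            for b in rng.choice(n, 2, replace=False):
                u = np.arange(n)[:, None] - b
                psi = (Psi[None, :] * np.exp(2j * np.pi * k[None, :] * u / n)
                       ).sum(axis=1) / n
                w_direct = np.sum(x * np.conj(psi))
                assert abs(w_direct - sc.values[ai, b]) <= \
                    1e-6 * max(abs(sc.values[ai, b]), 1e-12)

    def test_shift_covariance_interior(self, rng):
        p = WaveletParams(nv=8)
        x = rng.standard_normal(256)
        k = 7
        a = cwt(np.roll(x, k), p, boundary="periodic").values
        b = np.roll(cwt(x, p, boundary="periodic").values, k, axis=1)
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestSynchrosqueeze:
    def test_zero_in_zero_out(self):
        p = WaveletParams(nv=8)
        x = np.zeros(64)
        sc = cwt(x, p)
        out = synchrosqueeze(sc, x, p)
        assert np.abs(out.values).max() == 0.0
        assert out.axis == "frequency"

    def test_magnitude_only_input_rejected(self):
        p = WaveletParams(nv=8)
        x = np.sin(np.arange(64.0))
        sc = cwt(x, p)
        mag = Scalogram(sc.magnitude(), sc.scales, sc.positions, axis="scale")
        with pytest.raises(ValueError, match="complex"):
            synchrosqueeze(mag, x, p)

    def test_pure_tone_energy_concentrates(self):
        p = WaveletParams(nv=32)
        f0 = 0.05
        x = np.cos(2 * np.pi * f0 * np.arange(512))
        out = synchrosqueeze(cwt(x, p), x, p)
        e = out.magnitude() ** 2
        fbin = np.argmin(np.abs(out.scales - f0))
        frac = e[max(0, fbin - 2):fbin + 3].sum() / e.sum()
        assert frac >= 0.90

    def test_two_tones_make_disjoint_ridges(self):
        p = WaveletParams(nv=32)
        t = np.arange(1024)
        x = np.cos(2 * np.pi * 0.02 * t) + np.cos(2 * np.pi * 0.2 * t)
        out = synchrosqueeze(cwt(x, p), x, p)
        e = out.magnitude() ** 2
        row_energy = e.sum(axis=1) / e.sum()
        b1 = np.argmin(np.abs(out.scales - 0.02))
        b2 = np.argmin(np.abs(out.scales - 0.2))
        near1 = row_energy[b1 - 3:b1 + 4].sum()
        near2 = row_energy[b2 - 3:b2 + 4].sum()
        between = row_energy[b1 + 10:b2 - 10].sum()
        assert near1 > 0.3 and near2 > 0.3 and between < 0.05

    def test_frequency_marginal_conserved_exactly(self, rng):
        """Reassignment moves coefficients between bins without changing
        their sum: the frequency marginal equals the d(log a)-weighted scale
        marginal (restricted to cells with an in-range instantaneous
        frequency)."""
        p = WaveletParams(nv=16)
        x = np.cos(2 * np.pi * 0.07 * np.arange(256))
        sc = cwt(x, p)
        out = synchrosqueeze(sc, x, p)
        # on a clean tone every significant cell maps in-range
        lhs = out.values.sum(axis=0)
        rhs = sc.values.sum(axis=0) * (np.log(2) / p.nv)
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 0.01


class TestInversion:
    def test_zero_round_trip(self):
        p = WaveletParams(nv=8)
        x = np.zeros(64)
        np.testing.assert_allclose(invert_cwt(cwt(x, p), p), 0.0)

    def test_two_band_spectrum_round_trip(self):
        p = WaveletParams(nv=32)
        grid = np.linspace(200, 3400, 1601)
        sig = (np.exp(-((grid - 960) ** 2) / (2 * 15**2))
               + 0.7 * np.exp(-((grid - 1380) ** 2) / (2 * 20**2)))
        sig = (sig - sig.mean()) / sig.std()
        sig = project_to_band(sig, p)  # band-limit within the scale range
        rec = invert_cwt(cwt(sig, p, boundary="periodic"), p)
        assert np.linalg.norm(rec - sig) / np.linalg.norm(sig) <= 0.05

    def test_synchrosqueezed_tone_round_trip(self):
        p = WaveletParams(nv=32)
        x = np.cos(2 * np.pi * 0.05 * np.arange(512))
        out = synchrosqueeze(cwt(x, p), x, p)
        rec = invert_cwt(out, p)
        r = np.corrcoef(rec[40:-40], x[40:-40])[0, 1]
        assert r >= 0.99

    def test_axis_mismatch_rejected(self):
        p = WaveletParams(nv=8)
        sc = cwt(np.sin(np.arange(64.0)), p)
        bad = Scalogram(sc.values[:-3], sc.scales[:-3], sc.positions, "scale")
        with pytest.raises(ValueError, match="match"):
            invert_cwt(bad, p)


class TestRendering:
    def test_jet_endpoints(self):
        np.testing.assert_allclose(jet_colormap(np.array(0.0)), [0.0, 0.0, 0.5])
        np.testing.assert_allclose(jet_colormap(np.array(1.0)), [0.5, 0.0, 0.0])

    def test_output_shape_and_range(self, rng):
        sc = cwt(rng.standard_normal(128), WaveletParams(nv=8))
        img = scalogram_to_rgb(sc)
        assert img.shape == (224, 224, 3)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_constant_scalogram_maps_to_value0_color(self):
        sc = Scalogram(np.ones((10, 20)), np.arange(1, 11.0),
                       np.arange(20), "scale")
        img = scalogram_to_rgb(sc)
        expected = np.broadcast_to(jet_colormap(np.zeros(1))[0], (224, 224, 3))
        np.testing.assert_allclose(img.pixels, expected)

    def test_max_pixel_renders_colormap_endpoint(self, rng):
        vals = rng.random((32, 32))
        vals[10, 12] = 10.0  # global max well above the rest
        sc = Scalogram(vals, np.arange(1, 33.0), np.arange(32), "scale")
        img = scalogram_to_rgb(sc, out_size=32)
        flat = img.pixels.reshape(-1, 3)
        target = jet_colormap(np.ones(1))[0]
        assert np.min(np.abs(flat - target).sum(axis=1)) < 0.15

    def test_invariant_to_positive_rescaling(self, rng):
        vals = rng.random((16, 16)) + 0.1
        sc1 = Scalogram(vals, np.arange(1, 17.0), np.arange(16), "scale")
        sc2 = Scalogram(vals * 7.3, np.arange(1, 17.0), np.arange(16), "scale")
        np.testing.assert_allclose(scalogram_to_rgb(sc1, out_size=32).pixels,
                                   scalogram_to_rgb(sc2, out_size=32).pixels,
                                   atol=1e-12)

    def test_bilinear_resize_constant_preserved(self):
        out = bilinear_resize(np.full((7, 7), 3.0), 224, 224)
        np.testing.assert_allclose(out, 3.0)

    def test_rgb_image_shape_validation(self):
        with pytest.raises(ValueError):
            RGBImage(np.zeros((224, 224)))
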