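"""Welch transfer function estimates, band averages, coherence rule."""

import numpy as np
import pytest

from autoreg.preprocessing import DataError, UniformSignal
from autoreg.tfa import BANDS, band_average, coherence_criterion, welch_transfer


def _noise_signal(rng, n=3000, rate=5.0):
    return UniformSignal(rng.standard_normal(n), rate=rate)


def dft_transfer_oracle(p, v, rate, seg_len=512, overlap=0.5):
    """Direct per-segment DFT estimate: explicit loop, no library call.

    Mirrors the density-scaled Welch convention: Hann window, per-segment
    linear detrend, conj(P)*V cross spectrum, one-sided doubling.
    """
    step = int(seg_len * (1 - overlap))
    m = np.arange(seg_len)
    win = 0.5 - 0.5 * np.cos(2 * np.pi * m / seg_len)  # periodic Hann
    n_seg = 1 + (len(p) - seg_len) // step
    spp = svv = spv = 0.0
    for s in range(n_seg):
        seg_p = p[s * step : s * step + seg_len].copy()
        seg_v = v[s * step : s * step + seg_len].copy()
        for seg in (seg_p, seg_v):
            coef = np.polyfit(m, seg, 1)
            seg -= np.polyval(coef, m)
        P = np.fft.rfft(win * seg_p)
        V = np.fft.rfft(win * seg_v)
        spp = spp + (P.conj() * P).real
        svv = svv + (V.conj() * V).real
        spv = spv + P.conj() * V
    scale = 1.0 / (rate * np.sum(win**2))
    spp, svv, spv = spp * scale / n_seg, svv * scale / n_seg, spv * scale / n_seg
    for arr in (spp, svv):
        arr[1:-1] *= 2
    spv[1:-1] *= 2
    freqs = np.fft.rfftfreq(seg_len, 1 / rate)
    h = spv / spp
    coh = np.abs(spv) ** 2 / (spp * svv)
    return freqs, np.abs(h), np.angle(h), coh


class TestWelchTransfer:
    def test_identity_system(self, rng):
        p = _noise_signal(rng)
        est = welch_transfer(p, p)
        assert np.allclose(est.gain[1:], 1.0, atol=1e-8)
        assert np.allclose(est.phase[1:], 0.0, atol=1e-8)
        assert np.allclose(est.coherence[1:], 1.0, atol=1e-8)

    def test_pure_scaling(self, rng):
        p = _noise_signal(rng)
        v = UniformSignal(2.0 * p.values, rate=p.rate)
        est = welch_transfer(p, v)
        assert np.allclose(est.gain[1:], 2.0, atol=1e-8)
        assert np.allclose(est.phase[1:], 0.0, atol=1e-8)

    def test_pure_delay_phase_slope(self, rng):
        rate = 5.0
        delay_s = 1.0
        shift = int(delay_s * rate)
        x = rng.standard_normal(4000)
        p = UniformSignal(x[shift:], rate=rate)
        v = UniformSignal(x[: len(x) - shift], rate=rate)  # v lags p by 1 s
        est = welch_transfer(p, v)
        sel = (est.freqs >= 0.02) & (est.freqs <= 0.2)
        expected = -2 * np.pi * est.freqs[sel] * delay_s
        assert np.allclose(np.unwrap(est.phase[sel]), expected, rtol=0.05, atol=0.01)

    def test_matches_direct_dft_oracle(self, rng):
        p = UniformSignal(rng.standard_normal(1024), rate=5.0)
        v = UniformSignal(
            np.roll(p.values, 2) + 0.1 * rng.standard_normal(1024), rate=5.0
        )
        est = welch_transfer(p, v)
        f, gain, phase, coh = dft_transfer_oracle(p.values, v.values, 5.0)
        assert np.allclose(est.freqs, f, rtol=1e-12)
        assert np.allclose(est.gain, gain, rtol=1e-10)
        assert np.allclose(est.phase, phase, rtol=1e-10, atol=1e-12)
        assert np.allclose(est.coherence, coh, rtol=1e-10)

    def test_offset_invariance_of_gain(self, rng):
        p = _noise_signal(rng)
        v = UniformSignal(0.8 * p.values + 0.05 * rng.standard_normal(len(p)), rate=5.0)
        est1 = welch_transfer(p, v)
        est2 = welch_transfer(
            UniformSignal(p.values + 100.0, rate=5.0),
            UniformSignal(v.values + 57.0, rate=5.0),
        )
        assert np.allclose(est1.gain[1:], est2.gain[1:], rtol=1e-8)

    def test_too_short_input_rejected(self, rng):
        p = UniformSignal(rng.standard_normal(600), rate=5.0)
        with pytest.raises(DataError):
            welch_transfer(p, p)


class TestBandAverage:
    def _flat_estimate(self, gain_value=1.5):
        freqs = np.fft.rfftfreq(512, 0.2)  # 5 Hz resolution grid
        n = freqs.size
        from autoreg.tfa import SpectralEstimate

        return SpectralEstimate(
            freqs=freqs,
            gain=np.full(n, gain_value),
            phase=np.zeros(n),
            coherence=np.ones(n),
            n_windows=5,
        )

    def test_flat_gain_mean(self):
        s = band_average(self._flat_estimate(1.5), "LF")
        assert s.mean_gain == pytest.approx(1.5)

    def test_bin_inclusion_half_open(self):
        est = self._flat_estimate()
        for name, (lo, hi) in BANDS.items():
            s = band_average(est, name)
            expected = [f for f in est.freqs if lo <= f < hi]
            assert s.n_bins == len(expected)

    def test_single_bin_band(self):
        est = self._flat_estimate()
        est.gain[:] = np.arange(est.freqs.size)
        f0 = est.freqs[7]
        s = band_average(est, (f0, f0 + 1e-6))
        assert s.mean_gain == pytest.approx(7.0)

    def test_empty_band_rejected(self):
        from autoreg.preprocessing import ParameterError

        with pytest.raises(ParameterError):
            band_average(self._flat_estimate(), (0.0001, 0.0002))


class TestCoherenceCriterion:
    def test_closed_form_threshold_five_windows(self):
        est = TestBandAverage()._flat_estimate()
        s = coherence_criterion(est, "VLF", alpha=0.05)
        assert s.coherence_threshold == pytest.approx(1 - 0.05 ** (1 / 4))
        assert s.coherence_threshold == pytest.approx(0.527, abs=0.001)

    def test_unit_coherence_accepted(self):
        est = TestBandAverage()._flat_estimate()
        for L in (2, 3, 10):
            est.n_windows = L
            assert coherence_criterion(est, "LF").accepted

    def test_zero_coherence_rejected(self):
        est = TestBandAverage()._flat_estimate()
        est.coherence[:] = 0.0
        assert not coherence_criterion(est, "LF").accepted
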