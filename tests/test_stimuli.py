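"""Stimulus synthesis: calibration, FM/ITD/FFR/AM paradigms, event placement."""

import numpy as np
import pytest
from scipy.signal import hilbert

from tfs_assay import stimuli
from tfs_assay.stimuli import (
    StereoWaveform,
    StimulusSpec,
    db_spl_to_amplitude,
    erb,
    fractional_delay,
    synth_am_noise_trial,
    synth_ffr_sequence,
    synth_fm_tone,
    synth_itd_burst_pair,
    synth_itd_jump_trial,
)


def xcorr_lag_us(left: np.ndarray, right: np.ndarray, rate: float, upsample: int = 10) -> float:
    """Oracle: interaural lag via cross-correlation on a 10x-upsampled grid.

    Positive lag means the left channel leads (right is a delayed copy).
    """
    from scipy.signal import correlate

    n = left.size * upsample
    lf = np.fft.irfft(np.fft.rfft(left), n=n) * upsample
    rf = np.fft.irfft(np.fft.rfft(right), n=n) * upsample
    corr = correlate(rf, lf, mode="full", method="fft")
    lag_samples = np.argmax(corr) - (n - 1)
    return lag_samples / (rate * upsample) * 1e6


class TestCalibration:
    @pytest.mark.parametrize("level,cal,expected", [
        (100.0, 100.0, 1.0),
        (80.0, 100.0, 0.1),
        (70.0, 100.0, 10 ** (-1.5)),
    ])
    def test_level_to_amplitude(self, level, cal, expected):
        assert db_spl_to_amplitude(level, cal) == pytest.approx(expected, rel=1e-12)

    def test_clipping_level_rejected(self):
        with pytest.raises(ValueError):
            db_spl_to_amplitude(101.0, 100.0)

    def test_waveform_rejects_out_of_range_samples(self):
        with pytest.raises(ValueError):
            StereoWaveform(np.array([1.5]), np.array([1.5]), 48000)


class TestFmTone:
    def test_zero_depth_is_pure_tone(self):
        fm = synth_fm_tone(0.0)
        spec = StimulusSpec(paradigm="fm")
        t = np.arange(fm.n_samples) / fm.rate
        amp = db_spl_to_amplitude(spec.level_db_spl, spec.calibration)
        ref = amp * np.sin(2 * np.pi * 500.0 * t)
        ramp = np.ones(fm.n_samples)
        nr = round(0.005 * fm.rate)
        ramp[:nr] = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        ramp[-nr:] = ramp[:nr][::-1]
        assert np.allclose(fm.left, ref * ramp, atol=1e-12)
        assert np.array_equal(fm.left, fm.right)

    def test_instantaneous_frequency_extrema(self):
        # 13-Hz depth: instantaneous frequency must span 487-513 Hz.  A long
        # trial puts the modulation extrema well inside the Hilbert-safe core.
        fm = synth_fm_tone(13.0, StimulusSpec(paradigm="fm", duration_s=2.0))
        phase = np.unwrap(np.angle(hilbert(fm.left)))
        inst = np.diff(phase) * fm.rate / (2 * np.pi)
        core = inst[fm.rate // 10: -fm.rate // 10]
        assert core.min() == pytest.approx(487.0, abs=0.5)
        assert core.max() == pytest.approx(513.0, abs=0.5)

    def test_spectrum_bessel_sideband_ratios(self):
        # FFT oracle: a 5-Hz depth at a 2-Hz rate is modulation index 2.5, so
        # line magnitudes at 500 + 2k Hz must follow |J_k(2.5)|
        from scipy.special import jv

        spec = StimulusSpec(paradigm="fm", duration_s=4.0)
        fm = synth_fm_tone(5.0, spec)
        mags = np.abs(np.fft.rfft(fm.left))
        freqs = np.fft.rfftfreq(fm.n_samples, 1 / fm.rate)

        def mag_at(f):
            return mags[np.argmin(np.abs(freqs - f))]

        beta = 5.0 / 2.0
        assert mag_at(500.0) / mag_at(502.0) == pytest.approx(
            abs(jv(0, beta) / jv(1, beta)), abs=0.02)
        assert mag_at(504.0) / mag_at(502.0) == pytest.approx(
            abs(jv(2, beta) / jv(1, beta)), abs=0.02)
        # sidebands sit on a 2-Hz comb around the carrier
        assert mag_at(502.0) > 20 * np.median(mags[(freqs > 520) & (freqs < 560)])

    def test_depth_at_carrier_rejected(self):
        with pytest.raises(ValueError):
            synth_fm_tone(500.0)

    def test_ramp_profile_raised_cosine(self):
        fm = synth_fm_tone(0.0)
        nr = round(0.005 * fm.rate)
        t = np.arange(fm.n_samples) / fm.rate
        carrier = np.sin(2 * np.pi * 500.0 * t[:nr])
        expected = db_spl_to_amplitude(70, 100) * carrier * 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        assert np.allclose(fm.left[:nr], expected, atol=1e-6)


class TestItdBurstPair:
    def test_zero_itd_channels_identical(self):
        w = synth_itd_burst_pair(0.0)
        assert np.allclose(w.left, w.right, atol=1e-12)

    def test_cross_correlation_lag_flips_between_bursts(self):
        w = synth_itd_burst_pair(89.0, first_lead="left")
        n_burst = round(0.4 * w.rate)
        grid_us = 1e6 / (w.rate * 10)
        lag1 = xcorr_lag_us(w.left[:n_burst], w.right[:n_burst], w.rate)
        lag2 = xcorr_lag_us(w.left[n_burst:], w.right[n_burst:], w.rate)
        assert lag1 == pytest.approx(89.0, abs=grid_us)
        assert lag2 == pytest.approx(-89.0, abs=grid_us)

    def test_first_lead_symmetry(self):
        wl = synth_itd_burst_pair(500.0, first_lead="left")
        wr = synth_itd_burst_pair(500.0, first_lead="right")
        assert np.allclose(wl.left, wr.right, atol=1e-12)
        assert np.allclose(wl.right, wr.left, atol=1e-12)

    def test_itd_longer_than_burst_rejected(self):
        with pytest.raises(ValueError):
            synth_itd_burst_pair(500_000.0)


class TestItdJump:
    def test_interaural_lag_flips_and_preserves_magnitude(self):
        w = synth_itd_jump_trial(540.0, "LR")
        j = round(w.meta["jump_time_s"] * w.rate)
        grid_us = 1e6 / (w.rate * 10)
        pre = xcorr_lag_us(w.left[: j - 200], w.right[: j - 200], w.rate)
        post = xcorr_lag_us(w.left[j + 200:], w.right[j + 200:], w.rate)
        assert pre == pytest.approx(270.0, abs=max(grid_us, 3.0))
        assert post == pytest.approx(-270.0, abs=max(grid_us, 3.0))

    @pytest.mark.parametrize("jump_us", [20.0, 180.0, 540.0])
    def test_envelope_near_zero_at_jump(self, jump_us):
        w = synth_itd_jump_trial(jump_us)
        env = np.abs(hilbert(w.left))
        j = round(w.meta["jump_time_s"] * w.rate)
        assert env[j] < 0.01 * env.max()

    def test_jump_time_is_trough_nearest_one_second(self):
        w = synth_itd_jump_trial(180.0)
        tj = dict((lab, t) for t, lab in w.events)["itd_jump"]
        k = tj * 40.8
        assert k == pytest.approx(round(k), abs=1e-9)  # integer # of AM periods
        assert abs(tj - 1.0) <= 0.5 / 40.8             # nearest trough to 1 s

    def test_nonunit_depth_warns(self):
        spec = StimulusSpec(paradigm="itd_jump", duration_s=1.5, ramp_s=0.0,
                            am_rate_hz=40.8, am_depth=0.8)
        with pytest.warns(UserWarning):
            synth_itd_jump_trial(180.0, spec=spec)


class TestFfrSequence:
    def test_total_duration(self):
        for rate in (16000, 48000):
            w = synth_ffr_sequence(1, StimulusSpec(paradigm="ffr", duration_s=0.1,
                                                   ramp_s=0.005, rate=rate))
            assert w.duration == pytest.approx(0.351, abs=1.5 / rate)

    def test_polarity_antisymmetry_exact(self):
        wp = synth_ffr_sequence(+1)
        wn = synth_ffr_sequence(-1)
        assert np.array_equal(wp.left, -wn.left)

    def test_masker_probe_rms_ratio(self):
        w = synth_ffr_sequence(+1)
        seg = lambda t0: w.left[round((t0 + 0.02) * w.rate): round((t0 + 0.08) * w.rate)]
        rms = lambda x: np.sqrt(np.mean(x**2))
        ratio = rms(seg(0.150)) / rms(seg(0.0))
        assert ratio == pytest.approx(10 ** (10 / 20), rel=1e-3)

    def test_segment_events_recorded(self):
        w = synth_ffr_sequence(+1)
        labels = [lab for _, lab in w.events]
        assert labels == ["probe1", "masker", "probe2"]


class TestAmNoise:
    def test_erb_and_flanker_placement(self):
        assert erb(4000.0) == pytest.approx(456.5, abs=0.05)
        w = synth_am_noise_trial(0.5, 4000.0, seed=3)
        assert w.meta["flanker_hz"][0] == pytest.approx(4000 - 913.0, abs=0.1)
        assert w.meta["flanker_hz"][1] == pytest.approx(4000 + 913.0, abs=0.1)

    def test_zero_depth_matches_reference_spectrum(self):
        t0 = synth_am_noise_trial(0.0, 4000.0, seed=9)
        t1 = synth_am_noise_trial(0.0, 4000.0, seed=9)
        assert np.array_equal(t0.left, t1.left)

    def test_full_depth_envelope_peak_at_19_hz(self):
        w = synth_am_noise_trial(1.0, 4000.0, seed=5,
                                 spec=StimulusSpec(paradigm="am_noise", duration_s=2.0,
                                                   ramp_s=0.005, level_db_spl=75.0,
                                                   am_rate_hz=19.0))
        # Hilbert-envelope FFT oracle on the noise band alone (flankers notched out)
        spec = np.fft.rfft(w.left)
        freqs = np.fft.rfftfreq(w.n_samples, 1 / w.rate)
        spec[(freqs < 3600) | (freqs > 4400)] = 0
        band = np.fft.irfft(spec, n=w.n_samples)
        env = np.abs(hilbert(band))
        env_spec = np.abs(np.fft.rfft(env - env.mean()))
        peak_hz = freqs[np.argmax(env_spec)]
        assert peak_hz == pytest.approx(19.0, abs=0.5)

    def test_depth_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            synth_am_noise_trial(1.2, 4000.0)


class TestFractionalDelay:
    def test_delay_of_sinusoid_matches_phase_shift(self):
        rate = 48000
        t = np.arange(4800) / rate
        x = np.sin(2 * np.pi * 500 * t) * np.hanning(t.size)
        tau = 37.3e-6
        y = fractional_delay(x, tau, rate)
        lag = xcorr_lag_us(x, y, rate)
        assert lag == pytest.approx(tau * 1e6, abs=1e6 / (rate * 10))
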