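"""Calibrated stereo stimulus synthesis for the TFS assay battery.

All paradigms render to a :class:`StereoWaveform`: a two-channel, full-scale
(±1) sample buffer with a calibration constant (the sound pressure level a
full-scale sinusoid would produce) and machine-readable event annotations.

Interaural time differences are realized as *fractional-sample* delays via a
frequency-domain phase ramp, split symmetrically across the two channels
(±ITD/2), so the sample rate never quantizes the ITD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

DEFAULT_RATE = 48_000
DEFAULT_CALIBRATION_DB_SPL = 100.0

__all__ = [
    "StereoWaveform",
    "StimulusSpec",
    "db_spl_to_amplitude",
    "erb",
    "fractional_delay",
    "synth_fm_tone",
    "synth_itd_burst_pair",
    "synth_itd_jump_trial",
    "synth_ffr_sequence",
    "synth_am_noise_trial",
]


@dataclass
class StereoWaveform:
    """Two-channel audio buffer with calibration and event annotations.

    Parameters
    ----------
    left, right : ndarray
        Dimensionless samples, ``max(|sample|) <= 1``.
    rate : int
        Sample rate in samples/s.
    calibration : float
        dB SPL produced by a full-scale (peak 1) sinusoid.
    events : list of (float, str)
        ``(time_s, label)`` pairs; every time lies in ``[0, duration]``.
    """

    left: np.ndarray
    right: np.ndarray
    rate: int
    calibration: float = DEFAULT_CALIBRATION_DB_SPL
    events: list[tuple[float, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left/right channels must have equal length")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        peak = max(np.max(np.abs(self.left), initial=0.0), np.max(np.abs(self.right), initial=0.0))
        if peak > 1.0 + 1e-9:
            raise ValueError(f"samples exceed full scale (peak {peak:.3g})")
        for t, label in self.events:
            if not 0.0 <= t <= self.duration + 1e-9:
                raise ValueError(f"event {label!r} at {t} s outside [0, {self.duration}]")

    @property
    def duration(self) -> float:
        return self.left.size / self.rate

    @property
    def n_samples(self) -> int:
        return self.left.size

    def stereo(self) -> np.ndarray:
        """Samples as an ``(n, 2)`` array (left, right)."""
        return np.stack([self.left, self.right], axis=1)

    def save_wav(self, path, sidecar: bool = True) -> None:
        """Write a 32-bit float stereo WAV plus a JSON sidecar.

        The sidecar records the paradigm parameters, calibration and events
        so the rendered level is reproducible.
        """
        wavfile.write(str(path), self.rate, self.stereo().astype(np.float32))
        if sidecar:
            side = {
                "calibration_db_spl": self.calibration,
                "rate": self.rate,
                "events": [{"t": float(t), "label": lab} for t, lab in self.events],
                **self.meta,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(side, fh, indent=2)

    def events_tsv(self) -> str:
        """Events as TSV text (onset_s, code)."""
        lines = ["onset_s\tcode"] + [f"{t:.6f}\t{lab}" for t, lab in self.events]
        return "\n".join(lines) + "\n"


@dataclass
class StimulusSpec:
    """Paradigm-independent stimulus parameters with paradigm-specific extras."""

    paradigm: str = "fm"
    carrier_hz: float = 500.0
    level_db_spl: float = 70.0
    duration_s: float = 0.5
    ramp_s: float = 0.005
    rate: int = DEFAULT_RATE
    calibration: float = DEFAULT_CALIBRATION_DB_SPL
    # paradigm-specific
    fm_rate_hz: float = 2.0
    itd_us: float = 0.0
    gap_s: float = 0.0
    jump_us: float = 180.0
    jump_direction: str = "LR"
    am_rate_hz: float = 40.8
    am_depth: float = 1.0
    center_hz: float = 4000.0
    polarity: int = 1

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.ramp_s < 0 or self.ramp_s > self.duration_s / 2:
            raise ValueError("ramp must be >= 0 and <= half the segment duration")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError("am_depth must lie in [0, 1]")


def db_spl_to_amplitude(level_db_spl: float, calibration: float = DEFAULT_CALIBRATION_DB_SPL) -> float:
    """Linear peak amplitude of a sinusoid presented at ``level_db_spl``.

    ``calibration`` is the level produced by a full-scale sinusoid, so
    ``amplitude = 10**((level - calibration) / 20)``.  Levels above the
    calibration would clip and are rejected.
    """
    if calibration <= 0:
        raise ValueError("calibration must be a positive dB SPL value")
    if level_db_spl > calibration:
        raise ValueError(
            f"level {level_db_spl} dB SPL exceeds calibration {calibration} dB SPL (would clip)"
        )
    return float(10.0 ** ((level_db_spl - calibration) / 20.0))


def erb(f_hz: float) -> float:
    """Equivalent rectangular bandwidth, ERB(f) = 24.7 * (4.37 f/1000 + 1) Hz."""
    return 24.7 * (4.37 * f_hz / 1000.0 + 1.0)


def _raised_cosine_ramp(n_total: int, n_ramp: int) -> np.ndarray:
    """Unit envelope with raised-cosine on/off ramps of ``n_ramp`` samples."""
    env = np.ones(n_total)
    if n_ramp > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = r
        env[-n_ramp:] = r[::-1]
    return env


def fractional_delay(x: np.ndarray, delay_s: float, rate: float) -> np.ndarray:
    """Delay ``x`` by an arbitrary (fractional-sample) amount.

    Implemented as a linear phase ramp in the frequency domain; positive
    ``delay_s`` shifts the waveform later in time.  The signal is zero-padded
    before the FFT so the circular wrap never folds content back in.
    """
    x = np.asarray(x, dtype=float)
    pad = int(np.ceil(abs(delay_s) * rate)) + 1
    xp = np.concatenate([np.zeros(pad), x, np.zeros(pad)])
    n = xp.size
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec = np.fft.rfft(xp) * np.exp(-2j * np.pi * freqs * delay_s)
    y = np.fft.irfft(spec, n=n)
    return y[pad : pad + x.size]


def synth_fm_tone(depth_hz: float, spec: StimulusSpec | None = None) -> StereoWaveform:
    """Diotic sinusoidally frequency-modulated tone.

    The instantaneous frequency is ``carrier + depth_hz * cos(2π fm_rate t)``,
    so the peak frequency deviation is exactly ``depth_hz`` and ``depth_hz=0``
    renders the pure-tone reference.  Defaults follow the assay: 500-Hz
    carrier, 2-Hz rate, 500 ms, 5-ms raised-cosine ramps, 70 dB SPL.
    """
    spec = spec or StimulusSpec(paradigm="fm")
    if depth_hz < 0:
        raise ValueError("depth_hz must be nonnegative")
    if depth_hz >= spec.carrier_hz:
        raise ValueError("FM depth at or above the carrier frequency is non-physical")
    n = round(spec.duration_s * spec.rate)
    t = np.arange(n) / spec.rate
    amp = db_spl_to_amplitude(spec.level_db_spl, spec.calibration)
    # phase integral of f(t) = fc + depth*cos(2π fm t)
    phase = 2 * np.pi * spec.carrier_hz * t
    if spec.fm_rate_hz > 0:
        phase = phase + (depth_hz / spec.fm_rate_hz) * np.sin(2 * np.pi * spec.fm_rate_hz * t)
    x = amp * np.sin(phase) * _raised_cosine_ramp(n, round(spec.ramp_s * spec.rate))
    events = [(0.0, "onset"), (spec.duration_s, "offset")]
    meta = {"paradigm": "fm", "depth_hz": depth_hz, "carrier_hz": spec.carrier_hz}
    return StereoWaveform(x, x.copy(), spec.rate, spec.calibration, events, meta)


def _delayed_pair(x: np.ndarray, itd_s: float, lead: str, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Split an ITD symmetrically: the leading ear is advanced by ITD/2, the
    lagging ear delayed by ITD/2."""
    adv = fractional_delay(x, -itd_s / 2.0, rate)
    lag = fractional_delay(x, +itd_s / 2.0, rate)
    if lead == "left":
        return adv, lag
    if lead == "right":
        return lag, adv
    raise ValueError("lead must be 'left' or 'right'")


def synth_itd_burst_pair(itd_us: float, first_lead: str = "left",
                         spec: StimulusSpec | None = None) -> StereoWaveform:
    """Two consecutive tone bursts whose leading ear switches between bursts.

    Defaults follow the behavioral ITD task: two 400-ms 500-Hz bursts with
    20-ms ramps at 70 dB SPL; burst 1 leads in ``first_lead`` by ``itd_us``,
    burst 2 leads in the opposite ear by the same amount.
    """
    spec = spec or StimulusSpec(paradigm="itd_burst", duration_s=0.4, ramp_s=0.020)
    if itd_us < 0:
        raise ValueError("itd_us must be nonnegative")
    itd_s = itd_us * 1e-6
    if itd_s > spec.duration_s:
        raise ValueError("ITD exceeds the burst duration")
    n = round(spec.duration_s * spec.rate)
    t = np.arange(n) / spec.rate
    amp = db_spl_to_amplitude(spec.level_db_spl, spec.calibration)
    burst = amp * np.sin(2 * np.pi * spec.carrier_hz * t)
    burst *= _raised_cosine_ramp(n, round(spec.ramp_s * spec.rate))
    other = {"left": "right", "right": "left"}[first_lead]
    l1, r1 = _delayed_pair(burst, itd_s, first_lead, spec.rate)
    l2, r2 = _delayed_pair(burst, itd_s, other, spec.rate)
    gap = np.zeros(round(spec.gap_s * spec.rate))
    left = np.concatenate([l1, gap, l2])
    right = np.concatenate([r1, gap, r2])
    peak = max(np.abs(left).max(), np.abs(right).max())
    if peak > 1.0:  # fractional delay ringing can overshoot by a hair
        left, right = left / peak, right / peak
    t2 = spec.duration_s + spec.gap_s
    events = [(0.0, "burst1"), (t2, "burst2"), (t2 + spec.duration_s, "offset")]
    meta = {"paradigm": "itd_burst", "itd_us": itd_us, "first_lead": first_lead}
    return StereoWaveform(left, right, spec.rate, spec.calibration, events, meta)


def am_trough_times(am_rate_hz: float, duration_s: float) -> np.ndarray:
    """Trough times of the envelope e(t) = ½(1 − cos(2π f t)): k / f."""
    k = np.arange(int(np.floor(duration_s * am_rate_hz)) + 1)
    return k / am_rate_hz


def synth_itd_jump_trial(jump_us: float, direction: str = "LR",
                         spec: StimulusSpec | None = None) -> StereoWaveform:
    """Amplitude-modulated tone whose ITD flips polarity mid-trial.

    A 1.5-s, 500-Hz tone, 100%-depth amplitude modulated at 40.8 Hz; the
    waveform starts with an ITD of ``jump_us / 2`` leading one ear and jumps
    to ``jump_us / 2`` leading the other, so the jump magnitude is
    ``jump_us``.  The envelope convention e(t) = ½(1 − cos(2π·40.8·t)) puts
    troughs exactly at k/40.8 s; the jump is placed at the trough nearest
    1.0 s, where the stimulus amplitude is (numerically) zero, so monaural
    cues cannot mark the transition.
    """
    import warnings

    spec = spec or StimulusSpec(paradigm="itd_jump", duration_s=1.5, ramp_s=0.0,
                                am_rate_hz=40.8, am_depth=1.0)
    if jump_us <= 0:
        raise ValueError("jump_us must be positive")
    if direction not in ("LR", "RL"):
        raise ValueError("direction must be 'LR' (left-leading first) or 'RL'")
    if spec.am_depth != 1.0:
        warnings.warn("AM depth != 1: envelope troughs are nonzero, so the ITD jump is "
                      "not fully amplitude-masked", stacklevel=2)
    n = round(spec.duration_s * spec.rate)
    t = np.arange(n) / spec.rate
    troughs = am_trough_times(spec.am_rate_hz, spec.duration_s)
    t_jump = float(troughs[np.argmin(np.abs(troughs - 1.0))])
    j = round(t_jump * spec.rate)

    amp = db_spl_to_amplitude(spec.level_db_spl, spec.calibration)
    env = 1.0 - spec.am_depth * 0.5 * (1.0 + np.cos(2 * np.pi * spec.am_rate_hz * t))
    x = amp * env * np.sin(2 * np.pi * spec.carrier_hz * t)
    itd_s = jump_us * 1e-6 / 2.0  # interaural difference before (and after) the jump
    lead1 = "left" if direction == "LR" else "right"
    lead2 = "right" if direction == "LR" else "left"
    l_pre, r_pre = _delayed_pair(x, itd_s, lead1, spec.rate)
    l_post, r_post = _delayed_pair(x, itd_s, lead2, spec.rate)
    left = np.concatenate([l_pre[:j], l_post[j:]])
    right = np.concatenate([r_pre[:j], r_post[j:]])
    peak = max(np.abs(left).max(), np.abs(right).max())
    if peak > 1.0:
        left, right = left / peak, right / peak
    events = [(0.0, "onset"), (t_jump, "itd_jump"), (spec.duration_s, "offset")]
    meta = {"paradigm": "itd_jump", "jump_us": jump_us, "direction": direction,
            "am_rate_hz": spec.am_rate_hz, "jump_time_s": t_jump}
    return StereoWaveform(left, right, spec.rate, spec.calibration, events, meta)


# segment layout of the forward-masking FFR sequence (seconds, dB SPL)
FFR_SEGMENTS = (
    ("probe1", 0.100, 75.0),
    ("gap1", 0.050, None),
    ("masker", 0.100, 85.0),
    ("gap2", 0.001, None),
    ("probe2", 0.100, 75.0),
)


def synth_ffr_sequence(polarity: int = 1, spec: StimulusSpec | None = None) -> StereoWaveform:
    """Probe–masker–probe sequence for forward-masked FFR recording.

    500-Hz probe (100 ms, 75 dB SPL), 50-ms gap, masker (100 ms, 85 dB SPL),
    1-ms gap, probe again — 351 ms total; each tonal segment has 5-ms ramps.
    ``polarity=-1`` renders the exact sample-wise negation, supporting
    polarity-alternated averaging downstream.
    """
    spec = spec or StimulusSpec(paradigm="ffr_sequence", duration_s=0.1, ramp_s=0.005)
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    pieces = []
    events = []
    t0 = 0.0
    for name, dur, level in FFR_SEGMENTS:
        n = round(dur * spec.rate)
        if level is None:
            pieces.append(np.zeros(n))
        else:
            amp = db_spl_to_amplitude(level, spec.calibration)
            tt = np.arange(n) / spec.rate
            seg = amp * np.sin(2 * np.pi * spec.carrier_hz * tt)
            seg *= _raised_cosine_ramp(n, round(spec.ramp_s * spec.rate))
            pieces.append(seg)
            events.append((t0, name))
        t0 += dur
    x = polarity * np.concatenate(pieces)
    meta = {"paradigm": "ffr_sequence", "polarity": polarity,
            "segment_onsets": {name: float(sum(d for _, d, _ in FFR_SEGMENTS[:i]))
                               for i, (name, _, lv) in enumerate(FFR_SEGMENTS) if lv is not None}}
    return StereoWaveform(x, x.copy(), spec.rate, spec.calibration, events, meta)


def _band_noise(n: int, lo_hz: float, hi_hz: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise band-limited to [lo, hi] Hz by spectral brick-wall, unit RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[(freqs < lo_hz) | (freqs > hi_hz)] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def synth_am_noise_trial(depth: float, center_hz: float = 4000.0, seed: int = 0,
                         spec: StimulusSpec | None = None) -> StereoWaveform:
    """Band-noise AM-detection target with unmodulated pure-tone flankers.

    A 500-Hz-wide Gaussian noise band centered at ``center_hz``, sinusoidally
    amplitude modulated at 19 Hz with the given ``depth``, plus two
    unmodulated tones 2 ERB above and below the center (each at the same
    75-dB SPL level) to discourage off-frequency listening.  ``depth=0`` with
    the same seed renders the statistically identical reference interval.
    """
    spec = spec or StimulusSpec(paradigm="am_noise", duration_s=0.5, ramp_s=0.005,
                                level_db_spl=75.0, am_rate_hz=19.0)
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = round(spec.duration_s * spec.rate)
    t = np.arange(n) / spec.rate
    noise = _band_noise(n, center_hz - 250.0, center_hz + 250.0, spec.rate, rng)
    env = 1.0 + depth * np.sin(2 * np.pi * spec.am_rate_hz * t)
    target = noise * env
    # noise RMS matched to a sinusoid at the nominal level
    amp = db_spl_to_amplitude(spec.level_db_spl, spec.calibration)
    target *= (amp / np.sqrt(2)) / np.sqrt(np.mean(target**2))
    bw = erb(center_hz)
    flankers = np.zeros(n)
    flank_freqs = (center_hz - 2 * bw, center_hz + 2 * bw)
    for f in flank_freqs:
        flankers += amp * np.sin(2 * np.pi * f * t + 2 * np.pi * rng.random())
    x = (target + flankers) * _raised_cosine_ramp(n, round(spec.ramp_s * spec.rate))
    peak = np.abs(x).max()
    if peak > 1.0:
        x = x / peak
    events = [(0.0, "onset"), (spec.duration_s, "offset")]
    meta = {"paradigm": "am_noise", "depth": depth, "center_hz": center_hz,
            "flanker_hz": [float(f) for f in flank_freqs], "seed": seed}
    return StereoWaveform(x, x.copy(), spec.rate, spec.calibration, events, meta)
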