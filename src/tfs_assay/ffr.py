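"""Forward-masked frequency-following-response (FFR) decomposition.

Alternating the stimulus polarity across trials lets the scalp response be
split into

* the *difference* average — components that flip with polarity, i.e.
  phase-locked to the 500-Hz temporal fine structure (TFS), mixing neural
  phase-locking with preneural sources such as the cochlear microphonic; and
* the *sum* average — polarity-invariant components: the envelope response
  plus a rectification product at twice the tone frequency (1000 Hz).

A loud forward masker placed 1 ms before the second probe suppresses the
(synaptic) neural part of the probe-2 response while leaving the preneural
part intact; subtracting the aligned probe-2 segment from the probe-1
segment therefore cancels the preneural component and leaves the masked
fraction of the neural response — the forward-masking residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tfs_assay.eeg import EpochArray
from tfs_assay.stimuli import FFR_SEGMENTS

__all__ = [
    "FfrDecomposition",
    "polarity_decompose",
    "segment_component",
    "forward_masking_residual",
    "partial_suppression_ratio",
    "decompose_ffr",
    "PROBE_ONSETS_S",
    "SEGMENT_WINDOW_S",
]

# probe onsets within the stimulus sequence (s re probe-1 onset)
PROBE_ONSETS_S = {
    "probe1": 0.0,
    "probe2": sum(d for _, d, _ in FFR_SEGMENTS[:-1]),  # 0.251 s
}
# analysis window relative to each probe onset: skips the 5-ms ramps and the
# onset transient, identical for both probes so linear components cancel
SEGMENT_WINDOW_S = (0.010, 0.090)

TFS_HZ = 500.0
ENV2_HZ = 1000.0


def polarity_decompose(epochs: EpochArray, channel: str | int = "Cz",
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Difference and sum averages across the two stimulus polarities.

    ``epochs.labels`` must hold +1/−1 polarity labels.  Trial counts are
    balanced by seeded subsampling of the larger class before averaging, so
    unequal rejection cannot leak envelope components into the difference.
    Returns ``(diff, sum)`` with diff = (mean₊ − mean₋)/2 and
    sum = (mean₊ + mean₋)/2 — an exact linear involution.
    """
    ci = channel if isinstance(channel, int) else epochs.ch_names.index(channel)
    pos = epochs.good(+1)[:, ci, :]
    neg = epochs.good(-1)[:, ci, :]
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise ValueError("both polarities must survive rejection")
    n = min(pos.shape[0], neg.shape[0])
    rng = np.random.default_rng(seed)
    if pos.shape[0] > n:
        pos = pos[rng.choice(pos.shape[0], n, replace=False)]
    if neg.shape[0] > n:
        neg = neg[rng.choice(neg.shape[0], n, replace=False)]
    mp, mn = pos.mean(axis=0), neg.mean(axis=0)
    return (mp - mn) / 2.0, (mp + mn) / 2.0


def segment_component(average: np.ndarray, rate: float, window_samples: slice,
                      target_hz: float) -> tuple[float, float]:
    """Hann-windowed spectral magnitude at ``target_hz`` plus a noise floor.

    The magnitude is read at the DFT bin nearest the target; the noise floor
    is the mean magnitude over the 10 bins on either side, excluding ±2 bins
    around the target.  The window must span at least 20 cycles of the
    target so the bin resolution separates signal from floor.
    """
    seg = np.asarray(average[window_samples], dtype=float)
    n = seg.size
    if n / rate * target_hz < 20:
        raise ValueError("analysis window shorter than 20 cycles of the target frequency")
    win = np.hanning(n)
    spec = np.abs(np.fft.rfft(seg * win)) / (win.sum() / 2.0)  # amplitude-calibrated
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    k = int(np.argmin(np.abs(freqs - target_hz)))
    neighbors = [j for j in range(max(0, k - 12), min(spec.size, k + 13)) if abs(j - k) > 2]
    return float(spec[k]), float(np.mean(spec[neighbors]))


@dataclass
class FfrDecomposition:
    """Segment magnitudes and forward-masking residuals of one FFR recording."""

    diff: np.ndarray
    sum: np.ndarray
    rate: float
    d1: float = np.nan    # 500-Hz magnitude, probe-1 difference segment
    d2: float = np.nan    # … probe-2
    s1: float = np.nan    # 1000-Hz magnitude, probe-1 sum segment
    s2: float = np.nan
    r_d: float = np.nan   # residual |probe1 − probe2| at 500 Hz (difference)
    r_s: float = np.nan   # residual at 1000 Hz (sum)
    noise_floors: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)  # segment name → slice


def _probe_windows(rate: float, tmin: float) -> dict:
    out = {}
    for name, onset in PROBE_ONSETS_S.items():
        a = int(round((onset + SEGMENT_WINDOW_S[0] - tmin) * rate))
        b = a + int(round((SEGMENT_WINDOW_S[1] - SEGMENT_WINDOW_S[0]) * rate))
        out[name] = slice(a, b)
    return out


def decompose_ffr(epochs: EpochArray, channel: str | int = "Cz",
                  seed: int = 0) -> FfrDecomposition:
    """Full decomposition: polarity split, segment magnitudes, residuals."""
    diff, summ = polarity_decompose(epochs, channel, seed=seed)
    dec = FfrDecomposition(diff, summ, epochs.rate,
                           windows=_probe_windows(epochs.rate, epochs.tmin))
    w1, w2 = dec.windows["probe1"], dec.windows["probe2"]
    dec.d1, dec.noise_floors["d1"] = segment_component(diff, epochs.rate, w1, TFS_HZ)
    dec.d2, dec.noise_floors["d2"] = segment_component(diff, epochs.rate, w2, TFS_HZ)
    dec.s1, dec.noise_floors["s1"] = segment_component(summ, epochs.rate, w1, ENV2_HZ)
    dec.s2, dec.noise_floors["s2"] = segment_component(summ, epochs.rate, w2, ENV2_HZ)
    dec.r_d, dec.r_s = forward_masking_residual(dec)
    return dec


def forward_masking_residual(dec: FfrDecomposition) -> tuple[float, float]:
    """Time-domain probe1 − probe2 subtraction, then spectral magnitude.

    Cancels components insensitive to forward masking (preneural, e.g. the
    cochlear microphonic) and leaves the masked fraction of the neural
    response: r_d at 500 Hz from the difference average, r_s at 1000 Hz
    from the sum average.
    """
    w1, w2 = dec.windows["probe1"], dec.windows["probe2"]
    if (w1.stop - w1.start) != (w2.stop - w2.start):
        raise ValueError("probe segment windows must have identical length")
    rd, _ = segment_component(dec.diff[w1] - dec.diff[w2], dec.rate,
                              slice(0, w1.stop - w1.start), TFS_HZ)
    rs, _ = segment_component(dec.sum[w1] - dec.sum[w2], dec.rate,
                              slice(0, w1.stop - w1.start), ENV2_HZ)
    return float(rd), float(rs)


def partial_suppression_ratio(dec: FfrDecomposition) -> tuple[float, float]:
    """Probe-2 / probe-1 magnitude ratios (d2/d1, s2/s1).

    A ratio near 1 means the masker barely suppressed the response —
    preneural-dominated; a ratio well below 1 indicates a dominant neural
    (maskable) contribution.  Undefined when the denominator sits at or
    below its noise floor.
    """
    # a noise-only bin is Rayleigh-distributed around the floor, so demand a
    # 2x margin before calling the denominator measurable
    if dec.d1 <= 2.0 * dec.noise_floors.get("d1", 0.0):
        raise ValueError("d1 at or below the noise floor; ratio undefined")
    if dec.s1 <= 2.0 * dec.noise_floors.get("s1", 0.0):
        raise ValueError("s1 at or below the noise floor; ratio undefined")
    return float(dec.d2 / dec.d1), float(dec.s2 / dec.s1)
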