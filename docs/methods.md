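# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `tfs_assay`. It is written for a reader who wants to
know exactly what the code computes and what passing tests do — and do not
— establish about real data.

## Stimulus synthesis

All paradigms render to a calibrated stereo buffer in which a full-scale
sinusoid corresponds to a declared sound pressure level (default
100 dB SPL, recorded in every WAV sidecar), so presentation levels
(70/75/85 dB SPL) map deterministically to sample amplitudes via
`10^((level − calibration)/20)`.

* **FM tone** — instantaneous frequency `f_c + depth·cos(2π·2·t)` on a
  500-Hz carrier, 5-ms raised-cosine ramps, diotic. At depth *d* the
  rendered spectrum is the Bessel line series with modulation index
  β = d/2; note that at d = 5 Hz the carrier line is almost nulled
  (J₀(2.5) ≈ −0.05), which the tests assert via the line-magnitude ratios.
* **ITD rendering** — interaural time differences are applied as
  fractional-sample delays (frequency-domain phase ramp) split
  symmetrically, ±ITD/2 per channel, so the audio sample rate (48 kHz
  default) never quantizes the ITD. The delay acts on the whole waveform
  (carrier + envelope); for the jump stimulus the envelope trough at the
  switch suppresses any envelope cue regardless.
* **ITD-jump trial** — 1.5 s of a 500-Hz tone, 100%-depth AM at 40.8 Hz
  with the envelope convention e(t) = ½(1 − cos(2π·40.8·t)); troughs fall
  exactly at k/40.8 s and the ITD polarity switch is placed at the trough
  nearest 1.0 s (k = 41, t ≈ 1.0049 s). The waveform starts at ITD =
  jump/2 leading one ear and ends at jump/2 leading the other, so the
  *jump magnitude* equals the nominal condition (20/60/180/540 μs).
* **FFR sequence** — probe (100 ms, 75 dB SPL) · 50-ms gap · masker
  (100 ms, 85 dB SPL) · 1-ms gap · probe; 5-ms ramps; 351 ms total. The
  polarity argument negates the entire waveform sample-wise, which is what
  makes downstream difference/sum averaging exact.
* **AM noise** — a 500-Hz-wide spectral-brick-wall Gaussian band
  (seeded), sinusoidally modulated at 19 Hz, with unmodulated pure-tone
  flankers at ±2·ERB(f_c), ERB(f) = 24.7·(4.37·f/1000 + 1).

Open choice: the behavioral ITD burst pair is rendered with no gap between
the bursts (configurable), since nothing in the paradigm description
requires one.

## Observers and adaptive tracks

A simulated 2AFC observer is

P(correct | x) = γ + (1 − γ − λ)·F((x − θ)/σ),  γ = 0.5,

with F logistic and x on a dB axis (dB re 1 Hz for FM depth, dB re 1 μs
for ITD). λ is the lapse rate: it caps the asymptote at 1 − λ and is the
latent quantity the catch-trial "nonsensory score" estimates.

Two track rules are implemented with their classical equilibria:
three-down-one-up converges to the p³ = ½ point (79.4% correct) and the
weighted one-down-one-up with a 3:1 up/down step ratio to the 75% point
(p·s = (1−p)·3s). Tracks stop after 11 reversals by default; the FM
threshold is the median of all reversals and the ITD threshold the
geometric mean of the last nine (equivalently the arithmetic mean of their
dB values). Step size is 4 dB, halving to 2 dB after three reversals.

Start values (unstated in the source protocol) are set clearly
suprathreshold with respect to the published threshold ranges — 46 dB re
1 μs (200 μs) for ITD and 28 dB re 1 Hz (25 Hz) for FM — because the worst
published ITD threshold (89 μs) is close to a naive 100-μs start, and an
adaptive track must begin detectable for its down rule to engage.

Catch trials are flagged on the *presented* (clamped) value with strict
bounds: FM depth > 15 Hz, ITD > 80 μs (a value exactly at the bound is not
a catch trial; the comparison uses a 1e−9-dB tolerance so round-trip
arithmetic cannot flip it). Lapse rates pool counts over a task's blocks
rather than averaging per-block rates, because the adaptive procedure
yields unequal catch counts per block. Note that for subjects whose
threshold approaches the 80-μs bound the "easy" catch trials are not truly
asymptotic, so the estimated lapse partially absorbs sensory failures —
an inherent property of the estimator, reproduced rather than corrected
here.

Convergence accuracy: with a 1-dB final step, 200 reversals and 50 seeds,
mean reversal levels sit within ~0.15 dB of the analytic percent points;
at the production stopping rule (11 reversals, 2-dB final step) single
block estimates have an SD of roughly 1.5–2 dB.

## EEG preprocessing

Plain numpy containers (channels × samples recordings; trials × channels ×
time epochs) keep every step auditable; EDF/BDF ingestion goes through
MNE. Re-referencing subtracts the mean of the two earlobe channels.
Filtering is a windowed-sinc FIR applied forward–backward (zero phase, so
latency metrics are unbiased); transition width is a quarter of each band
edge (≥ 1 Hz), Hamming window, giving > 40 dB attenuation one octave
outside the band after the squared response. Ocular artifacts are removed
by signal-space projection: segments where the frontal channel exceeds 4×
its MAD-based SD for ≥ 50 ms define the blink subspace, and the rank-1 (by
default) orthogonal projector `I − UUᵀ` is applied to all samples; the
projector is symmetric and idempotent. Epoch rejection masks any trial
whose absolute amplitude on an analysis channel (Fz/Cz) exceeds 150 μV
(cortical) or 50 μV (subcortical).

Cortical ITD-jump epochs span (−0.6, +0.8) s around the jump: wide enough
for a 0.4-s pre-jump baseline and for the longest Morlet wavelet used.

## Cortical metrics

ITC is computed from a complex Morlet decomposition (MNE
`tfr_array_morlet`): 5-cycle wavelets, relaxed to 3 cycles below 10 Hz;
the default frequency grid is 4–50 Hz in 1-Hz steps — 4 Hz is the lowest
frequency whose 3-cycle wavelet fits a 1.4-s epoch, and jump-evoked
transients carry little energy below it. The low band for the condition
time course is therefore 4–20 Hz. The per-condition scalar is the peak of
the baseline-subtracted low-band ITC in (0, 0.4] s post-jump, baseline =
mean over (−0.4, 0] s; baseline subtraction supplies the noise floor.

ASSR quality is the ITC of the Hann-tapered DFT coefficient at 40.8 Hz
over the pre-jump interval (the taper suppresses leakage from nearby
non-ASSR components); an optional circular-shift surrogate distribution
gives an empirical null.

N1 is the most negative extremum in (0.05, 0.20] s post-jump and P2 the
most positive in (0.15, 0.35] s, constrained to follow N1; the latency
metric is their mean, read from the 180-μs condition (reliably above the
noise floor, below saturation). The growth slope is
(ITC₁₈₀ − ITC₆₀)/ITC₅₄₀, undefined when the 540-μs scalar is not positive.
Both metrics are exactly invariant to post-hoc scaling of the epoch
tensor, which is the design rationale: anatomical gain can only reach them
through single-trial SNR.

## FFR decomposition

Polarity classes are balanced by seeded subsampling of the larger class
(unequal rejection would otherwise leak envelope components into the
difference), then diff = (mean₊ − mean₋)/2 and sum = (mean₊ + mean₋)/2 —
an exact linear involution. Segment analysis windows are 10–90 ms
post-onset of each probe (skipping the 5-ms ramps and onset transient);
identical windows for both probes are the only requirement for the
subtraction to cancel linear components. Spectral magnitudes use a Hann
taper, amplitude-calibrated at the bin nearest the target (12.5-Hz bin
width at the 80-ms window), with the noise floor estimated from the
neighboring ±12 bins excluding ±2 around the target. The forward-masking
residual subtracts the aligned probe-2 segment from probe-1 in the time
domain and reads the 500-Hz (difference) / 1000-Hz (sum) magnitude; no
latency compensation is applied by default. The suppression ratios d2/d1
and s2/s1 require the denominator to exceed 2× its noise floor (a
noise-only bin is Rayleigh-distributed around the floor, so a margin is
needed before calling it measurable).

Masking convention: α is the *masked fraction* of the neural component —
the probe-2 neural amplitude is (1 − α)·A_neural — so the residual
recovers α·A_neural and the suppression ratio of a purely neural response
is 1 − α.

## Statistics

Pearson correlations (scipy) with pairwise-complete handling; the
variance partition is a fixed-entry-order hierarchical regression with
sequential (Type-I) increments, the only convention under which the
per-predictor percentages sum to the full-model R²; Benjamini–Hochberg FDR
via statsmodels, validated against brute-force step-up enumeration.

## The synthetic cohort

The generator draws, per subject: a binaural sensory midpoint θ_b
(mean 30, SD 3.5 dB re 1 μs), a monaural FM midpoint coupled to θ_b at
r = 0.3, a lapse rate λ (clipped normal, mean 0.12, SD 0.10, max 0.25 —
naive, untrained listeners), an anatomy gain g (log-normal, σ = 0.4,
independent of θ_b), a cortical latency shift (SD 15 ms, coupled to θ_b at
r = 0.6), a log-ITD sigmoid midpoint for the jump-response growth (around
50 μs, coupled to θ_b at r = 0.5), and FFR amplitudes A_neural ≈ 50 nV,
A_preneural ≈ 100 nV with masking fraction α ≈ 0.8. With these values the
low-lapse portion of a cohort spans roughly the published 21–39 dB re 1 μs
threshold range; high-lapse subjects exceed it because their tracks'
convergence point diverges as λ approaches 1 − 0.794 (their measured
thresholds are inflated without any sensory deficit — the phenomenon the
adjustment exists to remove).

Cortical trials are rendered directly as jump-aligned epochs at 256 Hz:
`g·[a(ITD)·(N1/P2 Gaussian kernels, σ = 25 ms, at 100/200 ms + latency
shift) + offset response] + g·ASSR sinusoid + pink + white noise` (8 μV
per component), noise added *after* the gain — so g moves single-trial SNR
and every ITC metric, reproducing the amplitude confound; multiplying the
finished tensor by a constant moves nothing (both properties are tested).
The default SNR puts the ASSR ITC near 0.25–0.45 and N1/P2 latency
recovery at ≈ 4–5 ms mean absolute error with 300 trials per condition.

FFR trials are rendered at 8 kHz with alternating polarity: a
polarity-flipping 500-Hz mixture of neural and preneural components, a
polarity-invariant 1000-Hz rectification component (same neural/preneural
split at half amplitude), probe-2 neural parts scaled by (1 − α), masker
response included, and 2 μV white noise per trial — representative of
residual noise in a 400–1300-Hz analysis band, and putting the residual
estimator's SD near 7% of a 40-nV residual at 8000 trials.

What the generator does *not* emulate: real scalp topography and channel
covariance (two channels, one scaled copy), non-Gaussian artifacts, blink
dynamics during the cortical paradigm, drifting attention (λ is constant
within a subject), off-frequency listening, or any biophysical cochlear /
cortical mechanism. Passing recovery tests therefore shows that the
*estimators* are correct and well-calibrated under the declared forward
model, not that the assays are valid in humans.

## Problem sizes

The test suite and acceptance script run reduced problem sizes chosen to
keep the estimators in the same statistical regime as the full study
conditions: 100 behavior-only cohorts of n = 32 for the adjustment
Monte-Carlo, one fully rendered cohort at 100 cortical trials per
condition for the variance-partition table, 300 trials per condition for
latency recovery, and the full 8000 trials for FFR recovery.

## Known limitations

* The nonsensory share of measured ITD-threshold variance in the default
  generator (~0.8 as estimated by the same regression a real analysis
  would run) is larger than values reported for human cohorts (~0.4),
  mainly because catch trials near the 80-μs bound conflate sensory and
  lapse failures for poor performers.
* The lapse-adjustment comparison ("adjusted beats raw") is a Monte-Carlo
  fraction with binomial noise ≈ ±3% at 100 cohorts; its expected value
  under the defaults is ≈ 0.93.
* ITC maps begin at 4 Hz; genuinely slower evoked energy is folded into
  the 4-Hz band by the wavelet bandwidth rather than resolved.
* The forward-masking residual is reported as a magnitude with a noise
  floor; for real recordings it is small, and no claim is made that it is
  purely neural.
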