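# tfs-assay

Individualized assays of **temporal fine structure (TFS)** coding in the human
auditory system: a tested Python pipeline covering stimulus synthesis,
adaptive psychophysics with lapse-rate ("nonsensory") adjustment, cortical
EEG phase-coherence metrics for interaural-time-difference (ITD) jumps,
forward-masked frequency-following-response (FFR) decomposition, and the
brain–behavior statistics that tie them together.

## The problem

Auditory neurons phase-lock to the cycle-by-cycle fine structure of low
frequency sounds, but there is no established assay of how *faithfully* a
given individual encodes TFS. Candidate measures are contaminated by
variance that has nothing to do with TFS coding:

* **Behavioral thresholds** (FM detection at 2 Hz on a 500-Hz carrier;
  ITD discrimination of 500-Hz tone bursts) absorb attention and motivation
  failures. A lapse rate λ caps the psychometric function,

  P(correct | x) = γ + (1 − γ − λ)·F((x − θ)/σ),

  (γ = 0.5 for 2AFC), so an adaptive track that targets a percent-correct
  point above 1 − λ is pushed upward regardless of the sensory parameter θ.
  Errors on easy *catch trials* (FM depth > 15 Hz; ITD > 80 μs) estimate λ;
  regressing thresholds on this nonsensory score and keeping the residuals
  yields "clean" thresholds.
* **Cortical EEG amplitude metrics** absorb anatomy (head size, source
  geometry): a multiplicative gain on the scalp signal moves the
  intertrial coherence

  ITC(f, t) = | (1/N) Σₙ exp(i·φₙ(f, t)) |

  through single-trial SNR even when TFS coding is identical. Two derived
  metrics dodge the gain: the **latency** of the jump-evoked response
  (mean of N1 and P2 latency, 180-μs condition) and the normalized growth
  **slope** (ITC₁₈₀ − ITC₆₀)/ITC₅₄₀ across jump sizes {20, 60, 180, 540} μs.
* **FFR** components at 500 Hz (polarity-difference average) and 1000 Hz
  (polarity-sum rectification product) mix neural phase-locking with
  preneural sources such as the cochlear microphonic. A loud forward
  masker suppresses only the (synaptic) neural part of a second probe, so
  the aligned probe1 − probe2 subtraction cancels the preneural component
  and leaves the masked neural fraction.

Because the original human recordings are not public, the package validates
the whole chain by **parameter recovery** on synthetic cohorts with known
latent sensory, lapse, anatomical-gain, latency and FFR parameters
(`tfs_assay.cohort`).

## Worked example

```python
import numpy as np
from tfs_assay.cohort import CohortConfig, end_to_end_recovery

rec = end_to_end_recovery(CohortConfig(n_subjects=32), seed=0,
                          n_cortical_trials=400)
print(rec["regression"].to_markdown())
print(f"raw corr with latent sensory parameter:      {rec['corr_raw_theta_b']:.3f}")
print(f"adjusted corr with latent sensory parameter: {rec['corr_adjusted_theta_b']:.3f}")
print(f"raw 540-us ITC vs anatomy gain (confound):   {rec['corr_itc540_gain']:.3f}")
```

prints

```
| Predictor | Variance explained |
| --- | --- |
| nonsensory_score | 89.39% |
| eeg_latency | 1.02% |
| eeg_slope | 2.07% |
| Explained | 92.48% |
| Unexplained | 7.52% |
raw corr with latent sensory parameter:      -0.059
adjusted corr with latent sensory parameter: 0.421
raw 540-us ITC vs anatomy gain (confound):   0.817
```

One synthetic cohort of 32 subjects is drawn, 8 ITD staircase blocks are
simulated per subject, catch-trial lapse rates are pooled, cortical epochs
are rendered and scored (ITC condition scalars, ASSR quality at 40.8 Hz,
N1/P2 latency, growth slope), and a sequential (Type-I) variance partition
of the measured ITD threshold on nonsensory score → EEG latency → EEG slope
is reported. On this cohort the raw threshold barely tracks the latent
sensory parameter (r ≈ −0.06) while the lapse-adjusted threshold recovers
it (r ≈ 0.42), and the raw 540-μs ITC mostly tracks the anatomy gain — the
two confounds the adjusted metrics are designed to remove.

A command-line interface mirrors the stages:

```bash
tfs-assay synth --paradigm itd_jump --jump-us 180 --direction LR --out stim/
tfs-assay simulate-behavior --task itd --n-blocks 8 --seed 7 --out beh/
tfs-assay run --n 32 --seed 0 --out results/
```

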