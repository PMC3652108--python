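# Methods

## The channel model

Each analysis channel mimics one cochlear place.  The input `x` is processed
by two causal pathways sharing a center frequency `cf` and summed:

- **Linear (tail) pathway** — fixed gain `G = 6` into a broad bandpass
  ("tail" of a tuning curve): Butterworth design order 2, passband
  `cf ± bw/2` where `bw` is the channel's tabulated analysis bandwidth.
- **Nonlinear (tip) pathway** — a sharp bandpass (design order 4, passband
  `cf ± bw/6`, i.e. one third the tail width) followed by the compressive
  nonlinearity `y = 2·arctan(15·x)`, a stand-in for outer-hair-cell
  saturation.

"Design order N" means the `N` of a Matlab/scipy-style `butter(N, [lo, hi])`
bandpass call; the resulting transfer function has `2N` poles.  This reading
makes the tip filter's stand-alone amplitude half-max width
`3^(1/8) · bw/3`, which is what the sharp low-level tuning of the model
calls for; a 2-pole tail would be too shallow to give usable band
separation.

### Applying the nonlinearity

The arctan law is pointwise, but applying it per sample distorts the
waveform.  The default mode (`nl_mode="rms_gain"`) instead converts it to a
slowly varying gain: a causal rectangular-window running RMS `r(t)` of the
**channel input** (window 8 ms — a few carrier cycles at every tabulated
`cf`, short enough to track syllabic level changes) drives

```
g(t) = 2·arctan(15·r(t)) / r(t),            g(0) = 30 (continuous limit)
```

which multiplies the tip-filtered waveform.  Driving `g` from the channel
input makes the *pathway balance* a function of stimulus level, which is the
model's purpose; a variant driven by the tip output's own RMS is available
(`rms_source="tip"`), as is the raw pointwise law (`nl_mode="instantaneous"`)
for sensitivity analysis.  In `rms_gain` mode the tip pathway's output RMS is
bounded by `2·arctan(15·r)·≈ π` however loud the input — the mechanism behind
formant capture at conversational levels: remote formant energy leaking
through the broad tail grows linearly with level while in-band noise through
the tip cannot.

All filters are cascaded second-order sections, zero initial state, causal —
no zero-phase filtering, matching a real-time processor.

### Level calibration

Stimulus levels are quoted in dB SPL and mapped to digital amplitude by an
explicit convention: peak amplitude 1.0 ≡ 40 dB SPL (configurable,
`Calibration.dbspl_at_unit_amplitude`).  The default places the 35/85-dB
operating points on either side of the knee of `2·arctan(15x)`: at 35 dB
(amplitude 0.56) the nonlinear pathway still dominates, at 85 dB (amplitude
178) it is fully saturated.

## Frequency-response characterization

A channel is probed with 0.5-s tones on a 201-point log grid from `cf/3` to
`3·cf`; the first 0.1 s (onset transient) is discarded.  **Gain is defined
as steady-state output RMS divided by probe peak amplitude** — the
convention under which the saturated channel's high-level peak gain equals
`G/√2 = 4.24`, matching the published characterization of this model class.
Peak gain is the curve maximum; FWHM is the width of the contiguous interval
around the peak where gain stays at or above half the peak, linearly
interpolated at the crossings (a curve that never falls below half maximum
inside the probed range has no measurable width and raises).

Measured values for the default 1500-Hz channel (tail 357 Hz / tip 119 Hz):
peak gain 9.24 and FWHM 96.5 Hz at 35 dB SPL; peak gain 4.26 and FWHM
468.6 Hz at 85 dB SPL.  The quiet-probe width deserves a note: because the
two causal pathways are summed coherently and the tip filter's phase rotates
through ±π across its band edges, the summed response carries deep
cancellation notches ≈65 Hz either side of `cf`, and the half-max crossings
sit on those notch walls.  A magnitude-summed or zero-phase realization
would show a smoother ~140-Hz-wide peak; we regard the notches as a faithful
property of the causal two-path architecture and keep them.

## Envelope detection

Standard detector: full-wave rectifier + 4th-order Butterworth lowpass,
400 Hz cutoff, unity DC gain (a steady tone of amplitude A settles at 2A/π).
Enhanced detector: the same rectifier feeds a second lowpass at 20 Hz; where
the fast envelope exceeds the slow one — rapid onsets — a multiplicative
gain is applied.  With ratio `r = fast/(slow + ε)`:

```
g = 1                                    for r ≤ θ      (θ = 1.5)
g = min(1 + β·(r − θ), g_max)            for r > θ      (β = 1, g_max = 3)
```

The published description of transient enhancement specifies the two
cutoffs and the idea of extra gain at onset points but not the gain law;
this threshold-and-cap rule is one admissible realization, deliberately
mild by default, and every constant is exposed.  On steady signals the
enhanced detector reduces exactly to the standard one.

## Vocoder

One sinusoid per channel at the channel `cf` (tail and tip share a center
frequency, so one carrier suffices), zero initial phase (reproducibility),
amplitude-modulated by the channel envelope and summed.  The logarithmic
compression a real implant applies before electrical stimulation is bypassed
in acoustic simulation; a compression hook exists and defaults to identity.
Output is rescaled to the input RMS by default so 16-bit export cannot clip.

## Dominant-frequency analysis and FERs

The cochlea is sampled as 181 log-spaced partitions from 100 Hz to 10 kHz
(log spacing matches tonotopy).  Per-partition analysis bandwidths are
interpolated linearly in log(cf)–log(bw) from the 12-channel table and
extrapolated with the end-segment slopes, so the dense bank uses only
tabulated numbers.  For each partition the stimulus (rescaled so its peak
amplitude corresponds to the requested SPL) is processed by that partition's
channel, and the output's dominant frequency is the argmax bin of a
Hann-windowed FFT zero-padded to ≥ 2^16 points (≈ 0.34 Hz bins at
22.05 kHz), restricted to the partition range.

`FER_k` is the fraction of partitions whose dominant frequency lies within
±2% of formant `k`.  The 2% window keeps the F1/F2 windows of all preset
vowels disjoint.  Because the synthetic vowels are harmonic (f0 = 100 Hz),
their spectral peaks sit on harmonics; FER comparisons therefore target the
*realized* formant peaks (300 and 2300 Hz for /i/), not the nominal resonator
frequencies (270/2290 Hz) at which a harmonic source has no energy.

## Synthetic stimuli

- **Vowels** — band-limited impulse train at f0 (equal-amplitude cosine
  harmonics to Nyquist; exactly periodic, alias-free) through a cascade of
  two-pole resonators (radius `exp(−πB/fs)`, unity DC gain) and a
  first-difference radiation filter, peak-normalized.  Presets: /i/ =
  (270, 2290, 3010) Hz; /a/ = (730, 1090, 2440) Hz and /u/ =
  (300, 870, 2240) Hz as classic reference values; bandwidths (60, 90,
  120) Hz; f0 = 100 Hz; 0.5 s.
- **WGN** — zero-mean unit-variance Gaussian, `numpy` Generator seeded
  explicitly; bit-reproducible.
- **SSN** — WGN through a 2nd-order Butterworth lowpass at 1100 Hz
  (≈ 12 dB/octave above the corner), approximating the long-term speech
  spectrum.
- **Mixing** — the noise is rescaled so the component power ratio meets the
  requested SNR exactly (measured over the full duration, no trimming);
  SNR = ∞ returns the clean signal.

What the synthetic fixtures do *not* emulate: glottal-source shape and
jitter, coarticulation, natural f0 contours, and recorded consonant
dynamics.  Passing the formant-representation tests therefore shows that
the nonlinear filterbank concentrates partitions on the spectral peaks of a
steady harmonic vowel in stationary noise — not that any listener-level
speech-intelligibility figure is reproduced.  Listener studies are outside
what synthetic stimuli can address; the end-to-end strategies are instead
pinned by checksum regression.

## Numerical choices and degenerate inputs

- Filter designs that would put a band edge at or beyond Nyquist raise at
  design time, naming the channel.
- `compressive_gain` is continuously extended to 30 at level 0; envelopes
  are clipped at 0 to remove causal-lowpass undershoot.
- Channel maps exist tabulated only for 4, 8, 12 channels; other counts
  raise rather than interpolate (custom maps can be built directly).
- The 1500-Hz demonstration channel has no tabulated bandwidth; it uses the
  nearest 12-channel entry (cf 1521 Hz → bw 357 Hz), configurable.
- All-zero signals raise in `dominant_frequency` (no dominant component)
  and in SNR mixing (undefined power ratio).

## Problem sizes used by the test suite

Probe-tone characterizations use 201 frequencies × 0.5 s (the per-channel
broadening sweep uses 61 × 0.3 s across the 8-channel map); the
formant-representation analysis uses the full 181 partitions on 0.5-s
stimuli; noise-spectrum checks use a 10-s realization.  The whole suite and
the acceptance script each complete in well under a minute.
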