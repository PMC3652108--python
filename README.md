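# sdpn — dual-path nonlinear cochlear-implant sound processing

Cochlear-implant (CI) processors decompose incoming sound into frequency
bands, extract each band's envelope, and use the envelopes to modulate
stimulation (or, in acoustic simulation for normal-hearing listeners, to
modulate one sinusoid per channel).  Conventional processors use a *fixed
linear* bandpass filterbank.  A healthy cochlea does something richer: outer-
hair-cell motility makes basilar-membrane tuning *level dependent* — sharp
and high-gain for quiet sounds, broad and compressive for loud ones — and
that active nonlinearity helps keep vowel formants salient in noise.

This package implements a simple dual path nonlinear (SDPN) channel model of
that behaviour and a complete vocoder strategy built on it, together with the
evaluation machinery needed to characterize it.  Each channel at center
frequency `cf` sums two causal pathways:

```
y(t) = G · tail(x)(t)  +  g(t) · tip(x)(t)

tail : 2nd-order Butterworth bandpass, width  bw          (broad, linear, G = 6)
tip  : 4th-order Butterworth bandpass, width  bw / 3      (sharp)
g(t) = 2 · arctan(15 · r(t)) / r(t),   r(t) = running RMS of the input
```

For quiet input `g → 2·15 = 30` and the sharp tip pathway dominates; for loud
input the arctan saturates, the tip contribution is bounded by π, and the
broad linear tail takes over.  The filterbank therefore broadens and
compresses exactly as input level rises.

Included alongside the channel model:

- tabulated 4/8/12-channel maps (logarithmic and mel spacing) with the 3:1
  tail/tip bandwidth split;
- standard (full-wave rectifier + 4th-order 400-Hz lowpass) and
  transient-enhanced (400-Hz/20-Hz detector pair with onset boost) envelope
  detectors;
- a sinusoidal vocoder and full `run_strategy` chain for both the linear and
  the nonlinear filterbank;
- probe-tone frequency-response characterization (peak gain, FWHM);
- dominant-frequency-component analysis over 181 log-spaced cochlear
  partitions (100 Hz–10 kHz) and the two formant extraction ratios
  FER1/FER2 — the fraction of partitions whose dominant output frequency
  matches the first/second formant;
- seeded synthetic stimuli: source-filter formant vowels (/i/, /a/, /u/),
  white Gaussian noise, speech-shaped noise (2nd-order 1100-Hz lowpassed
  WGN), exact SNR mixing, and an explicit dB-SPL → amplitude calibration.

## Worked example

Characterize the demonstration channel (cf 1500 Hz) at a quiet probe level:

```
$ sdpn --quiet response --cf 1500 --spl 35
{
  "peak_gain": 9.239355450360879,
  "fwhm_hz": 96.54094485767905,
  "peak_freq_hz": 1499.9999999999989,
  "n_freqs": 201
}
```

At 35 dB SPL the channel is sharply tuned with peak gain 9.24 (gain here is
steady-state output RMS over probe amplitude).  Repeating with `--spl 85`
gives peak gain 4.26 and FWHM 468.6 Hz: louder input, lower gain, three-to-
five-times broader tuning — the active-cochlea signature.

Formant representation of the /i/ vowel (F1/F2 spectral peaks at 300/2300 Hz
for the f0 = 100 Hz fixture) in speech-shaped noise at 5 dB SNR, 60 dB SPL:

```
$ sdpn --quiet fer --vowel i --noise ssn --snr 5 --seed 0 --spl 60 --model sdpn
{"fer1": 0.1492, "fer2": 0.2376, "f1_hz": 300.0, "f2_hz": 2300.0, "tolerance": 0.02}
$ sdpn --quiet fer --vowel i --noise ssn --snr 5 --seed 0 --spl 60 --model linear
{"fer1": 0.1381, "fer2": 0.0552, "f1_hz": 300.0, "f2_hz": 2300.0, "tolerance": 0.02}
```

Under identical noise, the nonlinear filterbank parks more cochlear
partitions on both formants than the linear filterbank (FER2: 24% of
partitions vs 6%) — formants are represented more robustly in noise.

Other entry points: `sdpn fixtures` writes the standard WAV test set,
`sdpn process` / `sdpn vocode` run the full strategies, `sdpn dfc` exports a
dominant-frequency profile as CSV.  Everything is also available as a plain
Python API (`import sdpn`).

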