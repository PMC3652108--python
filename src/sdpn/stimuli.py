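"""Synthetic stimuli: formant vowels, noises, SNR mixing, SPL calibration.

The analyses in this package need controlled inputs: steady vowels with
known formant structure, white Gaussian noise (WGN), speech-shaped noise
(SSN, a 2nd-order 1100-Hz lowpass applied to WGN so its long-term spectrum
resembles speech), and a convention mapping sound pressure level in dB to
digital amplitude.  Every generator is a pure function of its parameters
and seed, so fixtures are bit-reproducible.

Vowels are produced by source-filter synthesis: a glottal impulse train at
the fundamental f0 drives a cascade of two-pole resonators (one per
formant) followed by a first-difference radiation filter.  The /i/ preset
places F1-F3 at 270, 2290 and 3010 Hz; /a/ (730, 1090, 2440 Hz) and /u/
(300, 870, 2240 Hz) use classic reference formant values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .waveform import Waveform

__all__ = [
    "VowelSpec",
    "NoiseSpec",
    "Calibration",
    "VOWEL_PRESETS",
    "synth_vowel",
    "gen_wgn",
    "gen_ssn",
    "make_noise",
    "mix_at_snr",
    "spl_to_amplitude",
]

#: default resonator bandwidths for the three formants (Hz)
_DEFAULT_FORMANT_BWS = (60.0, 90.0, 120.0)


@dataclass(frozen=True)
class VowelSpec:
    """Formant vowel description: ``formants`` is [(freq Hz, bandwidth Hz), ...]."""

    formants: tuple[tuple[float, float], ...]
    f0: float = 100.0
    duration: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "formants", tuple((float(f), float(b)) for f, b in self.formants)
        )
        freqs = [f for f, _ in self.formants]
        if not freqs:
            raise ValueError("at least one formant is required")
        if not all(a < b for a, b in zip(freqs, freqs[1:])):
            raise ValueError("formant frequencies must be strictly increasing")
        if not self.f0 > 0:
            raise ValueError("fundamental frequency must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")


def _preset(freqs: Sequence[float], **kwargs) -> VowelSpec:
    return VowelSpec(
        formants=tuple(zip(freqs, _DEFAULT_FORMANT_BWS)), **kwargs
    )


VOWEL_PRESETS: dict[str, VowelSpec] = {
    "i": _preset((270.0, 2290.0, 3010.0)),
    "a": _preset((730.0, 1090.0, 2440.0)),
    "u": _preset((300.0, 870.0, 2240.0)),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Noise kind ('wgn' or 'ssn'), mixing SNR, seed, and SSN shaping filter."""

    kind: str = "ssn"
    snr_db: float = 5.0
    seed: int = 0
    ssn_order: int = 2
    ssn_fc: float = 1100.0

    def __post_init__(self) -> None:
        if self.kind not in ("wgn", "ssn"):
            raise ValueError(f"unknown noise kind: {self.kind!r}")
        if not self.ssn_fc > 0 or self.ssn_order < 1:
            raise ValueError("SSN shaping filter parameters must be positive")


@dataclass(frozen=True)
class Calibration:
    """Mapping between dB SPL and digital amplitude.

    ``dbspl_at_unit_amplitude`` is the SPL assigned to peak amplitude 1.0;
    the default of 40 dB places the 35/85 dB operating points on either
    side of the knee of the compressive nonlinearity 2*arctan(15x).
    """

    dbspl_at_unit_amplitude: float = 40.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.dbspl_at_unit_amplitude):
            raise ValueError("calibration reference must be finite")


def spl_to_amplitude(spl: float, calib: Calibration = Calibration()) -> float:
    """Peak amplitude of a stimulus presented at ``spl`` dB SPL."""
    if not math.isfinite(spl):
        raise ValueError("SPL must be finite")
    return 10.0 ** ((spl - calib.dbspl_at_unit_amplitude) / 20.0)


def synth_vowel(spec: VowelSpec, rate: float = 22050.0) -> Waveform:
    """Source-filter vowel synthesis, peak-normalized to 1.0.

    The glottal source is a band-limited impulse train at f0 (equal-
    amplitude cosine harmonics up to Nyquist — exactly periodic and free
    of the aliasing a sample-quantized impulse train would carry).  It is
    filtered by one digital resonator per formant (two poles at radius
    exp(-pi*B/rate), unity DC gain) and differentiated once to model lip
    radiation.
    """
    nyquist = rate / 2.0
    for freq, _ in spec.formants:
        if freq >= nyquist:
            raise ValueError(
                f"formant {freq} Hz is at or above the Nyquist frequency {nyquist} Hz"
            )
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate
    k_max = int(math.floor(0.999 * nyquist / spec.f0))
    harmonics = np.arange(1, k_max + 1)
    y = np.cos(2.0 * math.pi * spec.f0 * np.outer(harmonics, t)).sum(axis=0)
    for freq, bw in spec.formants:
        r = math.exp(-math.pi * bw / rate)
        theta = 2.0 * math.pi * freq / rate
        b1, b2 = 2.0 * r * math.cos(theta), -r * r
        gain = 1.0 - b1 - b2  # unity response at DC
        y = sps.lfilter([gain], [1.0, -b1, -b2], y)
    y = np.diff(y, prepend=0.0)
    peak = np.max(np.abs(y))
    return Waveform(y / peak, rate)


def gen_wgn(duration: float, rate: float, seed: int) -> Waveform:
    """Zero-mean, unit-variance white Gaussian noise; seed-reproducible."""
    if not duration > 0 or not rate > 0:
        raise ValueError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    return Waveform(rng.standard_normal(int(round(duration * rate))), rate)


def gen_ssn(
    duration: float, rate: float, seed: int, spec: NoiseSpec = NoiseSpec()
) -> Waveform:
    """Speech-shaped noise: lowpass-filtered WGN (default 2nd order, 1100 Hz)."""
    if spec.ssn_fc >= rate / 2.0:
        raise ValueError(
            f"SSN cutoff {spec.ssn_fc} Hz must be below Nyquist ({rate / 2} Hz)"
        )
    white = gen_wgn(duration, rate, seed)
    sos = sps.butter(spec.ssn_order, spec.ssn_fc, btype="low", fs=rate, output="sos")
    return Waveform(sps.sosfilt(sos, white.samples), rate)


def make_noise(spec: NoiseSpec, duration: float, rate: float) -> Waveform:
    """Generate the noise a :class:`NoiseSpec` describes."""
    if spec.kind == "wgn":
        return gen_wgn(duration, rate, spec.seed)
    return gen_ssn(duration, rate, spec.seed, spec)


def mix_at_snr(signal: Waveform, noise: Waveform, snr_db: float) -> Waveform:
    """Add noise rescaled so the signal-to-noise power ratio is exact.

    ``snr_db = inf`` returns the clean signal unchanged (the quiet
    condition).  SNR is measured over the full durations, no trimming.
    """
    if math.isinf(snr_db) and snr_db > 0:
        return signal
    if signal.rate != noise.rate:
        raise ValueError("signal and noise rates differ")
    if len(signal) != len(noise):
        raise ValueError(
            f"signal and noise lengths differ ({len(signal)} vs {len(noise)})"
        )
    p_signal = np.mean(np.square(signal.samples))
    p_noise = np.mean(np.square(noise.samples))
    if p_signal == 0 or p_noise == 0:
        raise ValueError("signal and noise must both have nonzero power")
    scale = math.sqrt(p_signal / (p_noise * 10.0 ** (snr_db / 10.0)))
    return Waveform(signal.samples + scale * noise.samples, signal.rate)
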