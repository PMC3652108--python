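"""Sampled audio waveforms and 16-bit PCM WAV I/O.

The :class:`Waveform` is the currency passed between every processing stage:
a 1-D float array of pressure-like samples plus its sampling rate.  Files are
read and written as 16-bit mono PCM WAV via :mod:`scipy.io.wavfile`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["Waveform", "read_wav", "write_wav"]

_PCM16_FULL_SCALE = 32768.0


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal: ``samples`` (float, dimensionless) at ``rate`` Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64).ravel()
        object.__setattr__(self, "samples", samples)
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must all be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples)))) if len(self) else 0.0

    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if len(self) else 0.0

    def scaled(self, factor: float) -> "Waveform":
        return Waveform(self.samples * float(factor), self.rate)

    def replace_samples(self, samples: np.ndarray) -> "Waveform":
        """Same rate, new samples (stage outputs keep the input's clock)."""
        return Waveform(samples, self.rate)


def read_wav(path: str | Path) -> Waveform:
    """Read a mono WAV file; integer PCM is rescaled to [-1, 1) floats."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"WAV file not found: {path}")
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"expected mono audio, got shape {data.shape}: {path}")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return Waveform(data, float(rate))


def write_wav(path: str | Path, wave: Waveform, *, normalize: bool = False) -> None:
    """Write 16-bit PCM mono.

    With ``normalize`` the signal is rescaled to 90% full scale; otherwise
    samples outside [-1, 1] raise instead of silently clipping.
    """
    samples = wave.samples
    if normalize:
        peak = wave.peak()
        if peak > 0:
            samples = samples * (0.9 / peak)
    elif np.max(np.abs(samples), initial=0.0) > 1.0:
        raise ValueError(
            "samples exceed full scale; pass normalize=True or rescale first"
        )
    pcm = np.round(samples * (_PCM16_FULL_SCALE - 1)).astype(np.int16)
    wavfile.write(Path(path), int(round(wave.rate)), pcm)
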