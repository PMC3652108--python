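"""The dual-path nonlinear channel model and its frequency-response probe.

Each channel imitates one place on the basilar membrane.  The input is
split into two pathways sharing a center frequency:

* a **linear pathway** — fixed gain (default 6) into a broad 2nd-order
  Butterworth bandpass, the *tail* filter;
* a **nonlinear pathway** — a sharp 4th-order Butterworth bandpass one
  third as wide, the *tip* filter, followed by the compressive
  nonlinearity ``y = 2 arctan(15 x)`` standing in for outer-hair-cell
  saturation.

The pathway outputs are summed.  At low input levels the tip pathway's
small-signal gain (2*15 = 30) dominates and the channel is sharply tuned
with high gain; at high levels the arctan saturates, the tip contribution
is bounded, and the broad linear tail takes over — the level-dependent
tuning of an active cochlea.

Filter orders are Butterworth *design* orders as in a Matlab/scipy
``butter(N, [lo, hi])`` call (a design order N bandpass has 2N poles).
All filtering is causal (cascaded second-order sections, zero initial
state); a real-time processor has no access to the future.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps

from .channels import ChannelSpec
from .stimuli import Calibration, spl_to_amplitude
from .waveform import Waveform

__all__ = [
    "SDPNParams",
    "ChannelFilters",
    "FrequencyResponse",
    "DEMO_CHANNEL",
    "compressive_gain",
    "design_channel_filters",
    "process_sdpn_channel",
    "process_linear_channel",
    "sdpn_channel_processor",
    "linear_channel_processor",
    "frequency_response",
    "fwhm_of",
    "response_to_csv",
    "response_summary",
]

#: order of the conventional strategy's fixed bandpass filters
CONVENTIONAL_ORDER = 4

#: the 1500-Hz demonstration channel; its bandwidths follow the nearest
#: tabulated 12-channel entry (cf 1521 Hz, bw 357 Hz)
DEMO_CHANNEL = ChannelSpec(cf=1500.0, bw_channel=357.0, bw_tail=357.0, bw_tip=119.0)


@dataclass(frozen=True)
class SDPNParams:
    """Tunable constants of the dual-path channel.

    ``nl_mode`` selects how the compressive nonlinearity is applied:

    * ``"rms_gain"`` (default) — a running RMS (causal rectangular window,
      ``rms_window`` seconds) of the drive signal sets a time-varying gain
      ``nl_scale*arctan(nl_slope*rms)/rms`` multiplying the tip output.
      This preserves waveform shape inside the tip band and avoids
      harmonic distortion.  ``rms_source`` picks the drive: the channel
      input (default; the pathway balance follows the input level) or the
      tip output itself.
    * ``"instantaneous"`` — ``nl_scale*arctan(nl_slope*x)`` per sample.
    """

    linear_gain: float = 6.0
    nl_scale: float = 2.0
    nl_slope: float = 15.0
    tail_order: int = 2
    tip_order: int = 4
    rms_window: float = 0.008
    nl_mode: str = "rms_gain"
    rms_source: str = "input"

    def __post_init__(self) -> None:
        if min(self.linear_gain, self.nl_scale, self.nl_slope) <= 0:
            raise ValueError("gains and nonlinearity constants must be positive")
        if self.tail_order < 1 or self.tip_order < 1:
            raise ValueError("filter orders must be positive integers")
        if not self.rms_window > 0:
            raise ValueError("RMS window must be positive")
        if self.nl_mode not in ("rms_gain", "instantaneous"):
            raise ValueError(f"unknown nl_mode: {self.nl_mode!r}")
        if self.rms_source not in ("input", "tip"):
            raise ValueError(f"unknown rms_source: {self.rms_source!r}")


@dataclass(frozen=True)
class ChannelFilters:
    """Designed tail/tip second-order-section filters for one channel."""

    tail: np.ndarray
    tip: np.ndarray
    rate: float
    spec: ChannelSpec

    def __post_init__(self) -> None:
        for name in ("tail", "tip"):
            sos = np.atleast_2d(np.asarray(getattr(self, name), dtype=np.float64))
            object.__setattr__(self, name, sos)
            poles = np.concatenate([np.roots(section[3:]) for section in sos])
            if np.any(np.abs(poles) >= 1.0):
                raise ValueError(f"{name} filter is unstable at rate {self.rate} Hz")


@dataclass(frozen=True)
class FrequencyResponse:
    """Probe-tone gain curve with its peak gain and half-maximum width.

    ``gain[i]`` is the steady-state output RMS divided by the probe-tone
    amplitude at ``freqs[i]`` (so a unit-gain channel passing a pure
    sinusoid scores 1/sqrt(2)).
    """

    freqs: np.ndarray
    gain: np.ndarray
    peak_gain: float
    fwhm: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=np.float64)
        gain = np.asarray(self.gain, dtype=np.float64)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "gain", gain)
        if freqs.shape != gain.shape or freqs.size == 0:
            raise ValueError("freqs and gain must be equal-length, nonempty")
        if np.any(gain < 0):
            raise ValueError("gains must be nonnegative")
        if self.fwhm < 0:
            raise ValueError("FWHM must be nonnegative")


def compressive_gain(level: float | np.ndarray, params: SDPNParams = SDPNParams()):
    """Amplitude gain of the compressive nonlinearity at an RMS ``level``.

    ``nl_scale*arctan(nl_slope*level)/level``, continuously extended to the
    small-signal limit ``nl_scale*nl_slope`` at level 0.  Monotonically
    non-increasing: louder input, less gain.
    """
    arr = np.asarray(level, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("level must be nonnegative")
    safe = np.where(arr > 0, arr, 1.0)
    gain = np.where(
        arr > 0,
        params.nl_scale * np.arctan(params.nl_slope * safe) / safe,
        params.nl_scale * params.nl_slope,
    )
    return float(gain) if np.isscalar(level) or np.ndim(level) == 0 else gain


def _design_bandpass(order: int, cf: float, bw: float, rate: float, label: str):
    lo, hi = cf - bw / 2.0, cf + bw / 2.0
    nyquist = rate / 2.0
    if lo <= 0 or hi >= nyquist:
        raise ValueError(
            f"{label} passband ({lo:.1f}-{hi:.1f} Hz) of channel cf={cf:.0f} Hz "
            f"does not fit below the Nyquist frequency {nyquist:.1f} Hz"
        )
    return sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")


def design_channel_filters(
    spec: ChannelSpec, params: SDPNParams, rate: float
) -> ChannelFilters:
    """Design the tail and tip bandpass filters of one dual-path channel."""
    tail = _design_bandpass(params.tail_order, spec.cf, spec.bw_tail, rate, "tail")
    tip = _design_bandpass(params.tip_order, spec.cf, spec.bw_tip, rate, "tip")
    return ChannelFilters(tail=tail, tip=tip, rate=rate, spec=spec)


def running_rms(x: np.ndarray, window: float, rate: float) -> np.ndarray:
    """Causal running RMS over a rectangular window of ``window`` seconds."""
    n = max(1, int(round(window * rate)))
    mean_sq = sps.lfilter(np.ones(n) / n, [1.0], np.square(x))
    return np.sqrt(np.maximum(mean_sq, 0.0))


def process_sdpn_channel(
    x: Waveform, filters: ChannelFilters, params: SDPNParams = SDPNParams()
) -> Waveform:
    """Run one dual-path channel: gain*tail(x) + NL[tip(x)]."""
    if x.rate != filters.rate:
        raise ValueError(
            f"waveform rate {x.rate} Hz does not match filter design rate "
            f"{filters.rate} Hz"
        )
    tail_out = sps.sosfilt(filters.tail, x.samples)
    tip_out = sps.sosfilt(filters.tip, x.samples)
    if params.nl_mode == "instantaneous":
        nl_out = params.nl_scale * np.arctan(params.nl_slope * tip_out)
    else:
        drive = x.samples if params.rms_source == "input" else tip_out
        level = running_rms(drive, params.rms_window, x.rate)
        nl_out = compressive_gain(level, params) * tip_out
    return x.replace_samples(params.linear_gain * tail_out + nl_out)


def process_linear_channel(
    x: Waveform, spec: ChannelSpec, rate: float, order: int = CONVENTIONAL_ORDER
) -> Waveform:
    """Run one fixed bandpass channel of the conventional strategy."""
    if x.rate != rate:
        raise ValueError(f"waveform rate {x.rate} Hz does not match {rate} Hz")
    sos = _design_bandpass(order, spec.cf, spec.bw_channel, rate, "channel")
    return x.replace_samples(sps.sosfilt(sos, x.samples))


def sdpn_channel_processor(
    spec: ChannelSpec, params: SDPNParams = SDPNParams(), rate: float = 22050.0
) -> Callable[[Waveform], Waveform]:
    """A reusable dual-path channel: designs filters once, returns a callable."""
    filters = design_channel_filters(spec, params, rate)
    return lambda x: process_sdpn_channel(x, filters, params)


def linear_channel_processor(
    spec: ChannelSpec, rate: float = 22050.0, order: int = CONVENTIONAL_ORDER
) -> Callable[[Waveform], Waveform]:
    return lambda x: process_linear_channel(x, spec, rate, order)


def default_probe_freqs(cf: float, n: int = 201) -> np.ndarray:
    """Log-spaced probe grid spanning cf/3 to 3*cf."""
    return np.geomspace(cf / 3.0, cf * 3.0, n)


def frequency_response(
    processor: Callable[[Waveform], Waveform],
    level: float,
    freqs: Sequence[float],
    calib: Calibration = Calibration(),
    *,
    rate: float = 22050.0,
    duration: float = 0.5,
    settle: float = 0.1,
) -> FrequencyResponse:
    """Probe a channel with steady tones and measure its gain curve.

    Each probe is a ``duration``-second tone at amplitude
    ``spl_to_amplitude(level)``; the first ``settle`` seconds are discarded
    as onset transient and the gain is the remaining output RMS divided by
    the probe amplitude.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.size == 0:
        raise ValueError("at least one probe frequency is required")
    nyquist = rate / 2.0
    if np.any(freqs <= 0) or np.any(freqs >= nyquist):
        raise ValueError("probe frequencies must lie strictly inside (0, Nyquist)")
    amplitude = spl_to_amplitude(level, calib)
    t = np.arange(int(round(duration * rate))) / rate
    keep = t >= settle
    gains = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        probe = Waveform(amplitude * np.sin(2.0 * math.pi * f * t), rate)
        out = processor(probe)
        gains[i] = np.sqrt(np.mean(np.square(out.samples[keep]))) / amplitude
    peak = float(np.max(gains))
    width = fwhm_of_curve(freqs, gains)
    return FrequencyResponse(freqs=freqs, gain=gains, peak_gain=peak, fwhm=width)


def fwhm_of_curve(freqs: np.ndarray, gains: np.ndarray) -> float:
    """Full width at half maximum of a sampled gain curve.

    Width of the contiguous interval around the (unique) peak where the
    gain stays at or above half the peak, with linear interpolation at the
    two crossings.  Raises if either crossing lies outside the sampled
    range — including the degenerate flat-curve case.
    """
    i_peak = int(np.argmax(gains))
    half = gains[i_peak] / 2.0
    lo = hi = None
    for j in range(i_peak, 0, -1):
        if gains[j - 1] < half:
            lo = freqs[j] + (freqs[j - 1] - freqs[j]) * (gains[j] - half) / (
                gains[j] - gains[j - 1]
            )
            break
    for j in range(i_peak, len(gains) - 1):
        if gains[j + 1] < half:
            hi = freqs[j] + (freqs[j + 1] - freqs[j]) * (gains[j] - half) / (
                gains[j] - gains[j + 1]
            )
            break
    if lo is None or hi is None:
        raise ValueError(
            "range too narrow: gain does not fall below half maximum on both "
            "sides of the peak"
        )
    return float(hi - lo)


def fwhm_of(response: FrequencyResponse) -> float:
    """FWHM (Hz) of a :class:`FrequencyResponse`."""
    return fwhm_of_curve(response.freqs, response.gain)


def response_to_csv(response: FrequencyResponse, path) -> None:
    import pandas as pd

    pd.DataFrame({"freq_hz": response.freqs, "gain": response.gain}).to_csv(
        path, index=False
    )


def response_summary(response: FrequencyResponse) -> dict:
    """JSON-ready summary of a gain curve."""
    return {
        "peak_gain": response.peak_gain,
        "fwhm_hz": response.fwhm,
        "peak_freq_hz": float(response.freqs[int(np.argmax(response.gain))]),
        "n_freqs": int(response.freqs.size),
    }
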