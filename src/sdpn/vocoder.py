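"""Sinusoidal vocoder: the acoustic simulation of electrical stimulation.

Each channel's envelope amplitude-modulates one sinusoid at the channel
center frequency (the tail and tip filters share a center frequency, so a
single carrier per channel suffices), and the modulated carriers are
summed.  Normal-hearing listeners presented with this synthesis hear an
approximation of what an implant user receives.

``run_strategy`` chains the full processor: frequency decomposition
(fixed linear filterbank or the dual-path nonlinear model) -> envelope
detection (standard or transient-enhanced) -> carrier synthesis.  The
logarithmic compression applied before electrical stimulation in a real
implant is bypassed in acoustic simulation; a compression hook exists and
defaults to identity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .channels import ChannelMap, make_channel_map
from .envelopes import EnvelopeParams, envelope_enhanced, envelope_standard
from .model import (
    CONVENTIONAL_ORDER,
    SDPNParams,
    design_channel_filters,
    process_linear_channel,
    process_sdpn_channel,
)
from .stimuli import Calibration
from .waveform import Waveform

__all__ = ["StrategyConfig", "vocode_channels", "run_strategy"]


@dataclass(frozen=True)
class StrategyConfig:
    """Complete description of one sound-processing strategy."""

    model: str = "sdpn"
    envelope: str = "standard"
    map: ChannelMap = field(default_factory=lambda: make_channel_map(8))
    calib: Calibration = field(default_factory=Calibration)
    normalize_output: bool = True
    sdpn_params: SDPNParams = field(default_factory=SDPNParams)
    env_params: EnvelopeParams = field(default_factory=EnvelopeParams)
    linear_order: int = CONVENTIONAL_ORDER
    compression: Optional[Callable[[Waveform], Waveform]] = None

    def __post_init__(self) -> None:
        if self.model not in ("linear", "sdpn"):
            raise ValueError(f"unknown model: {self.model!r}")
        if self.envelope not in ("standard", "enhanced"):
            raise ValueError(f"unknown envelope detector: {self.envelope!r}")
        if len(self.map) == 0:
            raise ValueError("channel map must be nonempty")


def vocode_channels(envelopes: Sequence[Waveform], cmap: ChannelMap) -> Waveform:
    """Sum envelope-modulated sinusoids, one per channel.

    ``output(t) = sum_i env_i(t) * sin(2*pi*cf_i*t)`` with zero initial
    phase for every carrier (fixed phases keep outputs bit-reproducible).
    """
    if len(envelopes) != len(cmap):
        raise ValueError(
            f"got {len(envelopes)} envelopes for {len(cmap)} channels"
        )
    rates = {env.rate for env in envelopes}
    lengths = {len(env) for env in envelopes}
    if len(rates) != 1 or len(lengths) != 1:
        raise ValueError("all envelopes must share one rate and length")
    rate = rates.pop()
    t = np.arange(lengths.pop()) / rate
    total = np.zeros_like(t)
    for env, spec in zip(envelopes, cmap):
        total += env.samples * np.sin(2.0 * math.pi * spec.cf * t)
    return Waveform(total, rate)


def _decompose(x: Waveform, config: StrategyConfig) -> list[Waveform]:
    outputs = []
    for spec in config.map:
        if config.model == "linear":
            outputs.append(
                process_linear_channel(x, spec, x.rate, config.linear_order)
            )
        else:
            filters = design_channel_filters(spec, config.sdpn_params, x.rate)
            outputs.append(process_sdpn_channel(x, filters, config.sdpn_params))
    return outputs


def run_strategy(x: Waveform, config: StrategyConfig) -> Waveform:
    """Run the full strategy: decompose -> envelopes -> vocode.

    With ``normalize_output`` (default) the synthesized signal is rescaled
    to the input RMS, preventing clipping on 16-bit export; a silent input
    is returned silent.
    """
    detect = envelope_standard if config.envelope == "standard" else envelope_enhanced
    envelopes = [
        detect(channel_out, config.env_params)
        for channel_out in _decompose(x, config)
    ]
    if config.compression is not None:
        envelopes = [config.compression(env) for env in envelopes]
    out = vocode_channels(envelopes, config.map)
    if config.normalize_output:
        out_rms = out.rms()
        if out_rms > 0:
            out = out.scaled(x.rms() / out_rms)
    return out
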