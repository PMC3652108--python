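"""The dual-path channel: compression, filter design, level-dependent tuning."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sps

from sdpn import (
    DEMO_CHANNEL,
    Calibration,
    ChannelSpec,
    FrequencyResponse,
    SDPNParams,
    Waveform,
    compressive_gain,
    design_channel_filters,
    frequency_response,
    fwhm_of,
    linear_channel_processor,
    make_channel_map,
    process_linear_channel,
    process_sdpn_channel,
    sdpn_channel_processor,
)
from sdpn.model import default_probe_freqs, fwhm_of_curve

RATE = 22050.0


class TestCompressiveGain:
    def test_small_signal_limit_is_scale_times_slope(self):
        assert compressive_gain(0.0) == pytest.approx(30.0)
        assert compressive_gain(1e-9) == pytest.approx(30.0, rel=1e-6)

    def test_unit_level(self):
        assert compressive_gain(1.0) == pytest.approx(2.0 * math.atan(15.0), rel=1e-12)

    @given(
        a=st.floats(0.0, 1e3, allow_nan=False),
        b=st.floats(0.0, 1e3, allow_nan=False),
    )
    def test_monotone_compression(self, a, b):
        lo, hi = sorted((a, b))
        assert compressive_gain(lo) >= compressive_gain(hi)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            compressive_gain(-0.1)


class TestFilterDesign:
    def test_edges_at_half_power(self):
        filt = design_channel_filters(DEMO_CHANNEL, SDPNParams(), RATE)
        for sos, bw in [(filt.tail, 357.0), (filt.tip, 119.0)]:
            edges = [1500.0 - bw / 2.0, 1500.0 + bw / 2.0]
            _, h = sps.sosfreqz(sos, worN=edges, fs=RATE)
            assert np.abs(h) == pytest.approx(1.0 / math.sqrt(2.0), rel=0.01)

    def test_passband_reaching_nyquist_is_an_error(self):
        spec = ChannelSpec.from_channel_bw(4078.0, 2426.0)
        with pytest.raises(ValueError, match="4078"):
            design_channel_filters(spec, SDPNParams(), rate=8000.0)


def _steady_gain(y: Waveform, x: Waveform, settle: float = 0.1) -> float:
    keep = y.times >= settle
    return float(
        np.sqrt(np.mean(y.samples[keep] ** 2)) / np.sqrt(np.mean(x.samples[keep] ** 2))
    )


class TestSDPNChannel:
    def test_silence_in_silence_out(self, tone):
        filt = design_channel_filters(DEMO_CHANNEL, SDPNParams(), RATE)
        x = Waveform(np.zeros(2048), RATE)
        assert not np.any(process_sdpn_channel(x, filt, SDPNParams()).samples)

    def test_rate_mismatch_rejected(self, tone):
        filt = design_channel_filters(DEMO_CHANNEL, SDPNParams(), RATE)
        with pytest.raises(ValueError, match="rate"):
            process_sdpn_channel(tone(1000.0, rate=16000.0), filt, SDPNParams())

    @pytest.mark.parametrize("nl_mode", ["rms_gain", "instantaneous"])
    def test_small_signal_matches_linear_two_path_system(self, tone, nl_mode):
        """Brute-force oracle: for 15*RMS < 0.01 the channel behaves as the
        linear system 6*H_tail + 30*H_tip applied directly."""
        params = SDPNParams(nl_mode=nl_mode)
        filt = design_channel_filters(DEMO_CHANNEL, params, RATE)
        x = tone(1500.0, amplitude=5e-4)
        assert 15.0 * x.rms() < 0.01
        got = process_sdpn_channel(x, filt, params)
        oracle = 6.0 * sps.sosfilt(filt.tail, x.samples) + 30.0 * sps.sosfilt(
            filt.tip, x.samples
        )
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(got.samples - oracle)) <= 0.01 * scale

    def test_small_signal_amplitude_prediction(self, tone):
        """Output amplitude at cf equals (6|H_tail| + 30|H_tip|)*A for tiny A,
        with the filter gains measured independently."""
        params = SDPNParams()
        filt = design_channel_filters(DEMO_CHANNEL, params, RATE)
        _, h_tail = sps.sosfreqz(filt.tail, worN=[1500.0], fs=RATE)
        _, h_tip = sps.sosfreqz(filt.tip, worN=[1500.0], fs=RATE)
        expected = 6.0 * np.abs(h_tail[0]) + 30.0 * np.abs(h_tip[0])
        x = tone(1500.0, amplitude=1e-4)
        y = process_sdpn_channel(x, filt, params)
        assert _steady_gain(y, x) == pytest.approx(expected, rel=0.02)

    def test_gain_compresses_with_level(self, tone):
        params = SDPNParams()
        filt = design_channel_filters(DEMO_CHANNEL, params, RATE)
        quiet = tone(1500.0, amplitude=1e-4)
        loud = tone(1500.0, amplitude=1e-2)
        g_quiet = _steady_gain(process_sdpn_channel(quiet, filt, params), quiet)
        g_loud = _steady_gain(process_sdpn_channel(loud, filt, params), loud)
        assert g_loud < g_quiet

    def test_small_signal_superposition(self, tone):
        """Below the compression knee the channel is linear: processing a sum
        equals the sum of processed parts."""
        params = SDPNParams()
        filt = design_channel_filters(DEMO_CHANNEL, params, RATE)
        a = tone(1450.0, amplitude=2e-4)
        b = tone(1550.0, amplitude=2e-4)
        both = Waveform(a.samples + b.samples, RATE)
        lhs = process_sdpn_channel(both, filt, params).samples
        rhs = (
            process_sdpn_channel(a, filt, params).samples
            + process_sdpn_channel(b, filt, params).samples
        )
        assert np.max(np.abs(lhs - rhs)) <= 0.02 * np.max(np.abs(lhs))

    def test_instantaneous_path_is_bounded_by_arctan_saturation(self, tone):
        """The nonlinear pathway contributes at most nl_scale*pi/2 per sample
        no matter how loud the input."""
        params = SDPNParams(nl_mode="instantaneous")
        filt = design_channel_filters(DEMO_CHANNEL, params, RATE)
        x = tone(1500.0, amplitude=1e4)
        out = process_sdpn_channel(x, filt, params)
        tail_part = 6.0 * sps.sosfilt(filt.tail, x.samples)
        nl_part = out.samples - tail_part
        assert np.max(np.abs(nl_part)) <= 2.0 * math.pi / 2.0 + 1e-9


class TestLinearChannel:
    def test_tone_at_cf_passes_at_full_gain(self, tone):
        x = tone(1500.0)
        y = process_linear_channel(x, DEMO_CHANNEL, RATE)
        assert _steady_gain(y, x) == pytest.approx(1.0, rel=0.01)

    def test_tone_at_four_cf_strongly_attenuated(self, tone):
        x_cf, x_far = tone(1500.0), tone(6000.0)
        g_cf = _steady_gain(process_linear_channel(x_cf, DEMO_CHANNEL, RATE), x_cf)
        g_far = _steady_gain(process_linear_channel(x_far, DEMO_CHANNEL, RATE), x_far)
        assert 20.0 * math.log10(g_cf / g_far) >= 20.0

    def test_silence(self):
        x = Waveform(np.zeros(1024), RATE)
        assert not np.any(process_linear_channel(x, DEMO_CHANNEL, RATE).samples)


class TestFrequencyResponse:
    def test_empty_probe_grid_rejected(self):
        proc = linear_channel_processor(DEMO_CHANNEL, RATE)
        with pytest.raises(ValueError):
            frequency_response(proc, 35.0, [], Calibration())

    def test_linear_channel_is_level_independent(self):
        proc = linear_channel_processor(DEMO_CHANNEL, RATE)
        freqs = default_probe_freqs(1500.0, 31)
        lo = frequency_response(proc, 35.0, freqs)
        hi = frequency_response(proc, 85.0, freqs)
        assert lo.gain == pytest.approx(hi.gain, rel=1e-9)

    def test_level_dependent_broadening_across_tabulated_channels(self):
        """Louder probes give broader, lower-gain tuning in every channel of
        the 8-channel map."""
        for spec in make_channel_map(8):
            proc = sdpn_channel_processor(spec, SDPNParams(), RATE)
            freqs = np.geomspace(spec.cf / 3.0, min(3.0 * spec.cf, 0.95 * RATE / 2), 61)
            quiet = frequency_response(proc, 35.0, freqs, duration=0.3)
            loud = frequency_response(proc, 85.0, freqs, duration=0.3)
            assert loud.fwhm > quiet.fwhm, f"no broadening at cf={spec.cf}"
            assert loud.peak_gain < quiet.peak_gain, f"no compression at cf={spec.cf}"


class TestFWHM:
    def test_triangular_curve(self):
        freqs = np.array([500.0, 1000.0, 1500.0])
        gains = np.array([0.0, 1.0, 0.0])
        assert fwhm_of_curve(freqs, gains) == pytest.approx(500.0)

    def test_flat_curve_has_no_width(self):
        freqs = np.linspace(100.0, 200.0, 11)
        with pytest.raises(ValueError, match="range too narrow"):
            fwhm_of_curve(freqs, np.ones_like(freqs))

    def test_gaussian_width_matches_closed_form(self):
        sigma = 80.0
        freqs = np.linspace(500.0, 2500.0, 801)
        gains = np.exp(-0.5 * ((freqs - 1500.0) / sigma) ** 2)
        expected = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma  # 2.3548*sigma
        resp = FrequencyResponse(freqs=freqs, gain=gains, peak_gain=1.0,
                                 fwhm=fwhm_of_curve(freqs, gains))
        assert fwhm_of(resp) == pytest.approx(expected, abs=2.0 * 2.5)
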