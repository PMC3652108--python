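"""Channel maps: tabulated analysis bands and the tail/tip bandwidth split.

Both processing strategies analyse sound in the same set of frequency bands.
The 4-, 8- and 12-channel maps (logarithmic spacing for 4 channels,
semilogarithmic mel spacing for 8 and 12) are embedded verbatim; they are
the ground truth, not re-derived from a spacing formula.

Each dual-path channel splits its analysis bandwidth between a broad linear
"tail" filter and a sharp "tip" filter one third as wide, mirroring the tail
and tip of a cochlear tuning curve.  Note: some published tabulations label
the broad row "tip" and the narrow row "tail"; here the broad filter is the
tail throughout, consistent with the physiological convention.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ChannelSpec",
    "ChannelMap",
    "split_bandwidths",
    "make_channel_map",
    "bandwidth_for_cf",
    "channel_map_to_csv",
    "channel_map_from_csv",
]

#: tail bandwidth : tip bandwidth ratio of the dual-path channel
TAIL_TIP_RATIO = 3.0

# Tabulated center frequencies and analysis bandwidths (Hz).
_TABLES: dict[int, tuple[str, tuple[float, ...], tuple[float, ...]]] = {
    4: (
        "logarithmic",
        (460.0, 953.0, 1971.0, 4078.0),
        (321.0, 664.0, 1373.0, 2426.0),
    ),
    8: (
        "mel",
        (394.0, 692.0, 1064.0, 1528.0, 2109.0, 2834.0, 3740.0, 4871.0),
        (265.0, 331.0, 431.0, 516.0, 645.0, 805.0, 1006.0, 1257.0),
    ),
    12: (
        "mel",
        (274.0, 453.0, 662.0, 905.0, 1190.0, 1521.0, 1908.0, 2359.0,
         2885.0, 3499.0, 4215.0, 5050.0),
        (165.0, 193.0, 225.0, 262.0, 306.0, 357.0, 416.0, 486.0,
         567.0, 661.0, 771.0, 900.0),
    ),
}


def split_bandwidths(bw_channel: float) -> tuple[float, float]:
    """Split a channel bandwidth into (tail, tip) bandwidths.

    The broad tail filter keeps the full analysis bandwidth; the sharp tip
    filter gets one third of it.

    >>> split_bandwidths(321.0)
    (321.0, 107.0)
    """
    if not bw_channel > 0:
        raise ValueError(f"bandwidth must be positive, got {bw_channel}")
    return float(bw_channel), float(bw_channel) / TAIL_TIP_RATIO


@dataclass(frozen=True)
class ChannelSpec:
    """One analysis channel: center frequency and its three bandwidths (Hz)."""

    cf: float
    bw_channel: float
    bw_tail: float
    bw_tip: float

    def __post_init__(self) -> None:
        if not self.cf > 0:
            raise ValueError(f"center frequency must be positive, got {self.cf}")
        for name in ("bw_channel", "bw_tail", "bw_tip"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.bw_tail - TAIL_TIP_RATIO * self.bw_tip) > 0.1 * TAIL_TIP_RATIO:
            raise ValueError(
                f"tail bandwidth must be {TAIL_TIP_RATIO}x the tip bandwidth "
                f"(got {self.bw_tail} vs {self.bw_tip})"
            )

    @classmethod
    def from_channel_bw(cls, cf: float, bw_channel: float) -> "ChannelSpec":
        tail, tip = split_bandwidths(bw_channel)
        return cls(cf=float(cf), bw_channel=float(bw_channel), bw_tail=tail, bw_tip=tip)


@dataclass(frozen=True)
class ChannelMap:
    """Ordered set of analysis channels plus the spacing rule that made them."""

    channels: tuple[ChannelSpec, ...]
    spacing_kind: str = "logarithmic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        if not self.channels:
            raise ValueError("channel map must contain at least one channel")
        cfs = [c.cf for c in self.channels]
        if not all(a < b for a, b in zip(cfs, cfs[1:])):
            raise ValueError("center frequencies must be strictly increasing")
        if self.spacing_kind not in ("logarithmic", "mel"):
            raise ValueError(f"unknown spacing kind: {self.spacing_kind!r}")

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self):
        return iter(self.channels)

    @property
    def cfs(self) -> np.ndarray:
        return np.array([c.cf for c in self.channels])


def make_channel_map(n: int) -> ChannelMap:
    """Return the tabulated ``n``-channel map (``n`` in {4, 8, 12}).

    Arbitrary maps can be assembled directly from :class:`ChannelSpec`
    objects; this constructor deliberately refuses to interpolate.
    """
    if n not in _TABLES:
        raise ValueError(
            f"no tabulated map for {n} channels (available: {sorted(_TABLES)})"
        )
    spacing, cfs, bws = _TABLES[n]
    channels = tuple(
        ChannelSpec.from_channel_bw(cf, bw) for cf, bw in zip(cfs, bws)
    )
    return ChannelMap(channels=channels, spacing_kind=spacing)


def bandwidth_for_cf(cf: float) -> float:
    """Analysis bandwidth at an arbitrary center frequency.

    Interpolates the 12-channel table linearly in log(cf)-log(bw) and
    extrapolates with the end-segment slopes, so per-partition analyses
    (100 Hz - 10 kHz) rely only on tabulated numbers.
    """
    if not cf > 0:
        raise ValueError(f"center frequency must be positive, got {cf}")
    _, cfs, bws = _TABLES[12]
    lx, ly = np.log(np.asarray(cfs)), np.log(np.asarray(bws))
    x = np.log(cf)
    if x <= lx[0]:
        slope = (ly[1] - ly[0]) / (lx[1] - lx[0])
        return float(np.exp(ly[0] + slope * (x - lx[0])))
    if x >= lx[-1]:
        slope = (ly[-1] - ly[-2]) / (lx[-1] - lx[-2])
        return float(np.exp(ly[-1] + slope * (x - lx[-1])))
    return float(np.exp(np.interp(x, lx, ly)))


_CSV_COLUMNS = ["channel", "cf_hz", "bw_channel_hz", "bw_tail_hz", "bw_tip_hz"]


def channel_map_to_csv(cmap: ChannelMap, path: str | Path | io.TextIOBase) -> None:
    frame = pd.DataFrame(
        {
            "channel": np.arange(1, len(cmap) + 1),
            "cf_hz": [c.cf for c in cmap],
            "bw_channel_hz": [c.bw_channel for c in cmap],
            "bw_tail_hz": [c.bw_tail for c in cmap],
            "bw_tip_hz": [c.bw_tip for c in cmap],
        }
    )
    frame.to_csv(path, index=False)


def channel_map_from_csv(
    path: str | Path | io.TextIOBase, spacing_kind: str = "logarithmic"
) -> ChannelMap:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"channel map CSV missing columns: {missing}")
    frame = frame.sort_values("channel")
    channels = tuple(
        ChannelSpec(
            cf=row.cf_hz,
            bw_channel=row.bw_channel_hz,
            bw_tail=row.bw_tail_hz,
            bw_tip=row.bw_tip_hz,
        )
        for row in frame.itertuples()
    )
    return ChannelMap(channels=channels, spacing_kind=spacing_kind)
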