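"""Minimum-coverage detectability model.

A plant covering a fraction f of the measuring spot shifts each Lab channel
of the reading linearly from the background mean toward the plant mean
(area-weighted mixing).  The statistical existence rule fires once that
shift reaches the summed standard deviations of background and object, so
the smallest detectable relative coverage for channel ch is

    A_ch = 100 * (sigma_ch,BG + sigma_ch,Obj) / |ch_Obj - ch_BG|   [percent]

The virtual d channel analog uses |a - b| means and the conservative
sigma_d = sigma_a + sigma_b propagation on each side.  Coinciding channel
means make the channel useless: A is then the +inf sentinel.  Values above
100% likewise mean "not detectable on this channel even at full coverage".

``coverage_table`` evaluates the model over whole background and green-tone
databases; ``min_plant_area`` converts a relative coverage into an absolute
plant area for a given circular spot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from labweed.color_db import ColorStats, ColorDatabase, GreenTone, SurfaceClass

__all__ = [
    "CoverageCell",
    "SpotGeometry",
    "required_coverage",
    "coverage_table",
    "coverage_frame",
    "min_plant_area",
    "CHANNELS",
]

CHANNELS = ("L", "a", "b", "d")


@dataclass(frozen=True)
class CoverageCell:
    """Required relative coverage A (percent of spot area) for one
    background x green x channel combination; math.inf when the channel
    means coincide."""

    background: str
    green: str
    channel: str
    A: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.A < 0 or math.isnan(self.A):
            raise ValueError(f"A must be >= 0, got {self.A}")


@dataclass(frozen=True)
class SpotGeometry:
    """Circular measuring spot; area follows from the diameter."""

    diameter: float

    def __post_init__(self) -> None:
        if not (self.diameter > 0 and math.isfinite(self.diameter)):
            raise ValueError(f"diameter must be positive, got {self.diameter}")

    @property
    def area(self) -> float:
        return math.pi * (self.diameter / 2.0) ** 2


def required_coverage(
    bg: ColorStats | SurfaceClass,
    obj: ColorStats | GreenTone,
    channel: str,
    bg_name: str | None = None,
    obj_name: str | None = None,
) -> CoverageCell:
    """Smallest detectable coverage (percent) on one channel."""
    if isinstance(bg, SurfaceClass):
        bg_name = bg_name or bg.name
        bg = bg.stats
    if isinstance(obj, GreenTone):
        obj_name = obj_name or obj.name
        obj = obj.stats
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
    separation = abs(obj.channel_mean(channel) - bg.channel_mean(channel))
    sigma_sum = bg.channel_sigma(channel) + obj.channel_sigma(channel)
    if separation == 0.0:
        warnings.warn(
            f"channel {channel} means coincide for {bg_name or 'background'} x "
            f"{obj_name or 'object'}; coverage undefined (+inf)",
            stacklevel=2,
        )
        A = math.inf
    else:
        A = 100.0 * sigma_sum / separation
    return CoverageCell(
        background=bg_name or "background",
        green=obj_name or "object",
        channel=channel,
        A=A,
    )


def coverage_table(
    backgrounds: tuple[SurfaceClass, ...] | list[SurfaceClass],
    greens: tuple[GreenTone, ...] | list[GreenTone],
    channels: tuple[str, ...] = CHANNELS,
) -> list[CoverageCell]:
    """Required coverage over a full background x green x channel grid.

    Cells are ordered background-major, then green, then channel, matching
    the standard tabular layout (rows = backgrounds, column blocks =
    greens x channels).
    """
    if not backgrounds or not greens or not channels:
        raise ValueError("backgrounds, greens and channels must all be non-empty")
    return [
        required_coverage(s, g, ch)
        for s in backgrounds
        for g in greens
        for ch in channels
    ]


def coverage_frame(db: ColorDatabase, channels: tuple[str, ...] = CHANNELS,
                   decimals: int = 1) -> pd.DataFrame:
    """Coverage grid as a DataFrame (rows = backgrounds, columns =
    (green, channel)), rounded for reporting."""
    cells = coverage_table(db.surfaces, db.greens, channels)
    df = pd.DataFrame([c.__dict__ for c in cells])
    wide = df.pivot(index="background", columns=["green", "channel"], values="A")
    wide = wide.reindex(index=[s.name for s in db.surfaces])
    wide = wide.reindex(
        columns=pd.MultiIndex.from_product(
            [[g.name for g in db.greens], list(channels)]
        )
    )
    return wide.round(decimals)


def min_plant_area(A_percent: float, spot: SpotGeometry) -> float:
    """Absolute plant area (cm^2) for coverage A percent of the spot,
    rounded to one decimal for reporting."""
    if A_percent < 0 or math.isnan(A_percent):
        raise ValueError(f"A_percent must be >= 0, got {A_percent}")
    return round(A_percent / 100.0 * spot.area, 1)
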