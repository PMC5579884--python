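"""CIE-Lab color types and color-difference math.

The CIE-Lab space separates luminance (L, nominally 0 for black to 100 for
white) from two opponent coloration axes: a (negative = green, positive =
red) and b (negative = blue, positive = yellow).  The total color difference
between two Lab triples is the Euclidean distance ``dE``; per-channel
differences ``dL``, ``da``, ``db`` are the absolute channel deltas, so that
``dE**2 == dL**2 + da**2 + db**2`` holds exactly.

A *virtual d channel* ``|a - b|`` serves as an auxiliary discrimination
feature: green vegetation has strongly negative a and (for most tones)
positive b, which spreads d well beyond the range of bare soils and
pavements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "LabColor",
    "DeltaVector",
    "delta_e",
    "delta_channels",
    "virtual_d",
    "categorize_delta_e",
    "DELTA_E_CATEGORIES",
]


@dataclass(frozen=True)
class LabColor:
    """One CIE-Lab triple.

    Construction rejects non-finite values.  Values outside the nominal
    ranges (L < 0 or L > 100, |a| or |b| > 128) are accepted with a warning
    because sensor calibration drift should not crash a pipeline.
    """

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("L", "a", "b"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise TypeError(f"channel {name} must be a real number, got {v!r}")
            if not math.isfinite(v):
                raise ValueError(f"channel {name} must be finite, got {v!r}")
        if not (0.0 <= self.L <= 100.0):
            warnings.warn(
                f"L={self.L} outside nominal 0-100 range (sensor drift?)",
                stacklevel=3,
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.L, self.a, self.b)


@dataclass(frozen=True)
class DeltaVector:
    """Per-channel color differences between two Lab readings.

    ``d_bg`` and ``d_reading`` carry the virtual d channel of each input so
    that downstream rules can compare them without re-deriving the colors.
    """

    dE: float
    dL: float
    da: float
    db: float
    d_bg: float = 0.0
    d_reading: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dE", "dL", "da", "db", "d_bg", "d_reading"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative number, got {v!r}")
        ssq = self.dL ** 2 + self.da ** 2 + self.db ** 2
        if not math.isclose(self.dE ** 2, ssq, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                f"inconsistent DeltaVector: dE^2={self.dE ** 2} != dL^2+da^2+db^2={ssq}"
            )


def _check(c: LabColor, arg: str) -> LabColor:
    if not isinstance(c, LabColor):
        raise TypeError(f"{arg} must be a LabColor, got {type(c).__name__}")
    return c


def delta_e(c1: LabColor, c2: LabColor) -> float:
    """Euclidean color distance between two Lab colors (symmetric, >= 0)."""
    _check(c1, "c1")
    _check(c2, "c2")
    return math.hypot(c1.L - c2.L, c1.a - c2.a, c1.b - c2.b)


def delta_channels(c1: LabColor, c2: LabColor) -> DeltaVector:
    """Absolute per-channel differences plus total dE and both d channels."""
    _check(c1, "c1")
    _check(c2, "c2")
    dL = abs(c1.L - c2.L)
    da = abs(c1.a - c2.a)
    db = abs(c1.b - c2.b)
    return DeltaVector(
        dE=math.hypot(dL, da, db),
        dL=dL,
        da=da,
        db=db,
        d_bg=virtual_d(c1),
        d_reading=virtual_d(c2),
    )


def virtual_d(c: LabColor) -> float:
    """Virtual d channel: absolute difference of the two coloration axes."""
    _check(c, "c")
    return abs(c.a - c.b)


#: Color-difference interpretation scale: (lower bound, label).  Intervals are
#: half-open [lower, next lower); the last category is open-ended.
DELTA_E_CATEGORIES: tuple[tuple[float, str], ...] = (
    (0.0, "no to almost no difference"),
    (0.5, "difference may be noticeable to the trained eye"),
    (1.0, "weak perceptible color difference"),
    (2.0, "perceived color difference"),
    (4.0, "substantial difference in color, which is rarely tolerated"),
    (5.0, "high difference defined as a different color"),
)


def categorize_delta_e(dE: float) -> str:
    """Map a color difference onto the six-step interpretation scale."""
    if not math.isfinite(dE) or dE < 0:
        raise ValueError(f"dE must be a finite non-negative number, got {dE!r}")
    label = DELTA_E_CATEGORIES[0][1]
    for lower, name in DELTA_E_CATEGORIES:
        if dE >= lower:
            label = name
        else:
            break
    return label
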