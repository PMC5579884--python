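"""Detection algorithms and the multistage green-tone classifier.

Four ways to decide whether a measuring spot contains a plant, all relative
to a calibrated background:

1. **Total color difference** — trigger when dE between reading and
   background mean exceeds a threshold (strict ``>``).
2. **Per-channel differences** — thresholds on dL, da, db (and optionally
   the virtual d channel), combined with *any* or *all*.
3. **Statistical existence rule** — a plant exists if, in at least one
   channel, the reading departs from the background mean by at least the sum
   of the background and object standard deviations (``>=`` at the
   boundary).
4. **Multistage differentiation** — first flag suspicious readings with dE,
   then attribute the flagged reading to a green tone by comparing the
   *direction* of its Lab offset from the background against each candidate
   tone's direction.  Under area-weighted linear mixing a plant covering a
   fraction f of the spot shifts the reading by f times the full
   background-to-green difference vector, so the direction is independent of
   plant size; cosine similarity therefore classifies the tone without
   knowing the coverage.

Boundary conventions (strict ``>`` for the threshold detectors, ``>=`` for
the statistical rule) are deliberate, documented constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from labweed.color_core import LabColor, DeltaVector, delta_channels, virtual_d
from labweed.color_db import ColorStats, GreenTone

__all__ = [
    "Thresholds",
    "Decision",
    "SprayCommand",
    "detect_delta_e",
    "detect_channels",
    "detect_statistical",
    "classify_green",
    "spray_decision",
    "PRESETS",
]

_CHANNELS = ("L", "a", "b")


@dataclass(frozen=True)
class Thresholds:
    """Detector thresholds; absent (None) channels do not participate.

    ``combine`` controls the channel detector: "any" (default) fires when
    any present channel exceeds its threshold, "all" requires every present
    channel to exceed.
    """

    t_dE: float | None = None
    t_dL: float | None = None
    t_da: float | None = None
    t_db: float | None = None
    t_dd: float | None = None
    combine: str = "any"

    def __post_init__(self) -> None:
        for name in ("t_dE", "t_dL", "t_da", "t_db", "t_dd"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.combine not in ("any", "all"):
            raise ValueError(f"combine must be 'any' or 'all', got {self.combine!r}")


#: Scenario presets: thresholds that filtered out all objects in the three
#: reference scenarios (paved ground, young wheat stand, dock on grassland).
PRESETS: dict[str, Thresholds] = {
    "paved": Thresholds(t_dE=5.0, t_dL=5.0, t_da=2.0, t_db=2.0),
    "wheat": Thresholds(t_dE=12.0),
    "grassland-dock": Thresholds(t_dE=7.0, t_dL=7.0),
}


@dataclass(frozen=True)
class Decision:
    """Outcome of one detector on one reading."""

    detect: bool
    triggered: frozenset[str]
    deltas: DeltaVector
    rule: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "triggered", frozenset(self.triggered))
        if self.detect != bool(self.triggered):
            raise ValueError("detect must be true iff the triggered set is non-empty")
        bad = self.triggered - {"E", "L", "a", "b", "d"}
        if bad:
            raise ValueError(f"unknown triggered channels: {sorted(bad)}")


_MODES = ("positive", "negative")


@dataclass(frozen=True)
class SprayCommand:
    spray: bool
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")


def detect_delta_e(reading: LabColor, background: ColorStats, t: Thresholds) -> Decision:
    """Detect when the total color difference to the background exceeds t_dE."""
    if t.t_dE is None:
        raise ValueError("detect_delta_e requires t_dE")
    deltas = delta_channels(background.mean, reading)
    hit = deltas.dE > t.t_dE
    return Decision(
        detect=hit,
        triggered=frozenset({"E"}) if hit else frozenset(),
        deltas=deltas,
        rule="delta_e",
    )


def detect_channels(reading: LabColor, background: ColorStats, t: Thresholds) -> Decision:
    """Detect on per-channel differences, combined with t.combine."""
    pairs = (("L", t.t_dL), ("a", t.t_da), ("b", t.t_db), ("d", t.t_dd))
    present = [(ch, thr) for ch, thr in pairs if thr is not None]
    if not present:
        raise ValueError("detect_channels requires at least one channel threshold")
    deltas = delta_channels(background.mean, reading)
    values = {
        "L": deltas.dL,
        "a": deltas.da,
        "b": deltas.db,
        "d": abs(deltas.d_reading - deltas.d_bg),
    }
    fired = {ch for ch, thr in present if values[ch] > thr}
    hit = bool(fired) if t.combine == "any" else len(fired) == len(present)
    return Decision(
        detect=hit,
        triggered=frozenset(fired) if hit else frozenset(),
        deltas=deltas,
        rule="channels",
    )


def detect_statistical(
    reading: LabColor, background: ColorStats, obj: ColorStats
) -> Decision:
    """Statistical existence rule.

    An object exists if, for at least one channel, the reading departs from
    the background mean by at least the summed background and object
    standard deviations.
    """
    sig_bg = background.effective_sigma()
    sig_obj = obj.effective_sigma()
    deltas = delta_channels(background.mean, reading)
    values = {"L": deltas.dL, "a": deltas.da, "b": deltas.db}
    fired = {
        ch
        for i, ch in enumerate(_CHANNELS)
        if values[ch] >= sig_bg[i] + sig_obj[i]
    }
    return Decision(
        detect=bool(fired),
        triggered=frozenset(fired),
        deltas=deltas,
        rule="statistical",
    )


def classify_green(
    reading: LabColor,
    background: ColorStats,
    greens: list[GreenTone] | tuple[GreenTone, ...],
    include_d: bool = False,
    tie_tol: float = 1e-12,
) -> tuple[GreenTone, float]:
    """Attribute an already-flagged reading to the best-matching green tone.

    Matches the direction of the observed offset ``reading - background
    mean`` against each candidate direction ``green mean - background mean``
    by cosine similarity; the winner and its score (in [-1, 1]) are
    returned.  Size-invariant: under noise-free linear mixing the offset is
    f times the candidate direction, for any coverage f > 0.

    ``include_d`` adds the virtual d channel as a fourth vector component;
    off by default since d is a function of a and b.
    """
    if not greens:
        raise ValueError("need at least one candidate green tone")

    def feature(c: LabColor) -> np.ndarray:
        v = [c.L, c.a, c.b]
        if include_d:
            v.append(virtual_d(c))
        return np.asarray(v, dtype=float)

    v = feature(reading) - feature(background.mean)
    nv = np.linalg.norm(v)
    if nv == 0.0:
        raise ValueError("reading equals the background mean; no direction to classify")
    scores = []
    for g in greens:
        u = feature(g.stats.mean) - feature(background.mean)
        nu = np.linalg.norm(u)
        if nu == 0.0:
            raise ValueError(f"green tone {g.name!r} coincides with the background mean")
        scores.append(float(v @ u / (nv * nu)))
    order = np.argsort(scores)[::-1]
    best, second = order[0], (order[1] if len(order) > 1 else None)
    if second is not None and scores[best] - scores[second] <= tie_tol:
        tied = [greens[i].name for i in order if scores[best] - scores[i] <= tie_tol]
        raise ValueError(f"ambiguous classification; tied candidates: {tied}")
    return greens[best], scores[best]


def spray_decision(d: Decision, mode: str) -> SprayCommand:
    """Positive mode sprays on detection; negative mode sprays unless detected."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    return SprayCommand(spray=d.detect if mode == "positive" else not d.detect, mode=mode)
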