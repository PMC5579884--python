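"""Color databases of backgrounds and green tones.

Detection is always *relative*: a reading is compared against the Lab
statistics of a plant-free reference surface (the background) and, for
classification and the coverage model, against one or more reference green
tones.  This module provides

* ``ColorStats`` — per-channel mean/median/sigma/min/max summary,
* ``SurfaceClass`` / ``GreenTone`` — a named background or green reference,
* ``summarize`` / ``calibrate_background`` — field calibration from a stream
  of readings taken on a weed-free patch,
* JSON persistence plus packaged fixture databases: ten backgrounds (seven
  anthropogenic pavements/gravels, three natural soil/grassland surfaces)
  and four green color tones from bright to dark green.

Green-tone fixtures carry no measured standard deviation; where one is
needed the quarter-range convention ``sigma = |max - min| / 4`` is applied
per channel (a small-sample approximation, overridable per entry).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from labweed.color_core import LabColor

__all__ = [
    "ColorStats",
    "SurfaceClass",
    "GreenTone",
    "ColorDatabase",
    "summarize",
    "calibrate_background",
    "load_database",
    "save_database",
    "default_database",
    "read_readings_csv",
]

_CHANNELS = ("L", "a", "b")


@dataclass(frozen=True)
class ColorStats:
    """Per-channel summary statistics of a surface or green tone.

    ``sigma`` may be absent (transcribed references without a printed
    standard deviation); :meth:`effective_sigma` then falls back to the
    quarter-range convention.  Channel-wise ``min <= mean <= max``
    violations are recorded in ``flags`` and warned about, not rejected,
    because transcribed reference tables are kept verbatim.
    """

    mean: LabColor
    sigma: tuple[float, float, float] | None = None
    min: LabColor | None = None
    max: LabColor | None = None
    median: LabColor | None = None
    n: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sigma is not None:
            sig = tuple(float(s) for s in self.sigma)
            if len(sig) != 3:
                raise ValueError("sigma must have exactly three components (L, a, b)")
            for s in sig:
                if not math.isfinite(s) or s < 0:
                    raise ValueError(f"sigma components must be finite and >= 0, got {s}")
            object.__setattr__(self, "sigma", sig)
        if self.n is not None and self.n < 1:
            raise ValueError(f"n must be positive, got {self.n}")
        suspect = list(self.flags)
        if self.min is not None and self.max is not None:
            for ch in _CHANNELS:
                lo, mu, hi = (
                    getattr(self.min, ch),
                    getattr(self.mean, ch),
                    getattr(self.max, ch),
                )
                if not (min(lo, hi) - 1e-9 <= mu <= max(lo, hi) + 1e-9) or lo > hi:
                    tag = f"suspect-{ch}"
                    if tag not in suspect:
                        suspect.append(tag)
        if tuple(suspect) != self.flags:
            warnings.warn(
                f"ColorStats min/mean/max ordering violated on "
                f"{[f for f in suspect if f not in self.flags]}; kept as transcribed",
                stacklevel=3,
            )
            object.__setattr__(self, "flags", tuple(suspect))

    def effective_sigma(self) -> tuple[float, float, float]:
        """Stored sigma, or the quarter-range ``|max - min| / 4`` fallback."""
        if self.sigma is not None:
            return self.sigma
        if self.min is None or self.max is None:
            raise ValueError("no sigma stored and no min/max to derive it from")
        return tuple(
            abs(getattr(self.max, ch) - getattr(self.min, ch)) / 4.0 for ch in _CHANNELS
        )

    def channel_mean(self, ch: str) -> float:
        if ch == "d":
            return abs(self.mean.a - self.mean.b)
        return getattr(self.mean, ch)

    def channel_sigma(self, ch: str) -> float:
        sig = self.effective_sigma()
        if ch == "d":
            # conservative propagation for the derived |a-b| channel
            return sig[1] + sig[2]
        return sig[_CHANNELS.index(ch)]


_CATEGORIES = ("anthropogenic", "natural")


@dataclass(frozen=True)
class SurfaceClass:
    """A named plant-free background surface with its color statistics."""

    name: str
    category: str
    stats: ColorStats
    aliases: tuple[str, ...] = ()
    provenance: str | None = None

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(
                f"category must be one of {_CATEGORIES}, got {self.category!r}"
            )


@dataclass(frozen=True)
class GreenTone:
    """A named reference green tone (plant color card) with statistics."""

    name: str
    stats: ColorStats


@dataclass(frozen=True)
class ColorDatabase:
    surfaces: tuple[SurfaceClass, ...] = ()
    greens: tuple[GreenTone, ...] = ()

    def surface(self, name: str) -> SurfaceClass:
        for s in self.surfaces:
            if s.name == name or name in s.aliases:
                return s
        raise KeyError(f"no surface named {name!r}")

    def green(self, name: str) -> GreenTone:
        for g in self.greens:
            if g.name == name:
                return g
        raise KeyError(f"no green tone named {name!r}")


def summarize(readings: Sequence[LabColor] | Iterable[LabColor]) -> ColorStats:
    """Per-channel mean, median, sample std (n-1), min, max of a reading stream.

    Requires at least two readings (the sample standard deviation is
    undefined for one).
    """
    arr = np.asarray([r.as_tuple() for r in readings], dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError(f"need at least 2 readings, got {0 if arr.size == 0 else arr.shape[0]}")
    mean = arr.mean(axis=0)
    return ColorStats(
        mean=LabColor(*mean),
        median=LabColor(*np.median(arr, axis=0)),
        sigma=tuple(arr.std(axis=0, ddof=1)),
        min=LabColor(*arr.min(axis=0)),
        max=LabColor(*arr.max(axis=0)),
        n=arr.shape[0],
    )


def calibrate_background(
    readings: Sequence[LabColor],
    name: str,
    category: str,
) -> SurfaceClass:
    """Characterize a background from readings taken on a weed-free patch.

    This is the first deployment step in the field: before spraying, the
    sensor records the plant-free surface and its noise, which all
    detectors are then referenced against.
    """
    stats = summarize(readings)
    stamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    return SurfaceClass(
        name=name,
        category=category,
        stats=stats,
        provenance=f"calibrated n={stats.n} at {stamp}",
    )


# ---------------------------------------------------------------------------
# JSON persistence

def _lab_to_json(c: LabColor | None) -> dict | None:
    if c is None:
        return None
    return {"L": c.L, "a": c.a, "b": c.b}


def _lab_from_json(obj, where: str) -> LabColor | None:
    if obj is None:
        return None
    if not isinstance(obj, dict):
        raise ValueError(f"{where}: expected an object with L/a/b, got {obj!r}")
    missing = [k for k in _CHANNELS if k not in obj]
    if missing:
        raise ValueError(f"{where}: missing channel field(s) {missing}")
    try:
        return LabColor(float(obj["L"]), float(obj["a"]), float(obj["b"]))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where}: {exc}") from exc


def _stats_to_json(st: ColorStats) -> dict:
    out: dict = {"mean": _lab_to_json(st.mean)}
    if st.sigma is not None:
        out["sigma"] = dict(zip(_CHANNELS, st.sigma))
    for key in ("min", "max", "median"):
        v = getattr(st, key)
        if v is not None:
            out[key] = _lab_to_json(v)
    if st.n is not None:
        out["n"] = st.n
    if st.flags:
        out["flags"] = list(st.flags)
    return out


def _stats_from_json(obj: dict, where: str) -> ColorStats:
    if "mean" not in obj:
        raise ValueError(f"{where}: missing required field 'mean'")
    sigma = None
    if obj.get("sigma") is not None:
        s = obj["sigma"]
        missing = [k for k in _CHANNELS if k not in s]
        if missing:
            raise ValueError(f"{where}.sigma: missing channel field(s) {missing}")
        sigma = tuple(float(s[k]) for k in _CHANNELS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # transcribed fixtures carry known flags
        return ColorStats(
            mean=_lab_from_json(obj["mean"], f"{where}.mean"),
            sigma=sigma,
            min=_lab_from_json(obj.get("min"), f"{where}.min"),
            max=_lab_from_json(obj.get("max"), f"{where}.max"),
            median=_lab_from_json(obj.get("median"), f"{where}.median"),
            n=obj.get("n"),
            flags=tuple(obj.get("flags", ())),
        )


def load_database(path: str | Path) -> ColorDatabase:
    """Load a surfaces/greens database from JSON, validating the schema."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return _database_from_json(raw, str(path))


def _database_from_json(raw: dict, where: str) -> ColorDatabase:
    if not isinstance(raw, dict):
        raise ValueError(f"{where}: database must be a JSON object")
    surfaces = []
    for i, s in enumerate(raw.get("surfaces", [])):
        loc = f"{where}:surfaces[{i}]"
        for req in ("name", "category"):
            if req not in s:
                raise ValueError(f"{loc}: missing required field {req!r}")
        surfaces.append(
            SurfaceClass(
                name=s["name"],
                category=s["category"],
                stats=_stats_from_json(s, loc),
                aliases=tuple(s.get("aliases", ())),
                provenance=s.get("provenance"),
            )
        )
    greens = []
    for i, g in enumerate(raw.get("greens", [])):
        loc = f"{where}:greens[{i}]"
        if "name" not in g:
            raise ValueError(f"{loc}: missing required field 'name'")
        greens.append(GreenTone(name=g["name"], stats=_stats_from_json(g, loc)))
    return ColorDatabase(surfaces=tuple(surfaces), greens=tuple(greens))


def save_database(db: ColorDatabase, path: str | Path) -> None:
    """Write a database to JSON (round-trips losslessly through load)."""
    raw: dict = {"surfaces": [], "greens": []}
    for s in db.surfaces:
        entry = {"name": s.name, "category": s.category, **_stats_to_json(s.stats)}
        if s.aliases:
            entry["aliases"] = list(s.aliases)
        if s.provenance:
            entry["provenance"] = s.provenance
        raw["surfaces"].append(entry)
    for g in db.greens:
        raw["greens"].append({"name": g.name, **_stats_to_json(g.stats)})
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(raw, fh, indent=1)
        fh.write("\n")


def default_database() -> ColorDatabase:
    """The packaged fixture database: ten backgrounds and four green tones."""
    pkg = resources.files("labweed.data")
    bg = _database_from_json(
        json.loads(pkg.joinpath("backgrounds.json").read_text()), "backgrounds.json"
    )
    gr = _database_from_json(
        json.loads(pkg.joinpath("greens.json").read_text()), "greens.json"
    )
    return ColorDatabase(surfaces=bg.surfaces, greens=gr.greens)


# ---------------------------------------------------------------------------
# CSV reading streams

def read_readings_csv(path: str | Path) -> pd.DataFrame:
    """Read a sensor stream CSV (columns t_s, x_cm, L, a, b; header required)."""
    df = pd.read_csv(path)
    required = ["t_s", "x_cm", "L", "a", "b"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: no readings")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed row at line {int(bad.idxmax()) + 2}")
    return df


def readings_to_colors(df: pd.DataFrame) -> list[LabColor]:
    return [LabColor(r.L, r.a, r.b) for r in df.itertuples()]
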