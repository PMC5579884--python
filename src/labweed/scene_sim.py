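"""Synthetic sensor-transect simulator.

Replaces the physical carrier: a circular measuring spot sweeps along a
straight track over a homogeneous background strewn with small disc-shaped
objects (plants, modeled as color cards).  Each reading mixes the
background and the dominant object's green tone linearly by the overlap
fraction of the spot, adds seeded Gaussian channel noise, and records the
ground-truth coverage so detector performance can be scored.

Geometry is in cm; the track axis is x, the spot center travels along
y = 0, and readings fall at spatial steps of ``speed * 100 / frequency``.
With the reference settings (150 cm track, 0.1 m/s, 10 Hz) that is one
reading per centimeter, 150 readings in 15 s.

Modeling choices:

* Mixing is area-weighted and linear per Lab channel — the same assumption
  the minimum-coverage model rests on.
* Noise sigma interpolates linearly between background and object sigma
  with the coverage fraction.
* Overlapping objects: coverage fractions are summed (capped at 1) and the
  object with the largest overlap supplies the green tone; per-reading
  multi-green color mixing is out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from labweed.color_core import LabColor
from labweed.color_db import ColorDatabase, ColorStats, GreenTone, SurfaceClass
from labweed.decision import Decision

__all__ = [
    "SceneObject",
    "SceneSpec",
    "Transect",
    "DetectionMetrics",
    "spot_overlap_area",
    "mixed_color",
    "make_transect",
    "evaluate_detection",
    "transect_to_csv",
    "transect_from_csv",
    "scene_from_json",
]


@dataclass(frozen=True)
class SceneObject:
    """A disc-shaped object on the track: position (cm), radius (cm), tone."""

    center_x: float
    center_y: float
    radius: float
    green: GreenTone

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"object radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class SceneSpec:
    background: SurfaceClass
    objects: tuple[SceneObject, ...]
    spot_diameter: float = 5.0
    speed: float = 0.1          # m/s
    frequency: float = 10.0     # Hz
    track_length: float = 150.0  # cm
    seed: int | None = None
    noise: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "objects", tuple(self.objects))
        for name in ("spot_diameter", "speed", "frequency", "track_length"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def step_cm(self) -> float:
        return self.speed * 100.0 / self.frequency


@dataclass(frozen=True)
class Transect:
    """Ordered readings with ground truth: times (s), positions (cm), Lab
    values, per-reading coverage fraction and dominant green label."""

    t_s: np.ndarray
    x_cm: np.ndarray
    lab: np.ndarray              # shape (n, 3)
    truth_coverage: np.ndarray
    truth_green: tuple[str | None, ...]
    spec: SceneSpec | None = None

    def __len__(self) -> int:
        return len(self.x_cm)

    def colors(self) -> list[LabColor]:
        return [LabColor(*row) for row in self.lab]


def spot_overlap_area(
    spot_center: tuple[float, float],
    spot_radius: float,
    obj_center: tuple[float, float],
    obj_radius: float,
) -> float:
    """Exact intersection area of two discs (circular-lens formula)."""
    if not (spot_radius > 0) or not (obj_radius > 0):
        raise ValueError("radii must be > 0")
    r1, r2 = spot_radius, obj_radius
    d = math.hypot(spot_center[0] - obj_center[0], spot_center[1] - obj_center[1])
    if d >= r1 + r2:
        return 0.0
    rmin = min(r1, r2)
    if d <= abs(r1 - r2):
        return math.pi * rmin ** 2
    # circular segment angles at each center
    cos1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1)
    cos2 = (d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2)
    a1 = math.acos(max(-1.0, min(1.0, cos1)))
    a2 = math.acos(max(-1.0, min(1.0, cos2)))
    area = (
        r1 * r1 * (a1 - math.sin(2.0 * a1) / 2.0)
        + r2 * r2 * (a2 - math.sin(2.0 * a2) / 2.0)
    )
    return max(0.0, min(area, math.pi * rmin ** 2))


def mixed_color(
    bg: ColorStats,
    green: ColorStats,
    f: float,
    rng: np.random.Generator | None = None,
) -> LabColor:
    """One reading of a spot covered by fraction f of a green object.

    Mean is the area-weighted blend per channel; if ``rng`` is given,
    Gaussian noise with sigma = (1-f)*sigma_bg + f*sigma_green per channel
    is added.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"coverage fraction must be in [0, 1], got {f}")
    mu = (1.0 - f) * np.asarray(bg.mean.as_tuple()) + f * np.asarray(
        green.mean.as_tuple()
    )
    if rng is not None:
        sig = (1.0 - f) * np.asarray(bg.effective_sigma()) + f * np.asarray(
            green.effective_sigma()
        )
        mu = mu + rng.normal(0.0, 1.0, size=3) * sig
    return LabColor(*mu)


def make_transect(spec: SceneSpec) -> Transect:
    """Simulate one pass of the sensor over the scene.

    Deterministic given the spec (including seed): the same spec always
    yields a bit-identical transect.
    """
    step = spec.step_cm
    n = int(math.floor(spec.track_length / step + 1e-9))
    t = np.arange(n) / spec.frequency
    x = np.arange(n) * step
    spot_r = spec.spot_diameter / 2.0
    spot_area = math.pi * spot_r ** 2
    rng = np.random.default_rng(spec.seed) if spec.noise else None

    lab = np.empty((n, 3))
    coverage = np.zeros(n)
    green_label: list[str | None] = []
    for i in range(n):
        overlaps = [
            (spot_overlap_area((x[i], 0.0), spot_r, (o.center_x, o.center_y), o.radius), o)
            for o in spec.objects
        ]
        total = sum(a for a, _ in overlaps)
        f = min(total / spot_area, 1.0)
        dominant = max(overlaps, key=lambda ao: ao[0], default=(0.0, None))
        if f > 0.0 and dominant[0] > 0.0:
            green = dominant[1].green
            color = mixed_color(spec.background.stats, green.stats, f, rng)
            green_label.append(green.name)
        else:
            f = 0.0
            color = mixed_color(
                spec.background.stats, spec.background.stats, 0.0, rng
            )
            green_label.append(None)
        lab[i] = color.as_tuple()
        coverage[i] = f
    return Transect(
        t_s=t,
        x_cm=x,
        lab=lab,
        truth_coverage=coverage,
        truth_green=tuple(green_label),
        spec=spec,
    )


@dataclass(frozen=True)
class DetectionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    recall: float
    precision: float
    objects_total: int
    objects_detected: int


def evaluate_detection(
    decisions: list[Decision] | tuple[Decision, ...],
    transect: Transect,
    coverage_cutoff: float = 0.0,
) -> DetectionMetrics:
    """Score a decision stream against the transect's ground truth.

    Reading-level truth is ``truth_coverage > coverage_cutoff``.  An object
    counts as detected if at least one reading overlapping it (coverage
    above the cutoff) detects.
    """
    if len(decisions) != len(transect):
        raise ValueError(
            f"length mismatch: {len(decisions)} decisions vs {len(transect)} readings"
        )
    truth = transect.truth_coverage > coverage_cutoff
    pred = np.array([d.detect for d in decisions], dtype=bool)
    tp = int(np.sum(truth & pred))
    fp = int(np.sum(~truth & pred))
    fn = int(np.sum(truth & ~pred))
    tn = int(np.sum(~truth & ~pred))
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0

    objects_total = objects_detected = 0
    if transect.spec is not None:
        spot_r = transect.spec.spot_diameter / 2.0
        for o in transect.spec.objects:
            objects_total += 1
            covered = np.array(
                [
                    spot_overlap_area((xi, 0.0), spot_r, (o.center_x, o.center_y), o.radius) > 0
                    for xi in transect.x_cm
                ]
            )
            if np.any(covered & truth & pred):
                objects_detected += 1
    return DetectionMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        recall=recall, precision=precision,
        objects_total=objects_total, objects_detected=objects_detected,
    )


# ---------------------------------------------------------------------------
# serialization

def transect_to_csv(tr: Transect, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t_s": np.round(tr.t_s, 6),
            "x_cm": np.round(tr.x_cm, 6),
            "L": np.round(tr.lab[:, 0], 6),
            "a": np.round(tr.lab[:, 1], 6),
            "b": np.round(tr.lab[:, 2], 6),
            "truth_coverage": np.round(tr.truth_coverage, 6),
            "truth_green": [g if g is not None else "" for g in tr.truth_green],
        }
    )
    df.to_csv(path, index=False)


def transect_from_csv(path: str | Path) -> Transect:
    df = pd.read_csv(path, keep_default_na=False)
    return Transect(
        t_s=df["t_s"].to_numpy(float),
        x_cm=df["x_cm"].to_numpy(float),
        lab=df[["L", "a", "b"]].to_numpy(float),
        truth_coverage=df["truth_coverage"].to_numpy(float),
        truth_green=tuple(g if g != "" else None for g in df["truth_green"]),
    )


def scene_from_json(path: str | Path, db: ColorDatabase) -> SceneSpec:
    """Build a SceneSpec from a JSON scene file, resolving names in ``db``.

    Schema: {"background": name, "objects": [{"center_x", "center_y",
    "radius", "green"}...], "spot_diameter", "speed", "frequency",
    "track_length", "seed", "noise"}.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if "background" not in raw:
        raise ValueError(f"{path}: missing required field 'background'")
    objects = []
    for i, o in enumerate(raw.get("objects", [])):
        for req in ("center_x", "radius", "green"):
            if req not in o:
                raise ValueError(f"{path}: objects[{i}] missing field {req!r}")
        objects.append(
            SceneObject(
                center_x=float(o["center_x"]),
                center_y=float(o.get("center_y", 0.0)),
                radius=float(o["radius"]),
                green=db.green(o["green"]),
            )
        )
    return SceneSpec(
        background=db.surface(raw["background"]),
        objects=tuple(objects),
        spot_diameter=float(raw.get("spot_diameter", 5.0)),
        speed=float(raw.get("speed", 0.1)),
        frequency=float(raw.get("frequency", 10.0)),
        track_length=float(raw.get("track_length", 150.0)),
        seed=raw.get("seed"),
        noise=bool(raw.get("noise", True)),
    )
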