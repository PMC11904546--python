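"""Scale-calibrated 2D cephalometric measurements on radiograph landmarks.

Radiograph measurements are taken on manually placed landmark coordinates
(pixels, image convention: origin top-left, y down).  Each image first gets
an individual distance calibration from a pixel pair of known physical
separation; distances are then reported in cm, ratios are unitless (the
calibration cancels), and angles in degrees.

The measure catalogue is a configurable definition table.  The shipped
default file contains the eight measures of the study's radiograph block
(``MO-MO``, ``ECA-ECA``, ``Nas-Tub``, ``EU-EU/MO-MO``, ``ECA-ECP/ECS-BA``,
``Inter-MO``, ``Inter-EU``, ``ECA-ECP``).  The landmark abbreviations are
treated as opaque names bound by the definition file; the ``Inter-*`` rows
default to angle measures (their magnitudes are far beyond plausible cm
distances) and all default kinds are provisional and overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError

VIEWS = ("frontal_pa", "lateral")


@dataclass(frozen=True)
class Landmark2DSet:
    """Named 2D image points (pixels) for one acquisition view."""

    points: dict[str, np.ndarray]
    view: str

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValidationError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        clean = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float).reshape(2)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"landmark {name!r} has non-finite coordinates")
            if name in clean:
                raise ValidationError(f"duplicate landmark name {name!r}")
            clean[name] = arr
        object.__setattr__(self, "points", clean)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points


@dataclass(frozen=True)
class ScaleCalibration:
    """cm-per-pixel factor derived from a pixel pair of known separation."""

    p1: np.ndarray
    p2: np.ndarray
    known_cm: float

    def __post_init__(self):
        object.__setattr__(self, "p1", np.asarray(self.p1, dtype=float).reshape(2))
        object.__setattr__(self, "p2", np.asarray(self.p2, dtype=float).reshape(2))

    @property
    def cm_per_pixel(self) -> float:
        return self.known_cm / float(np.linalg.norm(self.p2 - self.p1))


def calibrate_scale(p1, p2, known_cm: float) -> ScaleCalibration:
    """Derive the image scale from two pixel points a known distance apart."""
    p1 = np.asarray(p1, dtype=float).reshape(2)
    p2 = np.asarray(p2, dtype=float).reshape(2)
    if known_cm <= 0:
        raise ValidationError("calibration distance must be positive")
    if np.linalg.norm(p2 - p1) < 1e-12:
        raise ValidationError("zero baseline: calibration pixel points coincide")
    return ScaleCalibration(p1=p1, p2=p2, known_cm=float(known_cm))


@dataclass(frozen=True)
class MeasureDefinition:
    """One measure of the catalogue.

    ``kind`` is ``distance`` (operands: two landmark names), ``angle``
    (three names, vertex in the middle) or ``ratio`` (operands: mapping with
    ``num`` and ``den``, each a two-landmark distance).
    """

    name: str
    kind: str
    operands: tuple | dict
    view: str
    units: str = ""

    def __post_init__(self):
        if self.kind not in ("distance", "ratio", "angle"):
            raise ValidationError(f"measure {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "distance" and len(self.operands) != 2:
            raise ValidationError(f"measure {self.name!r}: distance needs two landmarks")
        if self.kind == "angle" and len(self.operands) != 3:
            raise ValidationError(f"measure {self.name!r}: angle needs three landmarks")
        if self.kind == "ratio" and set(self.operands) != {"num", "den"}:
            raise ValidationError(f"measure {self.name!r}: ratio needs 'num' and 'den'")

    @classmethod
    def from_dict(cls, d: dict) -> "MeasureDefinition":
        operands = d["operands"]
        if isinstance(operands, list):
            operands = tuple(operands)
        else:
            operands = {k: tuple(v) for k, v in operands.items()}
        default_units = {"distance": "cm", "ratio": "", "angle": "deg"}[d["kind"]]
        return cls(
            name=d["name"],
            kind=d["kind"],
            operands=operands,
            view=d["view"],
            units=d.get("units", default_units),
        )


def default_definitions() -> list[MeasureDefinition]:
    """The shipped radiograph measure catalogue (eight measures)."""
    path = resources.files("craniometrics").joinpath("data", "xray_defaults.json")
    with path.open("r") as fh:
        return [MeasureDefinition.from_dict(d) for d in json.load(fh)]


def _lookup(landmarks, view: str, name: str, measure: str) -> np.ndarray:
    if isinstance(landmarks, Landmark2DSet):
        sets = {landmarks.view: landmarks}
    else:
        sets = dict(landmarks)
    if view not in sets:
        raise ValidationError(
            f"measure {measure!r}: no landmark set supplied for view {view!r}"
        )
    lm = sets[view]
    if name not in lm:
        raise ValidationError(f"measure {measure!r}: landmark {name!r} missing in view {view!r}")
    return lm[name]


def _distance_cm(landmarks, view, pair, cal: ScaleCalibration, measure: str) -> float:
    a = _lookup(landmarks, view, pair[0], measure)
    b = _lookup(landmarks, view, pair[1], measure)
    return float(np.linalg.norm(b - a)) * cal.cm_per_pixel


def measure_2d(
    landmarks: Landmark2DSet | dict[str, Landmark2DSet],
    calibration: ScaleCalibration,
    definitions: list[MeasureDefinition] | None = None,
) -> pd.DataFrame:
    """Evaluate a measure-definition table against calibrated 2D landmarks.

    ``landmarks`` is a single view's set or a mapping view -> set.  The
    output table preserves the order of the definitions; distances in cm,
    ratios unitless, angles in degrees (image-plane convention-neutral).
    """
    if definitions is None:
        definitions = default_definitions()
    rows = []
    for d in definitions:
        if d.kind == "distance":
            value = _distance_cm(landmarks, d.view, d.operands, calibration, d.name)
        elif d.kind == "ratio":
            num = _distance_cm(landmarks, d.view, d.operands["num"], calibration, d.name)
            den = _distance_cm(landmarks, d.view, d.operands["den"], calibration, d.name)
            if den < 1e-12:
                raise ValidationError(f"degenerate ratio: zero denominator in {d.name!r}")
            value = num / den
        else:  # angle
            a = _lookup(landmarks, d.view, d.operands[0], d.name)
            v = _lookup(landmarks, d.view, d.operands[1], d.name)
            b = _lookup(landmarks, d.view, d.operands[2], d.name)
            u1, u2 = a - v, b - v
            n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
            if n1 < 1e-12 or n2 < 1e-12:
                raise ValidationError(f"degenerate angle: coincident points in {d.name!r}")
            value = float(np.degrees(np.arccos(np.clip(u1 @ u2 / (n1 * n2), -1.0, 1.0))))
        rows.append(
            {"name": d.name, "kind": d.kind, "view": d.view, "value": value, "units": d.units}
        )
    return pd.DataFrame(rows, columns=["name", "kind", "view", "value", "units"])
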