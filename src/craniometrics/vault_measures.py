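"""Vault symmetry and aesthetic indices computed from a slice stack.

Implements the 3D index catalogue used for craniosynostosis follow-up:

* per-slice cranial length (anteroposterior extent) and width (mediolateral
  extent), with the reported scalars being the maxima over the 11 analysed
  layers;
* the cranial index, CI = 100 x width / length, averaged over the analysed
  slices;
* oblique diagonals A/B through the slice centroid at +/- a fixed offset
  from the anteroposterior axis; their absolute difference is the vault
  asymmetry measure;
* quadrant volumes Q1–Q4 (anterior right/left, posterior right/left) from
  contour pieces cut by the midsagittal and coronal planes, in ml;
* the anterior and posterior (a)symmetry ratios ASR / PSR, by default the
  lower over the higher paired quadrant volume so that 1 means perfect
  symmetry;
* the frontal angle (at the nasion, between the two lateral-orbit points)
  and the right/left frontoparietal angles (at the nasion, between the
  same-side lateral-orbit and parietal points), evaluated in the axial
  projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from shapely.geometry import LineString, Polygon, box

from .core_frame import (
    LandmarkSet,
    ReferenceFrame,
    SliceStack,
    build_reference_frame,
    slice_head,
)
from .errors import ContourError, EmptyQuadrantError, IncompleteLandmarkError, ValidationError

_BIG = 1e4  # half-plane clipping extent, cm


@dataclass
class MeasurementRecord:
    """Per-subject vector of named index values plus per-slice sub-tables.

    ``values`` maps measure name to value, ``units`` the matching unit
    string; ``per_slice`` has one row per analysed layer with its extents,
    cranial index and quadrant areas.
    """

    values: dict[str, float] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    per_slice: pd.DataFrame = field(default_factory=pd.DataFrame)

    def set(self, name: str, value: float, unit: str) -> None:
        self.values[name] = float(value)
        self.units[name] = unit

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (name, value, units, layer)."""
        rows = [
            {"name": k, "value": v, "units": self.units.get(k, ""), "layer": ""}
            for k, v in self.values.items()
        ]
        for _, r in self.per_slice.iterrows():
            layer = int(r["layer"])
            for col in self.per_slice.columns:
                if col == "layer":
                    continue
                unit = "cm" if col.endswith("_cm") else ("cm2" if col.endswith("_cm2") else "%")
                rows.append(
                    {"name": col, "value": float(r[col]), "units": unit, "layer": str(layer)}
                )
        return pd.DataFrame(rows, columns=["name", "value", "units", "layer"])

    @property
    def n_values(self) -> int:
        return len(self.to_frame())

    def validate(self) -> None:
        v = self.values
        if not 0 < v.get("cranial_index_pct", 100) <= 200:
            raise ValidationError("cranial index outside (0, 200]")
        for q in ("q1_ml", "q2_ml", "q3_ml", "q4_ml"):
            if v.get(q, 0.0) < 0:
                raise ValidationError(f"{q} negative")
        for a in ("frontal_angle_deg", "frontoparietal_angle_r_deg", "frontoparietal_angle_l_deg"):
            if a in v and not 0 < v[a] < 180:
                raise ValidationError(f"{a} outside (0, 180)")


def _extents(layer) -> tuple[float, float]:
    """(length, width) = (y-extent, x-extent) of a layer contour."""
    c = np.asarray(layer.contour)
    if len(c) < 3:
        raise ContourError(f"layer {layer.index} has a degenerate contour")
    return float(c[:, 1].max() - c[:, 1].min()), float(c[:, 0].max() - c[:, 0].min())


def cranial_length_width(slices: SliceStack) -> tuple[float, float, pd.DataFrame]:
    """Maximal per-slice AP and ML extents over the analysed layers.

    Returns the scalar cranial length and width (maxima over layers 1–11,
    cm) and a per-slice table of the individual extents.
    """
    analysed = slices.analysed()
    if not analysed:
        raise ContourError("no analysable layers in slice stack")
    rows = []
    for layer in analysed:
        length, width = _extents(layer)
        rows.append({"layer": layer.index, "length_cm": length, "width_cm": width})
    table = pd.DataFrame(rows)
    return float(table["length_cm"].max()), float(table["width_cm"].max()), table


def cranial_index(slices: SliceStack) -> float:
    """Arithmetic mean over analysed slices of CI_k = 100 x width_k / length_k."""
    _, _, table = cranial_length_width(slices)
    if (table["length_cm"] <= 0).any():
        raise ContourError("degenerate contour: zero anteroposterior extent")
    return float((100.0 * table["width_cm"] / table["length_cm"]).mean())


def _chord_length(poly: Polygon, centre: np.ndarray, direction: np.ndarray) -> tuple[float, bool]:
    line = LineString([centre - _BIG * direction, centre + _BIG * direction])
    inter = poly.intersection(line)
    simple = inter.geom_type == "LineString"
    return float(inter.length), simple


def diagonals(
    slices: SliceStack, layer: int | None = None, offset_deg: float = 30.0
) -> tuple[float, float, float]:
    """Oblique chords through the contour centroid at +/- ``offset_deg`` from the AP axis.

    Diagonal A is tilted toward the right (+x), B toward the left.  By
    default the analysed layer with the largest contour area is used.
    Returns (diag_a_cm, diag_b_cm, |A - B|).
    """
    analysed = {l.index: l for l in slices.analysed()}
    if not analysed:
        raise ContourError("no analysable layers in slice stack")
    if layer is None:
        layer = max(analysed, key=lambda k: analysed[k].area)
    if layer not in analysed:
        raise ContourError(f"layer {layer} is not an analysed layer")
    lay = analysed[layer]
    poly = lay.polygon
    centre = np.array([poly.centroid.x, poly.centroid.y])
    theta = np.deg2rad(offset_deg)
    dir_a = np.array([np.sin(theta), np.cos(theta)])
    dir_b = np.array([-np.sin(theta), np.cos(theta)])
    diag_a, ok_a = _chord_length(poly, centre, dir_a)
    diag_b, ok_b = _chord_length(poly, centre, dir_b)
    if not (ok_a and ok_b):
        warnings.warn(
            f"layer {layer} contour is not star-shaped about its centroid; "
            "diagonals taken as total intersection length",
            stacklevel=2,
        )
    return diag_a, diag_b, abs(diag_a - diag_b)


_QUADRANT_BOXES = {
    "q1": box(0.0, 0.0, _BIG, _BIG),  # anterior right
    "q2": box(-_BIG, 0.0, 0.0, _BIG),  # anterior left
    "q3": box(0.0, -_BIG, _BIG, 0.0),  # posterior right
    "q4": box(-_BIG, -_BIG, 0.0, 0.0),  # posterior left
}


def quadrant_areas(layer) -> dict[str, float]:
    """Areas (cm2) of the four quadrant pieces of one layer contour."""
    poly = layer.polygon
    return {name: float(poly.intersection(b).area) for name, b in _QUADRANT_BOXES.items()}


def quadrant_volumes(slices: SliceStack) -> tuple[float, float, float, float]:
    """Quadrant volumes Q1–Q4 in ml summed over the analysed layers.

    Each analysed contour is split by the midsagittal (x = 0) and coronal
    (y = 0) frame planes; quadrant volume is the piece area times the layer
    thickness (1 cm3 = 1 ml).  The four volumes sum to the total analysed
    slice volume by construction.
    """
    t = slices.thickness
    totals = {"q1": 0.0, "q2": 0.0, "q3": 0.0, "q4": 0.0}
    for layer in slices.analysed():
        for name, area in quadrant_areas(layer).items():
            totals[name] += area * t
    return totals["q1"], totals["q2"], totals["q3"], totals["q4"]


def asymmetry_ratio(
    volume_right: float,
    volume_left: float,
    convention: str = "lower_over_higher",
) -> float:
    """Ratio of a paired quadrant volume (anterior for ASR, posterior for PSR).

    ``lower_over_higher`` (default) scores a perfectly symmetric head as 1
    and asymmetry as < 1; ``higher_over_lower`` is its exact reciprocal.
    """
    if volume_right <= 0 or volume_left <= 0:
        raise EmptyQuadrantError("empty quadrant: cannot form an asymmetry ratio")
    lo, hi = sorted((volume_right, volume_left))
    if convention == "lower_over_higher":
        return lo / hi
    if convention == "higher_over_lower":
        return hi / lo
    raise ValidationError(f"unknown asymmetry ratio convention {convention!r}")


def _axial_angle(
    landmarks: LandmarkSet, vertex: str, ray_a: str, ray_b: str, frame: ReferenceFrame | None
) -> float:
    landmarks.require(vertex, ray_a, ray_b)
    if frame is None:
        frame = build_reference_frame(landmarks)
    pts = frame.to_frame(np.stack([landmarks[vertex], landmarks[ray_a], landmarks[ray_b]]))
    u = pts[1, :2] - pts[0, :2]
    v = pts[2, :2] - pts[0, :2]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise IncompleteLandmarkError(
            f"degenerate angle: ray point coincides with vertex {vertex!r} in axial projection"
        )
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def frontal_angle(
    landmarks: LandmarkSet,
    vertex: str = "nasion",
    orbit: str = "exocanthion",
    frame: ReferenceFrame | None = None,
) -> float:
    """Angle at the vertex (nasion by default; glabella selectable) between
    the rays to the right and left lateral-orbit landmarks, in the axial
    projection.  ``orbit`` selects the lateral-orbit pair
    (``exocanthion`` or ``frontotemporal``)."""
    return _axial_angle(landmarks, vertex, f"{orbit}_r", f"{orbit}_l", frame)


def frontoparietal_angles(
    landmarks: LandmarkSet,
    vertex: str = "nasion",
    orbit: str = "exocanthion",
    frame: ReferenceFrame | None = None,
) -> tuple[float, float]:
    """Per-side angle at the nasion between the rays to that side's
    lateral-orbit point and that side's parietal point (axial projection).
    Returns (right, left) in degrees."""
    right = _axial_angle(landmarks, vertex, f"{orbit}_r", "parietal_r", frame)
    left = _axial_angle(landmarks, vertex, f"{orbit}_l", "parietal_l", frame)
    return right, left


def measure_all(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    offset_deg: float = 30.0,
    convention: str = "lower_over_higher",
    vertex: str = "nasion",
    orbit: str = "exocanthion",
    n_layers: int = 12,
) -> MeasurementRecord:
    """Run the full pipeline: frame, slicing, and every vault index.

    The record carries the scalar indices plus an 11-row per-slice table
    (length, width, CI and quadrant areas per analysed layer).
    """
    frame = build_reference_frame(landmarks)
    slices = slice_head(mesh, frame, n_layers=n_layers)

    record = MeasurementRecord()
    length, width, table = cranial_length_width(slices)
    record.set("cranial_length_cm", length, "cm")
    record.set("cranial_width_cm", width, "cm")
    record.set("cranial_index_pct", cranial_index(slices), "%")

    diag_a, diag_b, diag_diff = diagonals(slices, offset_deg=offset_deg)
    record.set("diagonal_a_cm", diag_a, "cm")
    record.set("diagonal_b_cm", diag_b, "cm")
    record.set("diagonal_diff_cm", diag_diff, "cm")

    q1, q2, q3, q4 = quadrant_volumes(slices)
    record.set("q1_ml", q1, "ml")
    record.set("q2_ml", q2, "ml")
    record.set("q3_ml", q3, "ml")
    record.set("q4_ml", q4, "ml")
    record.set("total_volume_ml", q1 + q2 + q3 + q4, "ml")
    record.set("asr", asymmetry_ratio(q1, q2, convention), "")
    record.set("psr", asymmetry_ratio(q3, q4, convention), "")

    try:
        record.set("frontal_angle_deg", frontal_angle(landmarks, vertex, orbit, frame), "deg")
        fp_r, fp_l = frontoparietal_angles(landmarks, vertex="nasion", orbit=orbit, frame=frame)
        record.set("frontoparietal_angle_r_deg", fp_r, "deg")
        record.set("frontoparietal_angle_l_deg", fp_l, "deg")
        record.set("frontoparietal_angle_mean_deg", 0.5 * (fp_r + fp_l), "deg")
    except IncompleteLandmarkError as exc:
        raise IncompleteLandmarkError(f"angle measures failed: {exc}") from exc

    qa_rows = []
    for layer in slices.analysed():
        qa = quadrant_areas(layer)
        qa_rows.append(
            {
                "layer": layer.index,
                "q1_area_cm2": qa["q1"],
                "q2_area_cm2": qa["q2"],
                "q3_area_cm2": qa["q3"],
                "q4_area_cm2": qa["q4"],
            }
        )
    per_slice = table.merge(pd.DataFrame(qa_rows), on="layer")
    per_slice.insert(3, "ci_pct", 100.0 * per_slice["width_cm"] / per_slice["length_cm"])
    record.per_slice = per_slice
    record.validate()
    return record
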