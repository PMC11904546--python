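"""Readers and writers for meshes, landmark files, records and tables.

Centimetres are the canonical unit everywhere; millimetre inputs are never
auto-detected but converted explicitly via ``units="mm"``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .core_frame import LandmarkSet, validate_mesh
from .errors import MeshReadError, ValidationError
from .vault_measures import MeasurementRecord
from .xray_cephalometrics import Landmark2DSet, MeasureDefinition

MESH_EXTENSIONS = (".ply", ".obj", ".stl")
_UNIT_FACTORS = {"cm": 1.0, "mm": 0.1}


def _unit_factor(units: str) -> float:
    if units not in _UNIT_FACTORS:
        raise ValidationError(f"unknown units {units!r}; choose 'cm' or 'mm'")
    return _UNIT_FACTORS[units]


def read_mesh(path, units: str = "cm") -> trimesh.Trimesh:
    """Load a watertight head mesh (PLY/OBJ/STL, ASCII or binary).

    Parse failures raise :class:`MeshReadError`; topology failures (open
    surface, non-positive volume) raise :class:`OpenMeshError` — distinct
    codes so callers can tell a broken file from a broken scan.
    """
    path = Path(path)
    if path.suffix.lower() not in MESH_EXTENSIONS:
        raise MeshReadError(f"unsupported mesh extension {path.suffix!r}")
    if not path.exists():
        raise MeshReadError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # parse error: distinct from topology failure
        raise MeshReadError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh):
        raise MeshReadError(f"file {path} does not contain a triangulated surface")
    factor = _unit_factor(units)
    if factor != 1.0:
        mesh = trimesh.Trimesh(vertices=mesh.vertices * factor, faces=mesh.faces, process=False)
    validate_mesh(mesh)
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path, **kwargs) -> None:
    path = Path(path)
    if path.suffix.lower() == ".obj":
        # full float precision so geometry round-trips losslessly
        kwargs.setdefault("digits", 17)
    mesh.export(str(path), **kwargs)


def read_landmarks(path, units: str = "cm") -> LandmarkSet:
    """Read a 3D landmark file: JSON ``{name: [x, y, z]}`` or CSV with
    columns name,x,y,z."""
    path = Path(path)
    factor = _unit_factor(units)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        points = {str(k): np.asarray(v, dtype=float) * factor for k, v in data.items()}
    elif path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        required = {"name", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise ValidationError(f"landmark CSV must contain columns {sorted(required)}")
        points = {
            str(r["name"]): np.array([r["x"], r["y"], r["z"]], dtype=float) * factor
            for _, r in df.iterrows()
        }
    else:
        raise ValidationError(f"unsupported landmark file extension {path.suffix!r}")
    return LandmarkSet(points)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    path = Path(path)
    data = {k: [float(c) for c in v] for k, v in sorted(landmarks.points.items())}
    path.write_text(json.dumps(data, indent=1) + "\n")


def read_landmarks_2d(path) -> dict[str, Landmark2DSet]:
    """Read radiograph landmark CSV (name,x,y,view) into per-view sets."""
    df = pd.read_csv(path)
    required = {"name", "x", "y", "view"}
    if not required.issubset(df.columns):
        raise ValidationError(f"2D landmark CSV must contain columns {sorted(required)}")
    out = {}
    for view, part in df.groupby("view"):
        points = {
            str(r["name"]): np.array([r["x"], r["y"]], dtype=float) for _, r in part.iterrows()
        }
        out[str(view)] = Landmark2DSet(points=points, view=str(view))
    return out


def read_definitions(path) -> list[MeasureDefinition]:
    data = json.loads(Path(path).read_text())
    return [MeasureDefinition.from_dict(d) for d in data]


def write_record(record: MeasurementRecord, path, format: str | None = None) -> None:
    """Serialise a measurement record to CSV or JSON (stable order, lossless
    round trip through the matching reader)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    table = record.to_frame()
    if fmt == "csv":
        table.to_csv(path, index=False, float_format=None)
    elif fmt == "json":
        payload = {
            "values": record.values,
            "units": record.units,
            "per_slice": record.per_slice.to_dict(orient="list"),
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValidationError(f"unsupported record format {fmt!r}")


def read_record(path) -> MeasurementRecord:
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    record = MeasurementRecord()
    if fmt == "csv":
        table = pd.read_csv(
            path, dtype={"layer": str}, keep_default_na=False, float_precision="round_trip"
        )
        scalars = table[table["layer"] == ""]
        for _, r in scalars.iterrows():
            record.set(r["name"], float(r["value"]), r["units"])
        per = table[table["layer"] != ""]
        if len(per):
            wide = per.pivot(index="layer", columns="name", values="value").reset_index()
            wide["layer"] = wide["layer"].astype(int)
            cols = ["layer"] + [c for c in (
                "length_cm", "width_cm", "ci_pct",
                "q1_area_cm2", "q2_area_cm2", "q3_area_cm2", "q4_area_cm2",
            ) if c in wide.columns]
            record.per_slice = wide[cols].sort_values("layer").reset_index(drop=True)
    elif fmt == "json":
        payload = json.loads(path.read_text())
        for k, v in payload["values"].items():
            record.set(k, v, payload["units"].get(k, ""))
        record.per_slice = pd.DataFrame(payload["per_slice"])
    else:
        raise ValidationError(f"unsupported record format {fmt!r}")
    return record
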