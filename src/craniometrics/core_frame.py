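"""Anatomical reference frame and layered slicing of a head surface mesh.

The measurement system anchors every index to a landmark-derived coordinate
frame so that values are comparable across visits and scanners:

* the origin is the midpoint of the two tragus points;
* the anterior Y axis points from the tragus midpoint toward the midpoint of
  the two lateral canthi;
* the lateral X axis is the unit normal of the midsagittal plane spanned by
  the tragus midpoint, the canthus midpoint and the subnasale, oriented so
  the right tragus has positive x;
* the superior Z axis completes the right-handed system (``z = x × y``).

The supra-basal head (everything above the horizontal plane through the
origin) is then divided into 12 equal-thickness layers along Z.  Layer 0 —
the band adjoining the face/skull base — is kept but flagged as excluded;
layers 1–11 carry the planar cross-section contours that all vault indices
are computed from.  All coordinates are centimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import Polygon

from .errors import (
    ContourError,
    DegenerateFrameError,
    IncompleteLandmarkError,
    OpenMeshError,
    ShortMeshError,
)

REQUIRED_LANDMARKS = (
    "tragus_r",
    "tragus_l",
    "canthus_lat_r",
    "canthus_lat_l",
    "subnasale",
)

OPTIONAL_LANDMARKS = (
    "nasion",
    "glabella",
    "frontotemporal_r",
    "frontotemporal_l",
    "parietal_r",
    "parietal_l",
    "exocanthion_r",
    "exocanthion_l",
    "preaural_r",
    "preaural_l",
    "infraorbital_r",
    "infraorbital_l",
)

#: coincidence tolerance for landmark points, cm
COINCIDENCE_TOL = 1e-6
#: orthonormality tolerance for frame axes
ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical 3D points in centimetres.

    ``points`` maps landmark name to a length-3 coordinate.  The five
    required names (tragi, lateral canthi, subnasale) must be present before
    a reference frame can be built; angle measurements additionally need
    nasion / lateral-orbit / parietal points.
    """

    points: dict[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise IncompleteLandmarkError(f"landmark {name!r} has non-finite coordinates")
            clean[name] = arr
        object.__setattr__(self, "points", clean)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self) -> list[str]:
        return sorted(self.points)

    def require(self, *names: str) -> None:
        for name in names:
            if name not in self.points:
                raise IncompleteLandmarkError(
                    f"incomplete landmark set: missing required point {name!r}"
                )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Return a copy under the rigid motion ``p -> R p + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        return LandmarkSet({k: R @ v + t for k, v in self.points.items()})

    def mirrored(self) -> "LandmarkSet":
        """Mirror through x=0 and swap ``_r``/``_l`` suffixes."""
        out = {}
        for name, p in self.points.items():
            if name.endswith("_r"):
                new = name[:-2] + "_l"
            elif name.endswith("_l"):
                new = name[:-2] + "_r"
            else:
                new = name
            out[new] = p * np.array([-1.0, 1.0, 1.0])
        return LandmarkSet(out)


@dataclass(frozen=True)
class ReferenceFrame:
    """Origin plus right-handed orthonormal axes (lateral X, anterior Y, superior Z)."""

    origin: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray

    def __post_init__(self):
        for name in ("origin", "axis_x", "axis_y", "axis_z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        for a in (self.axis_x, self.axis_y, self.axis_z):
            if abs(np.linalg.norm(a) - 1.0) > 1e-7:
                raise DegenerateFrameError("frame axis is not unit length")
        if (
            abs(self.axis_x @ self.axis_y) > 1e-7
            or abs(self.axis_x @ self.axis_z) > 1e-7
            or abs(self.axis_y @ self.axis_z) > 1e-7
        ):
            raise DegenerateFrameError("frame axes are not orthogonal")
        if np.linalg.norm(np.cross(self.axis_x, self.axis_y) - self.axis_z) > 1e-7:
            raise DegenerateFrameError("frame is not right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose columns are the frame axes (frame -> world)."""
        return np.stack([self.axis_x, self.axis_y, self.axis_z], axis=1)

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """Express world points in frame coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) @ self.rotation


def build_reference_frame(landmarks: LandmarkSet) -> ReferenceFrame:
    """Construct the anatomical reference frame from the five required landmarks.

    Raises
    ------
    IncompleteLandmarkError
        if a required landmark is absent.
    DegenerateFrameError
        if the tragus midpoint, canthus midpoint and subnasale are collinear
        (no midsagittal plane is defined) or required points coincide.
    """
    landmarks.require(*REQUIRED_LANDMARKS)
    tr, tl = landmarks["tragus_r"], landmarks["tragus_l"]
    cr, cl = landmarks["canthus_lat_r"], landmarks["canthus_lat_l"]
    sn = landmarks["subnasale"]

    if np.linalg.norm(tr - tl) < COINCIDENCE_TOL:
        raise DegenerateFrameError("degenerate frame: tragus points coincide")
    if np.linalg.norm(cr - cl) < COINCIDENCE_TOL:
        raise DegenerateFrameError("degenerate frame: canthus points coincide")

    origin = 0.5 * (tr + tl)
    canthus_mid = 0.5 * (cr + cl)

    y_raw = canthus_mid - origin
    if np.linalg.norm(y_raw) < COINCIDENCE_TOL:
        raise DegenerateFrameError("degenerate frame: canthus midpoint coincides with origin")
    axis_y = y_raw / np.linalg.norm(y_raw)

    # normal of the midsagittal plane through origin, canthus midpoint, subnasale
    n_raw = np.cross(y_raw, sn - origin)
    scale = max(np.linalg.norm(y_raw), np.linalg.norm(sn - origin), 1.0)
    if np.linalg.norm(n_raw) < COINCIDENCE_TOL * scale**2:
        raise DegenerateFrameError(
            "degenerate frame: tragus midpoint, canthus midpoint and subnasale are collinear"
        )
    axis_x = n_raw / np.linalg.norm(n_raw)
    # orient laterally: the right tragus must have positive x
    if (tr - origin) @ axis_x < 0:
        axis_x = -axis_x
    axis_z = np.cross(axis_x, axis_y)
    return ReferenceFrame(origin=origin, axis_x=axis_x, axis_y=axis_y, axis_z=axis_z)


@dataclass(frozen=True)
class SliceLayer:
    """One horizontal layer: its height band and the mid-height contour.

    ``contour`` is an (n, 2) closed polygon (first point not repeated) in
    frame x/y coordinates; empty for an excluded layer with no material.
    """

    index: int
    z_lower: float
    z_upper: float
    contour: np.ndarray
    excluded: bool = False

    @property
    def thickness(self) -> float:
        return self.z_upper - self.z_lower

    @property
    def z_mid(self) -> float:
        return 0.5 * (self.z_lower + self.z_upper)

    @property
    def polygon(self) -> Polygon:
        if len(self.contour) < 3:
            raise ContourError(f"layer {self.index} has no usable contour")
        return Polygon(self.contour)

    @property
    def area(self) -> float:
        return 0.0 if len(self.contour) < 3 else Polygon(self.contour).area


@dataclass(frozen=True)
class SliceStack:
    """The 12 contiguous layers of the supra-basal head.

    Layer 0 abuts the base plane and is excluded from analysis; layers 1–11
    are the analysed planes.  ``mesh_volume_cm3`` is the exact volume of the
    mesh above the base plane, kept for conservation checks.
    """

    layers: tuple[SliceLayer, ...]
    mesh_volume_cm3: float = field(default=float("nan"))

    def __post_init__(self):
        if len(self.layers) < 2:
            raise ContourError("slice stack needs at least two layers")

    @property
    def thickness(self) -> float:
        return self.layers[0].thickness

    def analysed(self) -> tuple[SliceLayer, ...]:
        return tuple(l for l in self.layers if not l.excluded)

    def slice_volume_cm3(self, analysed_only: bool = False) -> float:
        """Midpoint-rule volume: contour area x thickness, summed over layers."""
        layers = self.analysed() if analysed_only else self.layers
        return float(sum(l.area * l.thickness for l in layers))

    def to_dict(self) -> dict:
        return {
            "mesh_volume_cm3": self.mesh_volume_cm3,
            "layers": [
                {
                    "index": l.index,
                    "z_lower": l.z_lower,
                    "z_upper": l.z_upper,
                    "excluded": l.excluded,
                    "contour": np.asarray(l.contour).tolist(),
                }
                for l in self.layers
            ],
        }


def _section_contours(mesh_f: trimesh.Trimesh, z: float) -> list[np.ndarray]:
    """Closed cross-section polygons of a frame-aligned mesh at height z."""
    path = mesh_f.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
    if path is None:
        return []
    contours = []
    for poly in path.discrete:
        pts = np.asarray(poly, dtype=float)[:, :2]
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) >= 3:
            contours.append(pts)
    return contours


def validate_mesh(mesh: trimesh.Trimesh) -> None:
    """Raise :class:`OpenMeshError` unless the mesh encloses a positive volume."""
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise OpenMeshError("open mesh: no triangulated surface present")
    if not mesh.is_watertight:
        raise OpenMeshError("open mesh: surface is not watertight")
    if mesh.volume <= 0:
        raise OpenMeshError("open mesh: enclosed volume is not positive (inverted normals?)")
    if not np.all(np.isfinite(mesh.vertices)):
        raise OpenMeshError("open mesh: non-finite vertex coordinates")


def _tri_flux_z(tri: np.ndarray) -> float:
    """Flux of F=(0,0,z) through one triangle: projected signed area x mean z."""
    proj = 0.5 * (
        (tri[1, 0] - tri[0, 0]) * (tri[2, 1] - tri[0, 1])
        - (tri[2, 0] - tri[0, 0]) * (tri[1, 1] - tri[0, 1])
    )
    return proj * float(tri[:, 2].mean())


def _volume_above_base(mesh_f: trimesh.Trimesh) -> float:
    """Exact enclosed volume of the part of the mesh with z >= 0.

    Divergence theorem with F = (0, 0, z): the base-plane cap lies at z = 0
    and contributes nothing, so only the triangles (clipped to the upper
    half-space) need integrating — no re-triangulated cap is required.
    """
    tris = mesh_f.triangles
    min_z = float(mesh_f.vertices[:, 2].min())
    if min_z >= -1e-9:
        return float(sum(_tri_flux_z(t) for t in tris))

    total = 0.0
    for tri in tris:
        z = tri[:, 2]
        if np.all(z <= 0):
            continue
        if np.all(z >= 0):
            total += _tri_flux_z(tri)
            continue
        # clip the triangle to z >= 0 (Sutherland-Hodgman against one plane)
        poly = []
        for i in range(3):
            a, b = tri[i], tri[(i + 1) % 3]
            if a[2] >= 0:
                poly.append(a)
            if (a[2] >= 0) != (b[2] >= 0):
                s = a[2] / (a[2] - b[2])
                poly.append(a + s * (b - a))
        for j in range(1, len(poly) - 1):
            total += _tri_flux_z(np.array([poly[0], poly[j], poly[j + 1]]))
    return float(total)


def slice_head(
    mesh: trimesh.Trimesh,
    frame: ReferenceFrame,
    n_layers: int = 12,
    volume_check_rtol: float = 0.05,
) -> SliceStack:
    """Divide the supra-basal head into ``n_layers`` equal-thickness layers.

    The span from the base plane (z = 0 in frame coordinates) to the topmost
    vertex is divided evenly; each layer stores the single closed mesh
    cross-section contour at its mid-height.  Layer 0 is flagged excluded.

    A conservation check compares the midpoint-rule volume (sum of contour
    area x thickness) against the exact mesh volume above the base plane and
    warns if they disagree by more than ``volume_check_rtol``.
    """
    validate_mesh(mesh)
    verts_f = frame.to_frame(mesh.vertices)
    mesh_f = trimesh.Trimesh(vertices=verts_f, faces=mesh.faces, process=False)

    z_top = float(verts_f[:, 2].max())
    if z_top <= COINCIDENCE_TOL:
        raise ShortMeshError("short mesh: no vertices above the base plane")
    t = z_top / n_layers

    layers = []
    for k in range(n_layers):
        z_mid = (k + 0.5) * t
        contours = _section_contours(mesh_f, z_mid)
        excluded = k == 0
        if not contours:
            if excluded:
                layers.append(
                    SliceLayer(k, k * t, (k + 1) * t, np.empty((0, 2)), excluded=True)
                )
                continue
            raise ShortMeshError(f"short mesh: empty cross-section at layer {k}")
        if len(contours) > 1 and not excluded:
            # a head is simply connected above the base; several loops mean a
            # defective scan (e.g. ears scanned as separate shells)
            areas = [Polygon(c).area for c in contours]
            if sum(areas) - max(areas) > 1e-6 * max(areas):
                raise ContourError(
                    f"layer {k} has {len(contours)} disjoint cross-section contours"
                )
            contours = [contours[int(np.argmax(areas))]]
        contour = max(contours, key=lambda c: Polygon(c).area)
        poly = Polygon(contour)
        if not poly.is_valid:
            raise ContourError(f"layer {k} contour is self-intersecting")
        # store counter-clockwise for a positive shoelace area
        if not poly.exterior.is_ccw:
            contour = contour[::-1]
        layers.append(SliceLayer(k, k * t, (k + 1) * t, contour, excluded=excluded))

    stack = SliceStack(layers=tuple(layers), mesh_volume_cm3=_volume_above_base(mesh_f))
    est = stack.slice_volume_cm3()
    if stack.mesh_volume_cm3 > 0 and abs(est - stack.mesh_volume_cm3) > volume_check_rtol * stack.mesh_volume_cm3:
        warnings.warn(
            f"slice-integrated volume {est:.1f} cm3 deviates from mesh volume "
            f"{stack.mesh_volume_cm3:.1f} cm3 by more than {volume_check_rtol:.0%}",
            stacklevel=2,
        )
    return stack
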