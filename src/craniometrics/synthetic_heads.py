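"""Parametric synthetic head meshes with analytically known measurements.

No deposited head scans exist for this kind of study, so every pipeline
stage is exercised on generated geometry.  A head is modelled as a loft of
horizontal cross-sections over a total height ``H`` above the tragus plane:

* each cross-section is a superellipse with anteroposterior semi-axis
  ``a(z)`` and mediolateral semi-axis ``b(z)``;
* the anterior half (y > 0) is scaled in y by per-side factors ``s_r`` /
  ``s_l``, so each anterior quadrant area is exactly the quarter-section
  area times its side factor — unilateral frontal flattening and
  compensatory bossing are one parameter each;
* the semi-axis profiles taper toward the vertex as
  ``a(z) = a_max * (1 - v(z)^2) ** (ap_taper / 2)`` (and likewise for b),
  where ``v`` rises linearly from 0 at the mid-height of the first analysed
  layer to 1 at the apex; independent tapers let the slice-averaged cranial
  index differ from the ratio of the maximal extents, as observed in
  scaphocephaly.

Landmarks are placed by rule: tragi at the basal lateral extremes, canthi
and subnasale anterior-basal, and the angle landmarks (nasion,
exocanthions, parietal points) on rays from the nasion whose azimuths are
the preset's frontal and frontoparietal angle parameters — so the angle
measures of the pipeline recover the preset values exactly.

``analytic_measures`` evaluates every index in closed form (diagonals use a
dense 2D sampling of the exact cross-section; no mesh is involved), and
``calibrate_preset`` adjusts preset parameters by one-dimensional
root-finding until a named set of target index values is met, which is how
the frozen phenotype exemplars shipped with the package were produced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import trimesh
from scipy.optimize import brentq
from scipy.special import gamma
from shapely.geometry import Polygon

from .core_frame import LandmarkSet
from .errors import CalibrationError, ValidationError
from .vault_measures import MeasurementRecord, _chord_length

import pandas as pd


@dataclass(frozen=True)
class PhenotypePreset:
    """Parametric description of a synthetic head with closed-form measures.

    Lengths in cm, angles in degrees.  ``anterior_scale_r/l`` multiply the
    anterior (y > 0) half of every cross-section in y on that side;
    ``frontal_angle_deg`` and ``frontoparietal_angle_deg`` drive the
    landmark placement; the ``*_asym`` fields split the angle symmetrically
    between the sides while preserving the mean.
    """

    name: str
    height_cm: float
    ap_semi_axis_cm: float
    ml_semi_axis_cm: float
    ap_taper: float = 0.6
    ml_taper: float = 0.6
    anterior_scale_r: float = 1.0
    anterior_scale_l: float = 1.0
    exponent: float = 2.0
    frontal_angle_deg: float = 150.0
    frontoparietal_angle_deg: float = 137.0
    frontal_asym: float = 0.0
    frontoparietal_asym: float = 0.0
    nasion_y_frac: float = 0.9
    nasion_z_cm: float = 1.0
    orbit_ray_cm: float = 4.8
    parietal_ray_cm: float = 8.0
    noise_amplitude_cm: float = 0.0
    contour_points: int = 128
    rings_per_layer: int = 3
    apex_rings_per_layer: int = 7

    N_LAYERS = 12

    def __post_init__(self):
        if min(self.ap_semi_axis_cm, self.ml_semi_axis_cm, self.height_cm) <= 0:
            raise ValidationError("preset semi-axes and height must be positive")
        if min(self.anterior_scale_r, self.anterior_scale_l) <= 0:
            raise ValidationError("anterior side scale factors must be positive")
        if self.exponent < 1:
            raise ValidationError("superellipse exponent must be >= 1")
        if self.contour_points < 8 or self.contour_points % 4:
            raise ValidationError("contour_points must be a multiple of 4, at least 8")
        for ang in (self.frontal_angle_deg, self.frontoparietal_angle_deg):
            if not 0 < ang < 180:
                raise ValidationError("preset angles must lie in (0, 180) degrees")

    # -- vertical profile ---------------------------------------------------

    @property
    def thickness(self) -> float:
        return self.height_cm / self.N_LAYERS

    def _v(self, z):
        z1 = 1.5 * self.thickness  # mid-height of the first analysed layer
        return np.clip((np.asarray(z, dtype=float) - z1) / (self.height_cm - z1), 0.0, 1.0)

    def shape(self, z):
        """Dimensionless taper profile, 1 below layer-1 mid, 0 at the apex."""
        v = self._v(z)
        return np.sqrt(np.clip(1.0 - v * v, 0.0, None))

    def ap_semi(self, z):
        return self.ap_semi_axis_cm * self.shape(z) ** self.ap_taper

    def ml_semi(self, z):
        return self.ml_semi_axis_cm * self.shape(z) ** self.ml_taper

    def mid_heights(self) -> np.ndarray:
        return (np.arange(self.N_LAYERS) + 0.5) * self.thickness

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhenotypePreset":
        return cls(**d)

    def mirrored(self) -> "PhenotypePreset":
        """Swap the left/right anterior side scales and angle asymmetries."""
        return dataclasses.replace(
            self,
            anterior_scale_r=self.anterior_scale_l,
            anterior_scale_l=self.anterior_scale_r,
            frontal_asym=-self.frontal_asym,
            frontoparietal_asym=-self.frontoparietal_asym,
        )


def _superellipse_unit(tau: np.ndarray, p: float) -> tuple[np.ndarray, np.ndarray]:
    c, s = np.cos(tau), np.sin(tau)
    c[np.abs(c) < 1e-14] = 0.0
    s[np.abs(s) < 1e-14] = 0.0
    e = 2.0 / p
    return np.sign(c) * np.abs(c) ** e, np.sign(s) * np.abs(s) ** e


def cross_section(preset: PhenotypePreset, z: float, n: int | None = None) -> np.ndarray:
    """Closed (m, 2) polygon of the exact cross-section at height z (CCW).

    If the two anterior side scales differ, the contour carries a vertical
    step segment on the midsagittal line, represented by a duplicated x = 0
    vertex pair; quadrant areas then remain exactly linear in each side
    scale.
    """
    n = preset.contour_points if n is None else n
    a, b = float(preset.ap_semi(z)), float(preset.ml_semi(z))
    s_r, s_l = preset.anterior_scale_r, preset.anterior_scale_l
    tau = 2.0 * np.pi * np.arange(n) / n
    cu, su = _superellipse_unit(tau, preset.exponent)
    step = s_r != s_l
    i_q = n // 4  # tau = pi/2
    pts = []
    for i in range(n):
        if step and i == i_q:
            pts.append((0.0, a * s_r))
            pts.append((0.0, a * s_l))
            continue
        x = b * cu[i]
        y = a * su[i]
        if su[i] > 0:
            if cu[i] > 0:
                y *= s_r
            elif cu[i] < 0:
                y *= s_l
            else:
                y *= 0.5 * (s_r + s_l)
        pts.append((x, y))
    return np.asarray(pts, dtype=float)


def _ring_heights(preset: PhenotypePreset) -> np.ndarray:
    """Loft ring heights: several rings per layer, denser near the apex.

    Per-layer ring counts are odd so that no ring coincides with a layer
    mid-height; the analysed cross-sections are then recovered by linear
    interpolation between nearby rings without degenerate on-plane sections.
    """
    t = preset.thickness
    zs = []
    for k in range(preset.N_LAYERS):
        m = preset.apex_rings_per_layer if k >= preset.N_LAYERS - 2 else preset.rings_per_layer
        if m % 2 == 0:
            m += 1
        zs.extend(k * t + np.arange(m) * t / m)
    return np.asarray(zs)


def generate_head(preset: PhenotypePreset, seed: int = 0) -> tuple[trimesh.Trimesh, LandmarkSet]:
    """Build the watertight lofted mesh and its landmark set.

    Deterministic for a given (preset, seed); the seed only matters when
    ``noise_amplitude_cm`` is non-zero, in which case a smooth random radial
    modulation (low-order Fourier in azimuth, linear ramp in height) is
    applied to the rings.
    """
    zs = _ring_heights(preset)
    rings = [cross_section(preset, z) for z in zs]
    m = len(rings[0])
    if any(len(r) != m for r in rings):
        raise ValidationError("inconsistent ring vertex counts")

    if preset.noise_amplitude_cm > 0:
        rng = np.random.default_rng(seed)
        coeffs = rng.normal(0.0, preset.noise_amplitude_cm, size=(3, 2))
        for j, (ring, z) in enumerate(zip(rings, zs)):
            tau = np.arctan2(ring[:, 1], np.where(np.abs(ring[:, 0]) < 1e-12, 1e-12, ring[:, 0]))
            ramp = z / preset.height_cm
            mod = sum(
                coeffs[i, 0] * np.cos((i + 1) * tau) + coeffs[i, 1] * np.sin((i + 1) * tau)
                for i in range(3)
            )
            rings[j] = ring * (1.0 + ramp * mod / max(preset.ml_semi_axis_cm, 1.0))[:, None]

    vertices = [np.column_stack([r, np.full(m, z)]) for r, z in zip(rings, zs)]
    vertices = np.vstack(vertices)
    base_centre = len(vertices)
    apex = base_centre + 1
    vertices = np.vstack([vertices, [0.0, 0.0, 0.0], [0.0, 0.0, preset.height_cm]])

    faces = []
    n_rings = len(zs)
    for j in range(n_rings - 1):
        lo, hi = j * m, (j + 1) * m
        for i in range(m):
            i2 = (i + 1) % m
            faces.append((lo + i, lo + i2, hi + i))
            faces.append((lo + i2, hi + i2, hi + i))
    for i in range(m):  # bottom cap, outward normal -z
        faces.append((base_centre, (i + 1) % m, i))
    top = (n_rings - 1) * m
    for i in range(m):  # apex fan
        faces.append((apex, top + i, top + (i + 1) % m))

    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    if not mesh.is_watertight or mesh.volume <= 0:
        raise ValidationError("generated mesh failed the watertightness check")
    return mesh, place_landmarks(preset)


def _angle_rays(preset: PhenotypePreset) -> tuple[float, float, float, float]:
    """Azimuths (radians, from the anterior axis toward +x) of the orbit and
    parietal rays per side."""
    half = 0.5 * np.deg2rad(preset.frontal_angle_deg)
    beta_r = half * (1.0 + preset.frontal_asym)
    beta_l = half * (1.0 - preset.frontal_asym)
    psi = np.deg2rad(preset.frontoparietal_angle_deg)
    psi_r = psi * (1.0 + preset.frontoparietal_asym)
    psi_l = psi * (1.0 - preset.frontoparietal_asym)
    return beta_r, beta_l, psi_r, psi_l


def place_landmarks(preset: PhenotypePreset) -> LandmarkSet:
    """Parametric landmark placement rules for a preset.

    The tragi sit at the basal lateral extremes and the canthi/subnasale
    anterior-basal, which makes the landmark-derived reference frame the
    identity frame of the generator.  The exocanthion and parietal points
    are placed on rays from the nasion at the preset's angle parameters;
    the "parietal" point of each side lands across the midline in the axial
    plane, because an obtuse frontoparietal angle at the nasion sweeps from
    one orbital rim across the vault — the placements are parametric
    abstractions chosen to realise the preset angles, not measured anatomy.
    """
    a0 = float(preset.ap_semi(0.0))
    b0 = float(preset.ml_semi(0.0))
    n_y = preset.nasion_y_frac * a0
    n_z = preset.nasion_z_cm
    beta_r, beta_l, psi_r, psi_l = _angle_rays(preset)
    r_e, r_p = preset.orbit_ray_cm, preset.parietal_ray_cm

    def ray(origin_y, azimuth, radius, z):
        return (radius * np.sin(azimuth), origin_y - radius * np.cos(azimuth), z)

    points = {
        "tragus_r": (b0, 0.0, 0.0),
        "tragus_l": (-b0, 0.0, 0.0),
        "canthus_lat_r": (0.5 * b0, 0.7 * a0, 0.0),
        "canthus_lat_l": (-0.5 * b0, 0.7 * a0, 0.0),
        "subnasale": (0.0, 0.8 * a0, -1.5),
        "nasion": (0.0, n_y, n_z),
        "glabella": (0.0, float(preset.ap_semi(2.0)) * min(preset.anterior_scale_r,
                                                          preset.anterior_scale_l), 2.0),
        "exocanthion_r": ray(n_y, beta_r, r_e, n_z - 0.5),
        "exocanthion_l": (lambda p: (-p[0], p[1], p[2]))(ray(n_y, beta_l, r_e, n_z - 0.5)),
        "frontotemporal_r": ray(n_y, 0.9 * beta_r, 0.85 * r_e, n_z + 1.5),
        "frontotemporal_l": (lambda p: (-p[0], p[1], p[2]))(ray(n_y, 0.9 * beta_l, 0.85 * r_e, n_z + 1.5)),
        "parietal_r": ray(n_y, beta_r - psi_r, r_p, 1.0),
        "parietal_l": (lambda p: (-p[0], p[1], p[2]))(ray(n_y, beta_l - psi_l, r_p, 1.0)),
        "preaural_r": (0.97 * b0, -0.8, 0.5),
        "preaural_l": (-0.97 * b0, -0.8, 0.5),
        "infraorbital_r": (2.2, 0.75 * a0, n_z - 1.5),
        "infraorbital_l": (-2.2, 0.75 * a0, n_z - 1.5),
    }
    return LandmarkSet({k: np.asarray(v, dtype=float) for k, v in points.items()})


def _quarter_area_factor(p: float) -> float:
    """Area of a unit-semiaxis superellipse quadrant (pi/4 for an ellipse)."""
    return float(gamma(1.0 + 1.0 / p) ** 2 / gamma(1.0 + 2.0 / p))


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def analytic_measures(preset: PhenotypePreset, offset_deg: float = 30.0) -> MeasurementRecord:
    """Closed-form expected measurement record for a preset.

    Extents and quadrant volumes come from the superellipse quarter-area
    formula, angles from the parametric landmark coordinates by the vector
    formula; only the diagonals are evaluated on a dense (4096-point) exact
    cross-section polygon, still without any mesh or slicing involved.
    """
    t = preset.thickness
    mids = preset.mid_heights()
    s_r, s_l = preset.anterior_scale_r, preset.anterior_scale_l
    s_max = max(s_r, s_l)
    F = _quarter_area_factor(preset.exponent)

    rows = []
    for k in range(1, preset.N_LAYERS):
        a_k = float(preset.ap_semi(mids[k]))
        b_k = float(preset.ml_semi(mids[k]))
        rows.append(
            {
                "layer": k,
                "length_cm": a_k * (1.0 + s_max),
                "width_cm": 2.0 * b_k,
                "ci_pct": 100.0 * 2.0 * b_k / (a_k * (1.0 + s_max)),
                "q1_area_cm2": F * a_k * b_k * s_r,
                "q2_area_cm2": F * a_k * b_k * s_l,
                "q3_area_cm2": F * a_k * b_k,
                "q4_area_cm2": F * a_k * b_k,
            }
        )
    table = pd.DataFrame(rows)

    record = MeasurementRecord()
    record.set("cranial_length_cm", table["length_cm"].max(), "cm")
    record.set("cranial_width_cm", table["width_cm"].max(), "cm")
    record.set("cranial_index_pct", table["ci_pct"].mean(), "%")
    for q in ("q1", "q2", "q3", "q4"):
        record.set(f"{q}_ml", table[f"{q}_area_cm2"].sum() * t, "ml")
    record.set(
        "total_volume_ml",
        sum(record[f"{q}_ml"] for q in ("q1", "q2", "q3", "q4")),
        "ml",
    )
    record.set("asr", min(s_r, s_l) / max(s_r, s_l), "")
    record.set("psr", 1.0, "")

    lm = place_landmarks(preset)
    nas = lm["nasion"][:2]
    u_r = lm["exocanthion_r"][:2] - nas
    u_l = lm["exocanthion_l"][:2] - nas
    p_r = lm["parietal_r"][:2] - nas
    p_l = lm["parietal_l"][:2] - nas
    record.set("frontal_angle_deg", _angle_between(u_r, u_l), "deg")
    fp_r = _angle_between(u_r, p_r)
    fp_l = _angle_between(u_l, p_l)
    record.set("frontoparietal_angle_r_deg", fp_r, "deg")
    record.set("frontoparietal_angle_l_deg", fp_l, "deg")
    record.set("frontoparietal_angle_mean_deg", 0.5 * (fp_r + fp_l), "deg")

    # diagonals on the largest analysed cross-section, dense exact sampling
    areas = table.set_index("layer")[["q1_area_cm2", "q2_area_cm2", "q3_area_cm2", "q4_area_cm2"]].sum(axis=1)
    k_best = int(areas.idxmax())
    poly = Polygon(cross_section(preset, mids[k_best], n=4096))
    centre = np.array([poly.centroid.x, poly.centroid.y])
    theta = np.deg2rad(offset_deg)
    diag_a, _ = _chord_length(poly, centre, np.array([np.sin(theta), np.cos(theta)]))
    diag_b, _ = _chord_length(poly, centre, np.array([-np.sin(theta), np.cos(theta)]))
    record.set("diagonal_a_cm", diag_a, "cm")
    record.set("diagonal_b_cm", diag_b, "cm")
    record.set("diagonal_diff_cm", abs(diag_a - diag_b), "cm")

    record.per_slice = table
    return record


# ---------------------------------------------------------------------------
# calibration

#: target name -> description of the 1-D knob that controls it
CALIBRATABLE_TARGETS = (
    "cranial_length_cm",
    "cranial_width_cm",
    "cranial_index_pct",
    "q1_ml",
    "q2_ml",
    "asr",
    "frontal_angle_deg",
    "frontoparietal_mean_deg",
    "diagonal_diff_cm",
)

_TARGET_TO_RECORD_KEY = {
    "frontoparietal_mean_deg": "frontoparietal_angle_mean_deg",
}


def _record_value(record: MeasurementRecord, target: str) -> float:
    return record[_TARGET_TO_RECORD_KEY.get(target, target)]


def calibrate_preset(
    targets: dict[str, float],
    base: PhenotypePreset,
    rtol: float = 2e-3,
    max_sweeps: int = 100,
) -> PhenotypePreset:
    """Adjust preset parameters until every target index value is met.

    Each target is controlled by one preset parameter (cranial width by the
    ML semi-axis, cranial index by the AP taper exponent, quadrant volumes
    by the anterior side scales, angles by the angle parameters, ...); the
    solver sweeps the targets with exact or bracketed one-dimensional
    root-finding updates until all relative residuals fall below ``rtol``
    (stricter than the 0.5 % the frozen exemplars are required to meet).

    Raises :class:`CalibrationError` for unknown or jointly infeasible
    targets, listing the residuals.
    """
    unknown = set(targets) - set(CALIBRATABLE_TARGETS)
    if unknown:
        raise CalibrationError(f"calibration failed: unknown targets {sorted(unknown)}")
    if "asr" in targets and ("q2_ml" in targets or "diagonal_diff_cm" in targets):
        raise CalibrationError(
            "calibration failed: 'asr' conflicts with 'q2_ml'/'diagonal_diff_cm' "
            "(all are controlled by the anterior side-scale ratio)"
        )
    if "q2_ml" in targets and "diagonal_diff_cm" in targets:
        raise CalibrationError(
            "calibration failed: 'q2_ml' and 'diagonal_diff_cm' share a knob"
        )
    if "asr" in targets and not 0 < targets["asr"] <= 1:
        raise CalibrationError("calibration failed: asr target must lie in (0, 1]")

    preset = base

    def residuals(p: PhenotypePreset) -> dict[str, float]:
        rec = analytic_measures(p)
        return {
            name: (_record_value(rec, name) - val) / (abs(val) if val else 1.0)
            for name, val in targets.items()
        }

    def _brentq_knob(p, field, lo, hi, target_name):
        def g(x):
            rec = analytic_measures(dataclasses.replace(p, **{field: x}))
            return _record_value(rec, target_name) - targets[target_name]

        try:
            root = brentq(g, lo, hi, xtol=1e-10, rtol=1e-12, maxiter=200)
        except ValueError as exc:
            raise CalibrationError(
                f"calibration failed: target {target_name!r} not bracketed by "
                f"{field} in [{lo}, {hi}] ({exc})"
            ) from exc
        return dataclasses.replace(p, **{field: float(root)})

    for _ in range(max_sweeps):
        res = residuals(preset)
        if all(abs(r) <= rtol for r in res.values()):
            return preset
        for name, val in targets.items():
            if name == "cranial_width_cm":
                preset = dataclasses.replace(preset, ml_semi_axis_cm=val / 2.0)
            elif name == "cranial_length_cm":
                s_max = max(preset.anterior_scale_r, preset.anterior_scale_l)
                preset = dataclasses.replace(preset, ap_semi_axis_cm=val / (1.0 + s_max))
            elif name == "cranial_index_pct":
                preset = _brentq_knob(preset, "ap_taper", 0.02, 6.0, name)
            elif name == "frontal_angle_deg":
                preset = dataclasses.replace(preset, frontal_angle_deg=float(val))
            elif name == "frontoparietal_mean_deg":
                preset = dataclasses.replace(preset, frontoparietal_angle_deg=float(val))
            elif name == "q1_ml":
                rec = analytic_measures(preset)
                factor = val / rec["q1_ml"]
                preset = dataclasses.replace(
                    preset, anterior_scale_r=preset.anterior_scale_r * factor
                )
            elif name == "q2_ml":
                rec = analytic_measures(preset)
                factor = val / rec["q2_ml"]
                preset = dataclasses.replace(
                    preset, anterior_scale_l=preset.anterior_scale_l * factor
                )
            elif name == "asr":
                preset = dataclasses.replace(
                    preset, anterior_scale_l=preset.anterior_scale_r * float(val)
                )
            elif name == "diagonal_diff_cm":
                def g(rho):
                    p2 = dataclasses.replace(
                        preset, anterior_scale_l=preset.anterior_scale_r * rho
                    )
                    return analytic_measures(p2)["diagonal_diff_cm"] - val

                try:
                    rho = brentq(g, 0.25, 1.0, xtol=1e-10, maxiter=200)
                except ValueError as exc:
                    raise CalibrationError(
                        f"calibration failed: diagonal difference {val} cm is not "
                        f"reachable by the side-scale ratio ({exc})"
                    ) from exc
                preset = dataclasses.replace(
                    preset, anterior_scale_l=preset.anterior_scale_r * float(rho)
                )

    res = residuals(preset)
    raise CalibrationError(
        "calibration failed: residuals after "
        f"{max_sweeps} sweeps: " + ", ".join(f"{k}={v:+.2%}" for k, v in res.items())
    )


# ---------------------------------------------------------------------------
# shipped presets

PRESET_NAMES = ("control", "scaphocephaly", "trigonocephaly", "anterior_plagiocephaly")


def base_preset(name: str) -> PhenotypePreset:
    """Uncalibrated starting preset for each phenotype."""
    if name == "control":
        return PhenotypePreset(
            name="control", height_cm=13.2, ap_semi_axis_cm=8.5, ml_semi_axis_cm=7.5,
            frontal_angle_deg=150.0, frontoparietal_angle_deg=137.0,
        )
    if name == "scaphocephaly":
        return PhenotypePreset(
            name="scaphocephaly", height_cm=11.0, ap_semi_axis_cm=10.0,
            ml_semi_axis_cm=6.0, ap_taper=1.3,
            frontal_angle_deg=153.0, frontoparietal_angle_deg=138.0,
        )
    if name == "trigonocephaly":
        return PhenotypePreset(
            name="trigonocephaly", height_cm=13.2, ap_semi_axis_cm=9.7,
            ml_semi_axis_cm=7.5, anterior_scale_r=0.8, anterior_scale_l=0.8,
            frontal_angle_deg=130.0, frontoparietal_angle_deg=130.0,
        )
    if name == "anterior_plagiocephaly":
        return PhenotypePreset(
            name="anterior_plagiocephaly", height_cm=13.2, ap_semi_axis_cm=7.9,
            ml_semi_axis_cm=7.5, anterior_scale_r=1.1, anterior_scale_l=0.9,
            frontal_angle_deg=140.0, frontoparietal_angle_deg=134.0,
            frontal_asym=0.02, frontoparietal_asym=0.04,
        )
    raise ValidationError(f"unknown preset name {name!r}")


#: index targets each frozen phenotype exemplar is calibrated to (the group
#: means of the emulated study conditions); the control preset is left at
#: its symmetric base parameters.
EXEMPLAR_TARGETS: dict[str, dict[str, float]] = {
    "scaphocephaly": {
        "cranial_length_cm": 20.0,
        "cranial_width_cm": 12.0,
        "cranial_index_pct": 70.0,
        "frontal_angle_deg": 153.0,
        "frontoparietal_mean_deg": 138.0,
    },
    "trigonocephaly": {
        "cranial_length_cm": 17.0,
        "cranial_width_cm": 15.0,
        "q1_ml": 400.0,
        "q2_ml": 400.0,
        "frontal_angle_deg": 130.0,
        "frontoparietal_mean_deg": 130.0,
    },
    "anterior_plagiocephaly": {
        "cranial_length_cm": 17.0,
        "cranial_width_cm": 15.0,
        "q1_ml": 500.0,
        "asr": 0.8,
        "frontal_angle_deg": 140.0,
        "frontoparietal_mean_deg": 134.0,
    },
}


def load_preset(name: str) -> PhenotypePreset:
    """Load a frozen, calibrated phenotype preset shipped with the package."""
    if name not in PRESET_NAMES:
        raise ValidationError(f"unknown preset name {name!r}; choose from {PRESET_NAMES}")
    path = resources.files("craniometrics").joinpath("data", "presets", f"{name}.json")
    with path.open("r") as fh:
        return PhenotypePreset.from_dict(json.load(fh))


def freeze_exemplars(out_dir) -> dict[str, PhenotypePreset]:
    """Recompute every frozen exemplar from its base preset and targets and
    write them as JSON (used to produce the shipped preset files)."""
    from pathlib import Path

    out = {}
    for name in PRESET_NAMES:
        preset = base_preset(name)
        if name in EXEMPLAR_TARGETS:
            preset = calibrate_preset(EXEMPLAR_TARGETS[name], preset)
        out[name] = preset
        path = Path(out_dir) / f"{name}.json"
        path.write_text(json.dumps(preset.to_dict(), indent=1) + "\n")
    return out
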