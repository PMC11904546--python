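"""Independent brute-force oracles used to check the package's computations.

Everything here deliberately avoids the code paths under test: volumes are
counted on a voxel grid, angles come from the plain arccos formula, t tests
from the textbook equations, scores from explicit loops.
"""

from __future__ import annotations

import numpy as np
import shapely
import trimesh
from scipy import stats as sps
from shapely.geometry import Polygon


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rotation (via QR of a Gaussian matrix) + translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-20, 20, size=3)
    return q, t


def voxel_volumes(
    mesh: trimesh.Trimesh,
    rotation: np.ndarray,
    origin: np.ndarray,
    pitch: float = 0.2,
    z_min: float = 0.0,
    z_max: float | None = None,
) -> dict[str, float]:
    """Voxel-counted volume (cm3) of the mesh between two frame heights.

    Counts voxel centres inside per-z-level cross-sections of the
    frame-aligned mesh; returns the total and the per-quadrant split
    (anterior/posterior x right/left).  Independent of the layered
    midpoint-rule volume path in the package.
    """
    V = (mesh.vertices - origin) @ rotation
    mf = trimesh.Trimesh(V, mesh.faces, process=False)
    if z_max is None:
        z_max = float(V[:, 2].max())
    # grid aligned to the quadrant planes: voxel centres at (k + 1/2) * pitch,
    # so no voxel straddles x = 0 or y = 0
    xs = (np.arange(np.floor(V[:, 0].min() / pitch) - 1, np.ceil(V[:, 0].max() / pitch) + 1) + 0.5) * pitch
    ys = (np.arange(np.floor(V[:, 1].min() / pitch) - 1, np.ceil(V[:, 1].max() / pitch) + 1) + 0.5) * pitch
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    counts = {"total": 0, "q1": 0, "q2": 0, "q3": 0, "q4": 0}
    n_levels = int(np.floor((z_max - z_min) / pitch))
    for i in range(n_levels):
        z = z_min + (i + 0.5) * pitch
        path = mf.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
        if path is None:
            continue
        inside = np.zeros(len(gx), dtype=bool)
        for d in path.discrete:
            poly = Polygon(np.asarray(d)[:, :2])
            inside |= shapely.contains_xy(poly, gx, gy)
        counts["total"] += int(inside.sum())
        counts["q1"] += int((inside & (gx > 0) & (gy > 0)).sum())
        counts["q2"] += int((inside & (gx < 0) & (gy > 0)).sum())
        counts["q3"] += int((inside & (gx > 0) & (gy < 0)).sum())
        counts["q4"] += int((inside & (gx < 0) & (gy < 0)).sum())
    return {k: v * pitch**3 for k, v in counts.items()}


def angle_deg(vertex, p1, p2, project_axial: bool = True) -> float:
    """Plain arccos vector angle, optionally in the axial (x-y) projection."""
    u = np.asarray(p1, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(p2, dtype=float) - np.asarray(vertex, dtype=float)
    if project_axial:
        u, v = u[:2], v[:2]
    c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1, 1))))


def pooled_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Textbook pooled-variance two-sample two-tailed t test."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * sps.t.sf(abs(t), nx + ny - 2)
    return float(t), float(p)


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Textbook Welch two-sample two-tailed t test."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1) / nx, np.var(y, ddof=1) / ny
    t = (np.mean(x) - np.mean(y)) / np.sqrt(vx + vy)
    dof = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    p = 2 * sps.t.sf(abs(t), dof)
    return float(t), float(p)


def kidscreen_oracle(row: dict[str, float], item_map: dict[str, str]) -> dict[str, float]:
    """Sum-and-rescale one subject's responses by explicit loops."""
    cats: dict[str, list[float]] = {}
    for item, cat in item_map.items():
        cats.setdefault(cat, []).append(row[item])
    out = {}
    for cat, vals in cats.items():
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
            out[cat] = np.nan
        else:
            n = len(vals)
            out[cat] = 100.0 * (sum(vals) - n) / (4.0 * n)
    return out


def band_oracle(score: float, cuts: list[float], labels: tuple[str, ...]) -> str:
    """Linear interval search with lower-edge inclusion."""
    for i, cut in enumerate(cuts):
        if score < cut:
            return labels[i]
    return labels[len(cuts)]


def ellipse_chord(a_y: float, b_x: float, theta_deg: float) -> float:
    """Chord through the centre of an origin-centred ellipse at ``theta``
    degrees from the +y axis (polar form)."""
    th = np.deg2rad(theta_deg)
    r = 1.0 / np.sqrt((np.sin(th) / b_x) ** 2 + (np.cos(th) / a_y) ** 2)
    return 2.0 * r
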