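"""Vault index catalogue: extents, cranial index, diagonals, quadrants, angles."""

import numpy as np
import pytest
import trimesh

from craniometrics.core_frame import (
    LandmarkSet,
    SliceLayer,
    SliceStack,
    build_reference_frame,
    slice_head,
)
from craniometrics.errors import EmptyQuadrantError
from craniometrics.vault_measures import (
    asymmetry_ratio,
    cranial_index,
    cranial_length_width,
    diagonals,
    frontal_angle,
    frontoparietal_angles,
    measure_all,
    quadrant_volumes,
)
from oracles import angle_deg, ellipse_chord


def _ellipse_stack(a_y=10.0, b_x=6.0, n=720):
    """Hand-built stack with one analysed dense-ellipse layer."""
    tau = 2 * np.pi * np.arange(n) / n
    contour = np.column_stack([b_x * np.cos(tau), a_y * np.sin(tau)])
    layers = (
        SliceLayer(0, 0.0, 1.0, np.empty((0, 2)), excluded=True),
        SliceLayer(1, 1.0, 2.0, contour),
    )
    return SliceStack(layers=layers, mesh_volume_cm3=np.pi * a_y * b_x)


class TestExtentsAndIndex:
    def test_sphere_length_width_equal_diameter(self, sphere_fixture):
        mesh, lm = sphere_fixture
        stack = slice_head(mesh, build_reference_frame(lm))
        length, width, table = cranial_length_width(stack)
        assert length == pytest.approx(16.0, rel=1e-3)
        assert width == pytest.approx(16.0, rel=1e-3)
        assert len(table) == 11

    def test_sphere_cranial_index_100(self, sphere_fixture):
        mesh, lm = sphere_fixture
        stack = slice_head(mesh, build_reference_frame(lm))
        assert cranial_index(stack) == pytest.approx(100.0, rel=5e-3)

    def test_ellipsoid_sections_match_closed_form(self, sphere_fixture):
        """Ellipsoid with semi-axes (ML 6, AP 10, SI 9) sitting on the base
        plane: every slice is an ellipse scaled by sqrt(1-(z/9)^2)."""
        _, lm = sphere_fixture
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        mesh.apply_scale([6.0, 10.0, 9.0])
        stack = slice_head(mesh, build_reference_frame(lm))
        length, width, table = cranial_length_width(stack)
        t = 9.0 / 12.0
        for _, row in table.iterrows():
            z = (row["layer"] + 0.5) * t
            f = np.sqrt(1 - (z / 9.0) ** 2)
            assert row["length_cm"] == pytest.approx(20.0 * f, rel=1e-2)
            assert row["width_cm"] == pytest.approx(12.0 * f, rel=1e-2)
        # sections scale isotropically, so CI = 100 * ML/AP on every slice
        assert cranial_index(stack) == pytest.approx(60.0, rel=1e-2)


class TestDiagonals:
    def test_symmetric_contour_has_zero_difference(self):
        diag_a, diag_b, diff = diagonals(_ellipse_stack(), offset_deg=30.0)
        assert diff == pytest.approx(0.0, abs=1e-9)
        assert diag_a == pytest.approx(diag_b)

    @pytest.mark.parametrize("offset", [15.0, 30.0, 45.0])
    def test_ellipse_chords_match_polar_form(self, offset):
        diag_a, diag_b, _ = diagonals(_ellipse_stack(), offset_deg=offset)
        expected = ellipse_chord(10.0, 6.0, offset)
        assert diag_a == pytest.approx(expected, rel=1e-4)
        assert diag_b == pytest.approx(expected, rel=1e-4)


class TestQuadrants:
    def test_mirror_symmetric_quadrants_equal(self, preset_heads):
        _, mesh, lm = preset_heads["control"]
        stack = slice_head(mesh, build_reference_frame(lm))
        q1, q2, q3, q4 = quadrant_volumes(stack)
        assert q1 == pytest.approx(q2, rel=1e-9)
        assert q3 == pytest.approx(q4, rel=1e-9)

    def test_quadrants_partition_total_volume(self, preset_heads):
        _, mesh, lm = preset_heads["anterior_plagiocephaly"]
        stack = slice_head(mesh, build_reference_frame(lm))
        q = quadrant_volumes(stack)
        assert sum(q) == pytest.approx(stack.slice_volume_cm3(analysed_only=True), rel=1e-9)

    def test_quarter_ellipse_closed_form(self):
        q1, q2, q3, q4 = quadrant_volumes(_ellipse_stack())
        expected = np.pi * 10.0 * 6.0 / 4.0  # quarter area x unit thickness
        for q in (q1, q2, q3, q4):
            assert q == pytest.approx(expected, rel=1e-3)


class TestAsymmetryRatio:
    def test_direct_division_and_reciprocal_conventions(self):
        assert asymmetry_ratio(250.0, 312.5, "lower_over_higher") == pytest.approx(0.8)
        assert asymmetry_ratio(250.0, 312.5, "higher_over_lower") == pytest.approx(1.25)

    def test_conventions_are_exact_reciprocals(self, rng):
        for _ in range(50):
            a, b = rng.uniform(50, 800, 2)
            lo = asymmetry_ratio(a, b, "lower_over_higher")
            hi = asymmetry_ratio(a, b, "higher_over_lower")
            assert lo * hi == pytest.approx(1.0, rel=1e-12)
            assert 0 < lo <= 1.0

    def test_equal_quadrants_score_one(self):
        assert asymmetry_ratio(400.0, 400.0) == 1.0

    def test_zero_volume_rejected(self):
        with pytest.raises(EmptyQuadrantError):
            asymmetry_ratio(0.0, 100.0)


def _angle_landmarks(extra):
    base = {
        "tragus_r": [7.0, 0.0, 0.0],
        "tragus_l": [-7.0, 0.0, 0.0],
        "canthus_lat_r": [4.5, 8.0, 0.0],
        "canthus_lat_l": [-4.5, 8.0, 0.0],
        "subnasale": [0.0, 9.0, -1.0],
    }
    base.update(extra)
    return LandmarkSet(base)


class TestAngles:
    def test_orthogonal_rays_give_90_degrees(self):
        lm = _angle_landmarks(
            {
                "nasion": [0.0, 5.0, 1.0],
                "exocanthion_r": [1.0, 6.0, 0.5],
                "exocanthion_l": [-1.0, 6.0, 0.5],
            }
        )
        assert frontal_angle(lm) == pytest.approx(90.0, abs=1e-9)

    def test_matches_vector_angle_oracle_on_random_landmarks(self, rng):
        for _ in range(50):
            lm = _angle_landmarks(
                {
                    "nasion": [0.0, rng.uniform(4, 9), rng.uniform(0, 2)],
                    "exocanthion_r": rng.uniform([1, 2, -1], [6, 9, 2]),
                    "exocanthion_l": rng.uniform([-6, 2, -1], [-1, 9, 2]),
                    "parietal_r": rng.uniform([-8, -8, 0], [8, 2, 3]),
                    "parietal_l": rng.uniform([-8, -8, 0], [8, 2, 3]),
                }
            )
            frame = build_reference_frame(lm)
            pts = {k: frame.to_frame(v)[0] for k, v in lm.points.items()}
            assert frontal_angle(lm) == pytest.approx(
                angle_deg(pts["nasion"], pts["exocanthion_r"], pts["exocanthion_l"]), abs=1e-9
            )
            fp_r, fp_l = frontoparietal_angles(lm)
            assert fp_r == pytest.approx(
                angle_deg(pts["nasion"], pts["exocanthion_r"], pts["parietal_r"]), abs=1e-9
            )
            assert fp_l == pytest.approx(
                angle_deg(pts["nasion"], pts["exocanthion_l"], pts["parietal_l"]), abs=1e-9
            )

    def test_mirror_symmetric_landmarks_give_equal_sides(self):
        lm = _angle_landmarks(
            {
                "nasion": [0.0, 8.0, 1.0],
                "exocanthion_r": [4.0, 7.0, 0.5],
                "exocanthion_l": [-4.0, 7.0, 0.5],
                "parietal_r": [-6.0, 1.0, 1.0],
                "parietal_l": [6.0, 1.0, 1.0],
            }
        )
        fp_r, fp_l = frontoparietal_angles(lm)
        assert fp_r == pytest.approx(fp_l, abs=1e-9)


class TestMeasureAll:
    def test_record_has_at_least_60_named_values(self, preset_heads):
        _, mesh, lm = preset_heads["control"]
        record = measure_all(mesh, lm)
        assert record.n_values >= 60
        assert len(record.per_slice) == 11

    def test_control_head_is_fully_symmetric(self, preset_heads):
        _, mesh, lm = preset_heads["control"]
        record = measure_all(mesh, lm)
        assert record["asr"] == pytest.approx(1.0, abs=1e-6)
        assert record["psr"] == pytest.approx(1.0, abs=1e-6)
        assert record["diagonal_diff_cm"] == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance(self, preset_heads, rng):
        """Every scalar measure is invariant under a rigid motion of the
        head + landmarks (small sample here; the full 100-motion sweep runs
        in the acceptance suite)."""
        _, mesh, lm = preset_heads["anterior_plagiocephaly"]
        base = measure_all(mesh, lm)
        from oracles import random_rigid_motion

        for _ in range(5):
            R, t = random_rigid_motion(rng)
            moved_mesh = trimesh.Trimesh(mesh.vertices @ R.T + t, mesh.faces, process=False)
            moved = measure_all(moved_mesh, lm.transformed(R, t))
            for key, val in base.values.items():
                assert moved[key] == pytest.approx(val, rel=1e-6, abs=1e-6), key

    def test_mirroring_swaps_sides(self, preset_heads):
        """Mirroring the head and relabelling left/right swaps Q1/Q2, Q3/Q4
        and the frontoparietal sides but fixes ASR, PSR, CI and extents."""
        _, mesh, lm = preset_heads["anterior_plagiocephaly"]
        base = measure_all(mesh, lm)
        mirrored_mesh = trimesh.Trimesh(
            mesh.vertices * [-1, 1, 1], mesh.faces[:, ::-1], process=False
        )
        mirrored = measure_all(mirrored_mesh, lm.mirrored())
        assert mirrored["q1_ml"] == pytest.approx(base["q2_ml"], rel=1e-9)
        assert mirrored["q2_ml"] == pytest.approx(base["q1_ml"], rel=1e-9)
        assert mirrored["q3_ml"] == pytest.approx(base["q4_ml"], rel=1e-9)
        assert mirrored["frontoparietal_angle_r_deg"] == pytest.approx(
            base["frontoparietal_angle_l_deg"], abs=1e-9
        )
        for fixed in ("asr", "psr", "cranial_index_pct", "cranial_length_cm", "cranial_width_cm"):
            assert mirrored[fixed] == pytest.approx(base[fixed], rel=1e-9), fixed
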