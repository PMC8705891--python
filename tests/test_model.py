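"""Skeletal model: DoF bookkeeping, forward kinematics, knee-axis
modification, anthropometric scaling and serialization."""

from dataclasses import replace

import numpy as np
import pytest

from gaitprofile.errors import ConfigurationError, GeometryError, ValidationError
from gaitprofile.model import (GENERIC_GEOMETRY, Anthropometry, anthropometry_of,
                               apply_knee_axis_correction, build_generic_model,
                               forward_kinematics, joint_centres, load_model,
                               lock_subtalar, model_from_dict, model_to_dict,
                               rotation_about, save_model, scale_model)


def brute_force_fk(model, q):
    """Independent oracle: explicit 4x4 homogeneous-transform chain."""
    qmap = model.full_q(q)
    T = {}
    out = {}
    for seg in model.segments:
        Tp = T[seg.parent] if seg.parent else np.eye(4)
        A = np.eye(4)
        A[:3, 3] = seg.joint_origin_in_parent
        for axis, dof, cname in zip(seg.joint_axes, seg.joint_dof_types,
                                    seg.coordinate_names):
            B = np.eye(4)
            if dof == "trans":
                B[:3, 3] = axis * qmap[cname]
            else:
                B[:3, :3] = rotation_about(axis, qmap[cname])
            A = A @ B
        T[seg.name] = Tp @ A
        for label, local in seg.local_markers.items():
            out[label] = (T[seg.name] @ np.r_[local, 1.0])[:3]
    return out


def random_q(model, rng, scale=0.3):
    lo, hi = model.bounds_arrays()
    q = rng.uniform(-scale, scale, model.n_coordinates)
    return np.clip(q, lo, hi)


class TestConstruction:
    def test_coordinate_bookkeeping(self):
        assert build_generic_model().n_coordinates == 18
        assert build_generic_model(subtalar_locked=True).n_coordinates == 16

    def test_lock_subtalar_roundtrip(self, model):
        assert lock_subtalar(model).n_coordinates == 16
        assert lock_subtalar(lock_subtalar(model), locked=False).n_coordinates == 18

    def test_missing_mandatory_marker_named(self):
        spec = [m for m in build_generic_model().marker_labels if m != "LKNE"]
        with pytest.raises(ConfigurationError, match="LKNE"):
            build_generic_model(spec)

    def test_zero_pose_mirror_symmetry(self, zero_pose_markers):
        flip = np.array([1.0, -1.0, 1.0])
        for label, pos in zero_pose_markers.items():
            if label.startswith("R"):
                np.testing.assert_allclose(
                    pos * flip, zero_pose_markers["L" + label[1:]], atol=1e-12)

    def test_axes_unit_length(self, model):
        for seg in model.segments:
            for a in seg.joint_axes:
                assert abs(np.linalg.norm(a) - 1) < 1e-12


class TestForwardKinematics:
    def test_q_length_mismatch(self, model):
        with pytest.raises(ValidationError):
            forward_kinematics(model, np.zeros(5))

    def test_pure_pelvis_translation(self, model, zero_pose_markers):
        q = np.zeros(model.n_coordinates)
        q[model.coordinate_names.index("pelvis_tx")] = 1.0
        moved = forward_kinematics(model, q)
        for label in moved:
            np.testing.assert_allclose(
                moved[label] - zero_pose_markers[label], [1.0, 0, 0], atol=1e-12)

    def test_matches_homogeneous_transform_oracle(self, model, rng):
        for _ in range(10):
            q = random_q(model, rng)
            got = forward_kinematics(model, q)
            want = brute_force_fk(model, q)
            for label in got:
                np.testing.assert_allclose(got[label], want[label], atol=1e-10)

    def test_rigid_body_marker_distances_invariant(self, model, rng):
        base = forward_kinematics(model, np.zeros(model.n_coordinates))
        pairs = [("LASI", "RASI"), ("LASI", "SACR"), ("RTHI", "RKNE"),
                 ("RTIB", "RANK"), ("RHEE", "RTOE"), ("LHEE", "LTOE")]
        for _ in range(5):
            pos = forward_kinematics(model, random_q(model, rng))
            for a, b in pairs:
                assert abs(np.linalg.norm(pos[a] - pos[b])
                           - np.linalg.norm(base[a] - base[b])) < 1e-12

    def test_clinical_sign_conventions(self, model, zero_pose_markers):
        """Positive coordinates move segments in the clinically positive
        direction (flexion forward, adduction medial, dorsiflexion up)."""
        names = model.coordinate_names

        def displaced(coord, deg=20):
            q = np.zeros(model.n_coordinates)
            q[names.index(coord)] = np.radians(deg)
            return forward_kinematics(model, q)

        assert displaced("hip_flexion_r")["RKNE"][0] > zero_pose_markers["RKNE"][0]
        assert displaced("knee_flexion_r")["RANK"][0] < zero_pose_markers["RANK"][0]
        assert displaced("ankle_dorsiflexion_r")["RTOE"][2] > zero_pose_markers["RTOE"][2]
        # adduction moves the foot toward the midline on both sides
        assert displaced("hip_adduction_r")["RANK"][1] > zero_pose_markers["RANK"][1]
        assert displaced("hip_adduction_l")["LANK"][1] < zero_pose_markers["LANK"][1]
        # internal rotation swings the toe medially
        assert displaced("hip_rotation_r")["RTOE"][1] > zero_pose_markers["RTOE"][1]
        assert displaced("hip_rotation_l")["LTOE"][1] < zero_pose_markers["LTOE"][1]


class TestKneeAxisCorrection:
    def test_zero_is_identity(self, model):
        out = apply_knee_axis_correction(model, "right", 0.0)
        np.testing.assert_array_equal(out.segment("tibia_r").joint_axes[0],
                                      model.segment("tibia_r").joint_axes[0])

    def test_inverse_rotations_recover_axis(self, model):
        out = apply_knee_axis_correction(
            apply_knee_axis_correction(model, "right", 15.0), "right", -15.0)
        np.testing.assert_allclose(out.segment("tibia_r").joint_axes[0],
                                   model.segment("tibia_r").joint_axes[0], atol=1e-12)

    @pytest.mark.parametrize("side,angle", [("right", 20.0), ("left", 20.0),
                                            ("right", -35.0)])
    def test_transverse_plane_angle_matches(self, model, side, angle):
        # oracle: explicit rotation matrix + arccos of the transverse projection
        s = side[0]
        out = apply_knee_axis_correction(model, side, angle)
        old = model.segment(f"tibia_{s}").joint_axes[0][:2]
        new = out.segment(f"tibia_{s}").joint_axes[0][:2]
        cosang = np.dot(old, new) / (np.linalg.norm(old) * np.linalg.norm(new))
        assert abs(np.degrees(np.arccos(np.clip(cosang, -1, 1))) - abs(angle)) < 1e-9
        assert abs(np.linalg.norm(out.segment(f"tibia_{s}").joint_axes[0]) - 1) < 1e-12

    def test_other_axes_untouched_and_recorded(self, model):
        out = apply_knee_axis_correction(model, "left", 10.0)
        for seg_name in ("femur_r", "femur_l", "talus_r", "talus_l", "tibia_r"):
            for a, b in zip(out.segment(seg_name).joint_axes,
                            model.segment(seg_name).joint_axes):
                np.testing.assert_array_equal(a, b)
        assert out.knee_axis_correction_deg["left"] == 10.0
        assert model.knee_axis_correction_deg["left"] == 0.0

    def test_out_of_range_angle(self, model):
        with pytest.raises(ValidationError):
            apply_knee_axis_correction(model, "right", 90.0)


class TestScaling:
    def test_self_scaling_identity(self, model, zero_pose_markers, anthropometry):
        scaled, s = scale_model(model, zero_pose_markers, anthropometry)
        np.testing.assert_allclose(s.pelvis_factors, 1.0, atol=1e-9)
        for d in (s.femur_factor, s.tibia_factor, s.foot_factor):
            for v in d.values():
                assert abs(v - 1.0) < 1e-9

    def test_uniformly_enlarged_markers(self, model, zero_pose_markers, anthropometry):
        # oracle: forward kinematics of a uniformly 1.2x enlarged subject
        static = {k: 1.2 * v for k, v in zero_pose_markers.items()}
        anth = replace(anthropometry, leg_length=1.2 * anthropometry.leg_length,
                       ASIS_breadth=1.2 * anthropometry.ASIS_breadth,
                       knee_width=1.2 * anthropometry.knee_width,
                       ankle_width=1.2 * anthropometry.ankle_width)
        _, s = scale_model(model, static, anth)
        for d in (s.femur_factor, s.tibia_factor):
            for v in d.values():
                assert abs(v - 1.2) < 1e-6

    def test_idempotent(self, model, zero_pose_markers, anthropometry):
        static = {k: 1.1 * v for k, v in zero_pose_markers.items()}
        anth = replace(anthropometry, ASIS_breadth=1.1 * anthropometry.ASIS_breadth,
                       knee_width=1.1 * anthropometry.knee_width,
                       ankle_width=1.1 * anthropometry.ankle_width)
        scaled, _ = scale_model(model, static, anth)
        rescaled_pose = forward_kinematics(scaled, np.zeros(scaled.n_coordinates))
        _, s2 = scale_model(scaled, rescaled_pose, anth)
        np.testing.assert_allclose(s2.pelvis_factors, 1.0, atol=1e-9)
        for v in (*s2.femur_factor.values(), *s2.tibia_factor.values()):
            assert abs(v - 1.0) < 1e-9

    def test_degenerate_pelvis_geometry(self, model, zero_pose_markers, anthropometry):
        static = dict(zero_pose_markers)
        static["LASI"] = static["RASI"]          # zero ASIS breadth
        with pytest.raises(GeometryError):
            scale_model(model, static, anthropometry)

    def test_scaled_joint_centres_move(self, model, zero_pose_markers, anthropometry):
        static = {k: 1.2 * v for k, v in zero_pose_markers.items()}
        anth = replace(anthropometry, ASIS_breadth=1.2 * anthropometry.ASIS_breadth,
                       knee_width=1.2 * anthropometry.knee_width,
                       ankle_width=1.2 * anthropometry.ankle_width)
        scaled, _ = scale_model(model, static, anth)
        jc = joint_centres(scaled, np.zeros(scaled.n_coordinates))
        jc0 = joint_centres(model, np.zeros(model.n_coordinates))
        np.testing.assert_allclose(jc["knee_r"] - jc["hip_r"],
                                   1.2 * (jc0["knee_r"] - jc0["hip_r"]), atol=1e-9)


class TestAnthropometry:
    def test_positive_fields_enforced(self):
        with pytest.raises(ValidationError):
            Anthropometry(leg_length=0.8, ASIS_breadth=0.0, knee_width=0.1,
                          ankle_width=0.07)

    def test_derived_from_model(self, model, anthropometry):
        g = GENERIC_GEOMETRY
        assert abs(anthropometry.ASIS_breadth - 2 * g["asis_half_breadth"]) < 1e-12
        assert abs(anthropometry.knee_width - 2 * g["knee_half_width"]) < 1e-9
        assert abs(anthropometry.ankle_width - 2 * g["ankle_half_width"]) < 1e-9


class TestSerialization:
    def test_yaml_roundtrip_lossless(self, model, tmp_path, rng):
        path = tmp_path / "model.yaml"
        save_model(model, path)
        loaded = load_model(path)
        for a, b in zip(model.segments, loaded.segments):
            assert a.name == b.name and a.parent == b.parent
            np.testing.assert_array_equal(a.joint_origin_in_parent,
                                          b.joint_origin_in_parent)
            for ax, bx in zip(a.joint_axes, b.joint_axes):
                np.testing.assert_array_equal(ax, bx)
            for lab in a.local_markers:
                np.testing.assert_array_equal(a.local_markers[lab],
                                              b.local_markers[lab])
        assert loaded.coordinate_bounds == model.coordinate_bounds
        q = random_q(model, rng)
        got, want = forward_kinematics(loaded, q), forward_kinematics(model, q)
        for lab in want:
            np.testing.assert_array_equal(got[lab], want[lab])

    def test_dict_roundtrip(self, model):
        rebuilt = model_from_dict(model_to_dict(model))
        assert rebuilt.all_coordinate_names == model.all_coordinate_names
        assert rebuilt.locked_coordinates == model.locked_coordinates
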