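import numpy as np
import pytest

from tibiamap.core_io import LandmarkSet, VolumeStack
from tibiamap.landmarks import detect
from tibiamap.transforms import (
    RotationSpec,
    Transform3D,
    apply_transform,
    fit_affine_landmarks,
    fit_rigid_landmarks,
    refine_rigid_ssd,
    rotate_volume,
    rotation_sensitivity,
)


def dice(a, b):
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return 2 * (a & b).sum() / (a.sum() + b.sum())


def lm_from_mm(names, pts_mm, spacing=(0.15, 0.15, 0.15)):
    pts = np.asarray(pts_mm, float)
    dz, dy, dx = spacing
    return LandmarkSet(names, pts[:, 0] / dz + 1, pts[:, 1] / dy, pts[:, 2] / dx, spacing)


FIVE_PTS = np.array(
    [
        [0.0, 2.0, 1.0],
        [10.0, 1.5, 4.0],
        [14.0, 0.5, 5.0],
        [25.0, 0.0, 5.0],
        [33.0, 2.0, 7.0],
    ]
)


class TestRotateVolume:
    def test_zero_angle_is_identity(self, phantom):
        vol, _ = phantom
        out = rotate_volume(vol, RotationSpec("axial", 0.0))
        pad = [(out.shape[i] - vol.shape[i]) // 2 for i in range(3)]
        inner = out.voxels[
            pad[0] : pad[0] + vol.shape[0],
            pad[1] : pad[1] + vol.shape[1],
            pad[2] : pad[2] + vol.shape[2],
        ]
        assert np.array_equal(inner, vol.voxels)

    def test_rotation_round_trip_dice(self, phantom):
        vol, _ = phantom
        fwd = rotate_volume(vol, RotationSpec("axial", 10.0))
        back = rotate_volume(fwd, RotationSpec("axial", -10.0))
        # compare bone masks on the common centered grid
        a = vol.voxels > 0
        b = back.voxels > 0
        off = [(b.shape[i] - a.shape[i]) // 2 for i in range(3)]
        b_inner = b[
            off[0] : off[0] + a.shape[0], off[1] : off[1] + a.shape[1], off[2] : off[2] + a.shape[2]
        ]
        assert dice(a, b_inner) >= 0.98

    def test_angle_guard(self):
        with pytest.raises(ValueError, match="45"):
            RotationSpec("axial", 60.0)

    def test_coronal_rotation_keeps_image_numbers(self, pipeline, rotation_results):
        base = pipeline["rps"].image_numbers
        for angle in (-10.0, 10.0):
            assert np.array_equal(rotation_results[("coronal", angle)].image_numbers, base)


class TestRigidFit:
    def test_identity_on_identical_sets(self):
        lm = lm_from_mm(["a", "b", "c", "d", "e"], FIVE_PTS)
        t = fit_rigid_landmarks(lm, lm)
        assert np.allclose(t.matrix, np.eye(4), atol=1e-12)
        assert t.fre_mm == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rotation_translation(self):
        th = np.deg2rad(10.0)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        tvec = np.array([1.0, -2.0, 0.5])
        moved = (R @ FIVE_PTS.T).T + tvec
        fixed = lm_from_mm(list("abcde"), moved)
        moving = lm_from_mm(list("abcde"), FIVE_PTS)
        t = fit_rigid_landmarks(fixed, moving)
        assert np.allclose(t.matrix[:3, :3], R, atol=1e-6)
        assert np.allclose(t.matrix[:3, 3], tvec, atol=1e-6)
        assert t.fre_mm < 1e-6

    def test_fre_equals_bruteforce_residual_rms(self):
        rng = np.random.default_rng(0)
        noisy = FIVE_PTS + rng.normal(0, 0.3, FIVE_PTS.shape)
        fixed = lm_from_mm(list("abcde"), noisy)
        moving = lm_from_mm(list("abcde"), FIVE_PTS)
        t = fit_rigid_landmarks(fixed, moving)
        res = np.linalg.norm(t.apply_points(moving.mm) - fixed.mm, axis=1)
        assert t.fre_mm == pytest.approx(np.sqrt(np.mean(res**2)), abs=1e-12)

    def test_invariant_to_correspondence_order(self):
        rng = np.random.default_rng(1)
        noisy = FIVE_PTS + rng.normal(0, 0.2, FIVE_PTS.shape)
        fixed = lm_from_mm(list("abcde"), noisy)
        moving = lm_from_mm(list("abcde"), FIVE_PTS)
        t1 = fit_rigid_landmarks(fixed, moving)
        order = ["d", "a", "e", "b", "c"]
        t2 = fit_rigid_landmarks(fixed.subset(order), moving.subset(order))
        assert np.allclose(t1.matrix, t2.matrix, atol=1e-10)

    def test_collinear_points_raise(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]])
        lm = lm_from_mm(list("abc"), pts)
        with pytest.raises(ValueError, match="collinear"):
            fit_rigid_landmarks(lm, lm)

    def test_reflection_guard_keeps_proper_rotation(self):
        mirrored = FIVE_PTS * np.array([1, 1, -1.0]) + np.array([0, 0, 10.0])
        t = fit_rigid_landmarks(
            lm_from_mm(list("abcde"), mirrored), lm_from_mm(list("abcde"), FIVE_PTS)
        )
        assert np.linalg.det(t.matrix[:3, :3]) == pytest.approx(1.0)


class TestAffineFit:
    def test_identity_case(self):
        pts = np.vstack([FIVE_PTS, [[5.0, 7.0, 2.0]]])
        lm = lm_from_mm(list("abcdef"), pts)
        t = fit_affine_landmarks(lm, lm)
        assert np.allclose(t.matrix, np.eye(4), atol=1e-9)
        assert t.fre_mm == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_shear_and_scale(self):
        A = np.array([[1.1, 0.2, 0.0], [0.0, 0.9, 0.1], [0.05, 0.0, 1.2]])
        b = np.array([0.5, -1.0, 2.0])
        pts = np.vstack([FIVE_PTS, [[5.0, 7.0, 2.0]]])
        moved = (A @ pts.T).T + b
        t = fit_affine_landmarks(lm_from_mm(list("abcdef"), moved), lm_from_mm(list("abcdef"), pts))
        assert np.allclose(t.matrix[:3, :3], A, atol=1e-6)
        assert np.allclose(t.matrix[:3, 3], b, atol=1e-6)

    def test_coplanar_set_raises_with_advice(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 0, 1], [1, 0, 1.0]])
        lm = lm_from_mm(list("abcd"), pts)
        with pytest.raises(ValueError, match="coplanar"):
            fit_affine_landmarks(lm, lm)


class TestApplyTransform:
    def test_identity_is_voxel_exact(self, phantom):
        vol, _ = phantom
        out = apply_transform(vol, Transform3D.identity())
        assert np.array_equal(out.voxels, vol.voxels)

    def test_transform_then_inverse_dice(self, phantom):
        vol, _ = phantom
        th = np.deg2rad(8.0)
        mat = np.eye(4)
        mat[:3, :3] = np.array(
            [[np.cos(th), 0, -np.sin(th)], [0, 1, 0], [np.sin(th), 0, np.cos(th)]]
        )
        mat[:3, 3] = [1.0, 0.5, -0.7]
        # rotate about the volume center to keep content inside the grid
        c = np.array(vol.shape) * np.array(vol.spacing) / 2
        mat[:3, 3] += c - mat[:3, :3] @ c
        t = Transform3D("rigid", mat)
        fwd = apply_transform(vol, t)
        back = apply_transform(fwd, t.inverse())
        assert dice(vol.voxels > 0, back.voxels > 0) >= 0.98

    def test_singular_transform_raises(self, phantom):
        vol, _ = phantom
        mat = np.eye(4)
        mat[0, 0] = 0.0
        with pytest.raises(ValueError, match="singular"):
            apply_transform(vol, Transform3D("affine", mat))


class TestRotationSensitivity:
    def test_zero_angle_row_has_zero_deltas(self, phantom):
        vol, _ = phantom
        df = rotation_sensitivity(vol, angles=(0.0,), planes=("axial",))
        assert np.allclose(df[["rp2_delta", "rp3_delta", "rp4_delta"]].to_numpy(), 0.0)

    def test_sagittal_changes_exceed_axial(self, pipeline, rotation_results):
        base = pipeline["rps"].relative
        def max_delta(plane):
            return max(
                np.max(np.abs(rotation_results[(plane, a)].relative[1:4] - base[1:4]))
                for a in (-10.0, 10.0)
            )
        assert max_delta("sagittal") > max_delta("axial")


class TestRegistrationRoundTrip:
    def test_relative_positions_restored(self, registration_roundtrip):
        r0 = registration_roundtrip["baseline"]
        back = detect(registration_roundtrip["back"])
        assert np.max(np.abs(back.relative - r0.relative)) <= 1.5


class TestSSDRefinement:
    @staticmethod
    def blob_volume(offset=0):
        vox = np.zeros((48, 48, 48), dtype=np.uint8)
        vox[14 + offset : 30 + offset, 10:38, 12:36] = 1
        vox[20 + offset : 26 + offset, 18:30, 18:30] = 2
        return VolumeStack(vox, (0.2, 0.2, 0.2))

    def test_identity_input_stays_identity(self):
        v = self.blob_volume()
        t = refine_rigid_ssd(v, v, levels=(2,), maxiter=30)
        out = apply_transform(v, t, reference=v)
        assert dice(v.voxels > 0, out.voxels > 0) >= 0.999

    def test_two_voxel_offset_recovered(self):
        fixed = self.blob_volume(0)
        moving = self.blob_volume(2)  # shifted 2 voxels along z
        t = refine_rigid_ssd(fixed, moving, levels=(2, 1), maxiter=150)
        # translation recovered within half a voxel (0.1 mm)
        assert abs(t.matrix[0, 3] + 2 * 0.2) <= 0.1

    def test_ssd_never_worse_than_init(self):
        fixed = self.blob_volume(0)
        moving = self.blob_volume(3)
        init = Transform3D.identity()
        t = refine_rigid_ssd(fixed, moving, init=init, levels=(2, 1), maxiter=60)

        def ssd(tr):
            out = apply_transform(moving, tr, reference=fixed)
            return np.mean((fixed.voxels.astype(float) - out.voxels.astype(float)) ** 2)

        assert ssd(t) <= ssd(init) + 1e-12
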