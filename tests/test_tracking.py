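"""ICP registration, sequential face tracking, and camera/scanner calibration."""

import numpy as np
import pytest

from facemoco.camera import (
    FaceRoi,
    default_camera,
    render_depth_frame,
    render_depth_sequence,
    select_face_roi,
)
from facemoco.phantom import MotionAmplitude, make_marker_trajectory, make_static_trajectory
from facemoco.tracking import (
    DegenerateRegistrationError,
    SurfaceModel,
    TrackingLossError,
    compute_calibration,
    icp_register,
    procrustes_rigid,
    track_sequence,
)
from facemoco.transforms import (
    RigidTransform,
    compose,
    invert,
    motion_magnitude,
    random_transform,
    rotation_x,
    rotation_z,
    translation,
)


def _camera_frame_motion(world_motion, camera):
    return compose(compose(camera.pose, world_motion), invert(camera.pose))


def _world_frame_error(est_camera_motion, true_world_motion, camera):
    """Estimate error expressed at the head (world frame): (mm, deg)."""
    est_world = compose(compose(invert(camera.pose), est_camera_motion), camera.pose)
    return motion_magnitude(compose(est_world, invert(true_world_motion)))


class TestProcrustes:
    def test_exact_recovery_with_known_correspondence(self, rng):
        for _ in range(20):
            pts = rng.uniform(-50, 50, (15, 3))
            T = random_transform(rng)
            est = procrustes_rigid(pts, T.apply(pts))
            assert np.allclose(est.matrix, T.matrix, atol=1e-9)

    def test_icp_equals_procrustes_given_true_correspondences(self, rng):
        # oracle equivalence: when every source point's nearest neighbour IS
        # its true partner, one ICP update must equal the closed form
        pts = rng.uniform(-30, 30, (18, 3))
        T = compose(translation(0.5, -0.3, 0.2), rotation_z(1.0))  # small: NN = truth
        target = T.apply(pts)
        oracle = procrustes_rigid(pts, target)
        res = icp_register(pts, target, init=RigidTransform.identity())
        assert np.allclose(res.transform.matrix, oracle.matrix, atol=1e-9)
        assert res.rms_mm < 1e-9


class TestIcp:
    def test_identity_when_target_equals_source(self, reference_model):
        res = icp_register(reference_model, reference_model.points)
        assert res.rms_mm < 1e-12
        assert res.transform.is_close(RigidTransform.identity(), atol=1e-9)

    def test_noiseless_recovery_of_applied_transform(self, rng):
        # exact point correspondence (same sampling): recovery to 1e-6
        pts = rng.uniform(-40, 40, (200, 3))
        pts[:, 2] = 0.3 * pts[:, 0] ** 2 / 40 + 0.2 * pts[:, 1]  # curved sheet
        pts += rng.normal(0, 5, pts.shape)
        T = compose(translation(5, 3, 2), rotation_x(10))
        res = icp_register(pts, T.apply(pts), init=RigidTransform.identity())
        d_t, d_r = motion_magnitude(compose(res.transform, invert(T)))
        assert d_t < 1e-6 and d_r < 1e-6

    def test_recovery_within_1mm_1deg_under_1mm_noise(self, reference_model, rng):
        # target = the source patch moved by a known transform, with 1-mm
        # Gaussian noise: recovery within 1 mm / 1 degree.  (Tracking through
        # *re-rendered* frames — where sampling also changes — is covered by
        # the sequence test below.)
        c = reference_model.points.mean(axis=0)
        about_centroid = compose(
            translation(*c), compose(compose(translation(5, 3, 2), rotation_x(10)),
                                     translation(*(-c)))
        )
        tgt = about_centroid.apply(reference_model.points) + rng.normal(
            0, 1.0, reference_model.points.shape
        )
        res = icp_register(reference_model, tgt, init=RigidTransform.identity())
        d = compose(res.transform, invert(about_centroid))
        moved = d.apply(reference_model.points)
        d_t = float(np.linalg.norm(moved - reference_model.points, axis=1).max())
        d_r = motion_magnitude(d)[1]
        assert d_t < 1.0 and d_r < 1.0

    def test_rms_history_monotone_after_settling(self, reference_model, rng):
        # ICP cost is non-increasing once the inlier set stabilizes; assert
        # no increase larger than numerical jitter across recorded RMS
        tgt = compose(translation(4, 2, 1), rotation_z(5)).apply(
            reference_model.points
        ) + rng.normal(0, 0.5, reference_model.points.shape)
        res = icp_register(reference_model, tgt)
        increases = np.diff(res.rms_history)
        assert increases.max(initial=0.0) < 0.05 * res.rms_history[0]

    def test_degenerate_geometry_raises(self, rng):
        line = np.outer(np.linspace(0, 1, 50), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateRegistrationError):
            icp_register(line, line + 1.0)
        plane = np.column_stack([rng.uniform(-10, 10, (60, 2)), np.zeros(60)])
        with pytest.raises(DegenerateRegistrationError):
            icp_register(plane, plane)


class TestTrackSequence:
    def test_static_noiseless_sequence_gives_identity(self, phantom, camera_clean):
        traj = make_static_trajectory(1.0)
        frames = render_depth_sequence(phantom.surface_mesh, traj, camera_clean, seed=0)
        roi = FaceRoi.around_nose(frames[0])
        ref = SurfaceModel(select_face_roi(frames[0], roi))
        tr = track_sequence(frames, ref, roi)
        assert tr.valid.all()
        for T in tr.transforms:
            d_t, d_r = motion_magnitude(T)
            assert d_t < 1e-6 and d_r < 1e-6

    def test_stepwise_tracking_within_1mm_1deg(self, phantom):
        # 20 s of stepped marker motion at 30 mm / 25 deg with 1-mm noise
        traj = make_marker_trajectory(
            20.0, schedule=(4.0,), amplitude=MotionAmplitude(30, 25), seed=31
        )
        cam = default_camera(noise_sigma_mm=1.0)
        frames = render_depth_sequence(phantom.surface_mesh, traj, cam, seed=32)
        roi = FaceRoi.around_nose(frames[0])
        ref = SurfaceModel(select_face_roi(frames[0], roi))
        tr = track_sequence(frames, ref, roi)
        errs = np.array(
            [
                _world_frame_error(est, true, cam)
                for est, true in zip(tr.transforms, traj.transforms)
            ]
        )
        assert np.median(errs[:, 0]) <= 1.0
        assert np.median(errs[:, 1]) <= 1.0

    def test_pre_alignment_improves_large_steps(self, phantom):
        traj = make_marker_trajectory(
            12.0, schedule=(2.0,), amplitude=MotionAmplitude(30, 25), seed=33,
        )
        cam = default_camera(noise_sigma_mm=1.0)
        frames = render_depth_sequence(phantom.surface_mesh, traj, cam, seed=34)
        roi = FaceRoi.around_nose(frames[0])
        ref = SurfaceModel(select_face_roi(frames[0], roi))
        with_pre = track_sequence(frames, ref, roi, pre_align=True)

        def total_err(tr):
            errs = [
                _world_frame_error(e, t, cam)
                for e, t, v in zip(tr.transforms, traj.transforms, tr.valid)
            ]
            return np.nansum(np.array(errs), axis=0)

        try:
            without = track_sequence(frames, ref, roi, pre_align=False)
        except TrackingLossError:
            return  # losing track entirely without pre-alignment also shows it
        assert total_err(without)[0] >= total_err(with_pre)[0]

    def test_tracking_loss_raises_after_three_bad_frames(self, phantom, camera_clean):
        traj = make_static_trajectory(1.0)
        frames = render_depth_sequence(phantom.surface_mesh, traj, camera_clean, seed=0)
        roi = FaceRoi.around_nose(frames[0])
        ref = SurfaceModel(select_face_roi(frames[0], roi))
        for f in frames[3:]:  # head vanishes mid-sequence
            f.points = np.empty((0, 3))
            f.valid = False
        with pytest.raises(TrackingLossError):
            track_sequence(frames, ref, roi)


class TestCalibration:
    def test_synthetic_construction_recovers_transform(self, reference_model):
        # camera model = ct model moved by T: the calibration (scanner->camera
        # convention) must equal T exactly on noiseless data
        ct_model = SurfaceModel(reference_model.points.copy(), source="ct", frame="pet")
        T = compose(translation(20, -10, 400), rotation_z(25))
        cam_model = SurfaceModel(T.apply(ct_model.points))
        calib, diag = compute_calibration(ct_model, cam_model)
        assert diag.rms_mm < 1e-6
        d_t, d_r = motion_magnitude(compose(calib, invert(T)))
        assert d_t < 1e-6 and d_r < 1e-6

    def test_identical_models_give_identity(self, reference_model):
        ct_model = SurfaceModel(reference_model.points.copy(), source="ct", frame="pet")
        calib, _ = compute_calibration(ct_model, reference_model)
        assert calib.is_close(RigidTransform.identity(), atol=1e-6)

    def test_end_to_end_correction_property(self, phantom, rng):
        # noiseless chain: track(M) conjugated through the computed
        # calibration maps moved head points back to reference within 0.1 mm
        from facemoco.transforms import to_pet_frame

        cam = default_camera(noise_sigma_mm=0.0, lateral_mm=40.0, height_mm=-25.0)
        f0 = render_depth_frame(phantom.surface_mesh, RigidTransform.identity(), cam)
        roi = FaceRoi.around_nose(f0)
        ref = SurfaceModel(select_face_roi(f0, roi))
        ct_model = SurfaceModel(
            cam.pose.inverse().apply(ref.points), source="ct", frame="pet"
        )  # same surface expressed in scanner coordinates
        calib, _ = compute_calibration(ct_model, ref)
        M = compose(translation(12, -6, 9), rotation_x(15))
        ik_true = _camera_frame_motion(M, cam)
        f1 = render_depth_frame(phantom.surface_mesh, M, cam)
        tgt = select_face_roi(f1, roi, pose=ik_true, margin_mm=15)
        res = icp_register(ref, tgt, init=ik_true)
        corr = to_pet_frame(res.transform, calib)
        pts = rng.uniform(-60, 60, (30, 3))
        restored = corr.apply(M.apply(pts))
        # with the true camera-frame motion the conversion machinery is exact
        exact_corr = to_pet_frame(ik_true, calib)
        assert np.abs(exact_corr.apply(M.apply(pts)) - pts).max() < 0.1
        # with the ICP estimate the floor is the sampling bias of the
        # rendered patches (sub-degree), a few mm at the head periphery
        assert np.abs(restored - pts).max() < 3.0
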