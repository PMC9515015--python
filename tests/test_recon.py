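"""Siddon projector, list-mode MLEM/OSEM, and the Gaussian post-filter."""

import numpy as np
import pytest

import facemoco as fm
from facemoco.listmode import ScannerModel, simulate_listmode
from facemoco.phantom import make_static_trajectory
from facemoco.recon import (
    ReconConfig,
    backproject_ray,
    compute_sensitivity,
    gaussian_postfilter,
    reconstruct,
    siddon_line_integral,
)
from facemoco.volume import ImageVolume, centered_origin


class TestSiddon:
    def test_axis_aligned_ray_closed_form(self):
        # 10 unit-valued voxels of 2 mm along the ray: path length 20 mm
        vol = ImageVolume(np.ones((10, 4, 4)), 2.0, (0.0, 0.0, 0.0))
        assert siddon_line_integral(vol, (-50, 2, 2), (50, 2, 2)) == pytest.approx(20.0)

    def test_ray_outside_grid_is_zero(self):
        vol = ImageVolume(np.ones((10, 4, 4)), 2.0, (0.0, 0.0, 0.0))
        assert siddon_line_integral(vol, (-50, 200, 0), (50, 200, 0)) == 0.0

    def test_oblique_ray_diagonal_length(self):
        # body diagonal of a uniform cube: integral = diagonal length inside
        n, vox = 12, 2.0
        origin = centered_origin((n, n, n), (vox,) * 3)
        vol = ImageVolume(np.ones((n, n, n)), vox, origin)
        half = n * vox / 2
        p = np.array([half, half, half]) * 3  # far outside, on the diagonal
        got = siddon_line_integral(vol, -p, p)
        assert got == pytest.approx(2 * half * np.sqrt(3), rel=1e-9)

    def test_adjointness(self, rng):
        # <A x, y> == <x, A^T y> to 1e-9 over random volumes and rays
        vol = ImageVolume(rng.random((12, 11, 13)), 1.7, (-9.0, -8.0, -10.0))
        zero = vol.copy_with(np.zeros_like(vol.values))
        for _ in range(100):
            p1 = rng.uniform(-40, 40, 3)
            p2 = rng.uniform(-40, 40, 3)
            y = float(rng.random())
            lhs = siddon_line_integral(vol, p1, p2) * y
            aty = backproject_ray(zero, p1, p2, y)
            rhs = float((vol.values * aty.values).sum())
            assert lhs == pytest.approx(rhs, abs=1e-9 * max(1.0, abs(lhs)))

    def test_coincident_endpoints_rejected(self):
        vol = ImageVolume(np.ones((4, 4, 4)), 2.0, (0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            siddon_line_integral(vol, (1, 1, 1), (1, 1, 1))


@pytest.fixture(scope="module")
def static_events(phantom):
    sc = ScannerModel()
    ev, _ = simulate_listmode(
        phantom.activity, make_static_trajectory(60.0), sc, 400_000, seed=42
    )
    return sc, ev


class TestMlem:
    def test_nrmse_decreases_over_iterations(self, phantom, static_events):
        sc, ev = static_events
        truth = phantom.activity.resample_like(
            ReconConfig(grid_shape=(48,) * 3, voxel_mm=4.0).empty_volume(), order=1
        )
        errs = []
        for iters in (1, 2, 4):
            cfg = ReconConfig(
                n_iterations=iters, n_subsets=1, voxel_mm=4.0,
                grid_shape=(48,) * 3, motion_correction=False,
            )
            vol, _ = reconstruct(ev, cfg, scanner=sc)
            sm = gaussian_postfilter(vol, 4.0)
            from facemoco.evaluate import nrmse

            errs.append(nrmse(sm, truth))
        # EM converges towards the truth while bias dominates; at higher
        # iteration counts Poisson noise takes over (bias-variance turn),
        # so monotonicity is asserted on the early, bias-dominated passes
        assert all(b < a for a, b in zip(errs, errs[1:])), errs

    def test_sensitivity_weighted_total_equals_used_events(self, static_events):
        # MLEM fixed point: after each full update the sensitivity-weighted
        # activity equals the number of events with nonzero projection
        sc, ev = static_events
        cfg = ReconConfig(
            n_iterations=3, n_subsets=1, voxel_mm=4.0, grid_shape=(48,) * 3,
            motion_correction=False,
        )
        vol, meta = reconstruct(ev, cfg, scanner=sc)
        expected = len(ev) - meta["n_skipped_projections"] / cfg.n_iterations
        assert meta["sensitivity_weighted_total"] == pytest.approx(
            expected, rel=1e-6
        )

    def test_nonnegativity_and_metadata(self, static_events):
        sc, ev = static_events
        cfg = ReconConfig(
            n_iterations=1, n_subsets=4, voxel_mm=4.0, grid_shape=(48,) * 3,
            motion_correction=False,
        )
        vol, meta = reconstruct(ev, cfg, scanner=sc)
        assert np.all(vol.values >= 0)
        assert meta["n_events"] == len(ev)
        assert meta["n_subsets"] == 4

    def test_moco_requires_tracking_and_calibration(self, static_events):
        sc, ev = static_events
        cfg = ReconConfig(grid_shape=(32,) * 3, voxel_mm=6.0, motion_correction=True)
        with pytest.raises(ValueError, match="tracking and calibration"):
            reconstruct(ev, cfg, scanner=sc)

    def test_uniform_cylinder_reconstructs_uniform(self):
        # uniformity of a uniform cylinder at the package's operating point
        # (few EM passes + post-filter); unregularized EM at high iteration
        # counts amplifies Poisson noise far beyond this
        sc = ScannerModel()
        shape, vox = (48,) * 3, 4.0
        grid = ImageVolume(np.zeros(shape), vox, centered_origin(shape, (vox,) * 3))
        pts = grid.voxel_center_grid()
        r2 = pts[..., 0] ** 2 + pts[..., 1] ** 2
        act = ((r2 < 70.0**2) & (np.abs(pts[..., 2]) < 70)).astype(float)
        ev, _ = simulate_listmode(
            grid.copy_with(act), make_static_trajectory(60.0), sc, 1_000_000, seed=9
        )
        cfg = ReconConfig(
            n_iterations=2, n_subsets=1, voxel_mm=vox, grid_shape=shape,
            motion_correction=False,
        )
        vol, _ = reconstruct(ev, cfg, scanner=sc)
        sm = gaussian_postfilter(vol, 4.0)
        central = (r2 < 50.0**2) & (np.abs(pts[..., 2]) < 50)
        v = sm.values[central]
        assert v.std() / v.mean() < 0.12

    def test_correction_with_truth_beats_uncorrected(self, phantom):
        # moving phantom: correcting with the true motion must reproduce the
        # static reconstruction better than not correcting
        sc = ScannerModel()
        traj = fm.make_marker_trajectory(
            30.0, schedule=(6.0,), amplitude=fm.MotionAmplitude(25, 20), seed=13,
            jitter_mm=0.0, jitter_deg=0.0,
        )
        n = 400_000
        moved, _ = simulate_listmode(phantom.activity, traj, sc, n, seed=14)
        static, _ = simulate_listmode(
            phantom.activity, make_static_trajectory(30.0), sc, n, seed=15
        )
        cfg = lambda mc: ReconConfig(
            n_iterations=2, n_subsets=8, voxel_mm=4.0, grid_shape=(48,) * 3,
            motion_correction=mc,
        )
        from facemoco.evaluate import nrmse
        from facemoco.transforms import RigidTransform

        cor, _ = reconstruct(
            moved, cfg(True), tracking=traj, calib=RigidTransform.identity(),
            scanner=sc,
        )
        unc, _ = reconstruct(moved, cfg(False), scanner=sc)
        sta, _ = reconstruct(static, cfg(False), scanner=sc)
        cor, unc, sta = (gaussian_postfilter(v, 4.0) for v in (cor, unc, sta))
        assert nrmse(cor, sta) < nrmse(unc, sta)


class TestGaussianPostfilter:
    def test_sigma_conversion(self):
        # FWHM 4 mm -> sigma = 1.6986 mm
        from facemoco.recon import FWHM_TO_SIGMA

        assert 4.0 * FWHM_TO_SIGMA == pytest.approx(1.6986, abs=1e-4)

    def test_zero_fwhm_is_identity(self, rng):
        vol = ImageVolume(rng.random((10, 10, 10)), 2.0, (0, 0, 0))
        out = gaussian_postfilter(vol, 0.0)
        assert np.array_equal(out.values, vol.values)

    def test_sum_preserved(self, rng):
        vol = ImageVolume(rng.random((20, 18, 22)), 2.0, (0, 0, 0))
        out = gaussian_postfilter(vol, 4.0)
        assert out.values.sum() == pytest.approx(vol.values.sum(), rel=1e-6)

    def test_impulse_fwhm(self):
        shape = (41, 41, 41)
        vol = ImageVolume(np.zeros(shape), 1.0, centered_origin(shape, (1.0,) * 3))
        vol.values[20, 20, 20] = 1.0
        out = gaussian_postfilter(vol, 4.0)
        prof = out.values[:, 20, 20]
        half = prof.max() / 2
        above = np.flatnonzero(prof >= half)
        width = above[-1] - above[0] + 1  # voxel-quantized FWHM
        assert abs(width * 1.0 - 4.0) <= 1.0  # within a voxel


def test_sensitivity_positive_inside_fov():
    sc = ScannerModel()
    cfg = ReconConfig(grid_shape=(32,) * 3, voxel_mm=6.0, n_sensitivity_chords=100_000)
    grid = cfg.empty_volume()
    sens = compute_sensitivity(sc, grid, cfg)
    pts = grid.voxel_center_grid()
    inside = (np.hypot(pts[..., 0], pts[..., 1]) < 100) & (np.abs(pts[..., 2]) < 80)
    assert np.all(sens[inside] > 0)
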