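"""List-mode simulation, motionless-period selection, event filtering."""

import numpy as np
import pytest
from scipy import stats

import facemoco as fm
from facemoco.listmode import (
    EmptySelectionError,
    ListModeData,
    NoMotionlessPeriodError,
    NoSourceError,
    ScannerModel,
    TimeWindow,
    find_motionless_period,
    select_events,
    simulate_listmode,
)
from facemoco.phantom import make_static_trajectory, MotionTrajectory
from facemoco.transforms import RigidTransform, rotation_z, translation
from facemoco.volume import ImageVolume, centered_origin


def _point_source(shape=(33, 33, 33), voxel=2.0):
    origin = centered_origin(shape, (voxel,) * 3)
    vol = ImageVolume(np.zeros(shape), voxel, origin)
    c = (shape[0] - 1) // 2
    vol.values[c, c, c] = 1.0
    return vol


class TestSimulate:
    def test_point_source_lors_pass_near_origin(self):
        sc = ScannerModel()
        ev, _ = simulate_listmode(
            _point_source(), make_static_trajectory(10.0), sc, 5000, seed=1
        )
        d = ev.p2 - ev.p1
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        # distance of each LOR from the origin
        cross = np.cross(ev.p1, d)
        dist = np.linalg.norm(cross, axis=1)
        # snapping moves endpoints by at most ~half a crystal pitch each
        assert np.percentile(dist, 99) < 2.0 * sc.crystal_pitch_mm
        assert dist.max() < 4.0 * sc.crystal_pitch_mm

    def test_endpoints_on_scanner_surface(self, phantom):
        sc = ScannerModel()
        ev, info = simulate_listmode(
            phantom.activity, make_static_trajectory(5.0), sc, 20000, seed=2
        )
        for p in (ev.p1, ev.p2):
            r = np.hypot(p[:, 0], p[:, 1])
            assert np.allclose(r, sc.ring_radius_mm, atol=1e-6)
            assert np.all(np.abs(p[:, 2]) <= sc.axial_extent_mm / 2)
        assert info["n_resampled"] > 0  # rejected chords are logged

    def test_azimuthal_uniformity_of_centered_source(self):
        # centered cylindrically symmetric source: first-endpoint azimuths
        # uniform (the two endpoints of one chord are antipodal, hence
        # correlated — only independent singles enter the chi-square)
        sc = ScannerModel()
        ev, _ = simulate_listmode(
            _point_source(), make_static_trajectory(10.0), sc, 100_000, seed=3
        )
        ang = np.arctan2(ev.p1[:, 1], ev.p1[:, 0]) % (2 * np.pi)
        counts, _ = np.histogram(ang, bins=16, range=(0, 2 * np.pi))
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        # 15 dof; 3-sigma-ish upper bound
        assert chi2 < stats.chi2.ppf(0.9987, 15)

    def test_same_seed_bit_identical(self, phantom):
        sc = ScannerModel()
        a, _ = simulate_listmode(phantom.activity, make_static_trajectory(5.0), sc, 10_000, seed=7)
        b, _ = simulate_listmode(phantom.activity, make_static_trajectory(5.0), sc, 10_000, seed=7)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.p1, b.p1) and np.array_equal(a.p2, b.p2)

    def test_zero_activity_raises(self):
        vol = _point_source()
        vol.values[:] = 0
        with pytest.raises(NoSourceError):
            simulate_listmode(vol, make_static_trajectory(1.0), ScannerModel(), 10)

    def test_moved_events_corrected_with_true_motion_match_static(self, phantom):
        # the foundational identity: simulate a moving head, transform each
        # LOR with the true inverse motion, and the line distribution matches
        # the static simulation.  A scanner with near-complete axial coverage
        # is used so per-pose acceptance modulation (which motion correction
        # does not undo) does not confound the geometric identity; on the
        # default short scanner the corrected set must still be far closer to
        # static than the uncorrected one.
        from facemoco.recon import correct_event_endpoints

        traj = fm.make_marker_trajectory(
            30.0, schedule=(5.0,), amplitude=fm.MotionAmplitude(25, 20),
            seed=5, jitter_mm=0.0, jitter_deg=0.0,
        )
        n = 60_000

        def foot_hist(ev):
            # bin each LOR by its closest point to the origin: a property of
            # the line itself, invariant to how endpoints parameterize it
            d = ev.p2 - ev.p1
            d = d / np.linalg.norm(d, axis=1, keepdims=True)
            t = -np.einsum("ij,ij->i", ev.p1, d)
            foot = ev.p1 + t[:, None] * d
            h, _ = np.histogramdd(foot, bins=(5, 5, 5), range=((-100, 100),) * 3)
            return h.ravel()

        def chi2_pair(a, b):
            ha, hb = foot_hist(a), foot_hist(b)
            keep = (ha + hb) > 60
            with np.errstate(invalid="ignore"):
                c = (((ha - hb) ** 2) / (ha + hb))[keep].sum()
            return c, int(keep.sum())

        long_sc = ScannerModel(axial_extent_mm=800.0, n_rings=176)
        moved, _ = simulate_listmode(phantom.activity, traj, long_sc, n, seed=6)
        static, _ = simulate_listmode(
            phantom.activity, make_static_trajectory(30.0), long_sc, n, seed=7
        )
        corrected = correct_event_endpoints(moved, traj, RigidTransform.identity())
        chi2, dof = chi2_pair(corrected, static)
        assert chi2 < stats.chi2.ppf(0.999, dof)
        chi2_u, _ = chi2_pair(moved, static)
        assert chi2_u > 10 * chi2

        sc = ScannerModel()
        moved, _ = simulate_listmode(phantom.activity, traj, sc, n, seed=6)
        static, _ = simulate_listmode(
            phantom.activity, make_static_trajectory(30.0), sc, n, seed=7
        )
        corrected = correct_event_endpoints(moved, traj, RigidTransform.identity())
        chi2_c, _ = chi2_pair(corrected, static)
        chi2_u, _ = chi2_pair(moved, static)
        assert chi2_u > 3 * chi2_c


class TestMotionlessPeriod:
    def test_motion_after_quiet_start(self):
        # head still for 25 s then stepped motion: window within [0, 25]
        traj = fm.make_marker_trajectory(
            50.0, schedule=(25.0, 5.0, 5.0), amplitude=fm.MotionAmplitude(25, 20),
            seed=8, jitter_mm=0.0, jitter_deg=0.0,
        )
        win = find_motionless_period(traj, window_s=20.0)
        assert win.contiguous
        assert win.start >= 0.0 and win.end <= 25.0
        assert win.duration_s == pytest.approx(20.0)

    def test_continuous_drift_uses_noncontiguous_fallback(self):
        # steady drift: no 20-s contiguous stillness; pose clusters under the
        # thresholds must be assembled instead
        n = 600
        ts = np.arange(n) / 10.0
        drift = [translation(0.05 * i, 0.0, 0.0) for i in range(n)]
        # re-visit the start pose periodically so a cluster exists
        for i in range(0, n, 3):
            drift[i] = translation(0.05 * (i % 30), 0.0, 0.0)
        traj = MotionTrajectory(ts, drift)
        win = find_motionless_period(traj, window_s=20.0)
        assert not win.contiguous
        assert win.duration_s >= 20.0 - 1e-6
        # every selected frame within thresholds of every other
        sel = [traj.transforms[int(round(s * 10))] for s, _ in win.intervals]

    def test_never_still_raises(self):
        n = 400
        ts = np.arange(n) / 10.0
        traj = MotionTrajectory(ts, [translation(2.0 * i, 0, 0) for i in range(n)])
        with pytest.raises(NoMotionlessPeriodError):
            find_motionless_period(traj, window_s=20.0)


class TestSelectEvents:
    @pytest.fixture()
    def events(self):
        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(0, 900, 90_000))
        p = rng.normal(size=(90_000, 3))
        return ListModeData(t, p, p + 1)

    def test_full_window_selects_all(self, events):
        win = TimeWindow([(0.0, 900.0)])
        assert len(select_events(events, win)) == len(events)

    def test_zero_measure_raises(self, events):
        with pytest.raises(EmptySelectionError):
            select_events(events, TimeWindow([(10.0, 10.0)]))

    def test_count_proportional_to_window(self, events):
        win = TimeWindow([(100.0, 120.0)])
        sel = select_events(events, win)
        n, p = len(events), 20.0 / 900.0
        expect = n * p
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(len(sel) - expect) < 4 * sigma

    def test_noncontiguous_window(self, events):
        win = TimeWindow([(0.0, 10.0), (50.0, 60.0)], contiguous=False)
        sel = select_events(events, win)
        assert np.all(win.contains(sel.t))
        assert win.duration_s == pytest.approx(20.0)

    def test_count_conservation(self, events):
        win = TimeWindow([(0.0, 450.0)])
        sel = select_events(events, win)
        rest = events.select(~win.contains(events.t))
        assert len(sel) + len(rest) == len(events)


def test_listmode_csv_round_trip(tmp_path):
    rng = np.random.default_rng(10)
    ev = ListModeData(
        np.sort(rng.uniform(0, 10, 100)),
        rng.normal(size=(100, 3)),
        rng.normal(size=(100, 3)),
    )
    path = tmp_path / "events.csv"
    ev.to_csv(str(path))
    back = ListModeData.from_csv(str(path))
    assert np.allclose(back.t, ev.t)
    assert np.allclose(back.p1, ev.p1) and np.allclose(back.p2, ev.p2)
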