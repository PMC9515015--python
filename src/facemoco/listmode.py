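"""Cylindrical PET scanner model, list-mode coincidence simulation, and
motionless-period selection.

Events are generated one emission at a time: the emission point is drawn
proportional to the activity volume, moved by the head pose active at the
event time (camera and scanner share the 10-fps clock), a direction is
drawn isotropically, and the chord's two intersections with the detector
cylinder are snapped to the nearest crystals.  Chords that miss the axial
extent are redrawn (count logged).  No scatter/randoms/dead-time; optional
attenuation thinning and intrinsic-resolution blur.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .phantom import MotionTrajectory
from .tracking import TrackingResult
from .transforms import RigidTransform
from .volume import ImageVolume

__all__ = [
    "ScannerModel",
    "ListModeData",
    "TimeWindow",
    "NoSourceError",
    "NoMotionlessPeriodError",
    "EmptySelectionError",
    "simulate_listmode",
    "find_motionless_period",
    "select_events",
]


class NoSourceError(ValueError):
    """Activity volume is identically zero."""


class NoMotionlessPeriodError(RuntimeError):
    """No set of frames under the motion thresholds totals the window length."""


class EmptySelectionError(ValueError):
    """Event selection window contains no events."""


@dataclasses.dataclass
class ScannerModel:
    """Cylindrical scanner: ``n_rings`` rings of ``n_crystals_per_ring`` crystals."""

    ring_radius_mm: float = 250.0
    axial_extent_mm: float = 220.0
    n_rings: int = 48
    n_crystals_per_ring: int = 320

    @property
    def ring_pitch_mm(self) -> float:
        return self.axial_extent_mm / self.n_rings

    @property
    def crystal_pitch_mm(self) -> float:
        return 2.0 * np.pi * self.ring_radius_mm / self.n_crystals_per_ring

    def ring_z(self) -> np.ndarray:
        return (
            -self.axial_extent_mm / 2.0
            + (np.arange(self.n_rings) + 0.5) * self.ring_pitch_mm
        )

    def snap(self, pts: np.ndarray) -> np.ndarray:
        """Snap cylinder-surface points to the nearest crystal centers."""
        ring = np.clip(
            np.round(
                (pts[:, 2] + self.axial_extent_mm / 2.0) / self.ring_pitch_mm - 0.5
            ),
            0,
            self.n_rings - 1,
        )
        z = -self.axial_extent_mm / 2.0 + (ring + 0.5) * self.ring_pitch_mm
        ang = np.arctan2(pts[:, 1], pts[:, 0])
        k = np.round(ang / (2.0 * np.pi) * self.n_crystals_per_ring)
        ang_snapped = k * 2.0 * np.pi / self.n_crystals_per_ring
        return np.column_stack(
            [
                self.ring_radius_mm * np.cos(ang_snapped),
                self.ring_radius_mm * np.sin(ang_snapped),
                z,
            ]
        )

    def to_json(self, path: str) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ScannerModel":
        import json

        with open(path) as fh:
            return cls(**json.load(fh))


@dataclasses.dataclass
class ListModeData:
    """Coincidence events: timestamps and the two LOR endpoints (mm)."""

    t: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def select(self, mask: np.ndarray) -> "ListModeData":
        return ListModeData(self.t[mask], self.p1[mask], self.p2[mask])

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            np.column_stack([self.t, self.p1, self.p2]),
            columns=["t", "x1", "y1", "z1", "x2", "y2", "z2"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "ListModeData":
        a = pd.read_csv(path).to_numpy()
        return cls(a[:, 0], a[:, 1:4].copy(), a[:, 4:7].copy())


def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _cylinder_chord(
    pos: np.ndarray, d: np.ndarray, radius: float, half_axial: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Both intersections of lines (pos + t d) with the cylinder; returns
    (e1, e2, ok) where ok marks chords with both endpoints inside the axial
    extent."""
    a = d[:, 0] ** 2 + d[:, 1] ** 2
    b = 2.0 * (pos[:, 0] * d[:, 0] + pos[:, 1] * d[:, 1])
    c = pos[:, 0] ** 2 + pos[:, 1] ** 2 - radius**2
    ok = (a > 1e-12) & (c < 0)
    disc = np.where(ok, b * b - 4 * a * c, 1.0)
    sq = np.sqrt(np.maximum(disc, 0.0))
    t1 = (-b + sq) / (2 * np.maximum(a, 1e-300))
    t2 = (-b - sq) / (2 * np.maximum(a, 1e-300))
    e1 = pos + t1[:, None] * d
    e2 = pos + t2[:, None] * d
    ok &= (np.abs(e1[:, 2]) <= half_axial) & (np.abs(e2[:, 2]) <= half_axial)
    return e1, e2, ok


def simulate_listmode(
    activity: ImageVolume,
    trajectory: MotionTrajectory,
    scanner: ScannerModel,
    n_events: int,
    seed: int = 0,
    attenuation: ImageVolume | None = None,
    blur_fwhm_mm: float = 0.0,
) -> tuple[ListModeData, dict]:
    """Poisson list-mode simulation of a (possibly moving) activity volume.

    Emission voxels are drawn proportional to activity, jittered uniformly
    within the voxel, optionally blurred (``blur_fwhm_mm`` emulates
    intrinsic resolution), moved by the trajectory pose at the event time,
    and paired with an isotropic direction.  Chords missing the cylinder
    are resampled; with ``attenuation`` given, events are thinned by the
    line integral through the moved attenuation map.  Deterministic for a
    fixed seed.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    act = np.asarray(activity.values, dtype=float).ravel()
    total = act.sum()
    if total <= 0:
        raise NoSourceError("activity volume is identically zero")
    cdf = np.cumsum(act) / total
    rng = np.random.default_rng(seed)
    duration = trajectory.duration_s
    times = np.sort(rng.uniform(0.0, duration, n_events))
    frame_idx = trajectory.frame_index(times)
    mats = trajectory.matrices()
    R = mats[:, :3, :3]
    s = mats[:, :3, 3]
    shape = activity.shape
    half_axial = scanner.axial_extent_mm / 2.0
    sigma = blur_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    e1 = np.zeros((n_events, 3))
    e2 = np.zeros((n_events, 3))
    pending = np.arange(n_events)
    n_resampled = 0
    n_attenuated = 0
    while len(pending):
        m = len(pending)
        flat = np.searchsorted(cdf, rng.random(m), side="right")
        idx = np.column_stack(np.unravel_index(flat, shape))
        pos = activity.index_to_world(idx) + rng.uniform(-0.5, 0.5, (m, 3)) * activity.spacing
        if sigma > 0:
            pos = pos + rng.normal(0.0, sigma, (m, 3))
        f = frame_idx[pending]
        pos = np.einsum("nij,nj->ni", R[f], pos) + s[f]
        d = _isotropic_directions(rng, m)
        a, b, ok = _cylinder_chord(pos, d, scanner.ring_radius_mm, half_axial)
        if attenuation is not None:
            surv = np.exp(-_chord_attenuation(attenuation, mats, f, a, b))
            ok_att = rng.random(m) < surv
            n_attenuated += int((ok & ~ok_att).sum())
            ok &= ok_att
        good = pending[ok]
        e1[good] = a[ok]
        e2[good] = b[ok]
        n_resampled += int((~ok).sum())
        pending = pending[~ok]
    events = ListModeData(times, scanner.snap(e1), scanner.snap(e2))
    info = {
        "n_events": n_events,
        "n_resampled": n_resampled,
        "n_attenuated": n_attenuated,
        "duration_s": duration,
    }
    return events, info


def _chord_attenuation(
    attenuation: ImageVolume,
    traj_mats: np.ndarray,
    frame_idx: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    step_mm: float = 2.0,
) -> np.ndarray:
    """Line integral of the *moved* attenuation map along each chord,
    evaluated by pulling sample points back to the reference pose."""
    n_steps = 256
    u = (np.arange(n_steps) + 0.5) / n_steps
    out = np.zeros(len(e1))
    Rinv = np.transpose(traj_mats[:, :3, :3], (0, 2, 1))
    t = traj_mats[:, :3, 3]
    for i in range(len(e1)):
        pts = e1[i] + u[:, None] * (e2[i] - e1[i])
        f = frame_idx[i]
        ref_pts = (pts - t[f]) @ Rinv[f].T
        mu = attenuation.sample_world(ref_pts)
        out[i] = mu.sum() * np.linalg.norm(e2[i] - e1[i]) / n_steps
    return out


@dataclasses.dataclass
class TimeWindow:
    """A reference-image time window: one contiguous span or several chunks."""

    intervals: list
    contiguous: bool = True

    @property
    def start(self) -> float:
        return float(self.intervals[0][0])

    @property
    def end(self) -> float:
        return float(self.intervals[-1][1])

    @property
    def duration_s(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def contains(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for s, e in self.intervals:
            mask |= (t >= s) & (t < e)
        return mask


def _relative_motion(
    mats: np.ndarray, base: np.ndarray, anchor: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Motion of each pose relative to ``base``: displacement (mm) of the
    anchor point (a point on the head — using the coordinate origin instead
    would inflate rotations by the camera's lever arm) and rotation (deg)."""
    base_inv = np.eye(4)
    base_inv[:3, :3] = base[:3, :3].T
    base_inv[:3, 3] = -base[:3, :3].T @ base[:3, 3]
    rel = np.einsum("nij,jk->nik", mats, base_inv)
    moved = rel[:, :3, :3] @ anchor + rel[:, :3, 3]
    trans = np.linalg.norm(moved - anchor, axis=1)
    tr = np.trace(rel[:, :3, :3], axis1=1, axis2=2)
    rot = np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0)))
    return trans, rot


def find_motionless_period(
    tracking: TrackingResult | MotionTrajectory,
    window_s: float = 20.0,
    trans_thresh_mm: float = 1.0,
    rot_thresh_deg: float = 1.0,
    anchor_point: np.ndarray | None = None,
) -> TimeWindow:
    """Earliest ~``window_s`` stretch in which the head barely moves.

    Primary: the earliest contiguous window in which every frame stays
    within both thresholds of the window's first frame.  Fallback (frequent
    movers): assemble discontinuous frames of near-identical pose totalling
    ``window_s``, flagged non-contiguous.  Raises
    :class:`NoMotionlessPeriodError` when neither exists.

    ``anchor_point``: a point on the tracked head (e.g. the face-model
    centroid, in the same frame as the transforms) at which translation is
    measured; defaults to the coordinate origin, appropriate for
    head-centered trajectories.
    """
    ts = np.asarray(tracking.timestamps, dtype=float)
    if len(ts) < 2:
        raise NoMotionlessPeriodError("tracking shorter than the window")
    dt = float(ts[1] - ts[0])
    w = int(round(window_s / dt))
    if len(ts) < w:
        raise NoMotionlessPeriodError("tracking shorter than the window")
    mats = np.stack([T.matrix for T in tracking.transforms])
    valid = getattr(tracking, "valid", np.ones(len(ts), dtype=bool))
    anchor = (
        np.zeros(3) if anchor_point is None else np.asarray(anchor_point, float)
    )

    for s0 in range(len(ts) - w + 1):
        if not valid[s0]:
            continue
        trans, rot = _relative_motion(mats[s0 : s0 + w], mats[s0], anchor)
        ok = (trans < trans_thresh_mm) & (rot < rot_thresh_deg) & valid[s0 : s0 + w]
        if np.all(ok):
            return TimeWindow([(ts[s0], ts[s0] + window_s)], contiguous=True)

    # fallback: pose-cluster assembly of discontinuous frames
    best_sel: np.ndarray | None = None
    stride = max(1, len(ts) // 400)
    for a in range(0, len(ts), stride):
        if not valid[a]:
            continue
        trans, rot = _relative_motion(mats, mats[a], anchor)
        sel = (trans < trans_thresh_mm) & (rot < rot_thresh_deg) & valid
        if best_sel is None or sel.sum() > best_sel.sum():
            best_sel = sel
    if best_sel is None or best_sel.sum() * dt < window_s:
        raise NoMotionlessPeriodError(
            "no pose cluster under the motion thresholds totals "
            f"{window_s} s"
        )
    # earliest frames of the winning cluster, up to window_s
    idx = np.flatnonzero(best_sel)[: w]
    intervals: list[tuple[float, float]] = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            intervals.append((ts[run_start], ts[prev] + dt))
            run_start = i
        prev = i
    intervals.append((ts[run_start], ts[prev] + dt))
    return TimeWindow(intervals, contiguous=len(intervals) == 1)


def select_events(events: ListModeData, window: TimeWindow) -> ListModeData:
    """Events whose timestamps fall inside the window (any sub-interval)."""
    if window.duration_s <= 0:
        raise EmptySelectionError("window has zero measure")
    mask = window.contains(events.t)
    if not mask.any():
        raise EmptySelectionError("no events inside the window")
    return events.select(mask)
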