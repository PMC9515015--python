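"""Digital head phantom and ground-truth motion trajectories.

The phantom stands in for a volunteer's head, CT and FDG uptake: a single
analytic geometry (triaxial ellipsoid head with a protruding nose and two
eye-socket indentations, so the eyes+nose patch carries the geometric
curvature that surface tracking needs) is rasterized into co-registered
activity, attenuation and VOI-label volumes and triangulated into a closed
surface mesh.  World frame conventions: head center at the origin, +y out
of the face (towards the depth camera), +z superior (the scanner axis).

Motion trajectories emulate a marker-viewing protocol: the subject holds a
pose, then turns to look at the next of eight wall markers; the scan is
split into three equal sets whose dwell times default to 60, 30 and 20 s.
Transitions are ~1 s smoothstep moves; dwells carry small physiological
jitter (sigma 0.2 mm / 0.1 deg).  Frames are at 10 fps, frame 0 is the
identity reference pose.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial.transform import Rotation, Slerp

from .transforms import (
    RigidTransform,
    motion_magnitude,
    pose_to_transform,
    PoseParameters,
)
from .volume import ImageVolume, centered_origin

__all__ = [
    "HeadPhantom",
    "MotionTrajectory",
    "MotionAmplitude",
    "LABELS",
    "SUVR_VOI_NAMES",
    "DEFAULT_UPTAKE",
    "make_head_phantom",
    "make_marker_trajectory",
    "make_static_trajectory",
    "marker_move_times",
]

FPS = 10.0  # camera/PET synchronized frame rate (frames per second)

# integer codes of the VOI label volume
LABELS = {
    "background": 0,
    "frontal": 1,
    "medial_temporal": 2,
    "lateral_temporal": 3,
    "parietal": 4,
    "occipital": 5,
    "posterior_cingulate_precuneus": 6,
    "striatum": 7,
    "cerebellum": 8,
    "inferior_colliculus_left": 9,
    "inferior_colliculus_right": 10,
    "white_matter": 11,
    "scalp": 12,
}
#: the eight regions entering the SUVR table (cerebellum is the reference)
SUVR_VOI_NAMES = (
    "frontal",
    "medial_temporal",
    "lateral_temporal",
    "parietal",
    "occipital",
    "posterior_cingulate_precuneus",
    "striatum",
    "cerebellum",
)

# Relative uptake per compartment (cerebellum := 1), following the regional
# pattern of cortical FDG uptake but spread so the cerebellar-normalized
# SUVRs span ~0.4-1.5: correlation-based test-retest statistics need the
# between-VOI variance to dominate the per-VOI counting noise, and with a
# near-uniform cortex the eight SUVR points collapse onto one value.
DEFAULT_UPTAKE = {
    "frontal": 1.15,
    "medial_temporal": 0.40,
    "lateral_temporal": 0.85,
    "parietal": 1.05,
    "occipital": 1.25,
    "posterior_cingulate_precuneus": 1.40,
    "striatum": 1.50,
    "cerebellum": 1.00,
    "inferior_colliculus": 1.50,
    "white_matter": 0.35,
    # extracerebral soft tissue: FDG scalp/muscle uptake is what makes the
    # no-attenuation-correction reference PET show the head (and nose)
    # outline that CT registration locks onto
    "scalp": 0.25,
}

MU_SOFT_TISSUE = 0.0096  # 1/mm at 511 keV
MU_BONE = 0.0171         # 1/mm

# head geometry (mm); see docs/methods.md
HEAD_SEMI_AXES = np.array([75.0, 85.0, 95.0])
NOSE_DIR = np.array([0.0, 1.0, -0.30])
NOSE_AMP_MM = 25.0
NOSE_SIGMA_RAD = 0.16
EYE_DIRS = (np.array([-0.42, 1.0, 0.12]), np.array([0.42, 1.0, 0.12]))
EYE_DEPTH_MM = 8.0
EYE_SIGMA_RAD = 0.11

BRAIN_CENTER = np.array([0.0, -8.0, 8.0])
BRAIN_SEMI_AXES = np.array([58.0, 62.0, 70.0])
GM_SHELL_INNER = 0.82          # brain-ellipsoid radius where cortex begins
SKULL_INNER, SKULL_OUTER = 1.03, 1.17  # skull shell in brain-ellipsoid radii
STRIATUM_OFFSETS = (np.array([-22.0, 8.0, 6.0]), np.array([22.0, 8.0, 6.0]))
STRIATUM_SEMI_AXES = np.array([11.0, 18.0, 13.0])
IC_OFFSETS = (np.array([-4.0, -16.0, -38.0]), np.array([4.0, -16.0, -38.0]))
IC_RADIUS_MM = 3.0             # 6 mm diameter nuclei


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _radial_bump(units: np.ndarray) -> np.ndarray:
    """Radial surface offset (mm) at unit directions: nose out, eye sockets in."""
    ang_nose = np.arccos(np.clip(units @ _unit(NOSE_DIR), -1.0, 1.0))
    delta = NOSE_AMP_MM * np.exp(-0.5 * (ang_nose / NOSE_SIGMA_RAD) ** 2)
    for d in EYE_DIRS:
        ang = np.arccos(np.clip(units @ _unit(d), -1.0, 1.0))
        delta -= EYE_DEPTH_MM * np.exp(-0.5 * (ang / EYE_SIGMA_RAD) ** 2)
    return delta


def _head_surface_mesh(subdivisions: int) -> trimesh.Trimesh:
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    units = sphere.vertices / np.linalg.norm(sphere.vertices, axis=1, keepdims=True)
    base = units * HEAD_SEMI_AXES  # point on the unperturbed ellipsoid
    scale = 1.0 + _radial_bump(units) / np.linalg.norm(base, axis=1)
    return trimesh.Trimesh(base * scale[:, None], sphere.faces, process=False)


def _head_mask(points: np.ndarray) -> np.ndarray:
    """Inside-head test for (N, 3) world points, consistent with the mesh.

    A point p with unit direction u is inside iff its ellipsoid norm
    |p / semi| stays below 1 + bump(u) / |q(u)|, where q(u) is the point of
    the unperturbed ellipsoid in direction u (the same radial-offset rule
    the mesh vertices follow).
    """
    e = np.linalg.norm(points / HEAD_SEMI_AXES, axis=-1)
    r = np.linalg.norm(points, axis=-1)
    nz = r > 1e-9
    units = np.zeros_like(points)
    units[nz] = points[nz] / r[nz, None]
    base_r = 1.0 / np.maximum(
        np.linalg.norm(units / HEAD_SEMI_AXES, axis=-1), 1e-12
    )  # |q(u)|
    thresh = 1.0 + np.where(nz, _radial_bump(units) / base_r, 0.0)
    return e <= thresh


@dataclasses.dataclass
class HeadPhantom:
    """Co-registered face surface, activity, attenuation and VOI labels."""

    surface_mesh: trimesh.Trimesh
    activity: ImageVolume
    attenuation: ImageVolume
    voi_labels: ImageVolume
    uptake: dict

    def label_mask(self, name: str) -> np.ndarray:
        return self.voi_labels.values == LABELS[name]

    def label_centroid_mm(self, name: str) -> np.ndarray:
        idx = np.argwhere(self.label_mask(name))
        if len(idx) == 0:
            raise ValueError(f"label '{name}' is empty")
        return self.voi_labels.index_to_world(idx.mean(axis=0))

    def save(self, directory: str) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.surface_mesh.export(os.path.join(directory, "head_surface.ply"))
        self.activity.to_nifti(os.path.join(directory, "activity.nii.gz"))
        self.attenuation.to_nifti(os.path.join(directory, "attenuation.nii.gz"))
        self.voi_labels.to_nifti(os.path.join(directory, "voi_labels.nii.gz"))


def make_head_phantom(
    grid_shape: Sequence[int] = (64, 64, 64),
    voxel_mm: float | Sequence[float] = 3.0,
    seed: int = 0,
    mesh_subdivisions: int = 5,
    uptake: dict | None = None,
) -> HeadPhantom:
    """Build the default head phantom on a centered grid.

    Deterministic for fixed arguments (the seed is kept for interface
    stability; the geometry itself is analytic).  Raises if the grid does
    not contain the ~190 mm head.
    """
    del seed  # geometry is analytic and deterministic
    uptake = dict(DEFAULT_UPTAKE if uptake is None else uptake)
    shape = tuple(int(s) for s in grid_shape)
    spacing = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    extent = (np.array(shape) - 1) * spacing
    need = 2 * HEAD_SEMI_AXES * np.array([1.0, 1.0, 1.0])
    if np.any(extent + spacing < need * 0.98):
        raise ValueError(
            f"grid extent {extent + spacing} mm too small for the ~{need} mm head"
        )
    origin = centered_origin(shape, spacing)
    grid = ImageVolume(np.zeros(shape, dtype=np.float32), spacing, origin)
    pts = grid.voxel_center_grid().reshape(-1, 3)

    head = _head_mask(pts).reshape(shape)

    # brain-ellipsoid normalized coordinates
    bc = (pts - BRAIN_CENTER) / BRAIN_SEMI_AXES
    e_b = np.linalg.norm(bc, axis=1).reshape(shape)
    xi, eta, zeta = (bc[:, a].reshape(shape) for a in range(3))

    brain = e_b <= 1.0
    gm = brain & (e_b > GM_SHELL_INNER)
    wm = brain & ~gm

    labels = np.zeros(shape, dtype=np.int16)
    labels[wm] = LABELS["white_matter"]

    # cerebellum: inferior-posterior brain (its own compartment, not cortex)
    cereb = brain & (zeta < -0.45) & (eta < -0.05)
    labels[cereb] = LABELS["cerebellum"]

    # cortical lobes on the gray-matter shell (decision list, first hit wins)
    shell = gm & ~cereb
    unassigned = shell.copy()

    def take(cond: np.ndarray, name: str) -> None:
        sel = unassigned & cond
        labels[sel] = LABELS[name]
        unassigned[sel] = False

    take(eta <= -0.55, "occipital")
    take((np.abs(xi) <= 0.30) & (eta <= -0.10) & (zeta >= 0.10),
         "posterior_cingulate_precuneus")
    take(zeta >= 0.55, "parietal")
    take(eta >= 0.25, "frontal")
    take((zeta < 0.05) & (np.abs(xi) <= 0.55), "medial_temporal")
    take(np.abs(xi) > 0.55, "lateral_temporal")
    take(np.ones(shape, dtype=bool), "parietal")  # remaining mid-shell

    for off in STRIATUM_OFFSETS:
        c = BRAIN_CENTER + off
        d = np.linalg.norm((pts - c) / STRIATUM_SEMI_AXES, axis=1).reshape(shape)
        labels[(d <= 1.0) & brain] = LABELS["striatum"]

    for off, side in zip(IC_OFFSETS, ("left", "right")):
        c = BRAIN_CENTER + off
        d = np.linalg.norm(pts - c, axis=1).reshape(shape)
        labels[(d <= IC_RADIUS_MM) & brain] = LABELS[f"inferior_colliculus_{side}"]

    activity = np.zeros(shape, dtype=np.float32)
    for name, code in LABELS.items():
        if name in ("background",):
            continue
        key = (
            "inferior_colliculus"
            if name.startswith("inferior_colliculus")
            else name
        )
        activity[labels == code] = uptake[key]

    attenuation = np.zeros(shape, dtype=np.float32)
    attenuation[head] = MU_SOFT_TISSUE
    skull = head & (e_b > SKULL_INNER) & (e_b <= SKULL_OUTER)
    attenuation[skull] = MU_BONE

    scalp = head & ~brain & ~skull
    labels[scalp] = LABELS["scalp"]
    activity[scalp] = uptake["scalp"]

    mesh = _head_surface_mesh(mesh_subdivisions)
    return HeadPhantom(
        surface_mesh=mesh,
        activity=grid.copy_with(activity),
        attenuation=grid.copy_with(attenuation),
        voi_labels=grid.copy_with(labels),
        uptake=uptake,
    )


# ---------------------------------------------------------------------
# motion trajectories
# ---------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MotionAmplitude:
    translation_mm: float = 30.0
    rotation_deg: float = 25.0


@dataclasses.dataclass
class MotionTrajectory:
    """Head pose per 10-fps frame, relative to the frame-0 reference pose."""

    timestamps: np.ndarray
    transforms: list[RigidTransform]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.transforms):
            raise ValueError("timestamps and transforms length mismatch")
        dt = np.diff(self.timestamps)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], atol=1e-9)):
            raise ValueError("timestamps must be strictly increasing and uniform")

    def __len__(self) -> int:
        return len(self.transforms)

    @property
    def dt(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0]) if len(self) > 1 else 1.0 / FPS

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] + self.dt) if len(self) else 0.0

    def frame_index(self, t: np.ndarray | float) -> np.ndarray:
        idx = np.floor((np.asarray(t, dtype=float) - self.timestamps[0]) / self.dt)
        return np.clip(idx, 0, len(self) - 1).astype(np.int64)

    def transform_at(self, t: float) -> RigidTransform:
        return self.transforms[int(self.frame_index(t))]

    def matrices(self) -> np.ndarray:
        return np.stack([T.matrix for T in self.transforms])

    def magnitudes(self) -> np.ndarray:
        """(N, 2) array of (translation mm, rotation deg) per frame."""
        return np.array([motion_magnitude(T) for T in self.transforms])

    # CSV dialect: t, r11..r33, sx, sy, sz — same as tracking output
    def to_csv(self, path: str) -> None:
        rows = np.column_stack(
            [self.timestamps, np.stack([T.to_flat12() for T in self.transforms])]
        )
        cols = ["t"] + [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)] + [
            "sx",
            "sy",
            "sz",
        ]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "MotionTrajectory":
        df = pd.read_csv(path)
        ts = df["t"].to_numpy()
        Ts = [RigidTransform.from_flat12(row) for row in df.iloc[:, 1:13].to_numpy()]
        return cls(ts, Ts)


def make_static_trajectory(duration_s: float, fps: float = FPS) -> MotionTrajectory:
    """Identity pose at every frame (head-fixed scan analog)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * fps))
    ident = RigidTransform.identity()
    return MotionTrajectory(np.arange(n) / fps, [ident] * n)


def marker_move_times(
    duration_s: float, schedule: Sequence[float] = (60.0, 30.0, 20.0)
) -> list[float]:
    """Dwell-to-dwell move times: every ``schedule[s]`` seconds within set s.

    For 900 s with the default 60/30/20-s schedule this yields
    5 + 10 + 15 = 30 moves (a move falling exactly on the scan end is part
    of the protocol count but affects no frame).
    """
    set_len = duration_s / len(schedule)
    times: list[float] = []
    for s, dwell in enumerate(schedule):
        t = s * set_len + dwell
        while t <= (s + 1) * set_len + 1e-9 and t <= duration_s + 1e-9:
            times.append(round(t, 9))
            t += dwell
    return sorted(set(times))


# eight wall markers: (yaw fraction, pitch fraction) in a 2 x 4 layout
_MARKER_FRACTIONS = [
    (-1.0, 0.5), (-1.0 / 3.0, 0.5), (1.0 / 3.0, 0.5), (1.0, 0.5),
    (1.0, -0.5), (1.0 / 3.0, -0.5), (-1.0 / 3.0, -0.5), (-1.0, -0.5),
]


def _marker_poses(amplitude: MotionAmplitude) -> list[RigidTransform]:
    """Dwell poses for the 8 markers; peaks at 95% of the amplitude so dwell
    jitter cannot push a frame past the configured cap."""
    fr = np.array(_MARKER_FRACTIONS)
    tvec = np.column_stack([fr[:, 0], 0.25 * np.abs(fr[:, 0]), fr[:, 1]])
    tvec *= 0.95 * amplitude.translation_mm / np.linalg.norm(tvec, axis=1).max()

    yaw = fr[:, 0].copy()
    pitch = fr[:, 1].copy()
    scale = amplitude.rotation_deg / max(np.hypot(yaw, pitch).max(), 1e-9)
    poses = []
    for k in range(8):
        for _ in range(4):  # rescale so the combined angle meets the cap
            T = pose_to_transform(
                PoseParameters(
                    *tvec[k],
                    rx=pitch[k] * scale,
                    ry=0.0,
                    rz=yaw[k] * scale,
                )
            )
            _, rot = motion_magnitude(T)
            if rot <= 0.95 * amplitude.rotation_deg or rot < 1e-9:
                break
            scale *= 0.95 * amplitude.rotation_deg / rot
        poses.append(T)
    return poses


def _interp_pose(A: RigidTransform, B: RigidTransform, alpha: float) -> RigidTransform:
    rots = Rotation.from_matrix(np.stack([A.rotation, B.rotation]))
    R = Slerp([0.0, 1.0], rots)(alpha).as_matrix()
    t = (1 - alpha) * A.translation + alpha * B.translation
    return RigidTransform.from_rotation_translation(R, t)


def make_marker_trajectory(
    duration_s: float,
    schedule: Sequence[float] = (60.0, 30.0, 20.0),
    amplitude: MotionAmplitude = MotionAmplitude(),
    seed: int = 0,
    fps: float = FPS,
    transition_s: float = 1.0,
    jitter_mm: float = 0.2,
    jitter_deg: float = 0.1,
) -> MotionTrajectory:
    """Piecewise-stationary marker-viewing trajectory.

    The scan is split into ``len(schedule)`` equal sets; within set ``s``
    the head moves to the next marker every ``schedule[s]`` seconds
    (60/30/20 s by default — for a 15-min scan that is 5 + 10 + 15 = 30
    moves).  Dwell poses cycle through the 8 markers in ascending order,
    starting from the identity reference pose.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if amplitude.translation_mm > 60.0 or amplitude.rotation_deg > 45.0:
        raise ValueError(
            "amplitude beyond the trackable range (60 mm / 45 deg): at larger "
            "rotations the eyes+nose patch leaves the camera's view"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    ts = np.arange(n) / fps
    move_times = marker_move_times(duration_s, schedule)

    markers = _marker_poses(amplitude)
    ident = RigidTransform.identity()
    dwell_pose = lambda j: ident if j == 0 else markers[(j - 1) % 8]

    bounds = np.array([0.0] + move_times + [duration_s])
    transforms: list[RigidTransform] = []
    for i, t in enumerate(ts):
        j = int(np.searchsorted(bounds, t, side="right") - 1)
        cur, prev = dwell_pose(j), dwell_pose(j - 1) if j > 0 else ident
        t_move = bounds[j]
        in_transition = j > 0 and (t - t_move) < transition_s
        if in_transition:
            u = (t - t_move) / transition_s
            alpha = u * u * (3 - 2 * u)  # smoothstep
            T = _interp_pose(prev, cur, float(alpha))
        else:
            T = cur
        if i > 0 and not in_transition:  # physiological jitter on dwells only
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            jR = Rotation.from_rotvec(
                axis * np.radians(rng.normal(0.0, jitter_deg))
            ).as_matrix()
            jt = rng.normal(0.0, jitter_mm, size=3)
            T = RigidTransform.from_rotation_translation(jR, jt) @ T
        transforms.append(T if i > 0 else ident)
    return MotionTrajectory(ts, transforms)
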